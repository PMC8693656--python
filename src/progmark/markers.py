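"""Marker extraction from score strata, surface filtering, species mapping.

Differential expression between the score-low and score-high strata uses the
Mann-Whitney rank-sum test (exact p by enumeration for small tie-free
comparisons, tie-corrected normal approximation with continuity correction
otherwise) with Benjamini-Hochberg FDR control over all tested genes.
Candidates pass at the conventional thresholds fold change > 2 and
FDR < 0.05, are ordered significance-first (q, then log2FC descending, then
symbol; a pure-log2FC ordering is available), and the top ``n_top`` are
reported. The surface filter then keeps only surface-molecule genes — the
step that turns a list dominated by lineage-restricted effectors into an
actionable sorting marker.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError, NumericError
from .io import GeneSet, OrthologTable, SurfaceAnnotation
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

#: largest combined sample size for the exact rank-sum path
EXACT_MAX_N = 12


@dataclass
class MarkerResult:
    """Per-gene differential statistics for one candidate marker."""

    symbol: str
    log2fc: float
    u_statistic: float
    p: float
    q: float
    is_surface: bool | None = None
    rank: int = 0


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when |a|+|b| <= 12 and there are no ties;
    otherwise the normal approximation with tie-corrected variance and
    continuity correction. Returns (U statistic of ``a``, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("rank_sum_test: both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    n = a.size + b.size
    has_ties = np.unique(pooled).size < n
    if n <= EXACT_MAX_N and not has_ties:
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise DataError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _strata_groups(strata: pd.DataFrame) -> tuple[list, list]:
    """Cell ids of the (low-like, high-like) extreme strata."""
    labels = set(strata["stratum"].dropna().unique())
    if "low" in labels:
        low_label = "low"
    elif "neg" in labels:
        low_label = "neg"
    else:
        raise NumericError(f"no low/neg stratum present (found {sorted(map(str, labels))})")
    if "high" not in labels:
        raise NumericError(f"no high stratum present (found {sorted(map(str, labels))})")
    low = strata.index[strata["stratum"] == low_label].tolist()
    high = strata.index[strata["stratum"] == "high"].tolist()
    return low, high


def differential_table(sc, strata: pd.DataFrame) -> pd.DataFrame:
    """Rank-sum DE of every gene between the low and high strata.

    Returns a DataFrame indexed by symbol with columns log2fc (mean low -
    mean high on the log scale), u_statistic, p and BH-adjusted q over all
    tested genes. Genes with zero expression in both strata are skipped and
    logged; mid-stratum cells are excluded.
    """
    df = sc.data if isinstance(sc, ExpressionMatrix) else pd.DataFrame(sc)
    low, high = _strata_groups(strata)
    if not low or not high:
        raise NumericError("empty stratum: both extreme strata need >= 1 cell")
    lo = df[low].to_numpy(dtype=float)
    hi = df[high].to_numpy(dtype=float)
    tested = ~((lo == 0).all(axis=1) & (hi == 0).all(axis=1))
    n_skipped = int((~tested).sum())
    if n_skipped:
        logger.info("differential_table: %d gene(s) with zero expression in both strata skipped",
                    n_skipped)
    symbols = df.index[tested]
    lo, hi = lo[tested], hi[tested]
    log2fc = lo.mean(axis=1) - hi.mean(axis=1)

    n_small = len(low) + len(high) <= EXACT_MAX_N
    constant = (np.concatenate([lo, hi], axis=1) ==
                np.concatenate([lo, hi], axis=1)[:, :1]).all(axis=1)
    if n_small:
        stats = np.array([rank_sum_test(lo[i], hi[i]) for i in range(lo.shape[0])])
        u, p = stats[:, 0], stats[:, 1]
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = mannwhitneyu(lo, hi, alternative="two-sided", method="asymptotic",
                               use_continuity=True, axis=1)
        u, p = np.asarray(res.statistic, float), np.asarray(res.pvalue, float)
        u[constant] = len(low) * len(high) / 2.0
        p[constant] = 1.0
    q = bh_adjust(p)
    out = pd.DataFrame(
        {"log2fc": log2fc, "u_statistic": u, "p": p, "q": q},
        index=pd.Index(symbols, name="symbol"),
    )
    return out


def find_markers(
    sc,
    strata: pd.DataFrame,
    direction: str = "low-vs-high",
    n_top: int = 10,
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    order_by: str = "significance",
) -> list[MarkerResult]:
    """Top genes upregulated in the score-low stratum.

    Genes passing ``log2fc >= log2(fc_threshold)`` (flipped for
    direction="high-vs-low") and ``q <= q_threshold`` are ordered by
    (q ascending, log2fc descending, symbol) — or pure log2FC with
    ``order_by="log2fc"`` — and the top ``n_top`` returned with ranks 1..k.
    """
    if n_top < 1:
        raise ConfigError(f"n_top must be >= 1, got {n_top}")
    if direction not in ("low-vs-high", "high-vs-low"):
        raise ConfigError(f"unknown direction {direction!r}")
    if order_by not in ("significance", "log2fc"):
        raise ConfigError(f"unknown ordering {order_by!r}")
    table = differential_table(sc, strata)
    effect = table["log2fc"] if direction == "low-vs-high" else -table["log2fc"]
    passing = table[(effect >= math.log2(fc_threshold)) & (table["q"] <= q_threshold)].copy()
    passing["effect"] = effect[passing.index]
    passing = passing.loc[sorted(passing.index)]
    if order_by == "significance":
        passing = passing.sort_values(by=["q", "effect"], ascending=[True, False],
                                      kind="mergesort")
    else:
        passing = passing.sort_values(by=["effect", "q"], ascending=[False, True],
                                      kind="mergesort")
    results = [
        MarkerResult(
            symbol=str(sym),
            log2fc=float(row["log2fc"]),
            u_statistic=float(row["u_statistic"]),
            p=float(row["p"]),
            q=float(row["q"]),
            rank=i + 1,
        )
        for i, (sym, row) in enumerate(passing.head(n_top).iterrows())
    ]
    logger.info("find_markers: %d/%d gene(s) passed fc>%g, q<=%g; reporting top %d",
                len(passing), len(table), fc_threshold, q_threshold, len(results))
    return results


def filter_surface(results: list[MarkerResult], ann: SurfaceAnnotation) -> list[MarkerResult]:
    """Keep surface-molecule candidates, preserving order, renumbering ranks.

    Genes absent from the annotation are treated as non-surface and counted
    in a logged summary. An annotation with no surface gene at all is
    rejected as a misloaded file.
    """
    if ann.n_surface == 0:
        raise DataError("surface annotation contains no surface gene at all "
                        "(misloaded annotation file?)")
    kept: list[MarkerResult] = []
    n_unannotated = 0
    for r in results:
        flag = ann.is_surface(r.symbol)
        if flag is None:
            n_unannotated += 1
            continue
        if flag:
            kept.append(
                MarkerResult(symbol=r.symbol, log2fc=r.log2fc, u_statistic=r.u_statistic,
                             p=r.p, q=r.q, is_surface=True, rank=len(kept) + 1)
            )
    if n_unannotated:
        logger.info("filter_surface: %d candidate(s) unannotated, treated as non-surface",
                    n_unannotated)
    if not kept:
        logger.warning("filter_surface: no surface candidate among %d marker(s)", len(results))
    return kept


def map_symbols(
    gene_set: GeneSet,
    target_species: str,
    table: OrthologTable | None = None,
) -> GeneSet:
    """Map a gene set's symbols to another species.

    With an ortholog table, symbols map by exact match (one-to-many
    mappings expand, with a logged ambiguity flag; unmapped symbols drop
    with a warning). Without a table, the symbol-case heuristic applies:
    mouse→human upper-cases, human→mouse capitalizes (first letter upper,
    rest lower).
    """
    source_species = gene_set.species
    if source_species is None:
        raise ConfigError(f"gene set {gene_set.name!r} has no species tag")
    if source_species == target_species:
        raise ConfigError(f"source and target species are both {target_species!r}")

    mapped: list[str] = []
    if table is not None:
        lookup = table.mapping(source_species, target_species)
        n_unmapped = n_ambiguous = 0
        for sym in gene_set.members:
            targets = lookup.get(sym)
            if not targets:
                n_unmapped += 1
                continue
            if len(targets) > 1:
                n_ambiguous += 1
                logger.warning("map_symbols: %r maps one-to-many: %s", sym, targets)
            mapped.extend(targets)
        if n_unmapped:
            logger.warning("map_symbols: %d symbol(s) of %r absent from the ortholog table, dropped",
                           n_unmapped, gene_set.name)
    else:
        if (source_species, target_species) == ("mouse", "human"):
            mapped = [s.upper() for s in gene_set.members]
        elif (source_species, target_species) == ("human", "mouse"):
            mapped = [s[:1].upper() + s[1:].lower() for s in gene_set.members]
        else:
            raise ConfigError(
                f"no case heuristic for {source_species!r}->{target_species!r}; "
                "provide an ortholog table"
            )
    deduped = list(dict.fromkeys(mapped))
    if not deduped:
        raise DataError(f"no symbol of {gene_set.name!r} could be mapped to {target_species!r}")
    return GeneSet(
        name=gene_set.name,
        members=deduped,
        species=target_species,
        description=gene_set.description,
    )
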
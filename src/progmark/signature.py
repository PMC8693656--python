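"""Population signatures and per-cell summed Z-score stratification.

The discovery logic: rank genes by their log-scale mean difference between
two bulk populations and take the top k as the population's signature
(k=10 for scoring, k=200 for enrichment validation); standardize each gene
across single cells; score each cell by the sum of the signature genes'
Z-scores; split cells into score tertiles (top third "high", bottom third
"low"). Cells can alternatively be trisected by one marker gene's own
expression (negative / intermediate / high), to compare signature scores
across marker-defined strata.

Z-scores are computed per gene across all cells of the analyzed matrix
(the only orientation under which per-cell summation is defined); the
sample (n-1) standard deviation is used and zero-variance genes contribute
zero. A consequence used by the tests: summed scores over the cells they
were computed on total zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NumericError
from .io import GeneSet
from .matrix import SCALE_LOG_TPM, ExpressionMatrix

logger = logging.getLogger(__name__)

#: stratum labels by score tertile and by marker-gene trisection
SCORE_STRATA = ("low", "mid", "high")
MARKER_STRATA = ("neg", "int", "high")


def _as_frame(x) -> pd.DataFrame:
    return x.data if isinstance(x, ExpressionMatrix) else pd.DataFrame(x)


def _population_columns(columns: pd.Index, label: str) -> list[str]:
    """Columns belonging to a population: exact match or '<label>_<rep>'."""
    cols = [c for c in columns if c == label or str(c).startswith(label + "_")]
    return cols


def derive_signature(
    bulk: ExpressionMatrix,
    pop_a: str,
    pop_b: str,
    k: int,
    min_mean: float = 0.0,
    name: str | None = None,
    species: str | None = None,
) -> GeneSet:
    """Top-k genes most highly expressed in ``pop_a`` relative to ``pop_b``.

    Genes are ranked by the log-scale mean difference
    ``delta = mean(pop_a) - mean(pop_b)`` (a log2 fold change, since the
    matrix is on the log2(TPM+1) scale), descending; genes with
    ``mean(pop_a) < min_mean`` are excluded; ties break by larger
    ``mean(pop_a)``, then lexicographic symbol. Swapping the labels yields
    the opposite population's signature.
    """
    if bulk.scale != SCALE_LOG_TPM:
        raise DataError(f"derive_signature expects log2(TPM+1) input, got {bulk.scale!r}")
    if k < 1:
        raise ConfigError(f"signature size k must be >= 1, got {k}")
    cols_a = _population_columns(bulk.columns, pop_a)
    cols_b = _population_columns(bulk.columns, pop_b)
    if not cols_a:
        raise DataError(f"unknown population label {pop_a!r}")
    if not cols_b:
        raise DataError(f"unknown population label {pop_b!r}")

    mean_a = bulk.data[cols_a].mean(axis=1)
    mean_b = bulk.data[cols_b].mean(axis=1)
    eligible = mean_a >= min_mean
    n_eligible = int(eligible.sum())
    if k > n_eligible:
        raise DataError(
            f"requested k={k} signature genes but only {n_eligible} are eligible "
            f"(min_mean={min_mean}); shortfall of {k - n_eligible}"
        )
    delta = (mean_a - mean_b)[eligible]
    if delta.nunique() == 1:
        logger.warning("derive_signature: all %d eligible genes are tied (delta=%g)",
                       n_eligible, float(delta.iloc[0]))
    order = pd.DataFrame({"delta": delta, "mean_a": mean_a[eligible]})
    # mergesort is stable; pre-sorting by symbol realizes the lexicographic tie-break
    order = order.loc[sorted(order.index)].sort_values(
        by=["delta", "mean_a"], ascending=[False, False], kind="mergesort"
    )
    members = [str(g) for g in order.index[:k]]
    return GeneSet(
        name=name or f"{pop_a}_top{k}",
        members=members,
        species=species,
        description=f"top {k} genes by mean log2(TPM+1) difference {pop_a} - {pop_b}",
    )


def zscore_by_gene(sc) -> pd.DataFrame:
    """Standardize each gene across cells: z = (x - mean) / sd, ddof=1.

    Zero-variance genes map to all-zero rows. Accepts an ExpressionMatrix
    or a plain genes x cells DataFrame; returns a DataFrame of the same shape.
    """
    df = _as_frame(sc)
    if df.shape[1] < 2:
        raise DataError(f"zscore_by_gene needs >= 2 cells, got {df.shape[1]}")
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def score_cells(z: pd.DataFrame, gene_set: GeneSet) -> pd.DataFrame:
    """Per-cell summed Z-score over the set's genes present in the matrix.

    Returns a CellScoreTable: DataFrame indexed by cell identifier with
    columns ``score`` (float) and ``stratum`` (empty until stratification).
    Absent set members are logged and skipped; zero overlap is an error.
    """
    present = [g for g in gene_set.members if g in z.index]
    missing = [g for g in gene_set.members if g not in z.index]
    if not present:
        raise DataError(
            f"no member of gene set {gene_set.name!r} is present in the matrix; "
            f"missing symbols: {missing}"
        )
    if missing:
        logger.warning("score_cells: %d/%d member(s) of %r absent and skipped: %s",
                       len(missing), gene_set.k, gene_set.name, missing[:10])
    scores = z.loc[present].sum(axis=0)
    table = pd.DataFrame({"score": scores.astype(float), "stratum": pd.NA})
    table.index.name = "cell"
    if not np.isfinite(table["score"]).all():
        raise NumericError("non-finite cell score encountered")
    return table


def stratify_tertiles(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign score tertile strata: top floor(n/3) cells "high", bottom
    floor(n/3) "low", remainder "mid".

    Cells are ordered by (score descending, cell identifier ascending), so
    assignment is deterministic under ties and invariant to input order.
    """
    n = len(scores)
    if n < 3:
        raise NumericError(f"tertile stratification needs >= 3 cells, got {n}")
    out = scores.copy()
    order = out.reset_index()
    cell_col = order.columns[0]
    order = order.sort_values(by=["score", cell_col], ascending=[False, True], kind="mergesort")
    k = n // 3
    strata = np.array(["mid"] * n, dtype=object)
    strata[:k] = "high"
    strata[n - k:] = "low"
    out.loc[order[cell_col].to_numpy(), "stratum"] = strata
    return out


def stratify_by_gene(
    sc,
    gene: str,
    boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> pd.DataFrame:
    """Trisect cells by one gene's own expression into neg / int / high.

    Boundaries are empirical quantiles (lower interpolation) of the gene's
    expression; cells at or below the first quantile — and always cells with
    zero expression — are "neg", cells above the second are "high", the rest
    "int". The returned CellScoreTable's ``score`` column holds the gene's
    expression values.
    """
    df = _as_frame(sc)
    if gene not in df.index:
        raise DataError(f"gene {gene!r} not present in the matrix")
    q1, q2 = boundaries
    if not (0.0 < q1 < q2 < 1.0):
        raise ConfigError(f"quantile boundaries must satisfy 0 < q1 < q2 < 1, got {boundaries}")
    x = df.loc[gene].astype(float)
    lo = float(np.quantile(x.to_numpy(), q1, method="lower"))
    hi = float(np.quantile(x.to_numpy(), q2, method="lower"))
    strata = np.where(x > hi, "high", np.where(x <= lo, "neg", "int"))
    strata[(x == 0).to_numpy()] = "neg"
    if (x == 0).all():
        logger.warning("stratify_by_gene: %r has zero expression in every cell; all cells 'neg'", gene)
    table = pd.DataFrame({"score": x, "stratum": strata})
    table.index.name = "cell"
    return table
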
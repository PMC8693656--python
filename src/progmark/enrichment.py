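"""Gene-set enrichment: weighted running-sum statistic with a permutation null.

Genes are ranked by a signal-to-noise metric between two cell/sample groups
(standard-deviation floors as in the reference GSEA tool; log2FC fallback for
tiny groups). Walking the ranked list, set members ("hits") increment a
running sum by |metric|^p normalized over hits and non-members decrement by
1/(N - N_hits); the enrichment score ES is the running-sum value of maximal
absolute deviation, sign preserved. The null is gene-label permutation:
random same-size gene sets drawn without replacement. The permutation p-value
is one-sided in the direction of the observed ES, computed within the
sign-matched null class with a +1 correction (so it is never zero and is
uniform under the null); NES divides ES by the mean |null ES| of the same
sign and is flagged undefined when no null shares the sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, NumericError
from .io import GeneSet
from .markers import rank_sum_test
from .matrix import ExpressionMatrix
from .signature import score_cells, zscore_by_gene

logger = logging.getLogger(__name__)

#: relative and absolute floors on the per-group standard deviation,
#: the reference tool's signal-to-noise adjustment
SD_FLOOR_REL = 0.2
SD_FLOOR_ABS = 0.2


@dataclass
class RankedList:
    """Gene symbols ordered by a descending ranking metric (ties: symbol)."""

    symbols: list[str]
    metric: np.ndarray

    def __post_init__(self):
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.symbols) != self.metric.size:
            raise DataError("RankedList: symbols and metric lengths differ")
        if len(set(self.symbols)) != len(self.symbols):
            raise DataError("RankedList: duplicate symbols")
        if not np.isfinite(self.metric).all():
            raise DataError("RankedList: non-finite metric values")
        if np.any(np.diff(self.metric) > 0):
            raise DataError("RankedList: metric must be descending")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    nes_defined: bool
    p_perm: float
    n_perm: int
    leading_edge: list[str]
    seed: int
    running_sum: np.ndarray = field(repr=False, default=None)


def _ranked_from_metric(metric: pd.Series) -> RankedList:
    order = metric.loc[sorted(metric.index.astype(str))]
    order = order.sort_values(ascending=False, kind="mergesort")
    return RankedList(symbols=[str(s) for s in order.index], metric=order.to_numpy())


def signal_to_noise(expr, group_a, group_b) -> RankedList:
    """Per-gene (mu_a - mu_b) / (sigma_a + sigma_b) with floored sigmas.

    Each group's sd is floored at max(0.2*|mu|, 0.2). Falls back to the
    log-scale mean difference (log2FC) with a warning when either group has
    fewer than 2 members. Groups must not overlap.
    """
    df = expr.data if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise DataError(f"groups overlap: {sorted(overlap)[:5]}")
    for g in (group_a, group_b):
        missing = [c for c in g if c not in df.columns]
        if missing:
            raise DataError(f"unknown column(s): {missing[:5]}")
    if not group_a or not group_b:
        raise DataError("signal_to_noise: both groups must be non-empty")
    a = df[group_a].to_numpy(dtype=float)
    b = df[group_b].to_numpy(dtype=float)
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    if a.shape[1] < 2 or b.shape[1] < 2:
        logger.warning("signal_to_noise: group with < 2 members; falling back to log2FC metric")
        metric = mu_a - mu_b
    else:
        sd_a = np.maximum(a.std(axis=1, ddof=1), np.maximum(SD_FLOOR_REL * np.abs(mu_a), SD_FLOOR_ABS))
        sd_b = np.maximum(b.std(axis=1, ddof=1), np.maximum(SD_FLOOR_REL * np.abs(mu_b), SD_FLOOR_ABS))
        metric = (mu_a - mu_b) / (sd_a + sd_b)
    return _ranked_from_metric(pd.Series(metric, index=df.index))


def _running_sum(hit_mask: np.ndarray, metric: np.ndarray, weight_p: float) -> np.ndarray:
    n = hit_mask.size
    n_hits = int(hit_mask.sum())
    weights = np.abs(metric) ** weight_p
    hit_total = weights[hit_mask].sum()
    if hit_total == 0:
        # all hit weights zero (e.g. zero metric with p>0): fall back to equal steps
        weights = np.ones(n)
        hit_total = float(n_hits)
    steps = np.where(hit_mask, weights / hit_total, -1.0 / (n - n_hits))
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, list[str], np.ndarray]:
    """ES, leading-edge genes and the full running sum for one set.

    ES is the running-sum value of maximal absolute deviation from zero
    (first such position; sign preserved). The leading edge comprises set
    members at or before the extremum for positive ES, and strictly after
    it for negative ES.
    """
    members = set(gene_set.members)
    hit_mask = np.array([s in members for s in ranked.symbols])
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise DataError(f"gene set {gene_set.name!r} shares no gene with the ranked list")
    if n_hits == len(ranked):
        raise DataError(f"gene set {gene_set.name!r} covers the entire ranked list")
    running = _running_sum(hit_mask, ranked.metric, weight_p)
    i = int(np.argmax(np.abs(running)))
    es = float(running[i])
    if es >= 0:
        leading = [s for s, h in zip(ranked.symbols[: i + 1], hit_mask[: i + 1]) if h]
    else:
        leading = [s for s, h in zip(ranked.symbols[i + 1 :], hit_mask[i + 1 :]) if h]
    return es, leading, running


def gsea_from_ranked(
    ranked: RankedList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """GSEA of one set against a precomputed ranked list (gene-label null)."""
    if n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100, got {n_perm}")
    members_in_list = [s for s in gene_set.members if s in set(ranked.symbols)]
    if len(members_in_list) < 2:
        raise NumericError(
            f"gene set {gene_set.name!r} has {len(members_in_list)} gene(s) in the "
            "ranked list; need >= 2 for a non-degenerate null"
        )
    es, leading, running = enrichment_score(ranked, gene_set, weight_p)

    rng = np.random.default_rng(seed)
    n, size = len(ranked), len(members_in_list)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=size, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        run = _running_sum(mask, ranked.metric, weight_p)
        j = int(np.argmax(np.abs(run)))
        null_es[i] = run[j]

    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    n_same = int(same_sign.sum())
    n_extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
    p_perm = (1 + n_extreme) / (1 + n_same) if n_same else 1.0
    if n_same:
        nes = es / float(np.mean(np.abs(null_es[same_sign])))
        nes_defined = True
    else:
        nes, nes_defined = float("nan"), False
        logger.warning("gsea: no null ES shares the sign of the observed ES; NES undefined")
    return EnrichmentResult(
        set_name=gene_set.name, es=es, nes=nes, nes_defined=nes_defined,
        p_perm=float(p_perm), n_perm=n_perm, leading_edge=leading, seed=seed,
        running_sum=running,
    )


def gsea(
    expr,
    group_a,
    group_b,
    gene_set: GeneSet,
    n_perm: int = 1000,
    weight_p: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """Signal-to-noise ranking of ``group_a`` vs ``group_b`` + permutation GSEA."""
    ranked = signal_to_noise(expr, group_a, group_b)
    return gsea_from_ranked(ranked, gene_set, n_perm=n_perm, weight_p=weight_p, seed=seed)


def zscore_set_comparison(sc, gene_set: GeneSet, strata: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Summed Z-score of a set summarized per stratum.

    Returns (summary, p): per-stratum n/mean/sd of the per-cell summed
    Z-score, plus a rank-sum p-value between the two extreme strata
    (low/neg vs high). Strata present in the table but empty of cells are an
    error.
    """
    df = sc.data if isinstance(sc, ExpressionMatrix) else pd.DataFrame(sc)
    z = zscore_by_gene(df)
    scores = score_cells(z, gene_set)["score"]
    order = {"low": 0, "neg": 0, "mid": 1, "int": 1, "high": 2}
    labels = [l for l in strata["stratum"].dropna().unique()]
    labels.sort(key=lambda l: (order.get(str(l), 99), str(l)))
    rows = []
    groups: dict[str, pd.Series] = {}
    for label in labels:
        cells = strata.index[strata["stratum"] == label]
        vals = scores.loc[[c for c in cells if c in scores.index]]
        if len(vals) == 0:
            raise NumericError(f"stratum {label!r} has 0 cells")
        groups[str(label)] = vals
        rows.append({"stratum": str(label), "n": len(vals),
                     "mean": float(vals.mean()),
                     "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")})
    summary = pd.DataFrame(rows).set_index("stratum")
    lo_label, hi_label = str(labels[0]), str(labels[-1])
    if lo_label == hi_label:
        raise NumericError("need at least two strata to compare")
    _, p = rank_sum_test(groups[hi_label].to_numpy(), groups[lo_label].to_numpy())
    return summary, float(p)
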
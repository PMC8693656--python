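"""Synthetic bulk + single-cell data with a planted committed subpopulation.

The generator emulates the data structure the discovery pipeline assumes:

* two bulk RNA-seq populations (``POP_A``, a naive multipotent progenitor gate;
  ``POP_B``, its downstream lineage-restricted gate) whose contrast carries two
  opposed transcriptional *programs* of ``n_program_genes`` genes each;
* a single-cell matrix drawn from the nominally homogeneous POP_A-like gate in
  which a latent *committed* subpopulation (fraction ``committed_fraction``)
  has the downstream (POP_B) program up, the naive (POP_A) program down, a few
  lineage-restricted genes switched on, and one co-regulated surface-molecule
  gene (the L-selectin analog) up;
* a ground-truth record of every planted gene and cell.

Counts are negative-binomial around log-normal per-gene baseline abundances
with per-column library-size factors; the single-cell matrix additionally gets
logistic (in log mean) dropout. Bulk replicates use a smaller NB dispersion
than cells, as bulk RNA-seq does.

The bulk contrast deliberately carries only the program genes; the marker and
lineage-restricted genes are within-gate heterogeneity visible only in the
single-cell data. The planted marker is given a high baseline abundance
(surface adhesion molecules such as L-selectin are abundant transcripts),
program genes a moderate floor, so every planted gene is detectable at the
default sequencing depths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .io import SurfaceAnnotation
from .matrix import ROLE_BULK, ROLE_SINGLE_CELL, SCALE_COUNTS, ExpressionMatrix

logger = logging.getLogger(__name__)

#: lineage-restricted genes sit at this fraction of the baseline abundance
#: scale in naive cells ("expressed only in committed cells")
_LINEAGE_BASE_FRACTION = 0.02
#: rep-to-rep depth variability of bulk libraries (log sd, natural log)
_BULK_LIBRARY_LOG_SD = 0.1


@dataclass
class SimulationParams:
    """All knobs of the generator; defaults define the study conditions."""

    n_genes: int = 2000
    n_cells: int = 300
    n_bulk_reps: int = 3
    committed_fraction: float = 0.33
    n_program_genes: int = 10
    n_lineage_restricted: int = 3
    marker_log2fc: float = 2.0
    program_log2fc: float = 2.0
    lineage_log2fc: float = 6.0
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    dispersion: float = 0.3
    bulk_dispersion: float = 0.05
    library_size_log_sd: float = 0.3
    sc_library_size: float = 2.0e4
    bulk_library_size: float = 2.0e6
    dropout_midpoint: float = 0.0
    dropout_slope: float = 1.0
    n_decoy_surface: int = 50
    seed: int = 0

    def validate(self) -> None:
        n_planted = 2 * self.n_program_genes + self.n_lineage_restricted + 1
        if n_planted + self.n_decoy_surface > self.n_genes:
            raise ConfigError(
                "violated constraint: n_program_genes*2 + n_lineage_restricted + 1 "
                f"+ n_decoy_surface <= n_genes ({n_planted + self.n_decoy_surface} > {self.n_genes})"
            )
        if not 0.0 <= self.committed_fraction <= 1.0:
            raise ConfigError(
                f"violated constraint: 0 <= committed_fraction <= 1 (got {self.committed_fraction})"
            )
        if self.dispersion <= 0 or self.bulk_dispersion <= 0:
            raise ConfigError("violated constraint: dispersion > 0")
        for name in ("n_genes", "n_cells", "n_bulk_reps", "n_program_genes"):
            if getattr(self, name) < 1:
                raise ConfigError(f"violated constraint: {name} >= 1")


@dataclass
class GroundTruth:
    """Record of everything the generator planted."""

    committed_cell_ids: list[str]
    cmp_program_genes: list[str]
    gmp_program_genes: list[str]
    lineage_restricted_genes: list[str]
    planted_marker: str
    decoy_surface_genes: list[str]
    #: true log2 fold change (committed vs naive cells) for every planted gene
    effect_table: pd.Series

    def committed_mask(self, cell_ids) -> np.ndarray:
        committed = set(self.committed_cell_ids)
        return np.array([c in committed for c in cell_ids])

    def surface_annotation(self) -> SurfaceAnnotation:
        """Annotation covering planted and decoy surface genes.

        The planted marker and the decoys are flagged surface; the program and
        lineage-restricted genes are present but flagged non-surface — the
        CTSG/MPO/ELANE-versus-SELL situation.
        """
        symbols = (
            self.cmp_program_genes
            + self.gmp_program_genes
            + self.lineage_restricted_genes
            + [self.planted_marker]
            + self.decoy_surface_genes
        )
        flags = [s == self.planted_marker or s in set(self.decoy_surface_genes) for s in symbols]
        return SurfaceAnnotation(
            flags=pd.Series(flags, index=pd.Index(symbols, name="symbol"), name="is_surface"),
            provenance="synthetic: planted marker + decoy surface genes",
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def simulate_dataset(params: SimulationParams) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate (bulk, single-cell, ground truth) for one seed.

    Identical ``params`` (including seed) give bit-identical outputs.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_genes, n_cells = params.n_genes, params.n_cells

    genes = np.array([f"G{i + 1:04d}" for i in range(n_genes)])
    cells = np.array([f"C{i + 1:04d}" for i in range(n_cells)])

    # per-gene baseline relative abundance
    abundance = np.exp(rng.normal(params.baseline_log_mean, params.baseline_log_sd, n_genes))

    # planted-gene roles from a seeded shuffle of gene indices
    gene_perm = rng.permutation(n_genes)
    k = params.n_program_genes
    cmp_idx = gene_perm[:k]
    gmp_idx = gene_perm[k : 2 * k]
    lin_idx = gene_perm[2 * k : 2 * k + params.n_lineage_restricted]
    marker_idx = int(gene_perm[2 * k + params.n_lineage_restricted])
    decoy_idx = gene_perm[
        2 * k + params.n_lineage_restricted + 1 : 2 * k + params.n_lineage_restricted + 1 + params.n_decoy_surface
    ]

    # detectability floors (see module docstring)
    program_floor = np.exp(params.baseline_log_mean)
    marker_floor = np.exp(params.baseline_log_mean + 2.0 * params.baseline_log_sd)
    abundance[cmp_idx] = np.maximum(abundance[cmp_idx], program_floor)
    abundance[gmp_idx] = np.maximum(abundance[gmp_idx], program_floor)
    abundance[marker_idx] = max(abundance[marker_idx], marker_floor)
    abundance[lin_idx] = _LINEAGE_BASE_FRACTION * np.exp(params.baseline_log_mean)

    # committed cells: first round(f*n) indices after a seeded shuffle
    cell_perm = rng.permutation(n_cells)
    n_committed = int(np.floor(params.committed_fraction * n_cells + 0.5))
    committed_idx = np.sort(cell_perm[:n_committed])
    committed = np.zeros(n_cells, dtype=bool)
    committed[committed_idx] = True

    effect = pd.Series(0.0, index=pd.Index(genes, name="symbol"), name="true_log2fc")
    effect.iloc[gmp_idx] = params.program_log2fc
    effect.iloc[cmp_idx] = -params.program_log2fc
    effect.iloc[lin_idx] = params.lineage_log2fc
    effect.iloc[marker_idx] = params.marker_log2fc

    # ---- bulk: POP_A carries the naive program, POP_B the downstream program
    abund_a = abundance.copy()
    abund_a[cmp_idx] *= 2.0 ** params.program_log2fc
    abund_b = abundance.copy()
    abund_b[gmp_idx] *= 2.0 ** params.program_log2fc

    bulk_cols, bulk_means = [], []
    bulk_libs = params.bulk_library_size * np.exp(
        rng.normal(0.0, _BULK_LIBRARY_LOG_SD, 2 * params.n_bulk_reps)
    )
    for r in range(params.n_bulk_reps):
        bulk_cols.append(f"POP_A_{r + 1}")
        bulk_means.append(bulk_libs[r] * abund_a / abund_a.sum())
    for r in range(params.n_bulk_reps):
        bulk_cols.append(f"POP_B_{r + 1}")
        bulk_means.append(bulk_libs[params.n_bulk_reps + r] * abund_b / abund_b.sum())
    bulk_counts = _nb_draw(rng, np.column_stack(bulk_means), params.bulk_dispersion)
    bulk = ExpressionMatrix(
        pd.DataFrame(bulk_counts, index=genes, columns=bulk_cols).astype(float),
        scale=SCALE_COUNTS,
        role=ROLE_BULK,
    )

    # ---- single cells: committed columns get the planted shifts
    sc_abund = np.tile(abundance[:, None], (1, n_cells))
    shift = 2.0 ** effect.to_numpy()
    sc_abund[:, committed] *= shift[:, None]
    sc_abund /= sc_abund.sum(axis=0, keepdims=True)
    libs = params.sc_library_size * np.exp(rng.normal(0.0, params.library_size_log_sd, n_cells))
    sc_mean = sc_abund * libs[None, :]
    sc_counts = _nb_draw(rng, sc_mean, params.dispersion).astype(float)
    # logistic dropout in the log mean: rare at high expression
    p_drop = expit(params.dropout_midpoint - params.dropout_slope * np.log2(1.0 + sc_mean))
    sc_counts[rng.random(sc_counts.shape) < p_drop] = 0.0
    sc = ExpressionMatrix(
        pd.DataFrame(sc_counts, index=genes, columns=cells),
        scale=SCALE_COUNTS,
        role=ROLE_SINGLE_CELL,
    )

    planted = np.concatenate([cmp_idx, gmp_idx, lin_idx, [marker_idx]])
    truth = GroundTruth(
        committed_cell_ids=[str(c) for c in cells[committed_idx]],
        cmp_program_genes=[str(g) for g in genes[cmp_idx]],
        gmp_program_genes=[str(g) for g in genes[gmp_idx]],
        lineage_restricted_genes=[str(g) for g in genes[lin_idx]],
        planted_marker=str(genes[marker_idx]),
        decoy_surface_genes=[str(g) for g in genes[decoy_idx]],
        effect_table=effect.iloc[np.sort(planted)].copy(),
    )
    logger.info(
        "simulated %d genes x %d cells (%d committed), marker=%s",
        n_genes, n_cells, n_committed, truth.planted_marker,
    )
    return bulk, sc, truth
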
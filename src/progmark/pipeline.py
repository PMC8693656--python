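"""End-to-end discovery run: data -> signatures -> scores -> markers -> GSEA.

The stage sequence mirrors the discovery logic: obtain bulk and single-cell
matrices (simulated or loaded), normalize to log2(TPM+1), derive the naive
(k=10) and validation (k=200) signatures from the bulk contrast, score every
cell by the summed Z-score of the naive-population signature, split cells
into score tertiles, test each gene between the score-low and score-high
strata, filter candidates to surface-molecule genes, and validate the
signatures by gene-set enrichment between the two extreme strata.

All artifacts are plain text (TSV/GMT/JSON) under the configured output
directory; the summary carries a fingerprint (SHA-256 over every other
artifact) so identical config + inputs reproduce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .config import RunConfig
from .enrichment import EnrichmentResult, gsea
from .errors import ProgmarkError
from .markers import MarkerResult, filter_surface, find_markers, differential_table
from .matrix import ROLE_BULK, ROLE_SINGLE_CELL, SCALE_COUNTS, ExpressionMatrix, normalize_to_log_tpm
from .signature import derive_signature, score_cells, stratify_tertiles, zscore_by_gene
from .simulate import GroundTruth, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    out_dir: str
    paths: dict
    signatures: dict
    markers: list
    surface_candidates: list
    enrichment: list
    no_markers_at_thresholds: bool
    fingerprint: str
    truth: GroundTruth | None = None

    @property
    def top_surface_candidate(self) -> str | None:
        return self.surface_candidates[0].symbol if self.surface_candidates else None


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, ProgmarkError):
                exc.args = (f"[stage {name}] {exc.args[0]} "
                            f"(fix the {name} inputs/config and re-run this stage)",)
            return False
    return _Ctx()


def _write_markers_tsv(results: list[MarkerResult], path) -> None:
    df = pd.DataFrame(
        [{"symbol": r.symbol, "log2fc": r.log2fc, "u_statistic": r.u_statistic,
          "p": r.p, "q": r.q,
          "is_surface": "" if r.is_surface is None else int(r.is_surface),
          "rank": r.rank}
         for r in results],
        columns=["symbol", "log2fc", "u_statistic", "p", "q", "is_surface", "rank"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def _fingerprint(paths: dict, out_dir: Path) -> str:
    h = hashlib.sha256()
    for name in sorted(paths):
        p = Path(paths[name])
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: RunConfig):
    inp = cfg.inputs
    bulk = pio.read_expression(inp.bulk, format="dense-tsv", scale=inp.scale, role=ROLE_BULK)
    sc = pio.read_expression(inp.sc, format=inp.sc_format, scale=inp.scale,
                             role=ROLE_SINGLE_CELL,
                             genes_path=inp.sc_genes, cols_path=inp.sc_cells)
    surface = pio.read_surface_annotation(inp.surface)
    return bulk, sc, surface, None


def write_simulation(out_dir: Path, bulk, sc, truth: GroundTruth) -> dict:
    """Write the simulated dataset as the CLI's text artifacts."""
    paths = {}
    paths["bulk"] = out_dir / "bulk.tsv"
    pio.write_expression(bulk, paths["bulk"])
    paths["sc_mtx"] = out_dir / "sc.mtx"
    paths["sc_genes"] = out_dir / "genes.tsv"
    paths["sc_cells"] = out_dir / "cells.tsv"
    pio.write_matrix_market(sc, paths["sc_mtx"], paths["sc_genes"], paths["sc_cells"])
    paths["surface"] = out_dir / "surface.tsv"
    pio.write_surface_annotation(truth.surface_annotation(), paths["surface"])
    committed = set(truth.committed_cell_ids)
    cells_df = pd.DataFrame({"cell": list(sc.columns),
                             "committed": [int(c in committed) for c in sc.columns]})
    paths["truth_cells"] = out_dir / "truth_cells.tsv"
    cells_df.to_csv(paths["truth_cells"], sep="\t", index=False, lineterminator="\n")
    roles = {}
    for g in truth.cmp_program_genes:
        roles[g] = "cmp_program"
    for g in truth.gmp_program_genes:
        roles[g] = "gmp_program"
    for g in truth.lineage_restricted_genes:
        roles[g] = "lineage_restricted"
    roles[truth.planted_marker] = "surface_marker"
    genes_df = pd.DataFrame({
        "symbol": list(truth.effect_table.index),
        "role": [roles[g] for g in truth.effect_table.index],
        "true_log2fc": truth.effect_table.to_numpy(),
    })
    paths["truth_genes"] = out_dir / "truth_genes.tsv"
    genes_df.to_csv(paths["truth_genes"], sep="\t", index=False,
                    float_format="%.10g", lineterminator="\n")
    return paths


def run_discovery(cfg: RunConfig) -> RunReport:
    """Execute the full discovery loop and write all artifacts.

    An empty candidate list is a reported outcome, not an error.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {}
    truth = None

    with _stage("ingest"):
        if cfg.simulate is not None:
            bulk, sc, truth = simulate_dataset(cfg.simulate)
            paths.update(write_simulation(out_dir, bulk, sc, truth))
            surface = truth.surface_annotation()
            pop_a, pop_b = "POP_A", "POP_B"
        else:
            bulk, sc, surface, truth = _load_inputs(cfg)
            pop_a, pop_b = cfg.inputs.pop_a, cfg.inputs.pop_b

    with _stage("normalize"):
        if bulk.scale == SCALE_COUNTS:
            bulk = normalize_to_log_tpm(bulk)
        if sc.scale == SCALE_COUNTS:
            sc = normalize_to_log_tpm(sc)

    with _stage("derive-signature"):
        sig_a = derive_signature(bulk, pop_a, pop_b, cfg.signature_k, cfg.min_mean,
                                 name=f"{pop_a}_sig_k{cfg.signature_k}")
        sig_b = derive_signature(bulk, pop_b, pop_a, cfg.signature_k, cfg.min_mean,
                                 name=f"{pop_b}_sig_k{cfg.signature_k}")
        val_a = derive_signature(bulk, pop_a, pop_b, cfg.validation_k, cfg.min_mean,
                                 name=f"{pop_a}_sig_k{cfg.validation_k}")
        val_b = derive_signature(bulk, pop_b, pop_a, cfg.validation_k, cfg.min_mean,
                                 name=f"{pop_b}_sig_k{cfg.validation_k}")
        paths["signatures"] = out_dir / "signatures.gmt"
        pio.write_gmt([sig_a, sig_b, val_a, val_b], paths["signatures"])

    with _stage("score"):
        z = zscore_by_gene(sc)
        scores = score_cells(z, sig_a)
        strata = stratify_tertiles(scores)
        paths["cell_scores"] = out_dir / "cell_scores.tsv"
        strata.to_csv(paths["cell_scores"], sep="\t", float_format="%.10g",
                      lineterminator="\n")

    with _stage("find-markers"):
        de_table = differential_table(sc, strata)
        paths["markers_all"] = out_dir / "markers_all.tsv"
        de_table.to_csv(paths["markers_all"], sep="\t", float_format="%.10g",
                        lineterminator="\n")
        markers = find_markers(sc, strata, n_top=cfg.n_top,
                               fc_threshold=cfg.fc_threshold,
                               q_threshold=cfg.q_threshold, order_by=cfg.order_by)
        paths["markers_top"] = out_dir / "markers_top.tsv"
        _write_markers_tsv(markers, paths["markers_top"])

    with _stage("surface-filter"):
        candidates = filter_surface(markers, surface)
        paths["surface_candidates"] = out_dir / "surface_candidates.tsv"
        _write_markers_tsv(candidates, paths["surface_candidates"])

    with _stage("gsea"):
        low_cells = strata.index[strata["stratum"] == "low"].tolist()
        high_cells = strata.index[strata["stratum"] == "high"].tolist()
        enrichments = []
        for gene_set in (val_a, val_b):
            res = gsea(sc, low_cells, high_cells, gene_set,
                       n_perm=cfg.n_perm, weight_p=cfg.weight_p, seed=cfg.seed + 1)
            enrichments.append(res)
            run_path = out_dir / f"running_sum_{gene_set.name}.tsv"
            pd.DataFrame({"position": np.arange(1, len(res.running_sum) + 1),
                          "running_sum": res.running_sum}).to_csv(
                run_path, sep="\t", index=False, float_format="%.10g",
                lineterminator="\n")
            paths[f"running_sum_{gene_set.name}"] = run_path
        enr_df = pd.DataFrame(
            [{"set": r.set_name, "es": r.es, "nes": r.nes,
              "nes_defined": int(r.nes_defined), "p_perm": r.p_perm,
              "n_perm": r.n_perm, "seed": r.seed,
              "leading_edge": ",".join(r.leading_edge)}
             for r in enrichments])
        paths["enrichment"] = out_dir / "enrichment.tsv"
        enr_df.to_csv(paths["enrichment"], sep="\t", index=False,
                      float_format="%.10g", lineterminator="\n")

    # config echo + summary
    paths["config_echo"] = out_dir / "config_echo.yaml"
    with open(paths["config_echo"], "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(cfg.echo(), fh, sort_keys=True)

    no_markers = len(candidates) == 0
    fingerprint = _fingerprint(paths, out_dir)
    summary = {
        "config": cfg.echo(),
        "signatures": {s.name: s.members for s in (sig_a, sig_b)},
        "n_markers_reported": len(markers),
        "surface_candidates": [
            {"symbol": r.symbol, "log2fc": r.log2fc, "p": r.p, "q": r.q, "rank": r.rank}
            for r in candidates
        ],
        "no_markers_at_thresholds": no_markers,
        "enrichment": [
            {"set": r.set_name, "es": r.es, "nes": r.nes, "p_perm": r.p_perm,
             "n_perm": r.n_perm, "seed": r.seed}
            for r in enrichments
        ],
        "artifacts": {k: str(Path(v).name) for k, v in paths.items()},
        "fingerprint": fingerprint,
    }
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["summary"] = summary_path

    if no_markers:
        logger.warning("run_discovery: no markers at thresholds "
                       "(fc>%g, q<=%g) — reported outcome, not an error",
                       cfg.fc_threshold, cfg.q_threshold)
    return RunReport(
        out_dir=str(out_dir), paths={k: str(v) for k, v in paths.items()},
        signatures={s.name: s.members for s in (sig_a, sig_b, val_a, val_b)},
        markers=markers, surface_candidates=candidates, enrichment=enrichments,
        no_markers_at_thresholds=no_markers, fingerprint=fingerprint, truth=truth,
    )
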
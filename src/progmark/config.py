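"""Run configuration: schema-checked YAML with materialized defaults.

A run takes exactly one of a ``simulate`` block (generator parameters) or an
``inputs`` block (paths to on-disk matrices and annotation). All other
sections are optional and default to the study conventions: signature k=10,
validation signature k=200, tertile stratification, fold-change > 2 and
FDR < 0.05 marker thresholds, 1000 gene-label permutations for enrichment.

One master ``seed`` drives every stage: the generator uses it directly
(unless the simulate block pins its own) and the enrichment permutations use
``seed + 1``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .matrix import SCALE_COUNTS, SCALE_LOG_TPM
from .simulate import SimulationParams


@dataclass
class InputPaths:
    bulk: str = ""
    sc: str = ""
    sc_format: str = "dense-tsv"
    sc_genes: str | None = None
    sc_cells: str | None = None
    surface: str = ""
    ortholog: str | None = None
    scale: str = SCALE_COUNTS
    pop_a: str = "POP_A"
    pop_b: str = "POP_B"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "progmark_run"
    simulate: SimulationParams | None = None
    inputs: InputPaths | None = None
    signature_k: int = 10
    validation_k: int = 200
    min_mean: float = 0.0
    stratify_q1: float = 1.0 / 3.0
    stratify_q2: float = 2.0 / 3.0
    n_top: int = 10
    fc_threshold: float = 2.0
    q_threshold: float = 0.05
    order_by: str = "significance"
    n_perm: int = 1000
    weight_p: float = 1.0

    def echo(self) -> dict:
        """Fully materialized config as a plain dict (for logging/summary)."""
        out = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "signature": {"k": self.signature_k, "validation_k": self.validation_k,
                          "min_mean": self.min_mean},
            "stratify": {"q1": self.stratify_q1, "q2": self.stratify_q2},
            "markers": {"n_top": self.n_top, "fc_threshold": self.fc_threshold,
                        "q_threshold": self.q_threshold, "order_by": self.order_by},
            "gsea": {"n_perm": self.n_perm, "weight_p": self.weight_p},
        }
        if self.simulate is not None:
            out["simulate"] = dataclasses.asdict(self.simulate)
        if self.inputs is not None:
            out["inputs"] = dataclasses.asdict(self.inputs)
        return out


_SECTION_FIELDS = {
    "signature": {"k": int, "validation_k": int, "min_mean": float},
    "stratify": {"q1": float, "q2": float},
    "markers": {"n_top": int, "fc_threshold": float, "q_threshold": float, "order_by": str},
    "gsea": {"n_perm": int, "weight_p": float},
}


def _typed(section: str, key: str, value, typ):
    if typ is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if typ is int and isinstance(value, bool):
        raise ConfigError(f"{section}.{key}: expected {typ.__name__}, got bool")
    if not isinstance(value, typ):
        raise ConfigError(f"{section}.{key}: expected {typ.__name__}, got {type(value).__name__}")
    return value


def build_config(raw: dict) -> RunConfig:
    """Validate a raw config dict; unknown keys and type mismatches error."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known_top = {"seed", "out_dir", "simulate", "inputs"} | set(_SECTION_FIELDS)
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")

    cfg = RunConfig()
    if "seed" in raw:
        cfg.seed = _typed("<root>", "seed", raw["seed"], int)
    if "out_dir" in raw:
        cfg.out_dir = _typed("<root>", "out_dir", raw["out_dir"], str)

    has_sim = "simulate" in raw and raw["simulate"] is not None
    has_inputs = "inputs" in raw and raw["inputs"] is not None
    if has_sim and has_inputs:
        raise ConfigError("exactly one of 'simulate' and 'inputs' may be supplied, got both")
    if not has_sim and not has_inputs:
        raise ConfigError("exactly one of 'simulate' and 'inputs' must be supplied")

    if has_sim:
        block = raw["simulate"]
        if not isinstance(block, dict):
            raise ConfigError("simulate: expected a mapping of generator parameters")
        valid = {f.name: f.type for f in dataclasses.fields(SimulationParams)}
        unknown = set(block) - set(valid)
        if unknown:
            raise ConfigError(f"unknown simulate key(s): {sorted(unknown)}")
        params = SimulationParams(**{k: block[k] for k in block})
        if "seed" not in block:
            params.seed = cfg.seed
        params.validate()
        cfg.simulate = params
    else:
        block = raw["inputs"]
        if not isinstance(block, dict):
            raise ConfigError("inputs: expected a mapping")
        valid = {f.name for f in dataclasses.fields(InputPaths)}
        unknown = set(block) - valid
        if unknown:
            raise ConfigError(f"unknown inputs key(s): {sorted(unknown)}")
        paths = InputPaths(**block)
        for req in ("bulk", "sc", "surface"):
            if not getattr(paths, req):
                raise ConfigError(f"inputs.{req} is required")
        if paths.scale not in (SCALE_COUNTS, SCALE_LOG_TPM):
            raise ConfigError(f"inputs.scale: expected {SCALE_COUNTS!r} or {SCALE_LOG_TPM!r}")
        if paths.sc_format not in ("dense-tsv", "matrix-market"):
            raise ConfigError("inputs.sc_format: expected 'dense-tsv' or 'matrix-market'")
        cfg.inputs = paths

    attr_map = {
        ("signature", "k"): "signature_k",
        ("signature", "validation_k"): "validation_k",
        ("signature", "min_mean"): "min_mean",
        ("stratify", "q1"): "stratify_q1",
        ("stratify", "q2"): "stratify_q2",
        ("markers", "n_top"): "n_top",
        ("markers", "fc_threshold"): "fc_threshold",
        ("markers", "q_threshold"): "q_threshold",
        ("markers", "order_by"): "order_by",
        ("gsea", "n_perm"): "n_perm",
        ("gsea", "weight_p"): "weight_p",
    }
    for section, fields in _SECTION_FIELDS.items():
        if section not in raw or raw[section] is None:
            continue
        block = raw[section]
        if not isinstance(block, dict):
            raise ConfigError(f"{section}: expected a mapping")
        unknown = set(block) - set(fields)
        if unknown:
            raise ConfigError(f"unknown {section} key(s): {sorted(unknown)}")
        for key, typ in fields.items():
            if key in block:
                setattr(cfg, attr_map[(section, key)], _typed(section, key, block[key], typ))

    # cross-field invariants
    if cfg.signature_k < 1:
        raise ConfigError(f"signature.k must be >= 1, got {cfg.signature_k}")
    if cfg.validation_k < 1:
        raise ConfigError(f"signature.validation_k must be >= 1, got {cfg.validation_k}")
    if not (0.0 < cfg.stratify_q1 < cfg.stratify_q2 < 1.0):
        raise ConfigError(
            f"stratify quantiles must satisfy 0 < q1 < q2 < 1, got ({cfg.stratify_q1}, {cfg.stratify_q2})"
        )
    if cfg.n_top < 1:
        raise ConfigError(f"markers.n_top must be >= 1, got {cfg.n_top}")
    if cfg.fc_threshold <= 0:
        raise ConfigError(f"markers.fc_threshold must be > 0, got {cfg.fc_threshold}")
    if not 0.0 < cfg.q_threshold <= 1.0:
        raise ConfigError(f"markers.q_threshold must be in (0, 1], got {cfg.q_threshold}")
    if cfg.order_by not in ("significance", "log2fc"):
        raise ConfigError(f"markers.order_by must be 'significance' or 'log2fc', got {cfg.order_by!r}")
    if cfg.n_perm < 100:
        raise ConfigError(f"gsea.n_perm must be >= 100, got {cfg.n_perm}")
    return cfg


def validate_config(path) -> RunConfig:
    """Load a YAML config file, validate it, and return a RunConfig."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return build_config(raw)
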
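"""Readers and writers for every on-disk format the pipeline touches.

Formats: dense expression TSV (genes x columns), Matrix Market triplet
(.mtx plus row-name and column-name sidecar files), GMT gene sets,
surface-molecule annotation TSV, ortholog symbol TSV. All files are UTF-8
with UNIX newlines; floats are written with ``%.10g`` so that write→read
round trips are lossless in practice.

Validation failures raise :class:`~progmark.errors.ParseError` naming the
file and line. Matrix Market coordinates are 1-based on disk (the format
standard); everything in memory is 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DataError, ParseError
from .matrix import ROLE_SINGLE_CELL, SCALE_COUNTS, ExpressionMatrix

logger = logging.getLogger(__name__)

#: controlled vocabulary for species tags
SPECIES = ("mouse", "human")


@dataclass
class GeneSet:
    """A named, ordered collection of unique gene symbols."""

    name: str
    members: list[str]
    species: str | None = None
    description: str = "na"

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise DataError(f"gene set {self.name!r} has duplicate members")
        if not self.members:
            raise DataError(f"gene set {self.name!r} is empty")

    @property
    def k(self) -> int:
        return len(self.members)


@dataclass
class SurfaceAnnotation:
    """Mapping gene symbol -> is-surface flag, with provenance."""

    flags: pd.Series
    provenance: str = ""

    def __post_init__(self):
        if self.flags.index.has_duplicates:
            dups = self.flags.index[self.flags.index.duplicated()].unique().tolist()
            raise DataError(f"surface annotation has duplicate symbols: {dups[:5]}")
        self.flags = self.flags.astype(bool)

    def is_surface(self, symbol: str) -> bool | None:
        """True/False if annotated, None if the symbol is absent."""
        if symbol in self.flags.index:
            return bool(self.flags[symbol])
        return None

    @property
    def n_surface(self) -> int:
        return int(self.flags.sum())


@dataclass
class OrthologTable:
    """Rows of (source symbol, target symbol, source species, target species)."""

    table: pd.DataFrame

    REQUIRED = ("source_symbol", "target_symbol", "source_species", "target_species")

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise DataError(f"ortholog table missing required column {col!r}")
        for col in ("source_symbol", "target_symbol"):
            if (self.table[col].astype(str).str.len() == 0).any():
                raise DataError(f"ortholog table has empty {col} entries")
        for col in ("source_species", "target_species"):
            bad = set(self.table[col]) - set(SPECIES)
            if bad:
                raise DataError(f"unknown species tag(s) {sorted(bad)}; expected one of {SPECIES}")

    def mapping(self, source_species: str, target_species: str) -> dict[str, list[str]]:
        """source symbol -> ordered list of target symbols for one species pair."""
        sub = self.table[
            (self.table["source_species"] == source_species)
            & (self.table["target_species"] == target_species)
        ]
        out: dict[str, list[str]] = {}
        for src, tgt in zip(sub["source_symbol"], sub["target_symbol"]):
            out.setdefault(str(src), [])
            if str(tgt) not in out[str(src)]:
                out[str(src)].append(str(tgt))
        return out


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def _collapse_duplicate_genes(df: pd.DataFrame, path) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    dups = df.index[df.index.duplicated()].unique().tolist()
    logger.warning("%s: %d duplicated gene symbol(s) collapsed by summation: %s",
                   path, len(dups), dups[:5])
    order = df.index.unique()
    return df.groupby(level=0, sort=False).sum().loc[order]


def _read_dense_tsv(path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ParseError("empty file", path, 1)
    cols = header.split("\t")[1:]
    seen: set[str] = set()
    for c in cols:
        if c in seen:
            raise ParseError(f"duplicate column name {c!r}", path, 1)
        seen.add(c)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"non-numeric value {raw.iat[i, j]!r} for gene {raw.index[i]!r}, column {raw.columns[j]!r}",
            path, int(i) + 2,
        )
    numeric.index = numeric.index.astype(str)
    return numeric.astype(float)


def _read_names(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        names = [line.rstrip("\n") for line in fh if line.strip()]
    return names


def _read_matrix_market(path, genes_path, cols_path) -> pd.DataFrame:
    path = Path(path)
    genes_path = Path(genes_path) if genes_path else path.parent / "genes.tsv"
    cols_path = Path(cols_path) if cols_path else path.parent / "cells.tsv"
    try:
        mat = scipy.io.mmread(path)
    except Exception as exc:  # scipy raises ValueError on malformed input
        raise ParseError(f"invalid Matrix Market file: {exc}", path) from exc
    genes = _read_names(genes_path)
    cols = _read_names(cols_path)
    n, m = mat.shape
    if len(genes) != n:
        raise ParseError(
            f"dimension mismatch: .mtx header declares {n} rows but {genes_path} has {len(genes)} names",
            path,
        )
    if len(cols) != m:
        raise ParseError(
            f"dimension mismatch: .mtx header declares {m} columns but {cols_path} has {len(cols)} names",
            path,
        )
    if len(set(cols)) != len(cols):
        raise ParseError("duplicate column names in sidecar", cols_path)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    return pd.DataFrame(dense, index=pd.Index(genes, dtype=str), columns=cols)


def read_expression(
    path,
    format: str = "dense-tsv",
    scale: str = SCALE_COUNTS,
    role: str = ROLE_SINGLE_CELL,
    genes_path=None,
    cols_path=None,
) -> ExpressionMatrix:
    """Read an expression matrix from dense TSV or Matrix Market triplet.

    Duplicate gene rows are collapsed by summation with a logged warning;
    the scale/role tags are taken from the caller (default: raw counts).
    """
    if format == "dense-tsv":
        df = _read_dense_tsv(path)
    elif format == "matrix-market":
        df = _read_matrix_market(path, genes_path, cols_path)
    else:
        raise ParseError(f"unknown expression format {format!r}", path)
    df = _collapse_duplicate_genes(df, path)
    return ExpressionMatrix(df, scale=scale, role=role)


def write_expression(expr: ExpressionMatrix, path) -> None:
    """Write a dense genes x columns TSV with %.10g precision."""
    expr.data.to_csv(path, sep="\t", index_label="symbol",
                     float_format="%.10g", lineterminator="\n")


def write_matrix_market(expr: ExpressionMatrix, mtx_path, genes_path, cols_path) -> None:
    """Write .mtx (1-based coordinate triplets) plus name sidecars."""
    coo = scipy.sparse.coo_matrix(expr.data.to_numpy())
    scipy.io.mmwrite(str(mtx_path), coo)
    for p, names in ((genes_path, expr.genes), (cols_path, expr.columns)):
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            for name in names:
                fh.write(f"{name}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Read a GMT file (name TAB description TAB member symbols...).

    Duplicate members within a set are de-duplicated preserving first
    occurrence, with a warning; empty sets and short lines are rejected.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} field(s); expected name, description and >=1 member",
                    path, lineno,
                )
            name, description = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            n_dup = 0
            for sym in fields[2:]:
                if not sym:
                    continue
                if sym in seen:
                    n_dup += 1
                    continue
                seen.add(sym)
                members.append(sym)
            if n_dup:
                logger.warning("%s:%d: set %r: %d duplicated member(s) dropped",
                               path, lineno, name, n_dup)
            if not members:
                raise ParseError(f"gene set {name!r} is empty", path, lineno)
            sets.append(GeneSet(name=name, members=members, description=description))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description] + list(s.members)) + "\n")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

def read_surface_annotation(path, normalize_case: bool = False) -> SurfaceAnnotation:
    """Read a TSV with columns (symbol, is_surface in {0,1})."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("symbol", "is_surface"):
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}", path, 1)
    flags = {}
    for i, (sym, flag) in enumerate(zip(df["symbol"], df["is_surface"])):
        if flag not in ("0", "1"):
            raise ParseError(f"non-boolean is_surface value {flag!r} for {sym!r}", path, i + 2)
        key = sym.upper() if normalize_case else sym
        if key in flags:
            raise ParseError(f"duplicate symbol {sym!r}", path, i + 2)
        flags[key] = flag == "1"
    series = pd.Series(flags, dtype=bool, name="is_surface")
    series.index.name = "symbol"
    return SurfaceAnnotation(flags=series, provenance=str(path))


def write_surface_annotation(ann: SurfaceAnnotation, path) -> None:
    df = pd.DataFrame({"symbol": ann.flags.index, "is_surface": ann.flags.astype(int).to_numpy()})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ortholog_table(path) -> OrthologTable:
    """Read a TSV with columns (source_symbol, target_symbol, source_species, target_species)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in OrthologTable.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"missing required column(s) {missing}", path, 1)
    try:
        return OrthologTable(table=df)
    except DataError as exc:
        raise ParseError(str(exc), path) from exc


def write_ortholog_table(table: OrthologTable, path) -> None:
    table.table.to_csv(path, sep="\t", index=False, lineterminator="\n")
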
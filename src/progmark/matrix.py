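"""Expression-matrix container and scale conversion.

The pipeline's central container is a genes x columns :class:`pandas.DataFrame`
wrapped with two tags: the expression *scale* (raw counts, or log2(TPM+1))
and the *role* of the columns (bulk replicate samples, or single cells).
TPM here means column-proportional scaling to one million without gene-length
correction; the log scale is log2(TPM + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

SCALE_COUNTS = "counts"
SCALE_TPM = "TPM"
SCALE_LOG_TPM = "log2(TPM+1)"
VALID_SCALES = (SCALE_COUNTS, SCALE_TPM, SCALE_LOG_TPM)

ROLE_BULK = "bulk"
ROLE_SINGLE_CELL = "single-cell"


@dataclass
class ExpressionMatrix:
    """A genes x samples/cells numeric matrix with scale and role tags.

    Parameters
    ----------
    data
        DataFrame indexed by unique gene symbols, columns are unique
        sample/cell identifiers. Values must be numeric, finite and non-missing.
    scale
        One of ``counts``, ``TPM``, ``log2(TPM+1)``.
    role
        ``bulk`` or ``single-cell``.
    """

    data: pd.DataFrame
    scale: str = SCALE_COUNTS
    role: str = ROLE_SINGLE_CELL

    def __post_init__(self):
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.scale not in VALID_SCALES:
            raise DataError(f"unknown expression scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.role not in (ROLE_BULK, ROLE_SINGLE_CELL):
            raise DataError(f"unknown matrix role {self.role!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene symbols: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate column identifiers: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise DataError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            raise DataError("expression matrix contains missing or non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def columns(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self):
        return self.data.shape

    def subset_columns(self, columns) -> "ExpressionMatrix":
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            raise DataError(f"unknown columns: {missing[:5]}")
        return ExpressionMatrix(self.data[list(columns)], scale=self.scale, role=self.role)


def normalize_to_log_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Convert raw counts to log2(TPM+1).

    Each column is scaled to sum to 1e6 (length-free TPM), then
    ``log2(x + 1)`` is applied elementwise. Refuses to run twice: the input
    scale tag must be raw counts.
    """
    if expr.scale != SCALE_COUNTS:
        raise DataError(
            f"normalize_to_log_tpm expects raw counts, got scale {expr.scale!r} "
            "(no silent double-normalization)"
        )
    totals = expr.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise DataError(f"column(s) with zero total counts: {list(zero.index[:5])}")
    tpm = expr.data.div(totals, axis=1) * 1e6
    logged = np.log2(tpm + 1.0)
    return ExpressionMatrix(logged, scale=SCALE_LOG_TPM, role=expr.role)
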
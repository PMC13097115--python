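"""Composite clinical indices: Chol/HDL ratio, HOMA-IR, pooled group summaries."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedRatioError

#: Divisor of the mass-unit (mg/dL x uU/mL) insulin-resistance index.
HOMA_IR_DENOMINATOR = 405.0


def chol_hdl_ratio(chol, hdl):
    """Total cholesterol divided by HDL cholesterol (both mg/dL).

    Accepts scalars or arrays; raises :class:`UndefinedRatioError` when any
    HDL value is non-positive.
    """
    chol = np.asarray(chol, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    if np.any(hdl <= 0):
        raise UndefinedRatioError("HDL must be > 0 to form the Chol/HDL ratio")
    out = chol / hdl
    return float(out) if out.ndim == 0 else out


def homa_ir(glucose, insulin):
    """Insulin-resistance index from fasting glucose (mg/dL) and insulin (uU/mL).

    ``glucose * insulin / 405`` — the mass-unit convention.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if np.any(glucose < 0) or np.any(insulin < 0):
        raise DomainError("glucose and insulin must be non-negative")
    out = glucose * insulin / HOMA_IR_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def pooled_group_summary(means: Sequence[float], counts: Sequence[int]) -> float:
    """Count-weighted overall mean from per-group means.

    With equal counts this reduces to the simple mean of the group means.
    """
    means = np.asarray(means, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if means.shape != counts.shape:
        raise DomainError(
            f"means and counts differ in shape: {means.shape} vs {counts.shape}"
        )
    if np.any(counts <= 0):
        raise DomainError("all group counts must be positive")
    return float(np.sum(means * counts) / np.sum(counts))


def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append ``clin_chol_hdl_ratio`` and ``clin_homa_ir`` where inputs exist."""
    out = df.copy()
    if {"clin_chol", "clin_hdl"} <= set(out.columns):
        out["clin_chol_hdl_ratio"] = chol_hdl_ratio(out["clin_chol"], out["clin_hdl"])
    if {"clin_glucose", "clin_insulin"} <= set(out.columns):
        out["clin_homa_ir"] = homa_ir(out["clin_glucose"], out["clin_insulin"])
    return out
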
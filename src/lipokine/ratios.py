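"""Exhaustive lipid:cytokine ratio screen.

Every lipid/cytokine quotient is formed per subject, correlated (Pearson)
with a clinical endpoint separately within each racial stratum, and each
ratio is classified as significant uniquely in one stratum, shared, or none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import fdr_adjust
from .errors import DesignError, DomainError

STRATA = ("White", "AA")
CLASSES = ("unique_white", "unique_aa", "shared", "none")


@dataclass
class RatioFeatures:
    """Subjects x (lipid, cytokine) ratio matrix in lipid-major column order."""

    values: pd.DataFrame  # MultiIndex columns (lipid, cytokine)
    lipids: list
    cytokines: list

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def build_ratio_features(lipids: pd.DataFrame, cytokines: pd.DataFrame) -> RatioFeatures:
    """All L x C per-subject quotients; non-positive denominators become NaN."""
    if not lipids.index.equals(cytokines.index):
        raise DesignError("lipid and cytokine tables must share the subject index")
    L = lipids.to_numpy(dtype=float)
    C = cytokines.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(C > 0, C, np.nan)
        R = L[:, :, None] / denom[:, None, :]
    n = L.shape[0]
    R = R.reshape(n, -1)  # lipid-major: all cytokines of lipid 0, then lipid 1, ...
    cols = pd.MultiIndex.from_product(
        [list(lipids.columns), list(cytokines.columns)], names=["lipid", "cytokine"]
    )
    return RatioFeatures(
        values=pd.DataFrame(R, index=lipids.index, columns=cols),
        lipids=list(lipids.columns),
        cytokines=list(cytokines.columns),
    )


def _pearson_complete(X: np.ndarray, y: np.ndarray):
    """Vectorized complete-case Pearson r, two-sided p and n per column of X."""
    mask = np.isfinite(X) & np.isfinite(y)[:, None]
    Xv = np.where(mask, X, 0.0)
    yv = np.where(mask, y[:, None], 0.0)
    n = mask.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = Xv.sum(axis=0) / n
        my = yv.sum(axis=0) / n
    # two-pass centered sums keep full precision for the 1e-10 oracle match
    dx = np.where(mask, X - mx, 0.0)
    dy = np.where(mask, y[:, None] - my, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (dx * dy).sum(axis=0)
        varx = (dx * dx).sum(axis=0)
        vary = (dy * dy).sum(axis=0)
        r = cov / np.sqrt(varx * vary)
    # exact constancy check over complete pairs (robust to cancellation noise)
    xmax = np.where(mask, X, -np.inf).max(axis=0)
    xmin = np.where(mask, X, np.inf).min(axis=0)
    ymax = np.where(mask, y[:, None], -np.inf).max(axis=0)
    ymin = np.where(mask, y[:, None], np.inf).min(axis=0)
    bad = (n < 3) | (xmax == xmin) | (ymax == ymin)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.isnan(r), np.nan, np.where(np.abs(r) >= 1.0, 0.0, p))
    return r, p, n.astype(int)


def stratified_ratio_correlation(
    features: RatioFeatures,
    endpoint: pd.Series,
    strata: pd.Series,
    alpha: float = 0.05,
    endpoint_name: str | None = None,
) -> pd.DataFrame:
    """Per-feature, per-stratum Pearson screen against one endpoint.

    Output is long-form: one row per (lipid, cytokine, stratum) with ``r``,
    ``p``, ``n``, a convenience BH-FDR column per stratum, and a feature-level
    ``class`` label in {unique_white, unique_aa, shared, none} derived from
    the raw p-values at ``alpha`` (matching the raw-threshold filter).
    """
    if endpoint_name is None:
        endpoint_name = endpoint.name or "endpoint"
    strata = strata.reindex(features.values.index)
    endpoint = endpoint.reindex(features.values.index)
    results = {}
    for stratum in STRATA:
        sel = (strata == stratum).to_numpy()
        if sel.sum() < 4:
            raise DesignError(f"stratum {stratum} has fewer than 4 subjects")
        X = features.values.to_numpy(dtype=float)[sel]
        y = endpoint.to_numpy(dtype=float)[sel]
        r, p, n = _pearson_complete(X, y)
        results[stratum] = (r, p, n)

    pw = results["White"][1]
    pa = results["AA"][1]
    sig_w = np.isfinite(pw) & (pw < alpha)
    sig_a = np.isfinite(pa) & (pa < alpha)
    cls = np.full(pw.shape, "none", dtype=object)
    cls[sig_w & ~sig_a] = "unique_white"
    cls[sig_a & ~sig_w] = "unique_aa"
    cls[sig_w & sig_a] = "shared"

    frames = []
    lipid_names = features.values.columns.get_level_values("lipid")
    cyt_names = features.values.columns.get_level_values("cytokine")
    for stratum in STRATA:
        r, p, n = results[stratum]
        finite = np.isfinite(p)
        p_fdr = np.full_like(p, np.nan)
        if finite.any():
            p_fdr[finite] = fdr_adjust(p[finite])
        frames.append(
            pd.DataFrame(
                {
                    "lipid": lipid_names,
                    "cytokine": cyt_names,
                    "endpoint": endpoint_name,
                    "stratum": stratum,
                    "r": r,
                    "p": p,
                    "p_fdr": p_fdr,
                    "n": n,
                    "class": cls,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs["alpha"] = alpha
    return out


def filter_screen(screen: pd.DataFrame) -> pd.DataFrame:
    """Rows for features significant in at least one stratum (class != none)."""
    return screen[screen["class"] != "none"].reset_index(drop=True)


def volcano_table(screen: pd.DataFrame, alpha: float | None = None) -> pd.DataFrame:
    """Plot-ready (r, -log10 p, class, stratum) for the retained features."""
    if alpha is None:
        alpha = screen.attrs.get("alpha", 0.05)
    if not 0 < alpha < 1:
        raise DomainError("alpha must be in (0, 1)")
    kept = filter_screen(screen).copy()
    tiny = np.nextafter(0, 1)
    p = kept["p"].to_numpy(dtype=float)
    underflow = p <= 0
    p_clipped = np.where(underflow, tiny, p)
    kept["neg_log10_p"] = -np.log10(p_clipped)
    kept["p_underflow"] = underflow
    out = kept[["lipid", "cytokine", "endpoint", "stratum", "r", "neg_log10_p", "class", "p_underflow"]]
    out.attrs["threshold"] = -np.log10(alpha)
    return out
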
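"""Per-analyte Box-Cox transform, balanced two-way ANOVA, protected LSD, BH-FDR.

The factorial engine targets the balanced 2x2 (race x disease) design with
``n`` replicates per cell; under balance Type-I/II/III sums of squares
coincide, so everything is computed from cell-mean identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import GROUPS, CohortTable
from .errors import (
    DegenerateVarianceError,
    DesignError,
    DomainError,
)

#: The four pre-specified pairwise contrasts, in reporting order.
CONTRAST_PAIRS = (
    ("NoDx-White", "Dx-White"),
    ("NoDx-AA", "Dx-AA"),
    ("NoDx-White", "NoDx-AA"),
    ("Dx-White", "Dx-AA"),
)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

@dataclass
class BoxCoxFit:
    """Fitted power-transform parameters for one analyte."""

    lambda_: float
    shift: float
    loglik: float
    applied: bool


def boxcox_transform(values: np.ndarray, fit: BoxCoxFit) -> np.ndarray:
    """Apply a fitted transform: ``((y+shift)^lambda - 1)/lambda``, log at 0."""
    y = np.asarray(values, dtype=float) + fit.shift
    if not fit.applied:
        return np.asarray(values, dtype=float)
    if abs(fit.lambda_) < 1e-12:
        return np.log(y)
    return (y ** fit.lambda_ - 1.0) / fit.lambda_


def boxcox_profile_llf(lambdas, y: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the power-transform family at each exponent.

    ``(lam - 1) * sum(log y) - n/2 * log(var_mle(z))`` with z the transformed
    values; vectorized over the exponent grid.
    """
    lam = np.atleast_1d(np.asarray(lambdas, dtype=float))
    logy = np.log(y)
    n = y.size
    Z = np.empty((lam.size, n))
    nz = np.abs(lam) > 1e-12
    if nz.any():
        Z[nz] = np.expm1(np.outer(lam[nz], logy)) / lam[nz, None]
    if (~nz).any():
        Z[~nz] = logy
    var = Z.var(axis=1, ddof=0)
    with np.errstate(divide="ignore"):
        ll = lam * logy.sum() - logy.sum() - n / 2.0 * np.log(var)
    return ll


def boxcox_fit(values: Sequence[float], lambda_bounds: tuple[float, float] = (-5.0, 5.0)) -> BoxCoxFit:
    """Profile-likelihood fit of the Box-Cox exponent.

    A coarse grid over ``lambda_bounds`` locates the basin; bounded scalar
    maximization then refines the exponent.  Non-positive inputs are shifted
    just above zero first, and the shift is recorded so the transform is
    reproducible.  Constant input returns ``applied=False`` (nothing to fix).
    """
    y = np.asarray(values, dtype=float)
    y = y[np.isfinite(y)]
    if y.size < 3:
        raise DomainError("Box-Cox fit needs at least 3 finite values")
    if np.ptp(y) == 0:
        return BoxCoxFit(lambda_=1.0, shift=0.0, loglik=np.nan, applied=False)
    shift = 0.0
    if y.min() <= 0:
        shift = -y.min() + 1e-6 * max(np.ptp(y), 1.0)
    ys = y + shift

    grid = np.linspace(lambda_bounds[0], lambda_bounds[1], 201)
    ll = boxcox_profile_llf(grid, ys)
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda l: -float(boxcox_profile_llf(l, ys)[0]), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x)
    return BoxCoxFit(lambda_=lam, shift=shift, loglik=float(boxcox_profile_llf(lam, ys)[0]), applied=True)


def needs_transform(values: np.ndarray, group: pd.Series, alpha: float = 0.05) -> bool:
    """Trigger for the "as needed" transform decision.

    Apply when Shapiro-Wilk on cell-mean residuals rejects normality or
    Brown-Forsythe/Levene across the four groups rejects homoscedasticity.
    """
    y = np.asarray(values, dtype=float)
    groups = [y[np.asarray(group) == g] for g in GROUPS if np.any(np.asarray(group) == g)]
    resid = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(resid) == 0:
        return False
    sw_p = stats.shapiro(resid).pvalue
    lev_p = stats.levene(*groups, center="median").pvalue
    return bool(sw_p < alpha or lev_p < alpha)


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaRecord:
    analyte: str
    ss_race: float
    ss_disease: float
    ss_interaction: float
    ss_error: float
    ss_total: float
    df_race: int
    df_disease: int
    df_interaction: int
    df_error: int
    f_race: float
    f_disease: float
    f_interaction: float
    p_race: float
    p_disease: float
    p_interaction: float
    omnibus_f: float
    omnibus_p: float
    mse: float
    cell_means: dict = field(default_factory=dict)
    n_per_cell: int = 0


def twoway_anova(values, race, disease, analyte: str = "") -> AnovaRecord:
    """Balanced 2x2 ANOVA with interaction, via cell-mean identities.

    The omnibus test is the 3-df between-groups F over the four cells; the
    factor F statistics are ``MS_term / MSE``.
    """
    y = np.asarray(values, dtype=float)
    race = np.asarray(race)
    disease = np.asarray(disease)
    if not (y.shape == race.shape == disease.shape):
        raise DesignError("values, race and disease must be equal-length")

    cells: dict[tuple[str, str], np.ndarray] = {}
    for r in ("White", "AA"):
        for d in ("NoDx", "Dx"):
            sel = (race == r) & (disease == d)
            cells[(r, d)] = y[sel]
    sizes = {k: v.size for k, v in cells.items()}
    if min(sizes.values()) == 0:
        raise DesignError(f"empty design cell(s): {[k for k, s in sizes.items() if s == 0]}")
    if len(set(sizes.values())) != 1:
        raise DesignError(f"unbalanced design, cell sizes {sizes}")
    n = next(iter(sizes.values()))
    if n < 2:
        raise DesignError("need >= 2 replicates per cell")

    grand = y.mean()
    cm = {k: v.mean() for k, v in cells.items()}
    race_means = {r: (cm[(r, "NoDx")] + cm[(r, "Dx")]) / 2 for r in ("White", "AA")}
    dis_means = {d: (cm[("White", d)] + cm[("AA", d)]) / 2 for d in ("NoDx", "Dx")}

    ss_race = 2 * n * sum((race_means[r] - grand) ** 2 for r in ("White", "AA"))
    ss_dis = 2 * n * sum((dis_means[d] - grand) ** 2 for d in ("NoDx", "Dx"))
    ss_int = n * sum(
        (cm[(r, d)] - race_means[r] - dis_means[d] + grand) ** 2
        for r in ("White", "AA")
        for d in ("NoDx", "Dx")
    )
    ss_err = sum(float(((v - cm[k]) ** 2).sum()) for k, v in cells.items())
    ss_total = float(((y - grand) ** 2).sum())

    df_err = 4 * (n - 1)
    mse = ss_err / df_err
    scale = max(ss_total, 1.0)
    if mse <= 1e-14 * scale:
        raise DegenerateVarianceError(f"zero residual variance for {analyte or 'analyte'}")

    f_race = (ss_race / 1) / mse
    f_dis = (ss_dis / 1) / mse
    f_int = (ss_int / 1) / mse
    ss_between = ss_race + ss_dis + ss_int
    omnibus_f = (ss_between / 3) / mse

    sf = stats.f.sf
    group_means = {f"{d}-{r}": cm[(r, d)] for r in ("White", "AA") for d in ("NoDx", "Dx")}
    return AnovaRecord(
        analyte=analyte,
        ss_race=float(ss_race),
        ss_disease=float(ss_dis),
        ss_interaction=float(ss_int),
        ss_error=float(ss_err),
        ss_total=ss_total,
        df_race=1,
        df_disease=1,
        df_interaction=1,
        df_error=df_err,
        f_race=float(f_race),
        f_disease=float(f_dis),
        f_interaction=float(f_int),
        p_race=float(sf(f_race, 1, df_err)),
        p_disease=float(sf(f_dis, 1, df_err)),
        p_interaction=float(sf(f_int, 1, df_err)),
        omnibus_f=float(omnibus_f),
        omnibus_p=float(sf(omnibus_f, 3, df_err)),
        mse=float(mse),
        cell_means=group_means,
        n_per_cell=n,
    )


# ---------------------------------------------------------------------------
# Protected Fisher's LSD
# ---------------------------------------------------------------------------

@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    mean_diff: float
    pooled_se: float
    t: float
    p_raw: float
    p_fdr: float
    protected: bool


def protected_lsd(
    record: AnovaRecord,
    cell_means: Mapping[str, float] | None = None,
    n_per_cell: int | None = None,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """Fisher's LSD over the four pre-specified contrasts, gated on the omnibus F.

    ``t = diff / sqrt(MSE * 2/n)`` with the full-model error df ``4(n-1)``.
    Comparisons are always computed; ``protected`` records whether the omnibus
    test cleared ``alpha``.  ``p_fdr`` is BH over the four contrasts of this
    analyte; cross-analyte adjustment is done at the panel level.
    """
    cm = dict(cell_means) if cell_means is not None else record.cell_means
    n = n_per_cell if n_per_cell is not None else record.n_per_cell
    if record.df_error != 4 * (n - 1):
        raise DesignError(
            f"n_per_cell={n} inconsistent with error df {record.df_error}"
        )
    missing = [g for g in GROUPS if g not in cm]
    if missing:
        raise DesignError(f"cell means missing groups: {missing}")

    se = float(np.sqrt(record.mse * 2.0 / n))
    protected = bool(record.omnibus_p < alpha)
    raws = []
    out = []
    for a, b in CONTRAST_PAIRS:
        diff = float(cm[a] - cm[b])
        t = diff / se
        p = float(2 * stats.t.sf(abs(t), record.df_error))
        raws.append(p)
        out.append(
            PairwiseComparison(
                pair=(a, b), mean_diff=diff, pooled_se=se, t=float(t),
                p_raw=p, p_fdr=np.nan, protected=protected,
            )
        )
    adj = fdr_adjust(raws)
    for c, q in zip(out, adj):
        c.p_fdr = float(q)
    return out


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values, order-preserving on the input index."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # right-to-left running minimum enforces monotonicity
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Panel driver
# ---------------------------------------------------------------------------

def analyze_panel(
    cohort: CohortTable,
    panel: str,
    alpha: float = 0.05,
    boxcox: str = "auto",
) -> pd.DataFrame:
    """Run the full per-analyte pipeline over one panel.

    ``boxcox`` in {"auto", "always", "never"}: "auto" applies the transform
    only when the residual-normality / homoscedasticity trigger fires.
    Returns one row per analyte with SS/F/p per factor, raw and cross-analyte
    FDR-adjusted p-values, the four contrasts, and the Box-Cox decision.
    """
    if boxcox not in ("auto", "always", "never"):
        raise DomainError(f"boxcox must be auto|always|never, got {boxcox!r}")
    panel_df = cohort.panel(panel)
    race = cohort.race.to_numpy()
    disease = cohort.disease.to_numpy()
    group = cohort.group

    rows = []
    for analyte in panel_df.columns:
        y = panel_df[analyte].to_numpy(dtype=float)
        fit = BoxCoxFit(1.0, 0.0, np.nan, False)
        if boxcox != "never" and np.ptp(y) > 0:
            if boxcox == "always" or needs_transform(y, group):
                fit = boxcox_fit(y)
        yt = boxcox_transform(y, fit)
        rec = twoway_anova(yt, race, disease, analyte=analyte)
        comps = protected_lsd(rec, alpha=alpha)
        row = {
            "analyte": analyte,
            "boxcox_applied": fit.applied,
            "boxcox_lambda": fit.lambda_ if fit.applied else np.nan,
            "ss_race": rec.ss_race,
            "ss_disease": rec.ss_disease,
            "ss_interaction": rec.ss_interaction,
            "ss_error": rec.ss_error,
            "ss_total": rec.ss_total,
            "f_race": rec.f_race,
            "f_disease": rec.f_disease,
            "f_interaction": rec.f_interaction,
            "p_race": rec.p_race,
            "p_disease": rec.p_disease,
            "p_interaction": rec.p_interaction,
            "omnibus_f": rec.omnibus_f,
            "omnibus_p": rec.omnibus_p,
            "mse": rec.mse,
        }
        for (a, b), c in zip(CONTRAST_PAIRS, comps):
            tag = f"{a}_vs_{b}".replace("-", "")
            row[f"diff_{tag}"] = c.mean_diff
            row[f"t_{tag}"] = c.t
            row[f"p_{tag}"] = c.p_raw
            row[f"protected_{tag}"] = c.protected
        rows.append(row)
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    # FDR family: all analytes of this panel, one family per factor
    for factor in ("race", "disease", "interaction"):
        result[f"p_{factor}_fdr"] = fdr_adjust(result[f"p_{factor}"].to_numpy())
    result["omnibus_p_fdr"] = fdr_adjust(result["omnibus_p"].to_numpy())
    for a, b in CONTRAST_PAIRS:
        tag = f"{a}_vs_{b}".replace("-", "")
        result[f"p_{tag}_fdr"] = fdr_adjust(result[f"p_{tag}"].to_numpy())
    return result


def significant_analytes(panel_result: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Analytes FDR-significant for at least one factor (race/disease/interaction)."""
    if panel_result.empty:
        return []
    mask = (
        (panel_result["p_race_fdr"] < alpha)
        | (panel_result["p_disease_fdr"] < alpha)
        | (panel_result["p_interaction_fdr"] < alpha)
    )
    return panel_result.loc[mask, "analyte"].tolist()
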
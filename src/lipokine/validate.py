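"""Large-cohort confirmation stage: per-biomarker race contrast, raw and
covariate-adjusted (ordinary least squares with BMI and age).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable
from .errors import CollinearityError, DesignError, DomainError


@dataclass
class AdjustedComparison:
    biomarker: str
    raw_diff: float          # mean(White) - mean(AA)
    raw_p: float             # pooled-variance two-sample t
    welch_p: float           # unequal-variance t, reported alongside
    adjusted_diff: float     # race coefficient from biomarker ~ race + BMI + age
    adjusted_p: float        # Wald p for the race coefficient
    n_white: int
    n_aa: int
    log_transformed: bool


def race_contrast(
    biomarker,
    race,
    bmi,
    age,
    log_scale: bool = False,
    name: str = "",
) -> AdjustedComparison:
    """Raw and BMI/age-adjusted White-vs-AA contrast for one biomarker.

    The race regressor is coded White=1, AA=0, so both the raw difference and
    the adjusted coefficient are White minus AA.
    """
    y = np.asarray(biomarker, dtype=float)
    race = np.asarray(race)
    bmi = np.asarray(bmi, dtype=float)
    age = np.asarray(age, dtype=float)
    is_white = race == "White"
    is_aa = race == "AA"
    if not (is_white.any() and is_aa.any()):
        raise DesignError("both races must be present")
    if log_scale:
        if np.any(y <= 0):
            raise DomainError("log-scale analysis requires strictly positive values")
        y = np.log(y)

    yw, ya = y[is_white], y[is_aa]
    raw_diff = float(yw.mean() - ya.mean())
    raw = stats.ttest_ind(yw, ya, equal_var=True)
    welch = stats.ttest_ind(yw, ya, equal_var=False)

    X = np.column_stack([np.ones_like(y), is_white.astype(float), bmi, age])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient design (constant or collinear covariate)")
    fit = sm.OLS(y, X).fit()

    return AdjustedComparison(
        biomarker=name,
        raw_diff=raw_diff,
        raw_p=float(raw.pvalue),
        welch_p=float(welch.pvalue),
        adjusted_diff=float(fit.params[1]),
        adjusted_p=float(fit.pvalues[1]),
        n_white=int(is_white.sum()),
        n_aa=int(is_aa.sum()),
        log_transformed=log_scale,
    )


def apply_eligibility(
    df: pd.DataFrame,
    age_range: tuple[float, float] = (30.0, 65.0),
    bmi_range: tuple[float, float] = (20.0, 42.0),
    age_col: str = "age",
    bmi_col: str = "bmi",
) -> pd.DataFrame:
    """Replicate the confirmation-cohort eligibility window (age 30-65, BMI 20-42)."""
    keep = df[age_col].between(*age_range) & df[bmi_col].between(*bmi_range)
    return df[keep]


#: Biomarkers contrasted by default; hs-CRP runs on the log scale because of
#: its right-skewed (near-exponential) distribution.
DEFAULT_BIOMARKERS = {
    "clin_chol": False,
    "clin_chol_hdl_ratio": False,
    "clin_triglycerides": False,
    "clin_insulin": False,
    "clin_glucose": False,
    "clin_hs_crp": True,
}


def validate_panel(
    cohort: CohortTable,
    biomarkers: dict[str, bool] | None = None,
    eligibility: bool = True,
) -> pd.DataFrame:
    """Race contrasts for each biomarker; returns one tidy row per biomarker."""
    if biomarkers is None:
        biomarkers = {k: v for k, v in DEFAULT_BIOMARKERS.items() if k in cohort.data.columns}
    df = cohort.data
    if eligibility and {"age", "bmi"} <= set(df.columns):
        df = apply_eligibility(df)
    rows = []
    for marker, log_scale in biomarkers.items():
        comp = race_contrast(
            df[marker], df["race"], df["bmi"], df["age"], log_scale=log_scale, name=marker
        )
        rows.append(vars(comp))
    return pd.DataFrame(rows)
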
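"""Variable-attribution PCA: correlation-matrix eigendecomposition with
cos2 (quality of representation) and percentage contributions per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateVariableError, DomainError


@dataclass
class PcaResult:
    loadings: pd.DataFrame            # variables x components (correlation-circle coords)
    scores: pd.DataFrame              # subjects x components, unit variance
    explained_variance_fraction: pd.Series
    cos2: pd.DataFrame                # variables x components, in [0, 1]
    contribution_pct: pd.DataFrame    # variables x components, columns sum to 100
    eigenvalues: pd.Series

    def pc1_ranking(self) -> pd.Series:
        """Variables ordered by descending contribution to PC1."""
        return self.contribution_pct.iloc[:, 0].sort_values(ascending=False)


def pca_variability(table: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """Eigendecomposition of the correlation (or covariance) matrix.

    cos2 is the squared correlation-circle coordinate; contributions are
    cos2 normalized per component to percentages.  The sign of each
    component is fixed so its largest-|loading| entry is positive.
    """
    X = table.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2 or n < 3:
        raise DomainError("PCA needs >= 2 variables and >= 3 subjects")
    if np.any(~np.isfinite(X)):
        raise DomainError("PCA input contains missing/non-finite values")

    sd = X.std(axis=0, ddof=1)
    if standardize:
        bad = np.asarray(table.columns)[sd == 0]
        if bad.size:
            raise DegenerateVariableError(f"constant variable(s) under standardization: {list(bad)}")
        Z = (X - X.mean(axis=0)) / sd
        C = (Z.T @ Z) / (n - 1)
    else:
        Z = X - X.mean(axis=0)
        C = (Z.T @ Z) / (n - 1)

    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]

    # deterministic sign: largest-|entry| coordinate of each axis made positive
    for j in range(p):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]

    comps = [f"PC{i+1}" for i in range(p)]
    loadings = evecs * np.sqrt(evals)          # corr(variable, component score)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_sqrt = np.where(evals > 1e-12, 1.0 / np.sqrt(np.where(evals > 0, evals, 1.0)), 0.0)
    scores = Z @ evecs * inv_sqrt              # unit-variance scores; null axes -> 0

    cos2 = loadings ** 2
    row_tot = cos2.sum(axis=1, keepdims=True)
    cos2 = cos2 / np.where(row_tot > 0, row_tot, 1.0)
    col_tot = cos2.sum(axis=0, keepdims=True)
    contrib = 100.0 * cos2 / np.where(col_tot > 0, col_tot, 1.0)

    idx = table.columns
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=idx, columns=comps),
        scores=pd.DataFrame(scores, index=table.index, columns=comps),
        explained_variance_fraction=pd.Series(evals / evals.sum(), index=comps),
        cos2=pd.DataFrame(cos2, index=idx, columns=comps),
        contribution_pct=pd.DataFrame(contrib, index=idx, columns=comps),
        eigenvalues=pd.Series(evals, index=comps),
    )
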
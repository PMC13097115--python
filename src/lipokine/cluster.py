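"""K-means over analytes (in subject z-score space) with gap-statistic model
selection, and per-subject cluster-center scoring.

Analytes — not subjects — are the clustered objects: each analyte is a point
in R^{n_subjects} after z-scoring over subjects, and a cluster center score
for a subject is the mean z-score of the cluster's member analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "GapStatResult",
    "ClusterModel",
    "zscore_analytes",
    "kmeans_partition",
    "gap_statistic",
    "cluster_center_scores",
]


def zscore_analytes(panel_df: pd.DataFrame) -> pd.DataFrame:
    """Analytes x subjects matrix of z-scores (each analyte scaled over subjects)."""
    X = panel_df.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    return pd.DataFrame(Z.T, index=panel_df.columns, columns=panel_df.index)


# ---------------------------------------------------------------------------
# Lloyd's algorithm with k-means++ seeding
# ---------------------------------------------------------------------------

def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300, tol: float = 1e-10):
    """Lloyd iterations; returns (labels, centers, inertia, inertia_trace)."""
    k = centers.shape[0]
    trace: list[float] = []
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(X.shape[0]), labels].sum())
        if trace and trace[-1] - inertia < -1e-9 * max(trace[-1], 1.0):
            raise AssertionError("Lloyd iteration increased inertia")
        converged = bool(trace) and (trace[-1] - inertia) <= tol * max(inertia, 1.0)
        trace.append(inertia)
        new_centers = centers.copy()
        for j in range(k):
            members = X[labels == j]
            if members.size:
                new_centers[j] = members.mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fit point
                worst = int(d2[np.arange(X.shape[0]), labels].argmax())
                new_centers[j] = X[worst]
        if converged and np.allclose(new_centers, centers):
            break
        centers = new_centers
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    return labels, centers, inertia, trace


@dataclass
class ClusterModel:
    assignment: dict            # analyte -> 1-based cluster id
    centers: np.ndarray         # k x n_subjects centroid coordinates
    inertia: float
    k: int
    inertia_trace: list = field(default_factory=list)

    def members(self, cluster_id: int) -> list[str]:
        return [a for a, c in self.assignment.items() if c == cluster_id]


def kmeans_partition(
    features: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterModel:
    """Best-of-``n_init`` k-means (k-means++ seeding, Lloyd refinement).

    ``features`` is analytes x subjects; rows are the clustered points.
    """
    X = features.to_numpy(dtype=float)
    if k < 1:
        raise DomainError("k must be >= 1")
    if k > X.shape[0]:
        raise DomainError(f"k={k} exceeds number of analytes {X.shape[0]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    best = None
    for _ in range(n_init):
        centers0 = _kmeanspp(X, k, rng)
        labels, centers, inertia, trace = _lloyd(X, centers0)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia, trace)
    labels, centers, inertia, trace = best
    # relabel clusters by first-appearance order for determinism
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = {a: remap[lab] for a, lab in zip(features.index, labels)}
    centers = centers[[lab for lab, _ in sorted(remap.items(), key=lambda kv: kv[1])]]
    return ClusterModel(assignment=assignment, centers=centers, inertia=inertia, k=k, inertia_trace=trace)


# ---------------------------------------------------------------------------
# Gap statistic
# ---------------------------------------------------------------------------

@dataclass
class GapStatResult:
    k_grid: list
    gap: np.ndarray
    sk: np.ndarray
    k_star: int
    b_refs: int
    log_wk: np.ndarray
    ref_log_wk_mean: np.ndarray


def gap_statistic(
    features: pd.DataFrame,
    k_max: int,
    b_refs: int = 100,
    seed: int = 0,
    n_init: int = 5,
) -> GapStatResult:
    """Tibshirani gap statistic with principal-axes bounding-box references.

    ``Gap(k) = E*[log W_k] - log W_k``; ``k_star`` is the smallest k with
    ``Gap(k) >= Gap(k+1) - s_{k+1}`` (falling back to ``k_max``).
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if k_max < 1:
        raise DomainError("k_max must be >= 1")
    if k_max >= n:
        raise DomainError(f"k_max={k_max} must be < number of analytes ({n})")
    if b_refs < 20:
        raise DomainError("b_refs must be >= 20 for a usable reference distribution")

    ss = np.random.SeedSequence(seed)
    data_seed, ref_seed = ss.spawn(2)
    rng_ref = np.random.default_rng(ref_seed)

    mu = X.mean(axis=0)
    Xc = X - mu
    # principal-axes rotation of the bounding box (SVD right-singular vectors)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)

    k_grid = list(range(1, k_max + 1))
    data_child = data_seed.spawn(len(k_grid))
    log_wk = np.empty(len(k_grid))
    for i, k in enumerate(k_grid):
        model = kmeans_partition(features, k, seed=data_child[i].generate_state(1)[0], n_init=n_init)
        log_wk[i] = np.log(max(model.inertia, 1e-300))

    ref_log = np.empty((b_refs, len(k_grid)))
    for b in range(b_refs):
        Zp = rng_ref.uniform(lo, hi, size=Xp.shape)
        Z = Zp @ Vt + mu
        zdf = pd.DataFrame(Z)
        for i, k in enumerate(k_grid):
            m = kmeans_partition(zdf, k, seed=int(rng_ref.integers(2**31)), n_init=max(2, n_init // 2))
            ref_log[b, i] = np.log(max(m.inertia, 1e-300))

    gap = ref_log.mean(axis=0) - log_wk
    sk = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / b_refs)

    k_star = k_grid[-1]
    for i in range(len(k_grid) - 1):
        if gap[i] >= gap[i + 1] - sk[i + 1]:
            k_star = k_grid[i]
            break
    return GapStatResult(
        k_grid=k_grid, gap=gap, sk=sk, k_star=k_star, b_refs=b_refs,
        log_wk=log_wk, ref_log_wk_mean=ref_log.mean(axis=0),
    )


def cluster_center_scores(model: ClusterModel, panel_df: pd.DataFrame) -> pd.DataFrame:
    """Per-subject mean z-score over each cluster's member analytes.

    ``panel_df`` is subjects x analytes on the original scale; z-scoring over
    subjects happens here so scores are recomputable from the cohort alone.
    """
    missing = [a for a in model.assignment if a not in panel_df.columns]
    if missing:
        raise KeyError(f"model analytes absent from cohort: {missing[:5]}")
    Z = zscore_analytes(panel_df[list(model.assignment)])  # analytes x subjects
    out = {}
    for cid in sorted(set(model.assignment.values())):
        members = model.members(cid)
        out[f"cluster_{cid}"] = Z.loc[members].mean(axis=0)
    return pd.DataFrame(out, index=panel_df.index)
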
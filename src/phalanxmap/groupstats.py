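"""Multivariate comparison of thickness maps.

Standardized maps are flattened to a specimens × 4850 matrix and summarized by
PCA (mean-centered, unscaled — all cells share units).  Group structure is
then examined with a canonical variates analysis (CVA) on the leading PC
scores, a one-sample Hotelling T² test locating a single specimen relative to
a reference group, and typicality probabilities: the upper-tail probability of
a specimen's squared Mahalanobis distance to a group centroid, gauging how
plausibly the specimen belongs to that group.  Leave-one-out CVA
classification validates group separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .sectioning import ThicknessMap

__all__ = [
    "SampleMatrix",
    "PCAModel",
    "CVAModel",
    "TestResult",
    "TypicalityResult",
    "assemble_matrix",
    "pca",
    "hotelling_one_sample",
    "cva",
    "typicality",
    "loo_classification",
]

log = logging.getLogger("phalanxmap")


@dataclass
class SampleMatrix:
    """Specimens × cells data matrix with aligned labels and ids."""

    X: np.ndarray
    labels: list[str]
    ids: list[str]
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.X) or len(self.ids) != len(self.X):
            raise ValueError("labels/ids must align with rows of X")


@dataclass
class PCAModel:
    mean: np.ndarray            # (p,)
    components: np.ndarray      # (r, p) orthonormal rows
    eigenvalues: np.ndarray     # (r,) score variances
    scores: np.ndarray          # (n, r)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.mean) @ self.components.T


@dataclass
class CVAModel:
    axes: np.ndarray                    # (p, k) canonical axes, a^T S_w a = 1
    eigenvalues: np.ndarray             # (k,) between/within variance ratios
    grand_mean: np.ndarray              # (p,)
    group_names: list[str]
    group_means: np.ndarray             # (g, k) centroids in canonical space
    pooled_within_cov: np.ndarray       # (p, p)
    group_sizes: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def transform(self, scores: np.ndarray) -> np.ndarray:
        """Project PC-space vectors into canonical space (within-cov = I)."""
        return (np.atleast_2d(scores) - self.grand_mean) @ self.axes


@dataclass
class TestResult:
    T2: float
    F: float
    df1: int
    df2: int
    p_value: float


@dataclass
class TypicalityResult:
    group: str
    D2: float
    probability: float
    variant: str = "chi2"


# ---------------------------------------------------------------------------


def assemble_matrix(maps: Sequence[ThicknessMap], labels: Sequence[str],
                    ids: Optional[Sequence[str]] = None) -> SampleMatrix:
    """Flatten standardized maps row-major (level-major, then angle) into a
    specimens × cells matrix.

    Flagged (solid-section) cells are imputed with the per-column mean of
    unflagged values within the specimen's group; singleton groups fall back
    to the global column mean.  The imputation count is logged and recorded.
    """
    if len(maps) != len(labels):
        raise ValueError("one label per map required")
    if len(maps) < 3:
        raise ValueError("need at least 3 specimens")
    ref = maps[0]
    for m in maps:
        if not m.standardized:
            raise ValueError("all maps must be standardized before assembly")
        if m.shape != ref.shape or not np.allclose(m.levels, ref.levels):
            raise ValueError("maps are on different grids")
    X = np.vstack([m.values.ravel() for m in maps])
    M = np.vstack([m.mask.ravel() for m in maps])
    labels = list(labels)
    ids = list(ids) if ids is not None else \
        [m.meta.get("specimen_id") or f"s{i}" for i, m in enumerate(maps)]
    n_imputed = int(M.sum())
    if n_imputed:
        Xm = np.where(M, np.nan, X)
        global_col = np.nanmean(Xm, axis=0)
        for g in sorted(set(labels)):
            rows = np.array([i for i, l in enumerate(labels) if l == g])
            sub = Xm[rows]
            col = np.nanmean(sub, axis=0) if len(rows) > 1 else global_col.copy()
            col = np.where(np.isnan(col), global_col, col)
            sub = np.where(np.isnan(sub), col, sub)
            Xm[rows] = sub
        X = np.where(np.isnan(Xm), global_col, Xm)
        log.info("assemble_matrix: imputed %d flagged cells", n_imputed)
    return SampleMatrix(X=X, labels=labels, ids=ids, n_imputed=n_imputed)


def _fix_signs(components: np.ndarray, scores: Optional[np.ndarray] = None):
    """Deterministic sign convention: largest-|loading| element positive."""
    for j in range(components.shape[0]):
        i = int(np.argmax(np.abs(components[j])))
        if components[j, i] < 0:
            components[j] *= -1
            if scores is not None:
                scores[:, j] *= -1
    return components, scores


def pca(sample: SampleMatrix | np.ndarray, r: Optional[int] = None,
        scale: bool = False) -> PCAModel:
    """PCA by singular value decomposition of the mean-centered matrix.

    Cells are NOT scaled to unit variance by default (they share units);
    ``scale=True`` enables the correlation-matrix variant.  Component signs
    follow a deterministic convention (largest-magnitude loading positive).
    """
    X = sample.X if isinstance(sample, SampleMatrix) else np.asarray(sample, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 rows for PCA")
    mean = X.mean(axis=0)
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    rmax = min(n - 1, p)
    if r is None:
        r = rmax
    if not 1 <= r <= rmax:
        raise ValueError(f"r must be in [1, {rmax}]")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("data matrix has rank 0 (all rows identical)")
    eigenvalues = s ** 2 / (n - 1)
    components = Vt[:r]
    scores = U[:, :r] * s[:r]
    components, scores = _fix_signs(components, scores)
    return PCAModel(mean=mean, components=components,
                    eigenvalues=eigenvalues[:r], scores=scores)


def hotelling_one_sample(group_scores: np.ndarray, target: np.ndarray) -> TestResult:
    """One-sample Hotelling T²: does the sample mean differ from ``target``?

    T² = m (x̄ − μ₀)ᵀ S⁻¹ (x̄ − μ₀);  F = T² (m − p) / (p (m − 1)) on
    (p, m − p) degrees of freedom.
    """
    X = np.atleast_2d(np.asarray(group_scores, dtype=float))
    target = np.asarray(target, dtype=float).ravel()
    m, p = X.shape
    if m <= p:
        raise ValueError(f"need more observations ({m}) than dimensions ({p})")
    diff = X.mean(axis=0) - target
    S = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular sample covariance; use fewer PCs") from exc
    if np.linalg.cond(S) > 1e12:
        raise ValueError("near-singular sample covariance; use fewer PCs")
    T2 = float(m * diff @ sol)
    F = T2 * (m - p) / (p * (m - 1))
    pval = float(stats.f.sf(F, p, m - p))
    return TestResult(T2=T2, F=float(F), df1=p, df2=m - p, p_value=pval)


def cva(scores: np.ndarray, labels: Sequence[str]) -> CVAModel:
    """Canonical variates analysis on (typically the first 3) PC scores.

    Solves the generalized eigenproblem of between-group versus pooled
    within-group covariance; axes are scaled so the pooled within-group
    covariance is the identity in canonical space, and ordered by decreasing
    between/within variance ratio.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = list(labels)
    n, p = X.shape
    if len(labels) != n:
        raise ValueError("one label per row required")
    names = sorted(set(labels))
    g = len(names)
    if g < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.array([labels.count(name) for name in names])
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 members")
    grand = X.mean(axis=0)
    means = np.vstack([X[[i for i, l in enumerate(labels) if l == name]].mean(axis=0)
                       for name in names])
    W = np.zeros((p, p))
    for name in names:
        sub = X[[i for i, l in enumerate(labels) if l == name]]
        d = sub - sub.mean(axis=0)
        W += d.T @ d
    Sw = W / (n - g)
    B = np.zeros((p, p))
    for k, name in enumerate(names):
        d = (means[k] - grand)[:, None]
        B += sizes[k] * (d @ d.T)
    Sb = B / (g - 1)
    try:
        from scipy.linalg import eigh
        evals, evecs = eigh(Sb, Sw)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled within-group covariance") from exc
    order = np.argsort(evals)[::-1]
    k_axes = min(g - 1, p)
    evals = evals[order][:k_axes]
    A = evecs[:, order][:, :k_axes]          # already a^T Sw a = 1 from eigh
    A_t, _ = _fix_signs(A.T.copy())
    A = A_t.T
    group_means_canon = (means - grand) @ A
    return CVAModel(axes=A, eigenvalues=np.maximum(evals, 0.0), grand_mean=grand,
                    group_names=names, group_means=group_means_canon,
                    pooled_within_cov=Sw, group_sizes=sizes)


def typicality(model: CVAModel, specimen: np.ndarray, group: str,
               variant: str = "chi2") -> TypicalityResult:
    """Typicality probability of a specimen for one reference group.

    D² is the squared distance to the group centroid in canonical space
    (where the pooled within-group covariance is the identity, so this is the
    Mahalanobis distance).  ``variant='chi2'`` uses the large-sample χ²_k
    upper tail; ``variant='f'`` the small-sample F form for a new observation,
    F = D² · m(m − k) / (k (m − 1)(m + 1)) on (k, m − k) df.
    """
    if group not in model.group_names:
        raise ValueError(f"unknown group {group!r}; have {model.group_names}")
    z = model.transform(np.asarray(specimen, dtype=float))[0]
    gi = model.group_names.index(group)
    d2 = float(np.sum((z - model.group_means[gi]) ** 2))
    k = model.n_axes
    if variant == "chi2":
        prob = float(stats.chi2.sf(d2, k))
    elif variant == "f":
        m = int(model.group_sizes[gi])
        if m <= k:
            raise ValueError("group too small for the F-based typicality variant")
        Fstat = d2 * m * (m - k) / (k * (m - 1) * (m + 1))
        prob = float(stats.f.sf(Fstat, k, m - k))
    else:
        raise ValueError("variant must be 'chi2' or 'f'")
    return TypicalityResult(group=group, D2=d2, probability=prob, variant=variant)


def loo_classification(scores: np.ndarray, labels: Sequence[str],
                       ids: Optional[Sequence[str]] = None) -> dict:
    """Leave-one-out CVA classification to nearest group centroid.

    For each specimen the CVA is refitted without it and the held-out
    specimen assigned to the nearest centroid in canonical space.  Returns
    per-group accuracies, overall accuracy, and the confusion matrix.
    """
    X = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = list(labels)
    ids = list(ids) if ids is not None else [f"s{i}" for i in range(len(X))]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate specimen ids: {dup}")
    names = sorted(set(labels))
    counts = {name: labels.count(name) for name in names}
    small = [name for name, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"groups with fewer than 3 members: {small}")
    import pandas as pd
    confusion = pd.DataFrame(0, index=names, columns=names)
    for i in range(len(X)):
        keep = np.ones(len(X), dtype=bool)
        keep[i] = False
        model = cva(X[keep], [l for j, l in enumerate(labels) if j != i])
        z = model.transform(X[i])[0]
        d2 = np.sum((model.group_means - z) ** 2, axis=1)
        pred = model.group_names[int(np.argmin(d2))]
        confusion.loc[labels[i], pred] += 1
    per_group = {name: float(confusion.loc[name, name] / counts[name]) for name in names}
    overall = float(np.trace(confusion.to_numpy()) / len(X))
    return {"per_group_accuracy": per_group, "overall_accuracy": overall,
            "confusion": confusion}
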
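"""Ordinal (nonmetric) multidimensional scaling via stress majorization.

SMACOF with monotone regression on dissimilarity ranks (primary approach
to ties): each iteration fits disparities by isotonic regression of the
current configuration distances on the dissimilarity order, then applies
the Guttman transform, guaranteeing a non-increasing stress sequence.
Fit quality is Kruskal's stress-1.  The best of several starts (classical
Torgerson scaling plus random configurations) is retained, rotated to
principal axes, with axis signs fixed deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .dissimilarity import DissimMatrix
from .features import FeatureTable
from .rsa import fdr_correct, kendall_tau


class MDSError(ValueError):
    pass


@dataclass
class MDSSolution:
    coordinates: pd.DataFrame          # items x dimensions
    stress: float                      # Kruskal stress-1
    n_dimensions: int
    stress_trace: list[float] = field(default_factory=list)
    dimension_correlations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates.to_numpy())):
            raise MDSError("non-finite coordinates")


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    return float(np.sqrt(((dhat - d) ** 2).sum() / (d**2).sum()))


def _torgerson(delta_sq: np.ndarray, k: int) -> np.ndarray:
    """Classical (Torgerson) scaling of a squared-dissimilarity matrix."""
    n = delta_sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ delta_sq @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(lam)


def _smacof_single(delta: np.ndarray, X: np.ndarray, tol: float,
                   max_iter: int) -> tuple[np.ndarray, float, list[float]]:
    """One SMACOF run; returns (configuration, stress-1, stress trace)."""
    n = delta.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    dvec = delta[iu, ju]
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True)
    pos = np.arange(dvec.size, dtype=float)

    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        dhat_sorted = iso.fit_transform(pos, d[order])
        dhat = np.empty_like(d)
        dhat[order] = dhat_sorted
        # normalize disparities to the scale of the current distances
        scale = np.sqrt((d**2).sum() / max((dhat**2).sum(), 1e-300))
        dhat *= scale
        stress = _stress1(d, dhat)
        trace.append(stress)
        if prev - stress < tol * max(prev, 1e-12):
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n
    return X, trace[-1], trace


def ordinal_mds(
    matrix: DissimMatrix,
    n_dimensions: int = 3,
    n_starts: int = 8,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> MDSSolution:
    """Nonmetric MDS of a (symmetrized) dissimilarity matrix.

    The diagonal is defined as the scale minimum (identical pairs were
    never presented) and the fit uses only off-diagonal pairs.  The
    first start is classical Torgerson scaling; the remaining
    ``n_starts - 1`` are random.  The best-stress configuration is
    centered, rotated to principal axes, and sign-fixed (largest-
    magnitude coordinate positive per axis).
    """
    vals = np.asarray(matrix.values, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise MDSError("dissimilarity matrix must be square")
    delta = 0.5 * (vals + vals.T)
    if matrix.value_range is not None:
        np.fill_diagonal(delta, matrix.value_range[0])
    else:
        np.fill_diagonal(delta, 0.0)
    n = delta.shape[0]
    if n_dimensions >= n:
        raise MDSError("n_dimensions must be below the item count")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3D5]))
    starts = [_torgerson(delta**2, n_dimensions)]
    starts += [rng.standard_normal((n, n_dimensions)) * delta[np.triu_indices(n, 1)].mean()
               for _ in range(n_starts - 1)]

    best = None
    for X0 in starts:
        X, stress, trace = _smacof_single(delta, X0.copy(), tol, max_iter)
        if best is None or stress < best[1]:
            best = (X, stress, trace)
    X, stress, trace = best

    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T  # principal axes
    for k in range(n_dimensions):  # deterministic reflection
        if X[np.argmax(np.abs(X[:, k])), k] < 0:
            X[:, k] = -X[:, k]
    coords = pd.DataFrame(X, index=matrix.items,
                          columns=[f"dim{k + 1}" for k in range(n_dimensions)])
    return MDSSolution(coords, stress, n_dimensions, trace)


def stress_scree(matrix: DissimMatrix, max_dimensions: int = 6,
                 n_starts: int = 8, seed: int = 0) -> pd.DataFrame:
    """Stress-1 per dimensionality from 1 to ``max_dimensions``."""
    if max_dimensions >= len(matrix.items):
        raise MDSError("max_dimensions must be below the item count")
    rows = [(k, ordinal_mds(matrix, k, n_starts=n_starts, seed=seed).stress)
            for k in range(1, max_dimensions + 1)]
    return pd.DataFrame(rows, columns=["n_dimensions", "stress"])


def dimension_feature_correlations(
    solution: MDSSolution,
    features: FeatureTable,
    feature_names: list[str] | None = None,
) -> pd.DataFrame:
    """Kendall tau of each dimension's coordinates with each scalar feature.

    FDR correction is applied within each dimension; axes are reflected
    (in place on the solution) so the feature with the largest |tau| on
    each axis correlates positively.
    """
    names = feature_names or list(features.scalars.columns)
    coords = solution.coordinates
    missing = [i for i in coords.index if i not in features.scalars.index]
    if missing:
        raise MDSError(f"features missing for embedded items {missing[:5]}")
    feats = features.scalars.loc[coords.index]

    rows = []
    for dim in coords.columns:
        taus = {}
        for name in names:
            v = feats[name].to_numpy()
            try:
                taus[name] = kendall_tau(coords[dim].to_numpy(), v)
            except Exception:
                taus[name] = np.nan  # constant feature: undefined
        finite = {k: t for k, t in taus.items() if np.isfinite(t)}
        if finite:
            top = max(finite, key=lambda k: abs(finite[k]))
            if finite[top] < 0:  # orient axis toward its dominant feature
                coords[dim] = -coords[dim]
                taus = {k: (-t if np.isfinite(t) else t) for k, t in taus.items()}
        for name in names:
            rows.append((dim, name, taus[name]))
    table = pd.DataFrame(rows, columns=["dimension", "feature", "tau"])

    n_items = len(coords)
    table["p"] = np.nan
    table["p_fdr"] = np.nan
    for dim in coords.columns:
        mask = (table.dimension == dim) & table.tau.notna()
        if mask.any():
            sub = table.loc[mask]
            pvals = [two_sided_tau_p(t, n_items) for t in sub.tau]
            table.loc[mask, "p"] = pvals
            table.loc[mask, "p_fdr"] = fdr_correct(pvals)
    return table


def two_sided_tau_p(tau: float, n: int) -> float:
    """Two-sided p for Kendall tau with n observations (normal approximation)."""
    from scipy import stats as _st
    if n < 3:
        return np.nan
    var = 2 * (2 * n + 5) / (9 * n * (n - 1))
    z = tau / np.sqrt(var)
    return float(2 * _st.norm.sf(abs(z)))
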
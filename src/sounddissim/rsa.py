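"""Representational similarity analysis of dissimilarity vectors.

Standard and semi-partial Kendall tau-b correlations between a
behavioral dissimilarity vector and per-feature acoustic distance
vectors, with one-sided permutation p-values p = (r + 1)/(n + 1) (r =
number of null statistics meeting or exceeding the observed one over n
shuffles of the behavioral vector) and Benjamini-Hochberg FDR control
within each subset x statistic family.

The semi-partial statistic residualizes the *ranks* of the target
feature's distances on the ranks of the remaining features by least
squares and correlates the behavior with the residual, matching the
rank-ordered character of the base statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dissimilarity import DissimMatrix, subset_indices
from .features import FeatureTable, SCALAR_FEATURES, VECTOR_FEATURES
from . import dissimilarity as dsm


class RSAError(ValueError):
    pass


DEFAULT_N_PERMUTATIONS = 10_000

#: analysis subsets: name -> (category_a, category_b); None = all pairs
DEFAULT_SUBSETS = {
    "overall": (None, None),
    "environmental-environmental": ("environmental", "environmental"),
    "instrument-instrument": ("instrument", "instrument"),
    "vocal-vocal": ("vocal", "vocal"),
    "environmental-instrument": ("environmental", "instrument"),
    "environmental-vocal": ("environmental", "vocal"),
    "vocal-instrument": ("vocal", "instrument"),
}

#: F0 features are only informative where F0 was allowed to vary:
#: both F0 median and IQR in vocal-vocal, F0 IQR in vocal-instrument,
#: neither anywhere else (F0 was equated across the other comparisons).
_F0_RULE = {
    "vocal-vocal": {"f0_median", "f0_iqr"},
    "vocal-instrument": {"f0_iqr"},
}


def features_for_subset(subset_name: str,
                        base_features: list[str] | None = None) -> list[str]:
    """Applicable feature list for one analysis subset."""
    base = base_features or (SCALAR_FEATURES + VECTOR_FEATURES)
    allowed_f0 = _F0_RULE.get(subset_name, set())
    return [f for f in base if not f.startswith("f0_") or f in allowed_f0]


# ---------------------------------------------------------------------------
# Kendall tau
# ---------------------------------------------------------------------------

def kendall_tau(x, y) -> float:
    """Tie-corrected Kendall tau-b between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise RSAError("inputs must be equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise RSAError("zero variance input: tau undefined")
    return float(stats.kendalltau(x, y).statistic)


def _pair_index(m: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(m, k=1)


def _tie_term(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float((counts * (counts - 1) / 2).sum())


def tau_b_batch(Y: np.ndarray, x: np.ndarray, chunk: int = 256) -> np.ndarray:
    """Kendall tau-b of each row of ``Y`` against ``x``.

    Short vectors use the pairwise-sign representation (nc - nd = sum
    over pairs of sign(x_i - x_j) * sign(y_i - y_j), vectorized over
    rows); long vectors fall back to the O(m log m) merge-sort statistic
    per row, which is faster once the pair matrix no longer fits in
    cache.  Both paths are tie-corrected (tau-b).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    x = np.asarray(x, dtype=float)
    m = x.size
    n_pairs = m * (m - 1) // 2
    if Y.shape[0] * n_pairs > 2e8:
        return np.array([stats.kendalltau(row, x).statistic for row in Y])
    iu, ju = _pair_index(m)
    sx = np.sign(x[iu] - x[ju]).astype(np.float32)
    n0 = float(n_pairs)
    tx = _tie_term(x)
    out = np.empty(Y.shape[0])
    for start in range(0, Y.shape[0], chunk):
        block = Y[start : start + chunk]
        sy = np.sign(block[:, iu] - block[:, ju]).astype(np.float32)
        s = sy @ sx
        ny = np.array([_tie_term(row) for row in block])
        denom = np.sqrt((n0 - tx) * (n0 - ny))
        out[start : start + chunk] = s / denom
    return out


def semi_partial_residual(x, Z) -> np.ndarray:
    """Residual of rank(x) after least-squares regression on rank(Z)."""
    x = np.asarray(x, dtype=float)
    rx = stats.rankdata(x)
    if Z is None or (hasattr(Z, "size") and np.size(Z) == 0) or len(Z) == 0:
        return rx
    Z = np.column_stack([stats.rankdata(z) for z in np.atleast_2d(Z)])
    design = np.column_stack([np.ones(len(rx)), Z])
    beta, *_ = np.linalg.lstsq(design, rx, rcond=None)
    resid = rx - design @ beta
    if np.std(resid) < 1e-8 * (np.std(rx) + 1e-12):
        raise RSAError("degenerate semi-partial residual (target collinear "
                       "with controls)")
    return resid


def semi_partial_tau(y, x, Z=None) -> float:
    """Kendall tau of ``y`` with the rank-residualized ``x``.

    With empty ``Z`` this equals ``kendall_tau(y, x)``.
    """
    return kendall_tau(y, semi_partial_residual(x, Z))


def permutation_test(y, x, Z=None, n: int = DEFAULT_N_PERMUTATIONS,
                     seed=0, statistic: str = "standard"):
    """One-sided permutation test of a (semi-partial) Kendall correlation.

    The correspondence between behavior and features is broken by
    permuting ``y``; r counts null statistics >= the observed one and
    p = (r + 1)/(n + 1).  Returns (observed tau, r, p).
    """
    if n < 1:
        raise RSAError("n must be >= 1")
    y = np.asarray(y, dtype=float)
    if statistic == "standard":
        x_eff = np.asarray(x, dtype=float)
    elif statistic == "semipartial":
        x_eff = semi_partial_residual(x, Z)
    else:
        raise RSAError(f"unknown statistic {statistic!r}")
    observed = kendall_tau(y, x_eff)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(y, (n, 1)), axis=1)
    nulls = tau_b_batch(perms, x_eff)
    r = int(np.count_nonzero(nulls >= observed - 1e-12))
    return observed, r, (r + 1) / (n + 1)


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise RSAError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class RSAReport:
    """Tidy per-(subset, feature, statistic) RSA results."""

    table: pd.DataFrame
    n_iterations: int
    seed: int

    def top_feature(self, subset: str = "overall",
                    statistic: str = "standard") -> str:
        sub = self.table.query("subset == @subset and statistic == @statistic")
        return sub.loc[sub.tau.idxmax(), "feature"]


def rsa_report(
    behavior: DissimMatrix,
    features: FeatureTable,
    subsets: dict | None = None,
    n: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    feature_names: list[str] | None = None,
    pair_mode: str = "unordered",
) -> RSAReport:
    """Standard + semi-partial tau with permutation p for every subset.

    The behavioral matrix is symmetrized first and analyzed over
    unordered pairs by default (``pair_mode='ordered'`` duplicates each
    predictor value across both orders instead).  FDR is applied across
    features within each subset x statistic family.
    """
    if list(behavior.items) != list(features.items):
        raise RSAError("behavior matrix and feature table must cover the same "
                       "items in the same order")
    subsets = subsets or DEFAULT_SUBSETS
    base = feature_names or (SCALAR_FEATURES + VECTOR_FEATURES)
    beh = behavior.symmetrized()
    dist = {name: dsm.feature_distance_matrix(features, name) for name in base}

    rows = []
    for si, (sub_name, (cat_a, cat_b)) in enumerate(subsets.items()):
        ii, jj = subset_indices(beh.items, features.categories, cat_a, cat_b)
        if pair_mode == "ordered" and cat_a != cat_b:
            ii, jj = np.concatenate([ii, jj]), np.concatenate([jj, ii])
        y = beh.values[ii, jj]
        feats = features_for_subset(sub_name, base)
        X = {f: dist[f].values[ii, jj] for f in feats}
        for stat in ("standard", "semipartial"):
            for fi, fname in enumerate(feats):
                Z = ([X[g] for g in feats if g != fname]
                     if stat == "semipartial" else None)
                sub_seed = np.random.SeedSequence(
                    [int(seed), 0x25A, si, fi, 0 if stat == "standard" else 1])
                try:
                    tau, r, p = permutation_test(
                        y, X[fname], Z, n=n, seed=sub_seed, statistic=stat)
                    flag = ""
                except RSAError as err:
                    tau, r, p, flag = np.nan, -1, np.nan, str(err)
                rows.append((sub_name, fname, stat, tau, r, n, p, flag))
    table = pd.DataFrame(rows, columns=["subset", "feature", "statistic",
                                        "tau", "r", "n", "p", "flag"])
    table["p_fdr"] = np.nan
    for (sub_name, stat), grp in table.groupby(["subset", "statistic"]):
        ok = grp.p.notna()
        if ok.any():
            table.loc[grp.index[ok], "p_fdr"] = fdr_correct(grp.p[ok].to_numpy())
    return RSAReport(table, n, seed)
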
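"""Identification-side analyses and rating reliability.

Covers item-level identification accuracy, one-tailed Wilcoxon
signed-rank comparisons against chance with FDR correction,
within-subcategory recoding of accuracy, the Kendall correlation between
confusion rates and dissimilarity ratings (with diagonal-averaging), and
split-half reliability of ratings adjusted by the Spearman-Brown
prophecy formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dissimilarity import DissimMatrix, RatingTable
from .rsa import fdr_correct, kendall_tau


class BehaviorError(ValueError):
    pass


@dataclass
class ConfusionTable:
    """Stimulus x response counts, per participant.

    ``data`` is long format with columns participant, stimulus, response
    (one row per trial) or participant, stimulus, response, count.
    """

    data: pd.DataFrame
    items: list[str]
    subcategory_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"participant", "stimulus", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise BehaviorError(f"confusion table missing columns {sorted(missing)}")
        if "count" not in self.data.columns:
            self.data = (self.data.groupby(["participant", "stimulus", "response"])
                         .size().rename("count").reset_index())

    def pooled_counts(self) -> pd.DataFrame:
        """Stimulus x response count matrix pooled over participants."""
        mat = (self.data.groupby(["stimulus", "response"])["count"].sum()
               .unstack(fill_value=0))
        return mat.reindex(index=self.items, columns=self.items, fill_value=0)

    def participant_counts(self, participant: str) -> pd.DataFrame:
        sub = self.data[self.data.participant == participant]
        mat = sub.groupby(["stimulus", "response"])["count"].sum().unstack(fill_value=0)
        return mat.reindex(index=self.items, columns=self.items, fill_value=0)

    @property
    def participants(self) -> list[str]:
        return sorted(self.data.participant.unique())


def item_accuracy(conf: ConfusionTable) -> pd.DataFrame:
    """Proportion correct per (participant, item): diagonal / row sum."""
    rows = []
    for p in conf.participants:
        counts = conf.participant_counts(p)
        presentations = counts.sum(axis=1)
        if (presentations == 0).any():
            missing = list(presentations.index[presentations == 0])[:5]
            raise BehaviorError(f"no presentations for items {missing}")
        correct = pd.Series(np.diag(counts), index=counts.index)
        for item in conf.items:
            rows.append((p, item, correct[item] / presentations[item]))
    return pd.DataFrame(rows, columns=["participant", "item", "accuracy"])


def recode_subcategory(conf: ConfusionTable) -> pd.DataFrame:
    """Accuracy counting any response within the stimulus's subcategory as
    correct (instrument family, vowel, or excitation medium)."""
    unmapped = [i for i in conf.items if i not in conf.subcategory_map]
    if unmapped:
        raise BehaviorError(f"items missing from subcategory map: {unmapped[:5]}")
    sub = conf.subcategory_map
    rows = []
    for p in conf.participants:
        counts = conf.participant_counts(p)
        presentations = counts.sum(axis=1)
        for item in conf.items:
            same = [r for r in conf.items if sub[r] == sub[item]]
            hit = counts.loc[item, same].sum()
            rows.append((p, item, hit / presentations[item]))
    return pd.DataFrame(rows, columns=["participant", "item", "accuracy"])


def accuracy_vs_chance(per_participant_item_acc: pd.DataFrame,
                       chance_level: float) -> pd.DataFrame:
    """One-tailed Wilcoxon signed-rank test per item against chance.

    Tests whether participant-level accuracies for each item exceed
    ``chance_level`` (alternative = greater, zero differences dropped),
    with BH-FDR across items.  Items where every participant scores
    exactly chance are flagged (test undefined).
    """
    df = per_participant_item_acc
    if df.participant.nunique() < 2:
        raise BehaviorError("need at least 2 participants")
    rows = []
    for item, grp in df.groupby("item", sort=False):
        diffs = grp.accuracy.to_numpy() - chance_level
        if np.all(diffs == 0):
            rows.append((item, np.nan, "all values equal chance"))
            continue
        res = stats.wilcoxon(diffs, alternative="greater",
                             zero_method="wilcox", method="auto")
        rows.append((item, float(res.pvalue), ""))
    out = pd.DataFrame(rows, columns=["item", "p", "flag"])
    ok = out.p.notna()
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = fdr_correct(out.p[ok].to_numpy())
    return out


def confusion_dissim_correlation(conf: ConfusionTable, ratings: DissimMatrix,
                                 mode: str = "full") -> float:
    """Kendall tau between pooled confusion rates and dissimilarity ratings.

    Both matrices are averaged across their diagonals (symmetrized).  In
    ``full`` mode the diagonal is included, with the ratings diagonal set
    to the scale minimum; ``restricted`` mode keeps only off-diagonal
    cells with at least one confusion.
    """
    if list(conf.items) != list(ratings.items):
        raise BehaviorError("confusion and rating matrices must share items")
    C = conf.pooled_counts().to_numpy(dtype=float)
    C = C / C.sum(axis=1, keepdims=True)  # rates
    C = 0.5 * (C + C.T)
    R = ratings.symmetrized().values.copy()
    lo = ratings.value_range[0] if ratings.value_range else 1.0
    np.fill_diagonal(R, lo)
    n = len(conf.items)
    iu, ju = np.triu_indices(n, k=0 if mode == "full" else 1)
    c, r = C[iu, ju], R[iu, ju]
    if mode == "restricted":
        keep = c > 0
        if not keep.any():
            raise BehaviorError("restricted mode: no off-diagonal confusions")
        c, r = c[keep], r[keep]
    elif mode != "full":
        raise BehaviorError(f"unknown mode {mode!r}")
    return kendall_tau(c, r)


def spearman_brown(r: float) -> float:
    """Full-test reliability predicted from a split-half correlation."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(table: RatingTable, n_splits: int = 100,
                           seed: int = 0) -> float:
    """Mean Spearman-Brown-adjusted split-half correlation of pair means.

    Each split randomly halves the participants; per-half mean ratings
    per ordered pair are correlated (Pearson) over the pairs covered by
    both halves, then adjusted by 2r/(1 + r).
    """
    participants = sorted(table.data.participant.unique())
    if len(participants) < 4:
        raise BehaviorError("need at least 4 participants for split-half")
    df = table.data
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5B]))
    adjusted = []
    for _ in range(n_splits):
        perm = rng.permutation(participants)
        half_a = set(perm[: len(perm) // 2])
        mean_a = (df[df.participant.isin(half_a)]
                  .groupby(["item_first", "item_second"]).rating.mean())
        mean_b = (df[~df.participant.isin(half_a)]
                  .groupby(["item_first", "item_second"]).rating.mean())
        joined = pd.concat([mean_a, mean_b], axis=1, join="inner", keys=["a", "b"])
        if len(joined) < 3:
            continue
        if joined.a.std() == 0 and joined.b.std() == 0 and joined.a.equals(joined.b):
            r = 1.0
        elif joined.a.std() == 0 or joined.b.std() == 0:
            continue
        else:
            r = float(np.corrcoef(joined.a, joined.b)[0, 1])
        adjusted.append(spearman_brown(r))
    if not adjusted:
        raise BehaviorError("no valid splits")
    return float(np.mean(adjusted))
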
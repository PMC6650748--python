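"""Pairwise dissimilarity structures: behavioral ratings and acoustic distances.

Acoustic dissimilarity between two items is the absolute difference of a
scalar feature, or the Euclidean distance between vector representations
(cochleagram channel summaries, modulation power spectra).  Behavioral
dissimilarity is the mean 1-9 rating per ordered item pair, optionally
symmetrized by averaging (i, j) with (j, i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable, SCALAR_FEATURES
from .stimuli import StimulusSet


class DissimilarityError(ValueError):
    pass


@dataclass
class DissimMatrix:
    """Square item x item dissimilarity matrix with category labels."""

    items: list[str]
    values: np.ndarray
    kind: str  # behavioral_rating | acoustic_distance | confusion
    categories: dict[str, str] = field(default_factory=dict)
    value_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise DissimilarityError(
                f"matrix shape {self.values.shape} does not match {n} items"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    def symmetrized(self) -> "DissimMatrix":
        """Average each cell with its transpose counterpart."""
        return DissimMatrix(
            self.items, 0.5 * (self.values + self.values.T), self.kind,
            dict(self.categories), self.value_range,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.items, columns=self.items)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) values as a vector of unordered pairs."""
        iu, ju = np.triu_indices(self.n_items, k=1)
        return self.values[iu, ju]


@dataclass
class RatingTable:
    """Trial-level dissimilarity ratings (long format)."""

    data: pd.DataFrame  # participant, item_first, item_second, rating, block

    def __post_init__(self) -> None:
        required = {"participant", "item_first", "item_second", "rating"}
        missing = required - set(self.data.columns)
        if missing:
            raise DissimilarityError(f"rating table missing columns {sorted(missing)}")
        if len(self.data):
            if (self.data.item_first == self.data.item_second).any():
                raise DissimilarityError("item_first must differ from item_second")
            r = self.data.rating
            if ((r < 1) | (r > 9)).any():
                raise DissimilarityError("ratings must lie in 1..9")


def feature_distance_matrix(features: FeatureTable, feature_name: str,
                            metric: str = "auto") -> DissimMatrix:
    """Item x item distance matrix for one feature.

    Scalar features use |a - b|; vector features use Euclidean distance.
    """
    vals = features.feature_values(feature_name)
    finite = np.isfinite(vals) if np.ndim(vals) == 1 else np.isfinite(vals).all(axis=1)
    if not finite.all():
        bad = [features.items[i] for i in np.flatnonzero(~finite)]
        raise DissimilarityError(f"feature {feature_name!r} missing/undefined for {bad}")
    if metric == "auto":
        metric = "absdiff" if np.ndim(vals) == 1 else "euclidean"
    if metric == "absdiff":
        D = np.abs(vals[:, None] - vals[None, :])
    elif metric == "euclidean":
        V = np.atleast_2d(vals)
        sq = (V**2).sum(axis=1)
        D = np.sqrt(np.maximum(sq[:, None] + sq[None, :] - 2 * V @ V.T, 0.0))
        np.fill_diagonal(D, 0.0)
    else:
        raise DissimilarityError(f"unknown metric {metric!r}")
    return DissimMatrix(features.items, D, "acoustic_distance",
                        dict(features.categories))


def all_feature_distances(features: FeatureTable,
                          feature_names: list[str] | None = None) -> dict[str, DissimMatrix]:
    names = feature_names or list(features.scalars.columns) + list(features.vectors)
    return {name: feature_distance_matrix(features, name) for name in names}


def aggregate_ratings(table: RatingTable, items: list[str],
                      symmetrize: bool = False,
                      value_range: tuple[float, float] = (1.0, 9.0)) -> DissimMatrix:
    """Mean rating per ordered (first, second) pair.

    Every off-diagonal ordered pair must be covered by at least one
    rating; with ``symmetrize`` the (i, j) and (j, i) cells are averaged.
    """
    idx = {item: i for i, item in enumerate(items)}
    n = len(items)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n))
    df = table.data
    rows = df.item_first.map(idx).to_numpy()
    cols = df.item_second.map(idx).to_numpy()
    np.add.at(sums, (rows, cols), df.rating.to_numpy(dtype=float))
    np.add.at(counts, (rows, cols), 1)
    off = ~np.eye(n, dtype=bool)
    if np.any(counts[off] == 0):
        iu, ju = np.where((counts == 0) & off)
        missing = [(items[i], items[j]) for i, j in zip(iu[:5], ju[:5])]
        raise DissimilarityError(
            f"{(counts[off] == 0).sum()} ordered pairs have no ratings, e.g. {missing}"
        )
    values = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    mat = DissimMatrix(items, values, "behavioral_rating", value_range=value_range)
    return mat.symmetrized() if symmetrize else mat


def pairing_note_rule(item_i: str, item_j: str, stimulus_set: StimulusSet) -> dict[str, str]:
    """Which note each instrument in a pair is rendered at.

    A vocal-instrument pair uses the vowel's matched note; any other pair
    involving an instrument uses the default note (E3).  Returns a map
    from instrument label to note (empty when no instrument is involved).
    """
    cats = stimulus_set.categories
    result: dict[str, str] = {}
    pair = (item_i, item_j)
    vocal = next((p for p in pair if cats.get(p) == "vocal"), None)
    for p in pair:
        if cats.get(p) == "instrument":
            result[p] = (stimulus_set.note_table[vocal] if vocal is not None
                         else stimulus_set.default_note)
    return result


def subset_vector(matrix: DissimMatrix, category_a: str, category_b: str) -> np.ndarray:
    """Matrix cells for one within- or between-category subset.

    Within-category (a == b) returns the unordered pairs i < j; between
    categories it returns all row-in-a x column-in-b cells.
    """
    cats = [matrix.categories.get(i) for i in matrix.items]
    known = set(c for c in cats if c is not None)
    for c in (category_a, category_b):
        if c not in known:
            raise DissimilarityError(f"unknown category {c!r}")
    a_idx = np.array([i for i, c in enumerate(cats) if c == category_a])
    b_idx = np.array([i for i, c in enumerate(cats) if c == category_b])
    if category_a == category_b:
        iu, ju = np.triu_indices(len(a_idx), k=1)
        out = matrix.values[a_idx[iu], a_idx[ju]]
    else:
        out = matrix.values[np.ix_(a_idx, b_idx)].ravel()
    if out.size == 0:
        raise DissimilarityError("empty subset")
    return out


def subset_indices(items: list[str], categories: dict[str, str],
                   category_a: str | None, category_b: str | None) -> tuple[np.ndarray, np.ndarray]:
    """Row/column index arrays of the cells belonging to one subset.

    ``None`` categories select the overall subset: all unordered pairs.
    """
    n = len(items)
    if category_a is None or category_b is None:
        return np.triu_indices(n, k=1)
    cats = [categories.get(i) for i in items]
    a_idx = np.array([i for i, c in enumerate(cats) if c == category_a])
    b_idx = np.array([i for i, c in enumerate(cats) if c == category_b])
    if a_idx.size == 0 or b_idx.size == 0:
        raise DissimilarityError(f"empty subset ({category_a}, {category_b})")
    if category_a == category_b:
        iu, ju = np.triu_indices(len(a_idx), k=1)
        return a_idx[iu], a_idx[ju]
    rows = np.repeat(a_idx, b_idx.size)
    cols = np.tile(b_idx, a_idx.size)
    return rows, cols
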
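"""Importance aggregation: group → average → top-d → intersect → rank.

The importance rows produced by the L balanced samplings are partitioned into
q subgroups and averaged within each; each subgroup contributes its top-d
features (1-based positions); features common to ALL subgroups are kept, their
positions averaged, and the result sorted ascending by mean position.  The
final list can therefore be shorter than d.

Tie rules (deterministic, the procedure itself does not fix them):
within a subgroup, equal importances are broken by ascending feature index;
equal mean positions across subgroups are broken by higher overall mean
importance, then by ascending feature index (feature order taken from the
importance tensor, or lexicographic name order when used standalone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceTensor",
    "GroupRanking",
    "RankedFeatureList",
    "group_importances",
    "top_d",
    "intersect_and_rank",
    "aggregate",
]


@dataclass
class ImportanceTensor:
    """L × m per-sampling feature importances (rows normalized to sum 1)."""

    values: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be L × m")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if (self.values < 0).any():
            raise ValueError("importances must be non-negative")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


@dataclass
class GroupRanking:
    """Top-d features of one subgroup, positions 1..d strictly increasing."""

    group_index: int
    feature_names: list[str]
    positions: list[int]
    importances: list[float]

    def __post_init__(self) -> None:
        if list(self.positions) != list(range(1, len(self.feature_names) + 1)):
            raise ValueError("positions must be 1..d")
        if len(self.importances) != len(self.feature_names):
            raise ValueError("importances length mismatch")

    @property
    def d(self) -> int:
        return len(self.feature_names)

    def position_of(self, name: str) -> int:
        return self.positions[self.feature_names.index(name)]

    def importance_of(self, name: str) -> float:
        return self.importances[self.feature_names.index(name)]


@dataclass
class RankedFeatureList:
    """Final ordered selection: (name, mean position, mean importance, rank)."""

    feature_names: list[str] = field(default_factory=list)
    mean_positions: list[float] = field(default_factory=list)
    mean_importances: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.feature_names)
        if len(self.mean_positions) != k or len(self.mean_importances) != k:
            raise ValueError("parallel lists must have equal length")

    def __len__(self) -> int:
        return len(self.feature_names)

    @property
    def ranks(self) -> list[int]:
        return list(range(1, len(self) + 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": self.ranks,
                "feature_name": self.feature_names,
                "mean_position": self.mean_positions,
                "mean_importance": self.mean_importances,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedFeatureList):
            return NotImplemented
        return (
            self.feature_names == other.feature_names
            and np.allclose(self.mean_positions, other.mean_positions)
            and np.allclose(self.mean_importances, other.mean_importances)
        )


def group_importances(tensor: ImportanceTensor, q: int, interleaved: bool = False) -> np.ndarray:
    """Average the L importance rows into q subgroup vectors (q × m).

    Rows are assigned contiguously by default: subgroup g gets rows
    (g·L/q)..((g+1)·L/q − 1).  ``interleaved=True`` assigns row l to subgroup
    l mod q instead.
    """
    L = tensor.L
    if q < 1 or L % q != 0:
        raise ValueError(f"q={q} must be a positive divisor of L={L}")
    size = L // q
    if interleaved:
        return np.stack([tensor.values[g::q].mean(axis=0) for g in range(q)])
    return np.stack([tensor.values[g * size : (g + 1) * size].mean(axis=0) for g in range(q)])


def top_d(group_vector: np.ndarray, d: int, feature_names: Sequence[str], group_index: int = 1) -> GroupRanking:
    """Top-d features of one subgroup vector, importance descending.

    Ties are broken by ascending feature index, so the ranking is a pure
    deterministic function of the vector.
    """
    v = np.asarray(group_vector, dtype=float)
    m = v.shape[0]
    if d > m:
        raise ValueError(f"d={d} exceeds number of features m={m}")
    order = sorted(range(m), key=lambda j: (-v[j], j))[:d]
    return GroupRanking(
        group_index=group_index,
        feature_names=[feature_names[j] for j in order],
        positions=list(range(1, d + 1)),
        importances=[float(v[j]) for j in order],
    )


def intersect_and_rank(
    rankings: Sequence[GroupRanking], feature_order: Optional[Sequence[str]] = None
) -> RankedFeatureList:
    """Keep features present in every subgroup's top-d, rank by mean position.

    ``mean_position`` is the arithmetic mean of the feature's 1-based positions
    over the q subgroups; ``mean_importance`` the mean of its subgroup-mean
    importances.  Sorting is ascending by mean position, ties broken by higher
    mean importance, then by ``feature_order`` index (lexicographic name order
    when not supplied).  An empty intersection yields an empty list with a
    logged warning.
    """
    from .io import get_logger

    if len(rankings) < 1:
        raise ValueError("need at least one group ranking")
    common = set(rankings[0].feature_names)
    for r in rankings[1:]:
        common &= set(r.feature_names)
    if not common:
        get_logger().warning("subgroup top-d sets have empty intersection; no features selected")
        return RankedFeatureList()

    if feature_order is not None:
        index = {name: i for i, name in enumerate(feature_order)}
    else:
        index = {name: i for i, name in enumerate(sorted(common))}

    stats = []
    for name in common:
        positions = [r.position_of(name) for r in rankings]
        importances = [r.importance_of(name) for r in rankings]
        stats.append((name, float(np.mean(positions)), float(np.mean(importances))))
    stats.sort(key=lambda t: (t[1], -t[2], index[t[0]]))
    return RankedFeatureList(
        feature_names=[s[0] for s in stats],
        mean_positions=[s[1] for s in stats],
        mean_importances=[s[2] for s in stats],
    )


def aggregate(tensor: ImportanceTensor, q: int, d: int, interleaved: bool = False) -> RankedFeatureList:
    """Full pipeline: subgroup means → per-subgroup top-d → intersection rank."""
    vectors = group_importances(tensor, q, interleaved=interleaved)
    rankings = [
        top_d(vectors[g], d, tensor.feature_names, group_index=g + 1) for g in range(q)
    ]
    return intersect_and_rank(rankings, feature_order=tensor.feature_names)
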
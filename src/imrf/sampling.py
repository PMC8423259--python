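"""Balanced bootstrap sampling of an imbalanced cohort.

The imbalanced sample set is split into L class-balanced subsets, each holding
exactly n_min samples per class (n_min = size of the smallest class).  Unlike
per-iteration random undersampling, subsets are dealt in *rounds* so that every
sample — in particular every majority-class sample — is used at least once per
round:

* round size r = max over classes of ceil(n_c / n_min);
* within a round, each class's samples are freshly permuted and dealt into
  disjoint chunks of n_min; a trailing partial chunk is topped up by sampling
  without replacement from the class's other members, and if the class runs out
  of chunks before the round does, further chunks are dealt from a fresh
  permutation (the smallest class therefore contributes all of its samples to
  every subset, keeping its empirical distribution fixed);
* rounds repeat with fresh permutations until L subsets exist.  L is free and
  need not equal the round size.

Reading note: "bootstrapping" here is this disjoint dealing with top-up — NOT
independent with-replacement draws per subset — because only the dealing
variant guarantees that majority-class samples are collectively fully used
within a round.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import ceil

import numpy as np

from .io import LabelVector

__all__ = ["BalancedSubset", "SamplingPlan", "plan_subsets", "round_size_for"]


@dataclass
class BalancedSubset:
    """Per-class index lists, all of length n_min, no repeats within a class."""

    indices_by_class: dict
    subset_seed: int

    def __post_init__(self) -> None:
        sizes = {len(v) for v in self.indices_by_class.values()}
        if len(sizes) != 1:
            raise ValueError(f"per-class lists must have equal length, got sizes {sizes}")
        for cls, idx in self.indices_by_class.items():
            if len(set(idx)) != len(idx):
                raise ValueError(f"repeated index within class {cls!r}")

    @property
    def all_indices(self) -> list[int]:
        return [i for idx in self.indices_by_class.values() for i in idx]


@dataclass
class SamplingPlan:
    subsets: list
    round_size: int

    @property
    def L(self) -> int:
        return len(self.subsets)

    def to_json(self, path) -> None:
        payload = {
            "round_size": self.round_size,
            "subsets": [
                {str(c): [int(i) for i in idx] for c, idx in s.indices_by_class.items()}
                for s in self.subsets
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def round_size_for(labels: LabelVector) -> int:
    """Subsets needed for one full-coverage round: max_c ceil(n_c / n_min)."""
    n_min = labels.n_min
    return max(ceil(count / n_min) for count in labels.counts.values())


def plan_subsets(labels: LabelVector, L: int | None = None, seed: int = 0) -> SamplingPlan:
    """Build L balanced subsets in full-coverage rounds.

    Guarantees, asserted downstream: every subset holds exactly n_min indices
    per class with no within-class repeats, and within each complete round
    every sample index of every class appears in at least one subset.  Default
    L is two full rounds.
    """
    if any(count < 2 for count in labels.counts.values()):
        raise ValueError("every class needs at least 2 samples")
    r = round_size_for(labels)
    if L is None:
        L = 2 * r
    if L < 1:
        raise ValueError("L must be ≥ 1")

    n_min = labels.n_min
    rng = np.random.default_rng(seed)
    per_class_members = {c: labels.indices_of(c) for c in labels.class_set}

    subsets: list[BalancedSubset] = []
    while len(subsets) < L:
        chunks_by_class = {
            c: _class_round_chunks(per_class_members[c], n_min, r, rng)
            for c in labels.class_set
        }
        for j in range(r):
            if len(subsets) == L:
                break
            subset_seed = int(rng.integers(2**31))
            subsets.append(
                BalancedSubset(
                    indices_by_class={c: chunks_by_class[c][j] for c in labels.class_set},
                    subset_seed=subset_seed,
                )
            )
    return SamplingPlan(subsets=subsets, round_size=r)


def _class_round_chunks(members: np.ndarray, n_min: int, r: int, rng: np.random.Generator) -> list[list[int]]:
    """Deal one class's members into r disjoint-within-permutation chunks.

    Members are permuted and dealt sequentially into chunks of n_min; a
    trailing partial chunk is topped up without replacement from members not
    already in it; once a permutation is exhausted a fresh one is dealt, so a
    class smaller than r·n_min recycles (the smallest class yields all its
    members in every chunk).
    """
    members = list(members)
    chunks: list[list[int]] = []
    queue: list[int] = []
    while len(chunks) < r:
        if not queue:
            queue = list(rng.permutation(members))
        if len(queue) >= n_min:
            chunks.append([int(i) for i in queue[:n_min]])
            queue = queue[n_min:]
        else:
            partial = [int(i) for i in queue]
            others = [int(i) for i in members if i not in set(partial)]
            extra = rng.choice(len(others), size=n_min - len(partial), replace=False)
            chunks.append(partial + [others[k] for k in extra])
            queue = []
    return chunks
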
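"""Set operators on per-class feature images, and their exhaustive check.

For classes with feature images φ(O_1), ..., φ(O_k) (subsets of a finite
feature universe), define

* ``com`` — the common features, the intersection of all images;
* ``dis`` — the discriminating features, union minus intersection;
* for exactly three classes, a two-level stratification of ``dis``:
  ``dis_l1`` = union minus the union of all pairwise intersections (features
  private to a single class — the most differentiating), and
  ``dis_l2`` = union of pairwise intersections minus the triple intersection
  (features shared by exactly two classes).

These operators explain why features informative for many classes need not be
informative for fewer classes and vice versa — e.g. why a pixel shared by two
planted-image classes is useless for separating those two classes from each
other, and why two-class problems generally need fewer informative features
than four-class problems.  :func:`verify_theorem` checks the expected
identities over *all* triples of subsets of a small universe.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

__all__ = ["FeatureMap", "com", "dis", "dis_l1", "dis_l2", "verify_theorem", "TheoremReport"]


@dataclass
class FeatureMap:
    """Extensional class → feature-subset table over a finite universe."""

    universe: list
    assignments: dict

    def __post_init__(self) -> None:
        if len(self.assignments) < 2:
            raise ValueError("need at least 2 classes")
        uni = set(self.universe)
        for cls, subset in self.assignments.items():
            if not set(subset) <= uni:
                raise ValueError(f"assignment for {cls!r} outside universe")

    def images(self) -> list[frozenset]:
        return [frozenset(self.assignments[c]) for c in self.assignments]


def _as_sets(sets: Sequence) -> list[frozenset]:
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    return [frozenset(s) for s in sets]


def com(sets: Sequence) -> frozenset:
    """Common features: intersection of all images."""
    sets = _as_sets(sets)
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def dis(sets: Sequence) -> frozenset:
    """Discriminating features: union of all images minus their intersection."""
    sets = _as_sets(sets)
    union = frozenset().union(*sets)
    return union - com(sets)


def _require_three(sets: Sequence) -> list[frozenset]:
    if len(sets) != 3:
        raise ValueError("level stratification is defined for exactly 3 sets")
    return [frozenset(s) for s in sets]


def dis_l1(sets: Sequence) -> frozenset:
    """Level-1 discriminating features: in some image but in no pairwise overlap."""
    a, b, c = _require_three(sets)
    union = a | b | c
    pairwise = (a & b) | (a & c) | (b & c)
    return union - pairwise


def dis_l2(sets: Sequence) -> frozenset:
    """Level-2 discriminating features: in a pairwise overlap but not in all three."""
    a, b, c = _require_three(sets)
    pairwise = (a & b) | (a & c) | (b & c)
    return pairwise - (a & b & c)


@dataclass
class TheoremReport:
    universe_size: int
    triples_checked: int
    violations: int
    counterexample: tuple | None

    @property
    def ok(self) -> bool:
        return self.violations == 0


def _check_triple(a: int, b: int, c: int, full: int) -> bool:
    """Bitmask check of the identities for one triple of subsets.

    Checked properties (∪/∩ on bitmasks):
    1. Dis(abc) ⊆ a ∪ b ∪ c  (every discriminating feature lies in the pair's
       union, its intersection, or the third image);
    2. Dis(ab) ≠ ∅  ⇒  Dis(ab) ∩ Dis(abc) ≠ ∅;
    3. #Dis(ab) ≤ #Dis(abc);
    4.1 pairwise level-1 equals pairwise Dis;
    4.2 Dis_l1(abc) ∩ Dis_l2(abc) = ∅;
    4.3 Dis_l1(abc) ∪ Dis_l2(abc) = Dis(abc);
    4.4 Com(abc) ⊊ Com(ac) or Com(abc) ⊊ Com(bc)  ⇒  ∃ω ∈ Dis(ab) \\ Dis_l1(abc).
    """
    union3 = a | b | c
    inter3 = a & b & c
    dis3 = union3 & ~inter3 & full
    dis_ab = (a | b) & ~(a & b) & full
    pairwise = (a & b) | (a & c) | (b & c)
    l1 = union3 & ~pairwise & full
    l2 = pairwise & ~inter3 & full

    if dis3 & ~union3 & full:  # property 1 (subset form)
        return False
    if dis_ab and not (dis_ab & dis3):  # property 2
        return False
    if bin(dis_ab).count("1") > bin(dis3).count("1"):  # property 3
        return False
    if dis_ab != ((a | b) & ~(a & b) & full):  # property 4.1 (pairwise l1 = pairwise dis)
        return False
    if l1 & l2:  # property 4.2
        return False
    if (l1 | l2) != dis3:  # property 4.3
        return False
    com_ac, com_bc = a & c, b & c
    strict = (inter3 != com_ac and (inter3 & ~com_ac) == 0) or (
        inter3 != com_bc and (inter3 & ~com_bc) == 0
    )
    if strict and not (dis_ab & ~l1 & full):  # property 4.4
        return False
    return True


def verify_theorem(universe_size: int) -> TheoremReport:
    """Check all identities over every triple of subsets of a small universe.

    Enumerates all (2^u)^3 triples with bitmask arithmetic; ``universe_size``
    is capped at 6 (2^18 triples) to keep the enumeration exact and fast.
    """
    if not 1 <= universe_size <= 6:
        raise ValueError("universe_size must be in 1..6")
    full = (1 << universe_size) - 1
    n_subsets = 1 << universe_size
    checked = violations = 0
    counterexample = None
    for a in range(n_subsets):
        for b in range(n_subsets):
            for c in range(n_subsets):
                checked += 1
                if not _check_triple(a, b, c, full):
                    violations += 1
                    if counterexample is None:
                        counterexample = (a, b, c)
    return TheoremReport(
        universe_size=universe_size,
        triples_checked=checked,
        violations=violations,
        counterexample=counterexample,
    )
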
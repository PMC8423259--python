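"""Neuropathology-based subject categorization.

Subjects are assigned to one of four study classes from three post-mortem
scores: Braak stage (0–6, neurofibrillary-tangle distribution), CERAD score
(1–4, neuritic plaque density) and the dichotomized TDP-43 stage (0/1, the
LATE indicator).  AD-range pathology means Braak ≥ 5 together with CERAD ≤ 2;
TDP-43 = 1 calls LATE:

===========================================  =========
Braak ≥ 5 and CERAD ≤ 2 and TDP-43 = 1       LATE+AD
(Braak < 5 or CERAD > 2) and TDP-43 = 1      pure LATE
Braak ≥ 5 and CERAD ≤ 2 and TDP-43 = 0       pure AD
(Braak < 5 or CERAD > 2) and TDP-43 = 0      control
===========================================  =========

The four predicates partition the valid score grid: exactly one class fires
for every record.  A simpler Braak-only dichotomy (AD iff Braak ≥ 5) is
provided for cohorts without TDP-43 staging.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .io import LabelVector, _sep_for

__all__ = [
    "CLASS_SET",
    "NeuropathRecord",
    "categorize_subject",
    "categorize_cohort",
    "braak_dichotomy",
    "read_neuropath_table",
]

CLASS_SET = ["LATE+AD", "pure LATE", "pure AD", "control"]


@dataclass(frozen=True)
class NeuropathRecord:
    """One subject's Braak (0–6), CERAD (1–4) and TDP-43 (0/1) scores."""

    subject_id: str
    braak: int
    cerad: int
    tdp43: int

    def __post_init__(self) -> None:
        if not 0 <= self.braak <= 6:
            raise ValueError(f"braak must be in [0, 6], got {self.braak}")
        if not 1 <= self.cerad <= 4:
            raise ValueError(f"cerad must be in [1, 4], got {self.cerad}")
        if self.tdp43 not in (0, 1):
            raise ValueError(f"tdp43 must be 0 or 1, got {self.tdp43}")


def categorize_subject(record: NeuropathRecord) -> str:
    """Map one record to its study class (see module docstring for the rules)."""
    ad_pathology = record.braak >= 5 and record.cerad <= 2
    if record.tdp43 == 1:
        return "LATE+AD" if ad_pathology else "pure LATE"
    return "pure AD" if ad_pathology else "control"


def categorize_cohort(records: Iterable[NeuropathRecord]):
    """Categorize every record; returns (LabelVector, subject_ids).

    Subject IDs must be unique.  Class counts (including zero counts) are in
    the returned LabelVector.
    """
    records = list(records)
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate subject id(s): {dupes}")
    labels = LabelVector.from_labels(
        [categorize_subject(r) for r in records], class_set=CLASS_SET
    )
    return labels, ids


def braak_dichotomy(braak: int) -> str:
    """Binary AD call for cohorts staged by Braak only: AD iff Braak ≥ 5."""
    if not 0 <= braak <= 6:
        raise ValueError(f"braak must be in [0, 6], got {braak}")
    return "AD" if braak >= 5 else "control"


def read_neuropath_table(path, delimiter: Optional[str] = None) -> list[NeuropathRecord]:
    """Read a (subject_id, braak, cerad, tdp43) table with a header row."""
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=0)
    required = {"subject_id", "braak", "cerad", "tdp43"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    return [
        NeuropathRecord(
            subject_id=str(row.subject_id),
            braak=int(row.braak),
            cerad=int(row.cerad),
            tdp43=int(row.tdp43),
        )
        for row in df.itertuples()
    ]
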
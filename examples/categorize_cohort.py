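"""Stratify a synthetic autopsy cohort into the four study classes.

Draws Braak (0–6), CERAD (1–4) and dichotomized TDP-43 (0/1) scores for 430
synthetic subjects and applies the categorization rules: AD-range pathology
is Braak ≥ 5 with CERAD ≤ 2, and TDP-43 = 1 calls LATE, yielding LATE+AD,
pure LATE, pure AD and control.
"""

import numpy as np

from imrf import NeuropathRecord, categorize_cohort, categorize_subject

rng = np.random.default_rng(0)
records = [
    NeuropathRecord(
        subject_id=f"subj{i:03d}",
        braak=int(rng.integers(0, 7)),
        cerad=int(rng.integers(1, 5)),
        tdp43=int(rng.random() < 0.27),  # LATE prevalence in aged autopsy series
    )
    for i in range(430)
]
labels, ids = categorize_cohort(records)
print("class counts for 430 synthetic subjects:")
for cls, count in labels.counts.items():
    print(f"  {cls:10s} {count:4d}")

example = NeuropathRecord("demo", braak=5, cerad=2, tdp43=1)
print(f"\nBraak 5, CERAD 2, TDP-43 1  ->  {categorize_subject(example)}")
print("(both thresholds are inclusive: Braak ≥ 5 and CERAD ≤ 2 is AD-range pathology)")
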
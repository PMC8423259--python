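# Methods

## Model and procedure

The selector treats feature identification in imbalanced multi-class data as
an ensemble-of-ensembles problem. A single forest trained on the pooled
cohort optimizes pooled impurity, which under-weights splits that matter for
rare classes; a single undersampled forest discards most majority samples.
The integrated design does neither: it trains many forests, each on a
class-balanced subset, such that across one "round" of subsets every sample
of every class is used, and then demands that a feature prove itself in
*every* subgroup of runs before it is selected.

### Balanced sampling (stage 1)

With class counts *n₁ … n_k* and *n*<sub>min</sub> = min *n_c*, a round
consists of *r* = max<sub>c</sub> ⌈*n_c*/*n*<sub>min</sub>⌉ subsets. Per
round, each class's samples are freshly permuted and dealt into disjoint
chunks of size *n*<sub>min</sub>; a trailing partial chunk is topped up by
drawing, without replacement, from the class's other members, and a class
that runs out of chunks before the round does continues from a fresh
permutation. Consequences, asserted as invariants in the tests:

* every subset holds exactly *n*<sub>min</sub> indices per class, none
  repeated within a class;
* within a complete round, every sample index appears in ≥ 1 subset
  (full utilization of majority-class data — the designed contrast with
  per-iteration undersampling, which resamples with replacement and has no
  coverage guarantee);
* the smallest class is reused intact in every subset, keeping its empirical
  distribution fixed rather than bootstrap-perturbed.

The wording "bootstrapping to balance the samples" admits a
with-replacement reading; this package deliberately implements the
disjoint-dealing reading because only it delivers the coverage property that
motivates the design. *L* is free: rounds recycle until *L* subsets exist,
and the default *L* = 2*r* gives two full coverage rounds.

### Forests and importances (stages 2–4)

Each subset trains *p* forests of *T* trees with distinct derived seeds.
"Importance" is mean-decrease-in-impurity (Gini), the random-forest default,
normalized to sum to one per forest so rows are comparable across subsets;
the subset's importance row is the mean of its *p* normalized vectors
(re-normalized defensively). Validation uses a single stratified holdout
drawn once per run — 16 samples per class when every class can spare 16 and
still train, otherwise 20% of the smallest class — and each subset's report
scores the majority vote of its *p* forests; out-of-bag estimation is not
used because subsets are undersampled. Reports are averaged element-wise,
so an averaged F1 is the mean of F1s, not the harmonic mean of averaged
precision and recall.

### Aggregation (stage 5)

The *L* importance rows are partitioned contiguously into *q* subgroups
(*q* | *L*; an interleaved option exists) and averaged within each. Each
subgroup contributes its top *d* features at 1-based positions; only
features present in all *q* top-*d* lists survive; survivors are ranked by
arithmetic mean position. Tie rules are the package's own, deterministic
and documented: importance ties within a subgroup break by ascending feature
index; mean-position ties break by higher mean importance, then feature
index. The output is *not* padded back to *d* when the intersection is
small — a short list is information (the runs disagree), not a defect.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| L | balanced samplings | 2 × round size (config default 8) | two full coverage rounds |
| p | forest initializations per sampling | 2 | averages out seed noise at modest cost |
| q | aggregation subgroups | 4 | must divide L; more subgroups = stricter intersection |
| d | top features per subgroup | 20 | selection budget; final list ≤ d |
| T | trees per forest | 200 (tests/benchmarks); use ~10,000 for fidelity runs | importance variance falls with T |
| validation_per_class | holdout size | 16 per class when affordable | matches the benchmark protocol of 16 test samples per class |
| max_features / max_depth | split hyper-parameters | √m / unlimited | conventional forest defaults; exposed in config |

All randomness flows from one integer seed expanded through a
`numpy.random.SeedSequence` spawn tree (run seed → holdout / plan / forest
root → per-task seeds), so the L×p trainings are schedule-independent and a
run is a pure function of (data, config). Samples are canonically reordered
by sample id on entry, making results invariant to input row order.

## Synthetic benchmarks

`generate_planted_images` emulates the planted-feature image benchmark:
uniform integer noise on [0, 244], 4×4 intensity-0 squares at an upper-left
anchor (4, 4), a lower-left anchor (H−8, 4), and optionally a fixed shared
square at (H//2, W−8) for classes 1 and 2; each non-shared square is
displaced exactly `offset` pixels in one of the four axis directions, chosen
uniformly per image. Anchor coordinates and the four-direction reading of
the offset are this package's explicit choices; the truth mask is the exact
union of achievable square positions (60 pixels per jittered square at
offset 3). Class ratios are honored exactly (the ratio sum must divide n).

`generate_planted_tabular` emulates an imbalanced expression matrix:
Gaussian noise N(0, σ²) with each informative feature shifting one target
class (assigned in rotation) by `effect_size`. Null features are exactly
exchangeable across classes, so `effect_size=0` is a true global null.

What these benchmarks do **not** emulate: correlated genes, heavy-tailed or
heteroscedastic expression noise, batch effects, and probe-level redundancy.
Passing the recovery tests therefore shows the machinery ranks and
intersects correctly under known ground truth, not that selections from real
transcriptome data are biologically correct.

Benchmark problem sizes in the test suite and acceptance script are reduced
relative to a full study — 28×23 frames instead of 112×92, T = 200 instead
of 10,000, 5 seeds — chosen as the package's own trade-off between
statistical resolution and a comfortable desktop run; the class ratios,
intensity range, point geometry and offsets are kept at the study values.

## Statistical conventions

* ANOVA is the one-way fixed-effects F test computed per feature from sums
  of squares, vectorized over features; p from F(k−1, n−k). Degenerate
  conventions: a globally constant feature gets p = 1 (no signal); zero
  within-group variance with positive between-group variance gets p = 0
  (perfect separation). Zero-ness is judged at relative tolerance 1e−12
  against the feature's total sum of squares.
* Two threshold conventions coexist deliberately: counts use strictly
  "> α", ratio reports bucket the boundary into the "⩾ α" fraction. Both
  are exercised against the shipped published signature p-values.
* No multiple-testing correction is applied anywhere; all reported p-values
  are raw. Screening a selected signature with per-feature tests is
  descriptive, not inferential.
* The SVM harness uses a degree-3 polynomial kernel, C = 1, features
  standardized on the training split only; only the kernel family is fixed
  by the validation protocol, the rest are conventional defaults.
* Classification metrics are one-vs-rest; F1 = 2PR/(P+R), defined as 0 when
  P + R = 0.

## Set operators

For per-class feature images the package implements the common set
(intersection), discriminating set (union minus intersection), and — for
exactly three classes — the two-level stratification: level 1 (features
private to one class) and level 2 (features shared by exactly two). The
expected identities (levels partition the discriminating set; pairwise
discriminating sets embed in and never exceed the triple's; strict shrinkage
of the common set forces a level-2 feature) are verified exhaustively over
all (2^u)³ triples for universes u = 1…6 via bitmask enumeration. The
generalization of the levels beyond three classes is intentionally not
implemented.

## Design choices where the design was open

* **Subset construction** (dealing vs independent bootstraps): dealing, for
  the coverage guarantee; documented above.
* **Weight formula for the cost-weighted baseline**: inverse class
  frequency, n/(k·n_c) — the standard choice, via scikit-learn's
  "balanced" mode; the per-bootstrap variant uses "balanced_subsample",
  which recomputes weights from each tree's realized bootstrap counts.
* **Per-tree undersampling baseline** is hand-rolled over decision trees
  (fresh balanced draw per tree, majority classes with replacement) because
  no installed library implements that per-tree contract.
* **Holdout instead of out-of-bag** for validation, since balanced subsets
  break the out-of-bag premise.
* **Duplicate feature names** (repeated probes for one gene are kept as
  distinct columns) are disambiguated at load with a logged `.k` suffix.

## Known limitations

* Mean-decrease-in-impurity importance is biased toward high-cardinality
  features; on expression data all features are continuous so the bias is
  roughly uniform, but permutation importance is not offered.
* The intersection can be empty when subgroups disagree (warning, empty
  list); interpretation is left to the user.
* The level-stratified set operators are defined for exactly three classes.
* Balanced subsets contain n_min samples per class, so with a very small
  minority class each forest trains on few samples; conclusions then rest
  on the agreement across many such forests, not on any single one.
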
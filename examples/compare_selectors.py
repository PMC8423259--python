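"""Head-to-head selector comparison on strongly imbalanced tabular data.

Builds an expression-like table with 3 classes (100/80/6 samples) where a
third of the informative features shift only the 6-sample minority class.
Compares how many minority-specific features each selector places in its
top list — the regime the balanced-sampling design targets.
"""

from imrf import RunConfig, generate_planted_tabular, run_imrf
from imrf.baselines import SELECTORS

N_INFORMATIVE = 12
ds = generate_planted_tabular(
    {"A": 100, "B": 80, "C": 6}, m=60, n_informative=N_INFORMATIVE,
    effect_size=1.5, noise_sd=1.0, seed=3,
)
# the generator assigns target classes in rotation: j % 3 == 2 targets C
minority_truth = {f"f{j}" for j in range(N_INFORMATIVE) if j % 3 == 2}
print(f"classes {ds.labels.counts}; {len(minority_truth)} features shift only class C\n")

cfg = RunConfig(L=6, p=1, q=2, d=8, T=60, seed=3, validation_per_class=2)
selected = run_imrf(ds.matrix, ds.labels, cfg).ranked.feature_names
print(f"{'selector':12s} {'top list':>8s} {'minority features found':>24s}")
print(f"{'integrated':12s} {len(selected):8d} {len(set(selected) & minority_truth):24d}")
for name, fn in SELECTORS.items():
    ranked = fn(ds.matrix, ds.labels, T=60, d=8, seed=3).feature_names
    print(f"{name:12s} {len(ranked):8d} {len(set(ranked) & minority_truth):24d}")

print("\nSingle forests see the minority class in ~3% of samples, so splits on "
      "its features rarely reduce pooled impurity; balanced subsets give the "
      "minority class equal footing in every tree.")
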
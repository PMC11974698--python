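"""The shuffle test in miniature: which feature does each predictor use?

Builds a sweep-vs-neutral classification task, fits four single-statistic
"oracle" classifiers, and runs the degradation harness. Each oracle's
accuracy stays perfect exactly as long as the shuffle levels preserve its
statistic, then collapses to chance (0.5) — so the column in which a
predictor first breaks identifies the data feature it relies on. This is
how the same harness diagnoses an opaque CNN from its per-level
predictions.
"""

from confusenn import ShuffleLevel, fit_oracle, run_shuffle_test, sweep_neutral_task

dataset = sweep_neutral_task(n_per_class=100, master_seed=0)
oracles = ["pi", "h1", "seg_sites", "last_informative_column"]

print(f"{'level':<22}" + "".join(f"{s:>26}" for s in oracles))
reports = {
    stat: run_shuffle_test(dataset, fit_oracle(dataset, stat), master_seed=1)
    for stat in oracles
}
for level in ShuffleLevel:
    row = f"{level.name:<22}"
    for stat in oracles:
        row += f"{reports[stat].metrics[level.name]['accuracy']:>26.3f}"
    print(row)

print()
print("Accuracy 1.0 = statistic intact, 0.5 = chance on this balanced task.")
print("pi survives both count-preserving shuffles; H1 only the column")
print("shuffle; segregating sites everything except the block groupings;")
print("the apparent width (padding boundary) everything except the")
print("boundary-breaking grouping.")
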
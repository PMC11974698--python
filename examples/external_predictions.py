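"""Evaluate an external model from per-level prediction files.

A published CNN lives in its own code base: the workflow is (1) shuffle
the test data here and export it, (2) run the network over each level's
matrices there, (3) drop one ``<LEVEL>.tsv`` of predictions per level back
here and score them. This example fakes step (2) with a noisy
statistic-based stand-in so the whole loop runs locally, and aggregates
two "independently trained" instances with 95% percentile intervals.
"""

import os
import tempfile

import numpy as np

from confusenn import (
    PredictionFiles,
    ShuffleLevel,
    aggregate_instances,
    battery,
    run_shuffle_test,
    sweep_neutral_task,
)
from confusenn.stats import garud_h1

dataset = sweep_neutral_task(n_per_class=50, master_seed=3)
levels = list(ShuffleLevel)
master_seed = 4

reports = []
for instance in range(2):
    rng = np.random.default_rng(instance)
    with tempfile.TemporaryDirectory() as pred_dir:
        # stand-in for the external model: noisy H1 threshold
        shuffled = battery(dataset.matrices, levels, master_seed)
        for level in levels:
            with open(os.path.join(pred_dir, f"{level.name}.tsv"), "w") as fh:
                for m in shuffled[level]:
                    score = garud_h1(m) + rng.normal(0, 0.02)
                    label = "sweep" if score > 0.08 else "neutral"
                    fh.write(f"{label}\t{score}\n")
        reports.append(
            run_shuffle_test(
                dataset,
                PredictionFiles(pred_dir),
                levels,
                master_seed=master_seed,
                positive_label="sweep",
            )
        )

agg = aggregate_instances(reports)
print(f"{'level':<22}{'mean acc':>10}{'95% interval':>20}")
for level in agg.levels:
    a = agg.aggregate[level]["accuracy"]
    print(
        f"{level:<22}{a['mean']:>10.3f}"
        f"{'[' + format(a['ci_low'], '.3f') + ', ' + format(a['ci_high'], '.3f') + ']':>20}"
    )
print()
print("The H1-based stand-in survives only the column shuffle; intervals")
print("are empirical 2.5/97.5 percentiles across the two instances.")
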
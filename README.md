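# confusenn

Interpret classifiers and regressors that consume population-genomic
haplotype matrices by shuffling their test data.

Population-genetic deep learning models — CNNs for sweep detection,
demographic inference, recombination-rate estimation — take a binary
"genomic image" as input: one row per haplotype, one column per
segregating site (0 = ancestral, 1 = derived), columns ordered by genomic
position and often right-padded with all-zero columns to a fixed width.
How such a model achieves its accuracy is opaque. This package probes it
from the *data* side: a ladder of shuffling operations, each destroying
one more class of population-genetic structure, is applied to the test
set only, and the model's per-level performance drop reveals which
features it exploits — no access to network internals required.

## The shuffle ladder

| level | destroys (cumulatively) | still preserved |
|---|---|---|
| `IDENTITY` | nothing | everything (baseline) |
| `COLUMNS` | position ↔ genotype link, short-scale LD decay | AFS, π, S, H1, the multiset of pairwise r² |
| `WITHIN_COLUMNS` | haplotype identity, hence H1 and all LD | AFS, π, S, singleton fraction |
| `ALL_PIXELS` | the allele frequency spectrum | total derived count T |
| `BLOCK_KEEP_PADDING` | all per-site patterns (one solid block) | T, data width, the padding boundary |
| `BLOCK_BREAK_PADDING` | the zero-padding boundary itself | T only |

The statistics named here are the classics: the allele frequency spectrum
(AFS), nucleotide diversity π = Σⱼ dⱼ(n−dⱼ)/C(n,2), segregating-site
count S, Garud's haplotype homozygosity H1 = Σᵢ pᵢ², and linkage
disequilibrium r²(j,k) = (P₁₁ − pⱼpₖ)²/(pⱼ(1−pⱼ)pₖ(1−pₖ)). Randomized
levels are seeded and bit-reproducible; the block groupings are
deterministic; no level ever touches the genomic-positions vector.

## Worked example

`examples/oracle_degradation.py` builds a sweep-vs-neutral task (32
haplotypes; neutral windows carry 64 segregating sites, sweep windows 40,
both zero-padded to width 72), fits four single-statistic threshold
classifiers, and runs the harness:

```
level                         pi        h1 seg_sites  last_informative_column
IDENTITY                   1.000     1.000     1.000                    1.000
COLUMNS                    1.000     1.000     1.000                    1.000
WITHIN_COLUMNS             1.000     0.575     1.000                    1.000
ALL_PIXELS                 0.525     0.500     1.000                    1.000
BLOCK_KEEP_PADDING         0.500     0.500     0.500                    1.000
BLOCK_BREAK_PADDING        0.500     0.500     0.500                    0.500
```

Each column is one predictor's accuracy down the ladder (0.5 = chance on
this balanced task). A predictor's accuracy survives a level exactly when
the level preserves its statistic: the π classifier survives both
count-preserving shuffles, the H1 classifier only the column shuffle, and
a predictor reading only the apparent image width (the padding boundary)
survives everything until the boundary itself is broken. Applied to a
real CNN — via `run_shuffle_test` with an in-process callable, or
per-level prediction files from an external code base
(`examples/external_predictions.py`) — the same table diagnoses which
features the network actually learned. `examples/shuffle_levels.py`
shows the raw statistics falling level by level.

The CLI mirrors the library for shell use:

```sh
confusenn simulate --generator ld --n-hap 32 --n-sites 64 --seed 1 --out m.txt
confusenn stats --in m.txt --out stats.tsv
confusenn shuffle --in m.txt --level within_columns --seed 2 --out shuffled.txt
confusenn evaluate --task sweep-neutral --oracle h1 --seed 3 --out report/
```

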
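# Methods

## The data model

A `HaplotypeMatrix` is an n_hap × n_col binary array (0 = ancestral,
1 = derived), a `padding_width` counting trailing all-zero columns, and an
optional monotone positions vector for the data columns (base pairs, or
[0, 1)-scaled as in coalescent-simulator output). Padding shares the
ancestral value 0 deliberately: a padded column and a monomorphic-ancestral
column are pixel-identical, and only the metadata distinguishes them —
exactly the ambiguity a padding-blind consumer such as a CNN faces. The
*apparent* data/padding boundary is therefore defined behaviorally, as the
last column containing any derived allele (`last_informative_column`).

Only phased, biallelic input is accepted. Unphased VCF genotypes are
rejected rather than heuristically phased (an explicit
`allow_unphased` escape hatch treats `/` as `|` at the caller's risk);
non-biallelic or non-SNP records are skipped with a logged count.
Polarization defaults to the file's 0/1 encoding, with an optional fold to
the minor allele, since real datasets differ in whether ancestral states
are known. Positions are opaque metadata: VCF `POS` is stored verbatim and
ms positions are kept on their [0, 1) scale; no operation in the package
ever reorders, rescales, or rewrites them.

## The shuffle ladder

Each level is defined on the non-padding region only, except the final
boundary-breaking grouping:

- **COLUMNS** — a uniform permutation of data columns. Every per-column
  quantity and every whole-row quantity survives (AFS, π, S, singleton
  fraction, H1, and the multiset of pairwise r², since all pairs persist
  under relabeling); only the association between column content and
  genomic position — the distance structure of LD — is destroyed.
- **WITHIN_COLUMNS** — the composite: column shuffle, then an independent
  uniform permutation of entries within each column. Per-column derived
  counts survive; haplotype identity does not, so H1 collapses and
  between-site association (r²) falls to its independence level.
- **ALL_PIXELS** — a uniform permutation of all data-region entries,
  destroying the allele frequency spectrum; only the total derived count
  T survives.
- **BLOCK_KEEP_PADDING** — deterministic: the T derived alleles are packed
  into a solid block, column by column right-to-left, anchored at the last
  informative column, top-to-bottom within a column. T, the data width and
  the apparent boundary survive; every per-site pattern is gone. Anchoring
  at the last *informative* column (rather than the nominal last data
  column) makes boundary preservation exact even when a matrix happens to
  end in a monomorphic-ancestral column — the boundary a padding-blind
  consumer perceives is the informative one.
- **BLOCK_BREAK_PADDING** — deterministic: the same packing but
  left-to-right from column 0 across the full width, padding included. The
  apparent width becomes ⌈T/n_hap⌉, generally very different from the
  input's, so the output carries `padding_width = 0`; the (untouched)
  positions vector consequently no longer matches the padding metadata,
  which `validate` reports unless its positions checks are relaxed —
  consumers of this level must not rely on the boundary.

Within-column permutations are realized as per-column argsorts of iid
uniform keys, which are exactly uniform over permutations. Determinism:
identical (matrix, level, seed) triples give identical outputs;
`battery` derives per-matrix seeds from `SeedSequence([master, index,
level])`, so one level's randomness never depends on which other levels
are requested. The block groupings take no seed.

## Summary statistics

π and H1 are computed in integer arithmetic before a single final
division (π = Σ dⱼ(n−dⱼ) / C(n,2); H1 = Σ cᵢ² / n² over row-identity
class counts), so they are exact and independent of summation order — a
requirement for the bit-exact preservation tests, since column
permutations reorder floating-point reductions. r² is the squared Pearson
correlation between 0/1 columns, computed only over polymorphic columns;
pairs involving monomorphic columns are undefined and excluded, and a
matrix with fewer than two polymorphic columns yields an empty r² set
(mean r² = NaN). "Short-scale" LD is operationalized as the Spearman rank
correlation between inter-site distance and r² (average-rank ties;
all-tied inputs return 0 by convention); "long-scale" LD as the r²
multiset and its mean. The AFS is reported unfolded with
monomorphic-ancestral and fixed-derived columns tallied separately;
fixed-derived columns contribute to T and (zero) to π but not to S.

## Synthetic data

The generators are transparent stochastic constructions, not population
simulators. They emulate the three data features the shuffle ladder
targets, at desk scale:

- `simulate_neutral(n_hap, n_sites, seed)` — exchangeable sites; each
  column draws a derived count k ∝ 1/k (the neutral AFS shape) and places
  the alleles on a uniform row subset. No LD by construction.
- `simulate_ld_mosaic(n_hap, n_sites, n_founders=4, switch_rate=0.02,
  seed)` — founder haplotypes copied left to right with a switch to a
  random founder between adjacent sites at the given rate; a
  recombination-like process giving tunable distance-decaying LD and
  elevated haplotype homozygosity as the switch rate falls.
- `simulate_sweep_like(n_hap, n_sites, sweep_freq=0.8, seed,
  flip_rate=0.02)` — a neutral background in which round(sweep_freq·n_hap)
  rows are replaced by near-copies (per-site flip probability
  `flip_rate`) of one core haplotype: high H1, fewer realized segregating
  sites — the sweep signature.

What these deliberately do **not** capture: coalescent genealogies and
their correlated site patterns, recombination-distance heterogeneity,
demography, realistic mutation processes. Tests passing on these
generators establish that the *operations and harness* behave as
specified, not that any conclusion transfers to a particular empirical
dataset — for real analyses the test data come from whatever simulator
the model under study was built on.

The standard benchmark (`sweep_neutral_task`) uses 32 haplotypes, 64
neutral vs 40 sweep sites, both padded to width 72, 200 matrices per
class. The widths differ on purpose: in real pipelines the number of
segregating sites carries signal and the padding boundary encodes it, so
a boundary-reading predictor is diagnosable. All dataset construction
flows from one master seed via documented `SeedSequence` derivations and
regenerates bit-exactly from the recorded metadata.

## Oracles and the harness

An `OracleClassifier` sees the input only through one named statistic
(π, H1, singleton fraction, S, or the apparent width) and a threshold
fitted by exhaustive midpoint search (ties toward the lower threshold).
Because each level's preservation set is known exactly, each oracle's
degradation profile is analytically predictable, which turns the harness
into a self-verifying instrument: metrics at level L are bit-identical to
baseline iff L preserves the oracle's statistic.

One empirical caveat, measured on the benchmark: after WITHIN_COLUMNS the
H1 oracle is not exactly at chance. Low-diversity sweep matrices have few
effective polymorphic patterns, so random within-column reassignment
occasionally produces duplicate rows, leaving residual H1 signal (~0.55–
0.6 accuracy vs 1.0 at baseline); the degradation test therefore asserts
that residual skill above the no-information rate is at most a quarter of
baseline skill rather than exact chance.

`run_shuffle_test` accepts an in-process callable, an oracle, or
per-level prediction files (the interoperation route for external
networks), always evaluates IDENTITY as the baseline, and reports
accuracy with the no-information rate, per-class confusion matrices, and
for binary tasks a threshold-sweep ROC with trapezoidal AUC; regression
tasks get Spearman's r (0 with a degeneracy flag when either side is
constant) and RMSE. `aggregate_instances` summarizes independently
trained predictor instances by the mean and the empirical 2.5/97.5
percentile interval (linear interpolation), labeled as such in the
output; reports serialize to round-trippable JSON and a flat TSV.

## Numerical and design notes

- Statistic-preservation claims are tested as bit-exact equalities, made
  possible by the integer-arithmetic statistics above; r² multisets are
  compared after sorting (each pair's value is computed from the same two
  columns regardless of order, so equality is exact).
- LD-destruction is judged against the matched-permutation null: the
  independence reference distribution of mean off-diagonal r² is built by
  independent within-column permutations of the same matrix, and shuffled
  values are compared to its 99th percentile. Since the within-column
  shuffle is itself a draw from that null, the comparison verifies
  convergence to independence, and a shuffled value falls below the 99th
  percentile with probability ~0.99 by construction — the corresponding
  destruction rate is expected near, not above, 0.99.
- Degenerate inputs: an all-padding or all-zero data region makes the
  randomized shuffles a logged identity; `segsites: 0` ms replicates are
  returned as zero-width matrices that fail validation, leaving the
  policy to the caller; empty r² sets propagate as NaN means rather than
  being silently zeroed.
- Problem sizes throughout (≤ 32 haplotypes, ≤ 128 sites, hundreds of
  matrices, 500-seed destruction panels) were chosen as the smallest
  scales at which every exact property is exercised and every statistical
  property has clear resolution; all of them are parameters, not limits.
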
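"""Synthetic haplotype-matrix datasets and statistic-threshold oracles.

The generators here are deliberately simple stochastic constructions, not
coalescent simulators: they emulate the *features* the shuffle levels
manipulate — the 1/k-shaped allele frequency spectrum of neutral data,
tunable linkage structure via a founder-copying mosaic, and the reduced
haplotype diversity of a selective sweep — so the whole test bed is
self-contained and fast. See docs/methods.md for what they do and do not
capture about real data.

An :class:`OracleClassifier` predicts a class from a single summary
statistic and a threshold. Because each shuffle level preserves a known
set of statistics exactly, the degradation pattern of each oracle across
levels is analytically predictable, which makes the oracles the ground
truth against which the harness is verified: a diversity-only learner
survives every disruption except breaking the padding boundary, an
H1 learner survives only the column shuffle, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .io import pad_to_width
from .matrix import HaplotypeMatrix, last_informative_column
from . import stats as _stats

__all__ = [
    "LabeledDataset",
    "OracleClassifier",
    "ORACLE_STATISTICS",
    "simulate_neutral",
    "simulate_ld_mosaic",
    "simulate_sweep_like",
    "make_classification_dataset",
    "sweep_neutral_task",
    "three_class_selection_task",
    "regenerate",
    "save_dataset",
    "load_dataset",
    "fit_oracle",
    "predict_oracle",
    "fit_logistic_stat_predictor",
]


def _lic_value(m: HaplotypeMatrix) -> float:
    """last_informative_column as a real-valued statistic (-1 for an
    all-zero matrix)."""
    lic = last_informative_column(m)
    return -1.0 if lic is None else float(lic)


#: Statistics an :class:`OracleClassifier` may threshold on.
ORACLE_STATISTICS: dict[str, Callable[[HaplotypeMatrix], float]] = {
    "pi": _stats.pairwise_pi,
    "h1": _stats.garud_h1,
    "singleton_fraction": _stats.singleton_fraction,
    "seg_sites": lambda m: float(_stats.seg_sites(m)),
    "last_informative_column": _lic_value,
}


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_neutral(
    n_hap: int, n_sites: int, seed, positions: bool = True
) -> HaplotypeMatrix:
    """Exchangeable-site data with a neutral-shaped (1/k) AFS.

    Each column independently draws a derived-allele count
    k in {1..n_hap-1} with probability proportional to 1/k, then assigns
    the k derived alleles to a uniform random subset of rows. Columns are
    exchangeable, so there is no linkage structure by construction.
    Positions are sorted uniforms in [0, 1).
    """
    if n_hap < 2 or n_sites < 1:
        raise ValueError("need n_hap >= 2 and n_sites >= 1")
    rng = _rng(seed)
    k_vals = np.arange(1, n_hap)
    w = 1.0 / k_vals
    w /= w.sum()
    ks = rng.choice(k_vals, p=w, size=n_sites)
    # uniform k-subset per column: rows with the k smallest iid keys
    ranks = np.argsort(np.argsort(rng.random((n_hap, n_sites)), axis=0), axis=0)
    alleles = (ranks < ks[None, :]).astype(np.int8)
    pos = np.sort(rng.random(n_sites)) if positions else None
    return HaplotypeMatrix(alleles, 0, pos)


def simulate_ld_mosaic(
    n_hap: int,
    n_sites: int,
    n_founders: int = 4,
    switch_rate: float = 0.02,
    seed=0,
) -> HaplotypeMatrix:
    """Founder-copying mosaic data with tunable linkage structure.

    ``n_founders`` founder haplotypes are drawn with
    :func:`simulate_neutral`; each output haplotype then copies founders
    left to right, switching to a uniformly chosen founder between
    adjacent sites with probability ``switch_rate`` (a recombination-like
    process). Low switch rates give long shared tracts, hence high LD and
    high haplotype homozygosity; ``switch_rate`` 1 destroys distance-
    dependent LD.
    """
    if not (2 <= n_founders <= n_hap):
        raise ValueError("need 2 <= n_founders <= n_hap")
    if not (0.0 <= switch_rate <= 1.0):
        raise ValueError("switch_rate must be in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    founder_seed, mosaic_seed = ss.spawn(2)
    founders = simulate_neutral(n_founders, n_sites, founder_seed, positions=False)
    rng = _rng(mosaic_seed)
    switch = rng.random((n_hap, n_sites)) < switch_rate
    switch[:, 0] = True  # every haplotype starts from a fresh random founder
    choices = rng.integers(0, n_founders, size=(n_hap, n_sites))
    # forward-fill founder index across non-switch sites
    idx = np.where(switch, np.arange(n_sites)[None, :], 0)
    idx = np.maximum.accumulate(idx, axis=1)
    source = np.take_along_axis(choices, idx, axis=1)
    alleles = founders.alleles[source, np.arange(n_sites)[None, :]]
    pos = np.sort(rng.random(n_sites))
    return HaplotypeMatrix(alleles.astype(np.int8), 0, pos)


def simulate_sweep_like(
    n_hap: int,
    n_sites: int,
    sweep_freq: float = 0.8,
    seed=0,
    flip_rate: float = 0.02,
) -> HaplotypeMatrix:
    """Sweep-like data: one core haplotype at high frequency.

    A neutral background is drawn first; then ``round(sweep_freq * n_hap)``
    haplotypes are replaced by near-copies of one core haplotype (the
    first background row), each entry flipped independently with
    probability ``flip_rate`` (mutations accumulating on the swept
    haplotype). The remaining rows keep their neutral draw. The result
    shows the classic sweep signature: a dramatic reduction of haplotype
    diversity (high H1) and fewer realized segregating sites than a
    matched neutral draw.
    """
    if not (0.0 < sweep_freq <= 1.0):
        raise ValueError("sweep_freq must be in (0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    base_seed, flip_seed = ss.spawn(2)
    m = simulate_neutral(n_hap, n_sites, base_seed)
    rng = _rng(flip_seed)
    n_sweep = int(round(sweep_freq * n_hap))
    core = m.alleles[0].copy()
    flips = rng.random((n_sweep, n_sites)) < flip_rate
    m.alleles[:n_sweep] = np.where(flips, 1 - core[None, :], core[None, :])
    return m


_GENERATORS: dict[str, Callable[..., HaplotypeMatrix]] = {
    "neutral": simulate_neutral,
    "ld_mosaic": simulate_ld_mosaic,
    "sweep_like": simulate_sweep_like,
}


# ---------------------------------------------------------------------------
# Labeled datasets
# ---------------------------------------------------------------------------

@dataclass
class LabeledDataset:
    """Matrices with class labels or regression targets.

    ``metadata`` records the generator specification and master seed in
    full, so :func:`regenerate` reproduces the dataset bit-exactly.
    """

    matrices: list[HaplotypeMatrix]
    labels: list
    task: str  # "classification" | "regression"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.matrices) != len(self.labels):
            raise ValueError("labels length must equal matrices length")
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def classes(self) -> list:
        return sorted(set(self.labels))


def make_classification_dataset(
    n_per_class: int,
    class_specs: Mapping[str, tuple[str, Mapping]],
    pad_to: Optional[int] = None,
    master_seed: int = 0,
) -> LabeledDataset:
    """Balanced labeled dataset from per-class generator specifications.

    ``class_specs`` maps a class label to ``(generator_name, params)``
    with generator names ``neutral | ld_mosaic | sweep_like``. Per-matrix
    seeds derive from ``(master_seed, class index, replicate index)``;
    the same call reproduces the same dataset bit-exactly. With ``pad_to``
    every matrix is right-padded to that common width.
    """
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 1:
        raise ValueError("need n_per_class >= 1")
    matrices: list[HaplotypeMatrix] = []
    labels: list[str] = []
    for ci, (label, (gen_name, params)) in enumerate(sorted(class_specs.items())):
        gen = _GENERATORS[gen_name]
        for i in range(n_per_class):
            seed = np.random.SeedSequence([int(master_seed), ci, i])
            m = gen(seed=seed, **params)
            if pad_to is not None:
                m = pad_to_width(m, pad_to)
            matrices.append(m)
            labels.append(label)
    return LabeledDataset(
        matrices,
        labels,
        "classification",
        metadata={
            "generator": "make_classification_dataset",
            "n_per_class": n_per_class,
            "class_specs": {k: [g, dict(p)] for k, (g, p) in class_specs.items()},
            "pad_to": pad_to,
            "master_seed": int(master_seed),
        },
    )


def sweep_neutral_task(
    n_per_class: int = 200,
    master_seed: int = 0,
    n_hap: int = 32,
    neutral_sites: int = 64,
    sweep_sites: int = 40,
    sweep_freq: float = 0.8,
    pad_to: int = 72,
) -> LabeledDataset:
    """The standard binary sweep-vs-neutral benchmark task.

    Neutral windows carry more segregating sites than sweep windows, and
    both are zero-padded to a common image width, so — as in real
    CNN pipelines — the padding boundary itself carries class signal in
    addition to diversity and haplotype-homozygosity differences.
    """
    return make_classification_dataset(
        n_per_class,
        {
            "neutral": ("neutral", {"n_hap": n_hap, "n_sites": neutral_sites}),
            "sweep": (
                "sweep_like",
                {"n_hap": n_hap, "n_sites": sweep_sites, "sweep_freq": sweep_freq},
            ),
        },
        pad_to=pad_to,
        master_seed=master_seed,
    )


def three_class_selection_task(
    n_per_class: int = 100,
    master_seed: int = 0,
    n_hap: int = 32,
    n_sites: int = 48,
    pad_to: int = 64,
) -> LabeledDataset:
    """Three-way neutral / moderate-sweep / strong-sweep task.

    Mirrors the class structure of multiclass selection classifiers
    (labels are generator-strength tokens, not selection coefficients).
    """
    return make_classification_dataset(
        n_per_class,
        {
            "neutral": ("neutral", {"n_hap": n_hap, "n_sites": n_sites}),
            "sweep_moderate": (
                "sweep_like",
                {"n_hap": n_hap, "n_sites": n_sites, "sweep_freq": 0.5},
            ),
            "sweep_strong": (
                "sweep_like",
                {"n_hap": n_hap, "n_sites": n_sites, "sweep_freq": 0.9},
            ),
        },
        pad_to=pad_to,
        master_seed=master_seed,
    )


def regenerate(metadata: Mapping) -> LabeledDataset:
    """Rebuild a dataset bit-exactly from its generation metadata."""
    if metadata.get("generator") != "make_classification_dataset":
        raise ValueError("unrecognized dataset metadata")
    specs = {
        k: (g, dict(p)) for k, (g, p) in metadata["class_specs"].items()
    }
    return make_classification_dataset(
        metadata["n_per_class"],
        specs,
        pad_to=metadata["pad_to"],
        master_seed=metadata["master_seed"],
    )


# ---------------------------------------------------------------------------
# Dataset persistence (directory of archives + JSON sidecar)
# ---------------------------------------------------------------------------

def save_dataset(dataset: LabeledDataset, directory: str) -> None:
    """Write a dataset as matrix archives plus a ``dataset.json`` sidecar."""
    import json
    import os

    from .io import write_archive

    os.makedirs(directory, exist_ok=True)
    files = []
    for i, m in enumerate(dataset.matrices):
        name = f"matrix_{i:05d}.txt"
        write_archive(m, os.path.join(directory, name))
        files.append(name)
    with open(os.path.join(directory, "dataset.json"), "w") as fh:
        json.dump(
            {
                "task": dataset.task,
                "labels": dataset.labels,
                "files": files,
                "metadata": dataset.metadata,
            },
            fh,
            indent=1,
        )
        fh.write("\n")


def load_dataset(directory: str) -> LabeledDataset:
    """Read back a dataset written by :func:`save_dataset`."""
    import json
    import os

    from .io import read_archive

    with open(os.path.join(directory, "dataset.json")) as fh:
        meta = json.load(fh)
    matrices = [read_archive(os.path.join(directory, f)) for f in meta["files"]]
    return LabeledDataset(matrices, meta["labels"], meta["task"], meta["metadata"])


# ---------------------------------------------------------------------------
# Statistic-threshold oracle classifiers
# ---------------------------------------------------------------------------

@dataclass
class OracleClassifier:
    """A classifier that sees the input only through one summary statistic.

    Predicts ``class_high`` when the statistic exceeds ``threshold``,
    ``class_low`` otherwise. Because its information channel is a single
    named statistic, its performance across shuffle levels is analytically
    predictable from which levels preserve that statistic.
    """

    statistic: str
    threshold: float
    class_low: str
    class_high: str

    def statistic_fn(self) -> Callable[[HaplotypeMatrix], float]:
        return ORACLE_STATISTICS[self.statistic]


def fit_oracle(dataset: LabeledDataset, statistic: str) -> OracleClassifier:
    """Fit a threshold oracle on a binary classification dataset.

    The threshold maximizing training accuracy is chosen over the
    midpoints of consecutive sorted statistic values (ties broken toward
    the lower threshold), together with the class-to-side orientation.
    """
    if dataset.task != "classification":
        raise ValueError("fit_oracle requires a classification dataset")
    classes = dataset.classes
    if len(classes) != 2:
        raise ValueError(f"fit_oracle requires exactly 2 classes, got {classes}")
    if statistic not in ORACLE_STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from "
            + ", ".join(ORACLE_STATISTICS)
        )
    fn = ORACLE_STATISTICS[statistic]
    values = np.array([fn(m) for m in dataset.matrices])
    y = np.array([dataset.labels[i] == classes[1] for i in range(len(dataset))])

    uniq = np.unique(values)
    candidates = (
        [uniq[0] - 1.0]
        + list((uniq[:-1] + uniq[1:]) / 2.0)
        + [uniq[-1] + 1.0]
    )
    best = None
    for thr in candidates:
        above = values > thr
        acc_hi = np.mean(above == y)        # class_high = classes[1]
        acc_lo = np.mean(above == ~y)       # class_high = classes[0]
        for acc, (lo, hi) in (
            (acc_hi, (classes[0], classes[1])),
            (acc_lo, (classes[1], classes[0])),
        ):
            if best is None or acc > best[0]:
                best = (acc, thr, lo, hi)
    _, thr, lo, hi = best
    return OracleClassifier(statistic, float(thr), lo, hi)


def predict_oracle(
    c: OracleClassifier,
    dataset: Union["LabeledDataset", Sequence[HaplotypeMatrix]],
) -> list[tuple[str, float]]:
    """Predict ``(label, score)`` per matrix; the score is the raw
    statistic value (higher means more ``class_high``-like)."""
    matrices = dataset.matrices if isinstance(dataset, LabeledDataset) else dataset
    fn = c.statistic_fn()
    out = []
    for m in matrices:
        v = fn(m)
        out.append((c.class_high if v > c.threshold else c.class_low, v))
    return out


def fit_logistic_stat_predictor(
    dataset: LabeledDataset,
    statistics: Sequence[str] = ("pi", "h1", "singleton_fraction"),
):
    """Fixture classifier: logistic regression on several summary statistics.

    Trains on the (unshuffled) dataset and returns a predictor callable for
    :func:`confusenn.harness.run_shuffle_test`. Because it combines several
    statistics, its accuracy should decline monotonically as successive
    shuffle levels strip those statistics away.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    fns = [ORACLE_STATISTICS[s] for s in statistics]
    X = np.array([[fn(m) for fn in fns] for m in dataset.matrices])
    y = np.array(dataset.labels)
    scaler = StandardScaler().fit(X)
    clf = LogisticRegression(max_iter=1000).fit(scaler.transform(X), y)
    positive = clf.classes_[-1]

    def predictor(matrices):
        Xt = np.array([[fn(m) for fn in fns] for m in matrices])
        Xt = scaler.transform(Xt)
        labels = clf.predict(Xt)
        scores = clf.predict_proba(Xt)[:, -1]
        return [(l, float(s)) for l, s in zip(labels, scores)]

    predictor.positive_label = positive
    return predictor
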
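"""Synthetic data and fixtures with the structure the method assumes.

The five named profiles reproduce the class imbalances of the
PhysioNet/CinC 2015 arrhythmia alarm subsets (true vs. false alarm counts
per arrhythmia type).  Features are class-conditional Gaussians with a
tunable mean shift — a stand-in for the beat-detection and spectral
statistics real pipelines extract from the monitor signals, preserving
exactly what the classifier consumes: a small numeric table with a heavily
imbalanced binary label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datasets import TrainingSet
from .forest import ForestConfig, ForestModel, bootstrap_membership, fit_forest

__all__ = [
    "PROFILES",
    "DatasetProfile",
    "make_alarm_dataset",
    "corrupted_forest_fixture",
    "weighting_example",
    "WeightingExample",
]

# (n_neg, n_pos): false vs. true alarms per arrhythmia subset
PROFILES = {
    "asystole": (100, 22),
    "bradycardia": (43, 46),
    "tachycardia": (9, 131),
    "vtach": (252, 89),
    "vfib": (52, 6),
}


@dataclass(frozen=True)
class DatasetProfile:
    """Recipe for one synthetic alarm dataset.

    class_separation is the mean shift (in noise-sd units when
    noise_sd = 1) of the informative features between classes; defaults
    put a 100-tree forest in the high-but-imperfect AUC regime typical of
    these alarm subsets.
    """

    name: str = "custom"
    n_neg: int = 100
    n_pos: int = 22
    n_features: int = 10
    n_informative: int = 3
    class_separation: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2:
            raise ValueError("need at least 2 positive observations")
        if self.n_neg < 2:
            raise ValueError("need at least 2 negative observations")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must lie in [0, n_features]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @classmethod
    def from_name(cls, name: str, seed: int = 0, **overrides) -> "DatasetProfile":
        if name not in PROFILES:
            raise ValueError(
                f"unknown profile {name!r}; choose from {sorted(PROFILES)}"
            )
        n_neg, n_pos = PROFILES[name]
        return cls(name=name, n_neg=n_neg, n_pos=n_pos, seed=seed, **overrides)

    def with_seed(self, seed: int) -> "DatasetProfile":
        return replace(self, seed=seed)


def make_alarm_dataset(profile: DatasetProfile) -> TrainingSet:
    """Draw a dataset with exact class counts and Gaussian class structure.

    The first ``n_informative`` features are N(0, noise_sd) for negatives
    and N(class_separation, noise_sd) for positives; the rest are pure
    N(0, noise_sd) noise in both classes.  Fully determined by the
    profile's seed.
    """
    rng = np.random.default_rng(profile.seed)
    n = profile.n_neg + profile.n_pos
    x = rng.normal(0.0, profile.noise_sd, size=(n, profile.n_features))
    y = np.r_[np.zeros(profile.n_neg, dtype=np.int64),
              np.ones(profile.n_pos, dtype=np.int64)]
    x[y == 1, : profile.n_informative] += profile.class_separation
    names = [
        f"inf{k + 1}" if k < profile.n_informative else f"noise{k + 1 - profile.n_informative}"
        for k in range(profile.n_features)
    ]
    return TrainingSet(x, y, names, "alarm")


def corrupted_forest_fixture(
    data: TrainingSet,
    fconfig: ForestConfig,
    corrupt_fraction: float,
    seed: int,
    flip_prob: float = 0.4,
) -> tuple[ForestModel, np.ndarray]:
    """Forest in which a fraction of trees trained on label-flipped bags.

    A random subset of round(corrupt_fraction * ntree) trees has each
    in-bag label flipped independently with probability ``flip_prob``;
    bootstrap membership and all tree random streams are identical to
    :func:`~wrforest.forest.fit_forest` under the same config, so
    corrupt_fraction = 0 reproduces it exactly.  The corrupted trees carry
    a real performance deficit, giving the theta ranking a gradient to
    detect.

    Returns the fitted model and the boolean mask of corrupted trees.
    """
    if not 0 <= corrupt_fraction <= 1:
        raise ValueError("corrupt_fraction must lie in [0, 1]")
    ntree = fconfig.ntree
    rng = np.random.default_rng(seed)
    n_corrupt = round(corrupt_fraction * ntree)
    corrupted = np.zeros(ntree, dtype=bool)
    if n_corrupt:
        corrupted[rng.choice(ntree, size=n_corrupt, replace=False)] = True
    tree_labels = {}
    for j in np.flatnonzero(corrupted):
        flips = rng.random(data.n) < flip_prob
        tree_labels[int(j)] = np.where(flips, 1 - data.labels, data.labels)
    membership = bootstrap_membership(data.n, ntree, fconfig.seed)
    model = fit_forest(data, fconfig, membership=membership, tree_labels=tree_labels)
    return model, corrupted


@dataclass(frozen=True)
class WeightingExample:
    """The four-tree worked example of the weighting pipeline.

    Holds the per-tree in-bag/out-of-bag AUCs, the settings alpha = 0.5 and
    p = 2, and the reference ranking (3, 4, 1, 2).  The ranking is carried
    explicitly rather than rederived: applying
    theta = -alpha|AUC_INB - AUC_OOB| + (1 - alpha)AUC_OOB to these AUCs
    yields (0.350, 0.225, 0.350, 0.375), which orders the trees
    differently, so the example exercises the weight formula on a fixed
    ranking rather than the ranking step itself.
    """

    auc_inb: tuple = (0.70, 0.65, 0.90, 0.85)
    auc_oob: tuple = (0.70, 0.55, 0.80, 0.80)
    alpha: float = 0.5
    p_exp: float = 2.0
    ranks: tuple = (3, 4, 1, 2)


def weighting_example() -> WeightingExample:
    """The canonical four-tree weighting example (see :class:`WeightingExample`)."""
    return WeightingExample()
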
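"""Bagged randomized-tree ensembles with explicit bootstrap bookkeeping.

A standard bagged forest of unpruned CART trees, except that the bootstrap
membership of every (observation, tree) pair is recorded exactly: the
in-bag count matrix is drawn first, and each tree is fit on precisely that
multiset.  Everything downstream — out-of-bag residual weights, per-tree
in-bag/out-of-bag AUC, tree ranking — consumes this matrix, so the
bookkeeping must be exact rather than recovered after the fact.

Randomness is organised as one stream per tree, spawned from a single
integer seed, so growing the ensemble leaves earlier trees unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .datasets import TrainingSet

__all__ = [
    "ForestConfig",
    "MembershipMatrix",
    "ForestModel",
    "bootstrap_membership",
    "fit_forest",
    "tree_probabilities",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble hyperparameters.

    ntree : number of trees (default 500).
    mtry : features considered per split; "auto" resolves to
        floor(sqrt(n_features)), the usual classification default.
    seed : master seed; all bootstrap draws and split randomization
        derive from it through per-tree substreams.
    min_leaf : minimum observations per leaf; 1 grows trees to purity,
        so leaf class frequencies are the per-tree probabilities.
    """

    ntree: int = 500
    mtry: int | str = "auto"
    seed: int = 0
    min_leaf: int = 1

    def __post_init__(self) -> None:
        if self.ntree < 1:
            raise ValueError("ntree must be a positive integer")
        if self.mtry != "auto" and (not isinstance(self.mtry, int) or self.mtry < 1):
            raise ValueError("mtry must be 'auto' or a positive integer")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be a positive integer")

    def resolve_mtry(self, n_features: int) -> int:
        if self.mtry == "auto":
            return max(1, math.floor(math.sqrt(n_features)))
        if self.mtry > n_features:
            raise ValueError(
                f"mtry={self.mtry} exceeds the number of features ({n_features})"
            )
        return self.mtry


@dataclass
class MembershipMatrix:
    """Exact bootstrap membership: inbag_counts[i, j] = draws of row i into tree j.

    A pair (i, j) is out-of-bag iff its count is zero.  Every column sums to
    the bootstrap size n (sampling with replacement, n' = n).
    """

    inbag_counts: np.ndarray

    def __post_init__(self) -> None:
        self.inbag_counts = np.asarray(self.inbag_counts, dtype=np.int64)
        if self.inbag_counts.ndim != 2:
            raise ValueError("inbag_counts must be an n x ntree matrix")

    @property
    def n(self) -> int:
        return self.inbag_counts.shape[0]

    @property
    def ntree(self) -> int:
        return self.inbag_counts.shape[1]

    @property
    def oob_mask(self) -> np.ndarray:
        """Boolean (n, ntree) matrix, True where the row is out-of-bag."""
        return self.inbag_counts == 0


def _tree_streams(seed: int, ntree: int):
    """Per-tree (bootstrap, split) seed pairs from one master seed.

    Each tree gets its own child sequence, split again into a bootstrap
    stream and a split-randomization stream, so the two never interact and
    both are stable under changes to ntree.
    """
    for child in np.random.SeedSequence(seed).spawn(ntree):
        boot_ss, split_ss = child.spawn(2)
        yield boot_ss, int(split_ss.generate_state(1)[0] % (2**31))


def bootstrap_membership(n: int, ntree: int, seed: int) -> MembershipMatrix:
    """Draw the in-bag count matrix for a bagged ensemble.

    Each tree's bootstrap samples n rows uniformly with replacement from
    the n training rows; the expected unique in-bag fraction is
    1 - (1 - 1/n)^n, about 63.2% for large n.
    """
    if n < 1 or ntree < 1:
        raise ValueError("n and ntree must be positive integers")
    counts = np.empty((n, ntree), dtype=np.int64)
    for j, (boot_ss, _) in enumerate(_tree_streams(seed, ntree)):
        rng = np.random.default_rng(boot_ss)
        counts[:, j] = np.bincount(rng.integers(0, n, size=n), minlength=n)
    return MembershipMatrix(counts)


@dataclass
class ForestModel:
    """A fitted ensemble plus its exact bootstrap membership.

    class_order is fixed at (0, 1): probabilities everywhere refer to
    class 1.  feature_names is retained for prediction-time validation.
    """

    trees: list
    membership: MembershipMatrix
    config: ForestConfig
    feature_names: list[str] = field(default_factory=list)
    class_order: tuple = (0, 1)
    # per-tree training-label overrides (ablation fixtures); in-bag scoring
    # must evaluate each tree against the labels it actually trained on
    tree_labels: dict = field(default_factory=dict)

    @property
    def ntree(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


def fit_forest(
    data: TrainingSet,
    config: ForestConfig,
    membership: MembershipMatrix | None = None,
    tree_labels: dict[int, np.ndarray] | None = None,
) -> ForestModel:
    """Fit a bagged forest of unpruned randomized CART trees.

    Each tree is grown on its bootstrap multiset (bootstrap counts enter as
    sample weights on the in-bag rows) with ``mtry`` randomly chosen
    candidate features per split, to purity subject to ``min_leaf``.

    Parameters
    ----------
    membership : optional
        Externally supplied in-bag counts; by default drawn from
        ``config.seed`` via :func:`bootstrap_membership`.  Supplying a
        matrix makes the bag explicit, e.g. for audits or fixtures.
    tree_labels : optional
        Per-tree label overrides {tree index -> label vector of length n};
        used by ensemble-ablation fixtures that train some trees on
        deliberately corrupted labels.  Membership and all random streams
        are unaffected.
    """
    if not data.has_both_classes:
        raise ValueError("degenerate data: both classes must be present to fit")
    mtry = config.resolve_mtry(data.n_features)
    if membership is None:
        membership = bootstrap_membership(data.n, config.ntree, config.seed)
    if membership.n != data.n or membership.ntree != config.ntree:
        raise ValueError("membership matrix shape does not match data/config")
    tree_labels = tree_labels or {}

    trees = []
    for j, (_, split_seed) in enumerate(_tree_streams(config.seed, config.ntree)):
        counts = membership.inbag_counts[:, j]
        inb = counts > 0
        y_j = tree_labels.get(j, data.labels)
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=config.min_leaf,
            random_state=split_seed,
        )
        tree.fit(
            data.features[inb],
            y_j[inb],
            sample_weight=counts[inb].astype(float),
        )
        trees.append(tree)
    return ForestModel(
        trees, membership, config, list(data.feature_names), tree_labels=tree_labels
    )


def tree_probabilities(model: ForestModel, features: np.ndarray) -> np.ndarray:
    """Per-tree class-1 probabilities: an (n_rows, ntree) matrix.

    Entry (i, j) is the class-1 relative frequency in the leaf of tree j
    that row i falls into (weighted by bootstrap multiplicity).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got {features.shape}"
        )
    out = np.empty((features.shape[0], model.ntree), dtype=float)
    for j, tree in enumerate(model.trees):
        proba = tree.predict_proba(features)
        classes = list(tree.classes_)
        if 1 in classes:
            out[:, j] = proba[:, classes.index(1)]
        else:  # tree saw only class 0 in its bag
            out[:, j] = 0.0
    return out


def save_model(model: ForestModel, path) -> None:
    """Serialize to a binary artifact plus a JSON sidecar (config, seed, classes)."""
    path = Path(path)
    joblib.dump(model, path)
    sidecar = {
        "ntree": model.config.ntree,
        "mtry": model.config.mtry,
        "seed": model.config.seed,
        "min_leaf": model.config.min_leaf,
        "class_order": list(model.class_order),
        "feature_names": model.feature_names,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path) -> ForestModel:
    return joblib.load(path)


def with_seed(config: ForestConfig, seed: int) -> ForestConfig:
    """Copy of ``config`` with a different master seed."""
    return replace(config, seed=seed)
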
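"""Evaluation harness: Challenge Score, Youden thresholds, stratified CV,
and the alpha x p grid search.

The protocol mirrors how false-alarm classifiers are benchmarked on the
heavily imbalanced arrhythmia alarm subsets: stratified k-fold CV with k
capped by the minority class size, threshold selection by Youden index on
the training folds only, and a score that penalizes missed true alarms
(false negatives) five-fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datasets import TrainingSet
from .forest import ForestConfig, fit_forest, tree_probabilities, with_seed
from .weighting import (
    aggregate,
    observation_weights,
    rank_trees,
    rank_weights,
    score_trees,
)

__all__ = [
    "ConfusionCounts",
    "FoldAssignment",
    "EvaluationReport",
    "ImprovementGrid",
    "challenge_score",
    "confusion_counts",
    "youden_threshold",
    "stratified_folds",
    "evaluate_wrf",
    "evaluate_mean_baseline",
    "grid_search",
    "DEFAULT_ALPHA_GRID",
    "DEFAULT_P_GRID",
]

# default grids for the alpha x p sweep
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
DEFAULT_P_GRID = tuple(np.round(np.arange(0.0, 5.01, 0.5), 1))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts must not all be zero")


def confusion_counts(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Tally a binary confusion matrix from 0/1 labels and predictions."""
    labels = np.asarray(labels).astype(bool)
    predictions = np.asarray(predictions).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(labels & predictions)),
        fp=int(np.sum(~labels & predictions)),
        tn=int(np.sum(~labels & ~predictions)),
        fn=int(np.sum(labels & ~predictions)),
    )


def challenge_score(c: ConfusionCounts) -> float:
    """Alarm-classification score in [0, 100], harsh on false negatives:

        100 * (TP + TN) / (TP + FP + TN + 5 * FN).

    A missed true alarm costs five times an ordinary error, reflecting the
    clinical asymmetry between suppressing a real event and tolerating a
    false alarm.
    """
    return 100.0 * (c.tp + c.tn) / (c.tp + c.fp + c.tn + 5 * c.fn)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing the Youden index J = TPR - FPR (unweighted).

    Candidates are the distinct score values plus a sentinel above the
    maximum; a row is called positive when its score >= threshold.  Ties
    in J are broken toward the smallest maximizing threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    if not pos.any() or pos.all():
        raise ValueError("Youden threshold undefined: both classes required")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    distinct = np.r_[True, s[1:] != s[:-1]]
    idx = np.flatnonzero(distinct)
    block_end = np.r_[idx[1:] - 1, s.size - 1]
    tpr = np.cumsum(p)[block_end] / pos.sum()
    fpr = np.cumsum(~p)[block_end] / (~pos).sum()
    j = np.r_[0.0, tpr - fpr]  # sentinel above the max: J = 0
    candidates = np.r_[np.inf, s[idx]]
    best = np.flatnonzero(j == j.max())
    return float(candidates[best[-1]])  # descending order: last = smallest tau


@dataclass
class FoldAssignment:
    """Stratified fold ids (0..k-1) for every row."""

    fold_id: np.ndarray
    k: int


def stratified_folds(labels: np.ndarray, seed: int, k: int | None = None) -> FoldAssignment:
    """Stratified k-fold assignment with k adapted to the minority class.

    k defaults to 10 when the smaller class has more than 10 members,
    otherwise to the smaller class size, so every fold holds at least one
    observation of each class.  A minority class of size 1 is rejected
    (cross-validation needs at least 2 folds).
    """
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build folds")
    smaller = min(n_pos, n_neg)
    if k is None:
        k = 10 if smaller > 10 else smaller
    if k < 2:
        raise ValueError("cross-validation requires a minority class of size >= 2")
    if k > smaller:
        raise ValueError(f"k={k} exceeds the minority class size {smaller}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32 - 1))
    fold_id = np.empty(labels.size, dtype=np.int64)
    for f, (_, val_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        fold_id[val_idx] = f
    return FoldAssignment(fold_id, k)


@dataclass
class EvaluationReport:
    """Per-fold and mean validation performance of one (alpha, p) setting."""

    per_fold: pd.DataFrame
    mean_auc: float
    mean_score: float
    alpha: float
    p_exp: float

    def to_csv(self, path) -> None:
        self.per_fold.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "alpha": self.alpha,
            "p_exp": self.p_exp,
            "k": int(len(self.per_fold)),
            "mean_auc": self.mean_auc,
            "mean_score": self.mean_score,
            "equivalent_to_base": self.p_exp == 0,
        }


# ---------------------------------------------------------------------------
# cross-validated evaluation


def _fold_seed(seed: int, fold: int) -> int:
    """Deterministic per-fold forest seed (< 2^31), stable across entry points."""
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


@dataclass
class _FoldState:
    """Cached per-fold artifacts reused across all (alpha, p) cells."""

    probs_train: np.ndarray
    probs_val: np.ndarray
    y_train: np.ndarray
    y_val: np.ndarray
    membership: object
    obs_weights: object
    _auc_cache: tuple | None = field(default=None)

    def tree_aucs(self):
        """Per-tree weighted (AUC_INB, AUC_OOB), computed once per fold.

        alpha enters theta only through the closed-form combination of
        these two vectors, so the grid sweep never re-scores trees.
        """
        if self._auc_cache is None:
            perf = score_trees(
                self.probs_train,
                self.y_train,
                self.membership,
                self.obs_weights,
                alpha=0.0,
            )
            self._auc_cache = (perf.auc_inb, perf.auc_oob)
        return self._auc_cache


def _prepare_fold(
    data: TrainingSet, fconfig: ForestConfig, train_rows: np.ndarray,
    val_rows: np.ndarray, fold: int,
) -> _FoldState:
    cfg = with_seed(fconfig, _fold_seed(fconfig.seed, fold))
    train = data.subset(train_rows)
    model = fit_forest(train, cfg)
    probs_train = tree_probabilities(model, train.features)
    probs_val = tree_probabilities(model, data.features[val_rows])
    ow = observation_weights(probs_train, train.labels, model.membership)
    return _FoldState(
        probs_train, probs_val, train.labels, data.labels[val_rows],
        model.membership, ow,
    )


def _cell(state: _FoldState, alpha: float, p_exp: float) -> tuple[float, float, float]:
    """Validation (auc, score, threshold) for one (alpha, p) cell of one fold."""
    auc_inb, auc_oob = state.tree_aucs()
    theta = -alpha * np.abs(auc_inb - auc_oob) + (1 - alpha) * auc_oob
    tw = rank_weights(rank_trees(theta), p_exp)
    agg_train = aggregate(state.probs_train, tw).scores
    agg_val = aggregate(state.probs_val, tw).scores
    tau = youden_threshold(agg_train, state.y_train)
    auc = float(roc_auc_score(state.y_val, agg_val))
    score = challenge_score(confusion_counts(state.y_val, agg_val >= tau))
    return auc, score, tau


def _cell_mean(state: _FoldState) -> tuple[float, float, float]:
    """Same protocol with plain mean aggregation (the unweighted baseline)."""
    agg_train = aggregate(state.probs_train, method="mean").scores
    agg_val = aggregate(state.probs_val, method="mean").scores
    tau = youden_threshold(agg_train, state.y_train)
    auc = float(roc_auc_score(state.y_val, agg_val))
    score = challenge_score(confusion_counts(state.y_val, agg_val >= tau))
    return auc, score, tau


def _fold_states(data: TrainingSet, fconfig: ForestConfig, folds: FoldAssignment):
    for f in range(folds.k):
        val = folds.fold_id == f
        yield f, _prepare_fold(data, fconfig, ~val, val, f)


def _make_report(rows: list, alpha: float, p_exp: float) -> EvaluationReport:
    per_fold = pd.DataFrame(rows, columns=["fold", "auc", "score", "threshold"])
    return EvaluationReport(
        per_fold,
        float(per_fold["auc"].mean()),
        float(per_fold["score"].mean()),
        float(alpha),
        float(p_exp),
    )


def evaluate_wrf(
    data: TrainingSet,
    fconfig: ForestConfig,
    alpha: float,
    p_exp: float,
    folds: FoldAssignment,
) -> EvaluationReport:
    """Cross-validated weighted-forest evaluation at one (alpha, p).

    Per fold: fit the forest on the training portion, derive observation
    weights, theta, ranks and tree weights from the training portion only,
    aggregate the held-out probabilities with those frozen weights, and
    report held-out AUC plus the Challenge Score at the Youden threshold
    learned on the training scores.  Means are unweighted over folds.
    """
    rows = []
    for f, state in _fold_states(data, fconfig, folds):
        try:
            auc, score, tau = _cell(state, alpha, p_exp)
        except ValueError as err:
            raise ValueError(f"fold {f}: {err}") from err
        rows.append((f, auc, score, tau))
    return _make_report(rows, alpha, p_exp)


def evaluate_mean_baseline(
    data: TrainingSet, fconfig: ForestConfig, folds: FoldAssignment
) -> EvaluationReport:
    """The same protocol with equal-weight (mean) aggregation."""
    rows = []
    for f, state in _fold_states(data, fconfig, folds):
        auc, score, tau = _cell_mean(state)
        rows.append((f, auc, score, tau))
    return _make_report(rows, 0.0, 0.0)


# ---------------------------------------------------------------------------
# alpha x p grid search


@dataclass
class ImprovementGrid:
    """Validation improvement of weighted over mean aggregation on a grid.

    delta matrices are indexed (alpha, p); the p = 0 column is exactly zero
    because p = 0 reproduces mean aggregation.
    """

    alpha_grid: np.ndarray
    p_grid: np.ndarray
    base_auc: float
    base_score: float
    delta_auc: np.ndarray
    delta_score: np.ndarray

    def to_dict(self) -> dict:
        return {
            "alpha_grid": list(map(float, self.alpha_grid)),
            "p_grid": list(map(float, self.p_grid)),
            "base_auc": self.base_auc,
            "base_score": self.base_score,
            "delta_auc": self.delta_auc.tolist(),
            "delta_score": self.delta_score.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def render_text(self) -> str:
        """Plain-text grid in the base/alpha-rows/p-columns layout.

        Each cell carries a +/- marker for improvement/deterioration over
        the equal-weight base.
        """
        lines = []
        for name, base, delta, fmt in (
            ("AUC", self.base_auc, self.delta_auc, "{:+.3f}"),
            ("SCORE", self.base_score, self.delta_score, "{:+.2f}"),
        ):
            header = f"{name} = {base:.4g}".ljust(16) + "".join(
                f"{p:>9.1f}" for p in self.p_grid
            )
            lines.append(header)
            for a, row in zip(self.alpha_grid, delta):
                cells = "".join(
                    f"{fmt.format(d):>8} " if d != 0 else f"{'0':>8} " for d in row
                )
                lines.append(f"alpha={a:<9.1f}" + cells)
            lines.append("")
        return "\n".join(lines)


def grid_search(
    data: TrainingSet,
    fconfig: ForestConfig,
    alpha_grid=None,
    p_grid=None,
    folds: FoldAssignment | None = None,
) -> ImprovementGrid:
    """Sweep the alpha x p grid, refitting each fold's forest only once.

    Tree weights are post-hoc re-rankings of the fitted trees, so every
    (alpha, p) cell reuses the per-fold probability matrices and per-tree
    AUCs.  Deltas are against the p = 0 (mean aggregation) base; any cell
    equals an independent :func:`evaluate_wrf` run with the same seeds.
    """
    alpha_grid = np.asarray(
        DEFAULT_ALPHA_GRID if alpha_grid is None else alpha_grid, dtype=float
    )
    p_grid = np.asarray(DEFAULT_P_GRID if p_grid is None else p_grid, dtype=float)
    if alpha_grid.size == 0 or p_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if folds is None:
        folds = stratified_folds(data.labels, fconfig.seed)

    auc = np.zeros((alpha_grid.size, p_grid.size))
    score = np.zeros_like(auc)
    base_auc = 0.0
    base_score = 0.0
    for _, state in _fold_states(data, fconfig, folds):
        b_auc, b_score, _ = _cell_mean(state)
        base_auc += b_auc
        base_score += b_score
        for ai, a in enumerate(alpha_grid):
            for pi, p in enumerate(p_grid):
                c_auc, c_score, _ = _cell(state, float(a), float(p))
                auc[ai, pi] += c_auc
                score[ai, pi] += c_score
    k = folds.k
    auc /= k
    score /= k
    base_auc /= k
    base_score /= k
    return ImprovementGrid(
        alpha_grid, p_grid, float(base_auc), float(base_score),
        auc - base_auc, score - base_score,
    )
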
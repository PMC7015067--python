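"""Performance-based tree weighting for bagged ensembles.

The ensemble's final probability is a weighted mean of per-tree
probabilities, with tree weights derived in four steps:

1. Observation weights: each row's weight is its mean absolute out-of-bag
   residual, w_i = mean_{j : i OOB for tree j} |y_i - p_ij|.  Rows every
   tree already predicts perfectly get weight 0 and drop out of tree
   scoring; hard rows dominate it.
2. Weighted ROC/AUC: the ROC curve with TPR/FPR computed from those
   per-observation weights, integrated by the trapezoid rule.
3. Tree score: theta_j = -alpha * |AUC_INB_j - AUC_OOB_j|
   + (1 - alpha) * AUC_OOB_j, where the AUCs are the observation-weighted
   AUCs of tree j on its own in-bag and out-of-bag rows.  alpha in [0, 1]
   trades tree stability (small INB/OOB gap) against out-of-bag accuracy.
4. Rank-exponential weights: trees are ranked by theta (rank 1 = best) and
   weighted w_j proportional to (Ntree - r_j + 1)^p, normalized to sum to 1.
   p = 0 recovers equal weights (the plain forest); larger p concentrates
   weight on the top-ranked trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forest import ForestModel, MembershipMatrix, tree_probabilities

__all__ = [
    "ObservationWeights",
    "WeightedROC",
    "TreePerformance",
    "TreeWeights",
    "AggregatedScores",
    "TreeWeighting",
    "observation_weights",
    "weighted_roc",
    "weighted_auc",
    "tree_performance",
    "rank_trees",
    "rank_weights",
    "aggregate",
    "score_trees",
    "weight_trees",
]


# ---------------------------------------------------------------------------
# observation weights from OOB residuals


@dataclass
class ObservationWeights:
    """Per-row weights w_i = mean absolute OOB residual, in [0, 1].

    n_oob_trees counts the trees for which each row was out-of-bag;
    rows with zero OOB trees receive the mean of the defined weights and
    are flagged in ``fallback``.
    """

    w_obs: np.ndarray
    n_oob_trees: np.ndarray
    fallback: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "row_id": np.arange(len(self.w_obs)),
                "w_obs": self.w_obs,
                "n_oob_trees": self.n_oob_trees,
                "fallback": self.fallback,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def observation_weights(
    probs: np.ndarray, labels: np.ndarray, membership: MembershipMatrix
) -> ObservationWeights:
    """Mean absolute out-of-bag residual per observation.

    For each row i, averages |y_i - p_ij| over the trees j that did not see
    row i in their bootstrap.  A weight of 0 means every OOB tree already
    predicts the row perfectly, so it is ignored when scoring trees;
    misclassified rows carry the most influence.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size == 0:
        raise ValueError("empty probability matrix")
    labels = np.asarray(labels)
    if probs.shape != (membership.n, membership.ntree):
        raise ValueError("probs shape must match the membership matrix")
    if labels.shape != (membership.n,):
        raise ValueError("labels length must match the membership matrix")

    oob = membership.oob_mask
    resid = np.abs(labels[:, None] - probs)
    n_oob = oob.sum(axis=1)
    with np.errstate(invalid="ignore"):
        w = np.where(n_oob > 0, (resid * oob).sum(axis=1) / np.maximum(n_oob, 1), np.nan)
    fallback = n_oob == 0
    if fallback.any():
        defined = w[~fallback]
        if defined.size == 0:
            raise ValueError(
                "no observation was out-of-bag in any tree; increase ntree"
            )
        warnings.warn(
            f"{int(fallback.sum())} observation(s) were never out-of-bag; "
            "assigned the mean of the defined weights",
            stacklevel=2,
        )
        w = np.where(fallback, defined.mean(), w)
    return ObservationWeights(w, n_oob, fallback)


# ---------------------------------------------------------------------------
# weighted ROC / AUC


@dataclass
class WeightedROC:
    """A weighted ROC curve and its trapezoid area.

    thresholds are descending, starting with an +inf sentinel so the curve
    begins at (0, 0); a score is called positive when score >= threshold,
    so at and below the minimum score the curve reaches (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    w_pos_total: float
    w_neg_total: float


def weighted_roc(
    scores: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> WeightedROC:
    """ROC curve with observation-weighted TPR/FPR and trapezoid AUC.

    TPR(t) = sum of positive-class weights with score >= t over the total
    positive weight; FPR(t) likewise over negatives.  The curve is
    evaluated at every distinct score plus a sentinel above the maximum.
    Tied scores enter the curve as a single step, so the trapezoid area
    gives tied positive-negative pairs half credit.

    If one class has zero total weight (all its rows perfectly predicted),
    uniform weights are substituted for the computation and a warning is
    issued, so the AUC stays defined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = scores.shape[0]
    if labels.shape != (n,):
        raise ValueError("scores and labels must have the same length")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValueError("weights must have the same length as scores")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("AUC undefined: both classes must be present")

    w1 = float(weights[pos].sum())
    w0 = float(weights[neg].sum())
    if w1 == 0.0 or w0 == 0.0:
        warnings.warn(
            "one class has zero total observation weight; "
            "falling back to uniform weights for this ROC",
            stacklevel=2,
        )
        weights = np.ones(n)
        w1 = float(pos.sum())
        w0 = float(neg.sum())

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    wpos = np.where(pos, weights, 0.0)[order]
    wneg = np.where(neg, weights, 0.0)[order]
    # collapse tied scores into single thresholds
    distinct = np.r_[True, s[1:] != s[:-1]]
    idx = np.flatnonzero(distinct)
    thresholds = np.r_[np.inf, s[idx]]
    cum_pos = np.cumsum(wpos)
    cum_neg = np.cumsum(wneg)
    # value at the *last* element of each tied block
    block_end = np.r_[idx[1:] - 1, s.size - 1]
    tpr = np.r_[0.0, cum_pos[block_end] / w1]
    fpr = np.r_[0.0, cum_neg[block_end] / w0]
    auc = float(np.trapezoid(tpr, fpr))
    return WeightedROC(thresholds, fpr, tpr, auc, w1, w0)


def weighted_auc(
    scores: np.ndarray, labels: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Trapezoid area under the weighted ROC curve (see :func:`weighted_roc`)."""
    return weighted_roc(scores, labels, weights).auc


# ---------------------------------------------------------------------------
# tree score, ranking, rank-exponential weights


@dataclass
class TreePerformance:
    """Per-tree observation-weighted AUCs and the stability-penalized score."""

    auc_inb: np.ndarray
    auc_oob: np.ndarray
    theta: np.ndarray
    alpha: float


def tree_performance(auc_inb, auc_oob, alpha: float):
    """Stability-penalized tree score.

    theta = -alpha * |AUC_INB - AUC_OOB| + (1 - alpha) * AUC_OOB.

    alpha = 1 scores pure stability (the in-bag/out-of-bag gap); alpha = 0
    scores pure out-of-bag accuracy.  theta always lies in [-alpha, 1 - alpha].
    Accepts scalars or vectors.
    """
    auc_inb = np.asarray(auc_inb, dtype=float)
    auc_oob = np.asarray(auc_oob, dtype=float)
    if np.any((auc_inb < 0) | (auc_inb > 1)) or np.any((auc_oob < 0) | (auc_oob > 1)):
        raise ValueError("AUC values must lie in [0, 1]")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    theta = -alpha * np.abs(auc_inb - auc_oob) + (1 - alpha) * auc_oob
    return theta if theta.ndim else float(theta)


def rank_trees(theta: np.ndarray) -> np.ndarray:
    """Rank trees by score: rank 1 = largest theta; ties go to the lower index."""
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("cannot rank an empty score vector")
    order = np.lexsort((np.arange(theta.size), -theta))
    ranks = np.empty(theta.size, dtype=np.int64)
    ranks[order] = np.arange(1, theta.size + 1)
    return ranks


@dataclass
class TreeWeights:
    """Rank-exponential tree weights.

    weights[j] = (Ntree - ranks[j] + 1)^p_exp, normalized to sum to 1.
    p_exp = 0 gives equal weights; weights are strictly decreasing in rank
    when p_exp > 0.
    """

    ranks: np.ndarray
    p_exp: float
    weights: np.ndarray

    def to_frame(self, theta: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "tree_id": np.arange(len(self.ranks)),
                "rank": self.ranks,
                "weight": self.weights,
            }
        )
        if theta is not None:
            df.insert(2, "theta", np.asarray(theta, dtype=float))
        return df

    def to_csv(self, path, theta: np.ndarray | None = None) -> None:
        self.to_frame(theta).to_csv(path, index=False)


def rank_weights(ranks: np.ndarray, p_exp: float) -> TreeWeights:
    """Turn a tree ranking into normalized rank-exponential weights."""
    ranks = np.asarray(ranks, dtype=np.int64)
    ntree = ranks.size
    if not np.array_equal(np.sort(ranks), np.arange(1, ntree + 1)):
        raise ValueError("ranks must be a permutation of 1..Ntree")
    if p_exp < 0:
        raise ValueError("p_exp must be non-negative")
    base = (ntree - ranks + 1).astype(float) ** p_exp
    return TreeWeights(ranks, float(p_exp), base / base.sum())


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class AggregatedScores:
    """Ensemble scores in [0, 1] for one aggregation method."""

    scores: np.ndarray
    method: str


def aggregate(
    probs: np.ndarray,
    tree_weights: TreeWeights | np.ndarray | str | None = None,
    method: str = "weighted",
    vote_cutoff: float = 0.5,
    literal_scale: bool = False,
) -> AggregatedScores:
    """Combine per-tree probabilities into one score per observation.

    method="vote"     : fraction of trees with p_ij > vote_cutoff.
    method="mean"     : row mean of the probability matrix (the plain forest).
    method="weighted" : sum_j p_ij * w_j with weights summing to 1, i.e. a
        weighted mean that stays in [0, 1].  ``literal_scale=True`` divides
        additionally by Ntree — a rank-equivalent variant kept for audit;
        it rescales every score by the same constant, so ROC-based results
        are unchanged.
    """
    probs = np.asarray(probs, dtype=float)
    if method == "vote":
        return AggregatedScores((probs > vote_cutoff).mean(axis=1), "vote")
    if method == "mean":
        return AggregatedScores(probs.mean(axis=1), "mean")
    if method != "weighted":
        raise ValueError(f"unknown aggregation method {method!r}")
    if tree_weights is None:
        raise ValueError("weighted aggregation requires tree weights")
    if isinstance(tree_weights, str):
        if tree_weights != "equal":
            raise ValueError(f"unknown weight spec {tree_weights!r}")
        w = np.full(probs.shape[1], 1.0 / probs.shape[1])
    elif isinstance(tree_weights, TreeWeights):
        w = tree_weights.weights
    else:
        w = np.asarray(tree_weights, dtype=float)
    if w.shape != (probs.shape[1],):
        raise ValueError("tree weights length must equal the number of trees")
    if np.all(w == w[0]):
        # equal weights: use the mean path so the p=0 reduction is bitwise
        scores = probs.mean(axis=1)
    else:
        scores = probs @ w
    if literal_scale:
        scores = scores / probs.shape[1]
    return AggregatedScores(scores, "weighted")


# ---------------------------------------------------------------------------
# per-tree scoring pipeline


def _sample_auc(scores, y, w, kind: str) -> float:
    """Weighted AUC on one tree's INB or OOB rows, with degenerate fallbacks.

    Single-class samples get 0.5 (the tree is neither rewarded nor
    excluded).  A zero-weight class on the out-of-bag side also gets 0.5;
    on the in-bag side uniform weights are substituted (handled inside
    :func:`weighted_roc`).
    """
    y = np.asarray(y)
    if y.size < 2 or y.min() == y.max():
        warnings.warn(
            f"degenerate {kind} sample (single class); using AUC = 0.5",
            stacklevel=3,
        )
        return 0.5
    w = np.asarray(w, dtype=float)
    if kind == "oob" and (w[y == 1].sum() == 0.0 or w[y == 0].sum() == 0.0):
        warnings.warn(
            "zero total weight in one OOB class; using AUC = 0.5",
            stacklevel=3,
        )
        return 0.5
    return weighted_auc(scores, y, w)


def score_trees(
    probs: np.ndarray,
    labels: np.ndarray,
    membership: MembershipMatrix,
    obs_weights: ObservationWeights,
    alpha: float,
    oob_auc_weighted: bool = True,
    tree_labels: dict[int, np.ndarray] | None = None,
) -> TreePerformance:
    """Observation-weighted in-bag/out-of-bag AUC and theta for every tree.

    Each tree's in-bag AUC uses the unique in-bag rows (multiplicities do
    not enter the AUC) and its out-of-bag AUC the rows it never saw, both
    with the observation weights restricted to those rows.  With
    ``oob_auc_weighted=False`` the stability penalty compares against the
    *unweighted* out-of-bag AUC instead, while the accuracy term stays
    weighted.

    ``tree_labels`` maps tree index -> the label vector that tree trained
    on (ablation fixtures).  In-bag scoring evaluates each tree against
    its own training labels — training labels are the only labels the
    learning algorithm ever sees — while out-of-bag scoring always uses
    the shared labels.
    """
    labels = np.asarray(labels)
    tree_labels = tree_labels or {}
    w = obs_weights.w_obs
    ntree = membership.ntree
    auc_inb = np.empty(ntree)
    auc_oob = np.empty(ntree)
    pen_oob = np.empty(ntree)
    for j in range(ntree):
        inb = membership.inbag_counts[:, j] > 0
        oob = ~inb
        y_inb = np.asarray(tree_labels.get(j, labels))
        auc_inb[j] = _sample_auc(probs[inb, j], y_inb[inb], w[inb], "inb")
        auc_oob[j] = _sample_auc(probs[oob, j], labels[oob], w[oob], "oob")
        if oob_auc_weighted:
            pen_oob[j] = auc_oob[j]
        else:
            pen_oob[j] = _sample_auc(
                probs[oob, j], labels[oob], np.ones(int(oob.sum())), "oob"
            )
    theta = -alpha * np.abs(auc_inb - pen_oob) + (1 - alpha) * auc_oob
    return TreePerformance(auc_inb, auc_oob, theta, alpha)


@dataclass
class TreeWeighting:
    """Full weighting state of a fitted forest: w_obs, per-tree scores, weights."""

    obs_weights: ObservationWeights
    performance: TreePerformance
    tree_weights: TreeWeights
    alpha: float
    p_exp: float

    def to_frame(self) -> pd.DataFrame:
        return self.tree_weights.to_frame(self.performance.theta)


def weight_trees(
    model: ForestModel,
    features: np.ndarray,
    labels: np.ndarray,
    alpha: float,
    p_exp: float,
    oob_auc_weighted: bool = True,
    probs: np.ndarray | None = None,
) -> TreeWeighting:
    """End-to-end tree weighting on the training sample of a fitted forest.

    Runs the four-step pipeline (OOB residual weights, per-tree weighted
    AUCs, theta, rank-exponential weights).  ``features``/``labels`` must
    be the rows the forest was fit on, so the membership matrix applies.
    """
    if probs is None:
        probs = tree_probabilities(model, features)
    ow = observation_weights(probs, labels, model.membership)
    perf = score_trees(
        probs, labels, model.membership, ow, alpha, oob_auc_weighted,
        tree_labels=model.tree_labels,
    )
    tw = rank_weights(rank_trees(perf.theta), p_exp)
    return TreeWeighting(ow, perf, tw, float(alpha), float(p_exp))
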
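# Methods

## The model

`wrforest` implements a weighted random forest for binary classification.
The base learner is a standard bagged ensemble: each of `Ntree` trees is
grown on a bootstrap sample of size n drawn with replacement from the
training data (so each tree sees ~63.2% of unique rows in-bag, the rest
out-of-bag), splitting on `mtry` randomly chosen candidate features and
growing to purity subject to `min_leaf`. Per-tree probabilities are leaf
class-1 frequencies (weighted by bootstrap multiplicity).

Instead of averaging trees equally, the ensemble score is a weighted mean

    score_i = Σ_j p_ij · w_j,   Σ_j w_j = 1,

with tree weights derived in four steps, all from the training sample only:

1. **Observation weights.** For each row i,
   `w_i^obs = mean over trees j with i out-of-bag of |y_i − p_ij|` ∈ [0, 1].
   Rows every tree already classifies perfectly get weight 0 and drop out of
   tree scoring; hard rows dominate it. This is the "fairness" device: trees
   should not be rewarded for doing well on rows everyone gets right.
2. **Weighted ROC/AUC.** TPR and FPR at a threshold τ (positive call when
   score ≥ τ) are computed with the per-row weights, and the AUC is the
   trapezoid integral of the resulting curve over all distinct score values
   plus a sentinel above the maximum. Tied scores form a single ROC step, so
   tied positive–negative pairs receive half credit — the curve's area
   equals the weighted Mann–Whitney pair statistic exactly.
3. **Tree score.** Each tree j gets
   `θ_j = −α·|AUC_INB_j − AUC_OOB_j| + (1 − α)·AUC_OOB_j`,
   where both AUCs are observation-weighted and restricted to the tree's own
   unique in-bag rows / out-of-bag rows. α ∈ [0, 1] trades stability (a
   small in-bag/out-of-bag gap) against out-of-bag accuracy; θ always lies
   in [−α, 1 − α].
4. **Rank-exponential weights.** Trees are ranked by θ (rank 1 = best; ties
   broken by tree index) and weighted
   `w_j = (Ntree − r_j + 1)^p / Σ_k (Ntree − r_k + 1)^p`.
   p = 0 gives equal weights — exactly the plain forest — p = 1 the linear
   rank-sum scheme, and larger p concentrates mass on the top-ranked trees.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `ntree` | 500 | number of trees; tests and examples use 10–100 (desk scale) |
| `mtry` | `"auto"` = ⌊√n_features⌋ | candidate features per split |
| `min_leaf` | 1 | minimum rows per leaf; 1 grows trees to purity |
| `alpha` | — | stability vs out-of-bag accuracy trade-off in θ, in [0, 1] |
| `p_exp` | — | rank-weight exponent, ≥ 0; 0 = equal weights |
| grids | α: 0…1 step 0.1; p: 0…5 step 0.5 | the default 11×11 sweep |

All randomness flows from one integer seed. Each tree has its own
`SeedSequence` child, split again into a bootstrap stream and a
split-randomization stream, so growing `ntree` leaves earlier trees
unchanged, and refits are bit-for-bit reproducible. Cross-validation
derives per-fold forest seeds from `SeedSequence([seed, fold])`, which is
why a grid-search cell and an independent evaluation run at the same
(α, p) agree exactly.

## Evaluation protocol

Performance is estimated by stratified k-fold cross-validation with k = 10
when the minority class has more than 10 members, otherwise k = minority
size (so every fold holds both classes); a minority class of 1 is
rejected. Per fold, the forest, the observation weights, θ, ranks and tree
weights are all derived from the training portion; held-out rows never
influence weights. Two quantities are reported per fold and macro-averaged:

- **AUC** of the aggregated held-out scores (unweighted — the evaluation
  metric is deliberately not the training-side weighted AUC).
- **Score** = 100·(TP + TN)/(TP + FP + TN + 5·FN), the alarm-classification
  measure that charges a missed true alarm five ordinary errors. Class
  calls use the threshold maximizing the Youden index J = TPR − FPR on the
  *training* scores (fitting the threshold on validation would leak);
  ties in J resolve to the smallest maximizing threshold.

`grid_search` fits each fold's forest once and reuses the per-tree AUCs
across all (α, p) cells — weights are post-hoc re-rankings, so no refit is
needed. Deltas are reported against the p = 0 column, which is zero by
construction.

## Synthetic data

`make_alarm_dataset` emulates the five arrhythmia alarm subsets'
true/false-alarm imbalances (e.g. 100/22, 52/6) with class-conditional
Gaussian features: `n_informative` features shifted by `class_separation`
in the positive class, the rest pure noise. Defaults (10 features, 3
informative, separation 1.5, unit noise) put a 100-tree forest in the
0.87–0.99 AUC regime typical of these subsets. What it does **not**
emulate: feature correlation structure, heavy tails, label noise, and the
beat-detection / spectral-purity provenance of real monitor features — so
green tests demonstrate the mechanics and the weighting's behavior under
controlled corruption, not clinical performance.

`corrupted_forest_fixture` trains a chosen fraction of trees on bootstraps
whose in-bag labels are flipped with probability 0.4, creating a genuine
quality gradient across trees while keeping membership bookkeeping exact.

## Numerical choices and degenerate inputs

- **Aggregation normalization.** Weights sum to 1 and the score is the
  plain weighted mean, so it stays in [0, 1]. The variant that divides
  additionally by `Ntree` is available (`literal_scale=True`); it rescales
  all scores by one constant and is therefore rank-equivalent — identical
  ROC, AUC and Youden behavior.
- **Equal-weight fast path.** When all tree weights are equal the weighted
  mean is computed as the row mean, making the p = 0 reduction to the
  plain forest bitwise exact through thresholds and fold reports.
- **In-bag scoring labels.** A tree's in-bag AUC is evaluated against the
  labels it was trained on (for ordinary forests these are the dataset
  labels; for fixtures with per-tree label overrides, the overridden
  ones). Training labels are the only labels the learning algorithm sees;
  scoring a tree's bag against labels it never saw would conflate the
  stability penalty with label provenance.
- **Degenerate per-tree samples.** If a tree's in-bag or out-of-bag rows
  are single-class, its AUC for that sample is set to 0.5 with a warning —
  the tree is neither rewarded nor excluded. A zero total observation
  weight in an out-of-bag class likewise yields 0.5; on the in-bag side
  (or globally, when a class is predicted perfectly everywhere) uniform
  weights are substituted instead.
- **Never-OOB rows** receive the mean of the defined observation weights
  and are flagged.
- **Ties.** Ranking ties break by tree index; Youden ties by the smallest
  maximizing threshold; score-vs-threshold ties are positive calls (≥).

## Problem sizes

The test suite and examples run at desk scale by the package's own choice:
profiles of 58–341 rows, forests of 10–100 trees, 20 replicates for the
corrupted-ensemble comparison, and the bootstrap composition law checked at
n = 10,000 with 200 trees. The implementation itself has no special-cased
limits; `ntree=500` on these profiles runs in seconds.

## Known limitations

- Binary classification only; no multiclass or regression weighting.
- No missing-value handling; inputs must be complete numeric tables.
- θ is estimated from small per-tree OOB samples (~37% of n); on tiny
  datasets the ranking is noisy, and with heavy weight concentration
  (large p) this noise can cost ensemble diversity — the grid search
  exists precisely to expose where weighting helps or hurts.
- Tree-level weighting cannot repair a forest whose trees are uniformly
  bad; it reallocates trust, it does not relearn.
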
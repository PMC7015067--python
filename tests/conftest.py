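import numpy as np
import pytest

from wrforest import DatasetProfile, ForestConfig, make_alarm_dataset


def pair_count_auc(scores, labels, weights=None):
    """Independent weighted AUC oracle: normalized positive-negative pair
    count, with ties at half credit.

    AUC = sum_{i in pos} sum_{k in neg} w_i w_k (1[s_i > s_k] + 0.5 * 1[s_i = s_k])
          / (W1 * W0)
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    weights = np.ones(len(scores)) if weights is None else np.asarray(weights, float)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    total = 0.0
    for i in pos:
        for k in neg:
            if scores[i] > scores[k]:
                credit = 1.0
            elif scores[i] == scores[k]:
                credit = 0.5
            else:
                credit = 0.0
            total += weights[i] * weights[k] * credit
    return total / (weights[pos].sum() * weights[neg].sum())


@pytest.fixture
def asystole_data():
    return make_alarm_dataset(DatasetProfile.from_name("asystole", seed=11))


@pytest.fixture
def small_config():
    return ForestConfig(ntree=30, seed=7)


@pytest.fixture
def separable_data():
    """Two well-separated Gaussian clusters (trivially learnable)."""
    rng = np.random.default_rng(5)
    x0 = rng.normal(0.0, 0.3, size=(40, 4))
    x1 = rng.normal(5.0, 0.3, size=(40, 4))
    from wrforest import TrainingSet

    return TrainingSet(
        np.vstack([x0, x1]), np.r_[np.zeros(40, int), np.ones(40, int)]
    )
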
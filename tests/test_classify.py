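"""classify module: SMOTE, families, CV isolation, operating point."""

import warnings

import numpy as np
import pytest

from mscpheno.classify import (
    FAMILIES,
    EnsembleModel,
    bootstrap_auc_ci,
    crossval_auc,
    empirical_auc,
    operating_point,
    smote_balance,
    soft_vote,
    train_day_model,
    train_family,
    train_pipeline,
)


def _separable(n=60, d=4, seed=11, p_pos=0.5):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < p_pos).astype(int)
    X = rng.normal(size=(n, d)) + y[:, None] * 5.0
    return X, y


# ------------------------------------------------------------- SMOTE


def test_smote_balanced_input_unchanged():
    X = np.arange(20, dtype=float).reshape(10, 2)
    y = np.array([0] * 5 + [1] * 5)
    Xb, yb = smote_balance(X, y)
    assert np.array_equal(Xb, X) and np.array_equal(yb, y)


def test_smote_117_50_to_117_117():
    rng = np.random.default_rng(12)
    X = np.vstack([rng.normal(0, 1, (117, 3)), rng.normal(5, 1, (50, 3))])
    y = np.array([0] * 117 + [1] * 50)
    Xb, yb = smote_balance(X, y, seed=0)
    assert np.bincount(yb).tolist() == [117, 117]
    assert len(Xb) == 234
    # original samples untouched, synthetic appended at the end
    assert np.array_equal(Xb[:167], X)
    assert (yb[167:] == 1).all()


def test_smote_synthetic_on_minority_segments():
    rng = np.random.default_rng(13)
    Xmin = rng.normal(5, 1, (8, 2))
    X = np.vstack([rng.normal(0, 1, (20, 2)), Xmin])
    y = np.array([0] * 20 + [1] * 8)
    Xb, yb = smote_balance(X, y, seed=1, k=5)
    synth = Xb[28:]
    # each synthetic point lies on a segment between two minority points
    for s in synth:
        on_segment = False
        for i in range(len(Xmin)):
            for j in range(len(Xmin)):
                if i == j:
                    continue
                ab = Xmin[j] - Xmin[i]
                denom = ab @ ab
                t = (s - Xmin[i]) @ ab / denom
                if -1e-9 <= t <= 1 + 1e-9 and np.allclose(Xmin[i] + t * ab, s, atol=1e-8):
                    on_segment = True
                    break
            if on_segment:
                break
        assert on_segment


def test_smote_small_minority_reduces_k_with_warning():
    rng = np.random.default_rng(14)
    X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(5, 1, (3, 2))])
    y = np.array([0] * 10 + [1] * 3)
    with pytest.warns(UserWarning):
        Xb, yb = smote_balance(X, y, seed=0, k=5)
    assert np.bincount(yb).tolist() == [10, 10]


def test_smote_validation():
    with pytest.raises(ValueError):
        smote_balance(np.zeros((3, 2)), np.array([0, 0, 0]))
    with pytest.raises(ValueError):
        smote_balance(np.zeros((3, 2)), np.array([0, 0, 1]))  # minority < 2


# ------------------------------------------------------------- families


@pytest.mark.parametrize("family", FAMILIES)
def test_family_separable_training_auc_one(family):
    X, y = _separable()
    model = train_family(family, X, y, seed=0)
    auc = empirical_auc(model.predict_proba(X), y)
    assert auc == 1.0


def test_unknown_family():
    X, y = _separable()
    with pytest.raises(ValueError):
        train_family("MLP", X, y)


def test_train_family_requires_both_classes():
    X = np.zeros((5, 2))
    with pytest.raises(ValueError):
        train_family("LR", X, np.zeros(5, dtype=int))


def test_knn_probabilities_on_discrete_grid():
    X, y = _separable(n=80)
    model = train_family("KNN", X, y, seed=0)
    probs = model.predict_proba(X)
    k = 5
    grid = np.arange(k + 1) / k
    assert np.isin(np.round(probs * k) / k, grid).all()
    assert np.allclose(probs, np.round(probs * k) / k)


# ------------------------------------------------------------- AUC


def test_empirical_auc_hand_oracle():
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    labels = np.array([0, 0, 1, 1])
    # pairs: (0.35 vs 0.1)=1, (0.35 vs 0.4)=0, (0.8 vs 0.1)=1, (0.8 vs 0.4)=1
    assert empirical_auc(scores, labels) == pytest.approx(3 / 4)


def test_empirical_auc_ties():
    scores = np.array([0.5, 0.5])
    labels = np.array([0, 1])
    assert empirical_auc(scores, labels) == 0.5


def test_bootstrap_ci_brackets_point_estimate():
    rng = np.random.default_rng(15)
    labels = np.array([0] * 40 + [1] * 40)
    scores = rng.normal(0, 1, 80) + labels * 1.5
    auc = empirical_auc(scores, labels)
    lo, hi = bootstrap_auc_ci(scores, labels, n_reps=500, seed=2)
    assert lo <= auc <= hi
    assert 0 < lo < hi <= 1


# ------------------------------------------------------------- CV


def test_crossval_separable_mean_one():
    X, y = _separable(n=100)
    e = crossval_auc("LDA", X, y, seed=17)
    assert e.mean_auc == 1.0
    assert e.se_auc == 0.0
    assert len(e.fold_aucs) == 5


def test_crossval_no_leakage_from_test_fold():
    """Changing test-fold labels must not change fold models' predictions."""
    from sklearn.model_selection import StratifiedKFold

    X, y = _separable(n=60, seed=16)
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=17)
    train_idx, test_idx = next(iter(skf.split(X, y)))
    m1 = train_family("LR", X[train_idx], y[train_idx], seed=17)
    # corrupt the test-fold labels; the training fit cannot see them
    y2 = y.copy()
    y2[test_idx] = 1 - y2[test_idx]
    m2 = train_family("LR", X[train_idx], y2[train_idx], seed=17)
    probe = np.random.default_rng(0).normal(size=(10, X.shape[1]))
    assert np.array_equal(m1.predict_proba(probe), m2.predict_proba(probe))


def test_crossval_deterministic():
    X, y = _separable(n=60, seed=18, p_pos=0.4)
    a = crossval_auc("KNN", X, y, seed=17)
    b = crossval_auc("KNN", X, y, seed=17)
    assert a.fold_aucs == b.fold_aucs


# ------------------------------------------------------------- operating point


def _exhaustive_operating_point(scores, labels):
    best_t, best_val = None, np.inf
    for t in np.unique(scores):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        val = (1 - sens) ** 2 + (1 - spec) ** 2
        if val < best_val - 1e-12:
            best_val, best_t = val, t
    return best_t


def test_operating_point_equals_exhaustive_scan():
    rng = np.random.default_rng(19)
    for trial in range(20):
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.random(30)
        assert operating_point(scores, labels) == _exhaustive_operating_point(
            scores, labels
        ), trial


def test_operating_point_tie_goes_to_lower_threshold():
    scores = np.array([0.1, 0.6, 0.4, 0.9])
    labels = np.array([0, 0, 1, 1])
    # t=0.4 (sens 1, spec 0.5) and t=0.9 (sens 0.5, spec 1) both score 0.25;
    # the tie resolves to the lower, more sensitive threshold
    assert operating_point(scores, labels) == 0.4


# ------------------------------------------------------------- day models


def test_train_day_model_structure():
    X, y = _separable(n=80, seed=20, p_pos=0.35)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dm = train_day_model(X, y, day=2)
    assert set(dm.cv_report.entries) == set(FAMILIES)
    assert len(dm.top_families) == 2
    assert dm.top_families == tuple(dm.cv_report.ranking()[:2])
    assert 0.0 <= dm.threshold <= 1.0
    probs = soft_vote(dm.ensemble, X)
    member_probs = np.mean(
        [m.predict_proba(X) for m in dm.ensemble.members], axis=0
    )
    assert np.allclose(probs, member_probs)
    assert empirical_auc(probs, y) == 1.0


def test_train_day_model_warns_on_small_class():
    rng = np.random.default_rng(21)
    X = rng.normal(size=(20, 3))
    X[:5] += 4
    y = np.array([1] * 5 + [0] * 15)
    with pytest.warns(UserWarning):
        train_day_model(X, y, day=2)


def test_train_pipeline_by_day():
    X2, y2 = _separable(n=60, seed=22, p_pos=0.4)
    X4, y4 = _separable(n=60, seed=23, p_pos=0.4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models = train_pipeline({2: X2, 4: X4}, {2: y2, 4: y4})
    assert set(models) == {2, 4}
    assert models[2].day == 2 and models[4].day == 4
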
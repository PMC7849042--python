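"""Phenotype classification: SMOTE balancing, five classifier families,
stratified five-fold cross-validation, soft-voting ensembles and the ROC
operating point.

Feature matrices are standardised to zero mean / unit variance with training
statistics only; the minority class is oversampled with SMOTE inside each
training fold; model families are compared by mean cross-validated AUC and the
top two are fused by averaging their predicted probabilities. The convention
throughout is that models output the probability of the SR (slowly
replicating) phenotype, with labels RS=0, SR=1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.svm import SVC

from .config import ClassifyParams

FAMILIES = ("LSVM", "RSVM", "LDA", "KNN", "LR")


# ---------------------------------------------------------------- SMOTE


def smote_balance(
    X: np.ndarray, y: np.ndarray, seed: int = 0, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    New minority samples are drawn on the segment between a random minority
    point and one of its k nearest minority neighbours, until both classes
    have equal counts. The majority class is untouched.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_balance requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    deficit = n_maj - n_min
    if deficit == 0:
        return X.copy(), y.copy()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples")
    Xmin = X[y == minority]
    k_eff = min(k, n_min - 1)
    if k_eff < k:
        warnings.warn(f"minority too small for k={k}; using k={k_eff}", stacklevel=2)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    _, idx = nn.kneighbors(Xmin)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=deficit)
    neigh = idx[base, rng.integers(1, k_eff + 1, size=deficit)]
    gap = rng.random(deficit)[:, None]
    synth = Xmin[base] + gap * (Xmin[neigh] - Xmin[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(deficit, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------- models


@dataclass
class TrainedModel:
    family: str
    estimator: object
    mean: np.ndarray
    std: np.ndarray

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the SR (label 1) phenotype."""
        Z = (np.asarray(X) - self.mean) / self.std
        proba = self.estimator.predict_proba(Z)
        sr_col = list(self.estimator.classes_).index(1)
        return proba[:, sr_col]


@dataclass
class EnsembleModel:
    members: tuple[TrainedModel, TrainedModel]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)


def _make_estimator(family: str, params: ClassifyParams, seed: int):
    if family == "LSVM":
        # Platt-style sigmoid calibration provides SVM probabilities
        return CalibratedClassifierCV(
            SVC(kernel="linear", C=params.svm_C, random_state=seed),
            method="sigmoid", ensemble=False,
        )
    if family == "RSVM":
        return CalibratedClassifierCV(
            SVC(kernel="rbf", C=params.svm_C, gamma="scale", random_state=seed),
            method="sigmoid", ensemble=False,
        )
    if family == "LDA":
        # lsqr + automatic shrinkage keeps singular within-class covariance safe
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if family == "KNN":
        return KNeighborsClassifier(n_neighbors=params.knn_k, weights="uniform")
    if family == "LR":
        return LogisticRegression(C=params.lr_C, max_iter=1000)
    raise ValueError(f"unknown family {family!r}")


def train_family(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    params: ClassifyParams | None = None,
    seed: int = 0,
    balance: bool = True,
) -> TrainedModel:
    """Standardise (training statistics), optionally SMOTE-balance, and fit
    one model family. SVM probabilities come from Platt-style calibration."""
    p = params or ClassifyParams()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for training")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    if balance:
        Z, y = smote_balance(Z, y, seed=seed, k=p.smote_k)
    est = _make_estimator(family, p, seed)
    est.fit(Z, y)
    return TrainedModel(family=family, estimator=est, mean=mean, std=std)


# ---------------------------------------------------------------- evaluation


def empirical_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney empirical ROC AUC (label 1 = positive), unfolded."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    n_reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Stratified bootstrap percentile CI for the empirical AUC."""
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    aucs = np.empty(n_reps)
    for i in range(n_reps):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        aucs[i] = empirical_auc(scores[idx], labels[idx])
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class CVEntry:
    family: str
    mean_auc: float
    se_auc: float
    fold_aucs: list[float]


@dataclass
class CVReport:
    entries: dict[str, CVEntry] = field(default_factory=dict)
    seed: int = 0

    def ranking(self) -> list[str]:
        return sorted(self.entries, key=lambda f: -self.entries[f].mean_auc)


def crossval_auc(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 17,
    params: ClassifyParams | None = None,
) -> CVEntry:
    """Stratified k-fold CV AUC; standardisation and SMOTE are fitted inside
    each training fold only, so no test-fold information leaks into the fit."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    for train_idx, test_idx in skf.split(X, y):
        model = train_family(family, X[train_idx], y[train_idx], params, seed=seed)
        scores = model.predict_proba(X[test_idx])
        fold_aucs.append(empirical_auc(scores, y[test_idx]))
    fold_aucs = [float(a) for a in fold_aucs]
    mean = float(np.mean(fold_aucs))
    se = float(np.std(fold_aucs, ddof=1) / np.sqrt(k))
    return CVEntry(family=family, mean_auc=mean, se_auc=se, fold_aucs=fold_aucs)


def soft_vote(ensemble: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Mean of member SR-probabilities."""
    return ensemble.predict_proba(X)


def operating_point(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold minimising (1-sensitivity)^2 + (1-specificity)^2 over all
    candidate thresholds from held-out scores; ties go to the lower (more
    sensitive) threshold."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    candidates = np.unique(scores)
    best_t, best_val = None, np.inf
    for t in candidates:  # ascending: first minimum is the lowest threshold
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
    return float(best_t)


# ---------------------------------------------------------------- pipeline


@dataclass
class DayModel:
    day: int
    ensemble: EnsembleModel
    cv_report: CVReport
    top_families: tuple[str, str]
    threshold: float


def train_day_model(
    X: np.ndarray,
    y: np.ndarray,
    day: int,
    params: ClassifyParams | None = None,
    seed: int | None = None,
) -> DayModel:
    """CV the five families on one acquisition day's cells, fuse the top two
    by soft voting, refit on all of the day's training data, and store the
    operating point chosen on out-of-fold ensemble scores."""
    p = params or ClassifyParams()
    seed = p.cv_seed if seed is None else seed
    y = np.asarray(y)
    counts = np.bincount(y)
    if counts.min() < 10:
        warnings.warn(
            f"day {day}: fewer than 10 cells in a class ({counts.tolist()})",
            stacklevel=2,
        )
    report = CVReport(seed=seed)
    for family in FAMILIES:
        report.entries[family] = crossval_auc(family, X, y, k=p.cv_folds, seed=seed, params=p)
    top = tuple(report.ranking()[:2])
    members = tuple(train_family(f, X, y, p, seed=seed) for f in top)
    ensemble = EnsembleModel(members=members)
    # out-of-fold ensemble scores for the operating point
    skf = StratifiedKFold(n_splits=p.cv_folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        fold_members = tuple(
            train_family(f, X[train_idx], y[train_idx], p, seed=seed) for f in top
        )
        oof[test_idx] = EnsembleModel(members=fold_members).predict_proba(X[test_idx])
    threshold = operating_point(oof, y)
    return DayModel(day=day, ensemble=ensemble, cv_report=report, top_families=top, threshold=threshold)


def train_pipeline(
    X_by_day: dict[int, np.ndarray],
    y_by_day: dict[int, np.ndarray],
    params: ClassifyParams | None = None,
    seed: int | None = None,
) -> dict[int, DayModel]:
    """Day-specific ensembles: cells imaged on the same culture day share a
    model, since morphology distributions drift as the culture grows."""
    return {
        day: train_day_model(X_by_day[day], y_by_day[day], day, params, seed)
        for day in sorted(X_by_day)
    }
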
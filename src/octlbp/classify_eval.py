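"""Classifiers and leave-one-patient-out (LOPO) evaluation.

Volumes are classified normal vs. DME (DME is the positive class) with one
of five families: 3-NN, logistic regression, random forest and gradient
boosting with 100 unpruned trees, or an RBF-kernel SVM whose ``(C, gamma)``
are chosen by grid search with inner stratified cross-validation on the
training fold only.

The cohort is balanced with one volume per patient.  Each LOPO fold holds
out one DME-normal patient pair for testing and trains on all remaining
volumes; fold predictions are pooled into a single confusion matrix from
which sensitivity, specificity, accuracy and F1 are computed:

    SE  = TP / (TP + FN)          SP  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    F1  = 2 TP / (2 TP + FP + FN)

When the representation is a bag of words, the codebook is rebuilt inside
every training fold so no information from the held-out pair leaks into
the visual dictionary.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .represent import (
    Codebook,
    ElementHistogramSet,
    build_codebook,
    encode_bow,
    lowlevel_descriptor,
)

__all__ = [
    "ClassifierSpec",
    "RepresentationSpec",
    "VolumeFeatures",
    "ConfusionCounts",
    "EvalReport",
    "Fold",
    "lopo_splits",
    "make_classifier",
    "train_classifier",
    "metrics_from_counts",
    "evaluate",
]

POSITIVE = "DME"
NEGATIVE = "normal"

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** np.arange(-15, 4, 2))


@dataclass
class ClassifierSpec:
    """Which classifier family to train and its hyper-parameters."""

    family: str = "svm_rbf"  # knn | logistic | random_forest | gradient_boosting | svm_rbf
    knn_k: int = 3
    n_trees: int = 100
    svm_C_grid: tuple[float, ...] = DEFAULT_C_GRID
    svm_gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        families = ("knn", "logistic", "random_forest", "gradient_boosting", "svm_rbf")
        if self.family not in families:
            raise ValueError(f"family must be one of {families}")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be an odd positive integer")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not self.svm_C_grid or not self.svm_gamma_grid:
            raise ValueError("SVM grids must be non-empty")


@dataclass
class RepresentationSpec:
    """How per-volume element histograms become the classifier input.

    ``kind="histogram"`` concatenates global-mapping histograms (low-level);
    ``kind="bow"`` quantizes elements against a k-word codebook learned on
    the training fold.  ``max_train_elements`` caps the number of element
    histograms fed to codebook construction (a seeded uniform subsample);
    with tens of thousands of local patches per volume the cap keeps k-means
    tractable without biasing the dictionary.
    """

    kind: str = "bow"  # "histogram" | "bow"
    k: int = 70
    build: str = "kmeans"
    normalize: bool = True
    max_train_elements: int = 100_000

    def __post_init__(self) -> None:
        if self.kind not in ("histogram", "bow"):
            raise ValueError("kind must be 'histogram' or 'bow'")


@dataclass
class VolumeFeatures:
    """Element histograms of one patient's volume, ready for evaluation."""

    patient_id: str
    label: str
    elements: ElementHistogramSet


@dataclass
class Fold:
    test_ids: tuple[str, str]
    train_ids: tuple[str, ...]


@dataclass
class ConfusionCounts:
    """Pooled 2x2 confusion matrix; DME is the positive class."""

    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def add(self, true_label: str, pred_label: str) -> None:
        if true_label == POSITIVE:
            if pred_label == POSITIVE:
                self.TP += 1
            else:
                self.FN += 1
        else:
            if pred_label == POSITIVE:
                self.FP += 1
            else:
                self.TN += 1


@dataclass
class Metrics:
    se: float
    sp: float
    acc: float
    f1: float
    undefined: tuple[str, ...] = ()


@dataclass
class EvalReport:
    per_fold: list[dict]
    pooled: ConfusionCounts
    metrics: Metrics
    config_fingerprint: str


def lopo_splits(
    patient_labels: dict[str, str], seed: int = 0
) -> list[Fold]:
    """Build the leave-one-patient-pair-out folds.

    Each DME patient is paired with one normal patient by a seeded shuffle;
    every fold tests one pair and trains on all other patients.  Requires a
    balanced cohort (equal DME and normal counts) with at least two pairs,
    so no training fold is empty.
    """
    pos = sorted(p for p, lab in patient_labels.items() if lab == POSITIVE)
    neg = sorted(p for p, lab in patient_labels.items() if lab == NEGATIVE)
    if len(pos) != len(neg):
        raise ValueError(
            f"LOPO pairing needs a balanced cohort; got {len(pos)} DME "
            f"and {len(neg)} normal"
        )
    if len(pos) < 2:
        raise ValueError("need at least 2 patient pairs (training fold empty)")
    rng = np.random.default_rng(seed)
    pos = list(np.array(pos)[rng.permutation(len(pos))])
    neg = list(np.array(neg)[rng.permutation(len(neg))])
    all_ids = set(patient_labels)
    folds = []
    for p, n in zip(pos, neg):
        train = tuple(sorted(all_ids - {p, n}))
        folds.append(Fold(test_ids=(p, n), train_ids=train))
    return folds


def make_classifier(spec: ClassifierSpec):
    """Instantiate the (unfitted) scikit-learn estimator for a spec."""
    if spec.family == "knn":
        return KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    if spec.family == "logistic":
        return LogisticRegression(max_iter=2000, random_state=spec.seed)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, random_state=spec.seed
        )
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=spec.n_trees, learning_rate=0.1, max_depth=None,
            random_state=spec.seed,
        )
    # svm_rbf: nested (C, gamma) grid search on the training fold only.
    inner = StratifiedKFold(
        n_splits=spec.inner_cv_folds, shuffle=True, random_state=spec.seed
    )
    return GridSearchCV(
        SVC(kernel="rbf", random_state=spec.seed),
        {"C": list(spec.svm_C_grid), "gamma": list(spec.svm_gamma_grid)},
        cv=inner,
        n_jobs=1,
    )


def train_classifier(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Fit one classifier on a training fold.

    ``y`` holds string labels ("DME"/"normal"). Raises on a single-class
    training set or non-finite descriptors.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptors must be finite")
    clf = make_classifier(spec)
    clf.fit(X, y)
    return clf


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    """Exact rational evaluation of SE, SP, ACC and F1 from pooled counts.

    Degenerate denominators: SE (resp. SP) is NaN with an ``undefined``
    flag when there are no positive (resp. negative) ground-truth volumes;
    F1 is 0 and flagged when ``2 TP + FP + FN = 0``.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    undefined: list[str] = []

    def frac(num: int, den: int) -> float:
        return float(Fraction(num, den))

    if c.TP + c.FN > 0:
        se = frac(c.TP, c.TP + c.FN)
    else:
        se = float("nan")
        undefined.append("SE")
        warnings.warn("SE undefined: no positive ground-truth samples", stacklevel=2)
    if c.TN + c.FP > 0:
        sp = frac(c.TN, c.TN + c.FP)
    else:
        sp = float("nan")
        undefined.append("SP")
        warnings.warn("SP undefined: no negative ground-truth samples", stacklevel=2)
    acc = frac(c.TP + c.TN, c.total)
    if 2 * c.TP + c.FP + c.FN > 0:
        f1 = frac(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    else:
        f1 = 0.0
        undefined.append("F1")
    return Metrics(se=se, sp=sp, acc=acc, f1=f1, undefined=tuple(undefined))


def _fold_descriptors(
    feats: dict[str, VolumeFeatures],
    fold: Fold,
    rep: RepresentationSpec,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, Codebook | None]:
    """Build (X_train, y_train, X_test) for one fold, fitting any codebook
    on the training volumes only."""
    train = [feats[p] for p in fold.train_ids]
    test = [feats[p] for p in fold.test_ids]
    if rep.kind == "histogram":
        Xtr = np.stack(
            [lowlevel_descriptor(f.elements, normalize=rep.normalize) for f in train]
        )
        Xte = np.stack(
            [lowlevel_descriptor(f.elements, normalize=rep.normalize) for f in test]
        )
        cb = None
    else:
        pool = np.concatenate([f.elements.histograms for f in train])
        if pool.shape[0] > rep.max_train_elements:
            rng = np.random.default_rng(seed)
            idx = rng.choice(pool.shape[0], size=rep.max_train_elements, replace=False)
            pool = pool[idx]
        cb = build_codebook(pool, k=rep.k, build=rep.build, seed=seed)
        Xtr = np.stack(
            [encode_bow(f.elements, cb, normalize=rep.normalize) for f in train]
        )
        Xte = np.stack(
            [encode_bow(f.elements, cb, normalize=rep.normalize) for f in test]
        )
    ytr = np.array([f.label for f in train])
    return Xtr, ytr, Xte, cb


def evaluate(
    volumes: list[VolumeFeatures],
    clf_spec: ClassifierSpec,
    rep_spec: RepresentationSpec | None = None,
    seed: int = 0,
) -> EvalReport:
    """Full LOPO evaluation of a labeled, featurized cohort.

    For each fold: build descriptors (codebook from training volumes only
    when ``rep_spec.kind == "bow"``), fit the classifier on the training
    fold, predict the held-out DME-normal pair.  Predictions are pooled
    over folds into one confusion matrix.
    """
    rep_spec = rep_spec or RepresentationSpec()
    feats = {f.patient_id: f for f in volumes}
    if len(feats) != len(volumes):
        raise ValueError("duplicate patient ids (one volume per patient)")
    labels = {f.patient_id: f.label for f in volumes}
    folds = lopo_splits(labels, seed=seed)
    pooled = ConfusionCounts()
    per_fold: list[dict] = []
    for i, fold in enumerate(folds):
        fold_seed = (seed * 1_000_003 + i) % (2**31 - 1)
        Xtr, ytr, Xte, _ = _fold_descriptors(feats, fold, rep_spec, fold_seed)
        clf = train_classifier(Xtr, ytr, clf_spec)
        pred = clf.predict(Xte)
        truth = [feats[p].label for p in fold.test_ids]
        for t, p in zip(truth, pred):
            pooled.add(t, str(p))
        per_fold.append(
            {
                "fold": i,
                "test_ids": list(fold.test_ids),
                "true": list(truth),
                "pred": [str(p) for p in pred],
            }
        )
    metrics = metrics_from_counts(pooled)
    fp = config_fingerprint(
        {
            "classifier": vars(clf_spec).copy(),
            "representation": vars(rep_spec).copy(),
            "seed": seed,
            "n_volumes": len(volumes),
        }
    )
    return EvalReport(
        per_fold=per_fold, pooled=pooled, metrics=metrics, config_fingerprint=fp
    )


def config_fingerprint(config: dict) -> str:
    """Short stable hash identifying a full pipeline configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
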
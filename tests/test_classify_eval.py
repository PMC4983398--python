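import math
from fractions import Fraction

import numpy as np
import pytest

import octlbp as ol
from octlbp.classify_eval import (
    ConfusionCounts,
    Fold,
    _fold_descriptors,
    make_classifier,
)
from octlbp.represent import ElementHistogramSet, MappingSpec


def _labels(n_pos: int, n_neg: int) -> dict[str, str]:
    return {f"d{i:02d}": "DME" for i in range(n_pos)} | {
        f"n{i:02d}": "normal" for i in range(n_neg)
    }


def _fake_features(n_per_class=4, L=10, shift=3.0, seed=0, n_elements=12):
    """Synthetic cohorts: per-class element histograms whose *shapes* differ
    — each class concentrates mass on its own bin, `shift` setting how far
    apart the class means are relative to the within-class noise."""
    rng = np.random.default_rng(seed)
    feats = []
    for label, pid_prefix, peak in (("DME", "d", 0), ("normal", "n", 1)):
        for i in range(n_per_class):
            h = np.abs(rng.normal(5.0, 1.0, size=(n_elements, L)))
            h[:, peak] += 5.0 * shift
            el = ElementHistogramSet(h, "lbp", MappingSpec("global"), L)
            feats.append(
                ol.VolumeFeatures(f"{pid_prefix}{i:02d}", label, el)
            )
    return feats


# ---------------------------------------------------------------- LOPO ----


def test_lopo_16_plus_16_gives_16_pair_folds():
    folds = ol.lopo_splits(_labels(16, 16), seed=0)
    assert len(folds) == 16
    for f in folds:
        assert len(f.test_ids) == 2
        assert len(f.train_ids) == 30


def test_lopo_folds_partition_the_cohort():
    labels = _labels(5, 5)
    folds = ol.lopo_splits(labels, seed=3)
    tested = [p for f in folds for p in f.test_ids]
    assert sorted(tested) == sorted(labels)
    for f in folds:
        pair_labels = {labels[p] for p in f.test_ids}
        assert pair_labels == {"DME", "normal"}
        assert set(f.test_ids).isdisjoint(f.train_ids)


def test_lopo_rejects_unbalanced_or_degenerate_cohorts():
    with pytest.raises(ValueError, match="balanced"):
        ol.lopo_splits(_labels(3, 5), seed=0)
    with pytest.raises(ValueError, match="pairs"):
        ol.lopo_splits(_labels(1, 1), seed=0)


# --------------------------------------------------------------- metrics ----


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((13, 0, 0, 3), {"se": 0.8125}),
        ((16, 16, 0, 0), {"se": 1.0, "sp": 1.0, "acc": 1.0, "f1": 1.0}),
        ((12, 12, 4, 4), {"se": 0.75, "sp": 0.75, "acc": 0.75, "f1": 0.75}),
        ((13, 15, 1, 3), {"se": 0.8125, "sp": 0.9375}),
    ],
)
@pytest.mark.filterwarnings("ignore:SP undefined")
def test_metric_worked_examples(counts, expected):
    tp, tn, fp, fn = counts
    m = ol.metrics_from_counts(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
    for name, val in expected.items():
        assert getattr(m, name) == pytest.approx(val)


def test_f1_zero_denominator_convention():
    with pytest.warns(UserWarning, match="SE undefined"):
        m = ol.metrics_from_counts(ConfusionCounts(TP=0, TN=4, FP=0, FN=0))
    assert m.f1 == 0.0 and "F1" in m.undefined
    assert math.isnan(m.se) and "SE" in m.undefined


def test_sp_undefined_flagged():
    with pytest.warns(UserWarning, match="SP undefined"):
        m = ol.metrics_from_counts(ConfusionCounts(TP=3, TN=0, FP=0, FN=1))
    assert math.isnan(m.sp)
    assert m.se == 0.75


def test_metrics_reject_empty_counts():
    with pytest.raises(ValueError):
        ol.metrics_from_counts(ConfusionCounts())


def test_accuracy_between_se_and_sp_for_balanced_counts():
    m = ol.metrics_from_counts(ConfusionCounts(TP=10, TN=14, FP=2, FN=6))
    assert min(m.se, m.sp) <= m.acc <= max(m.se, m.sp)


# ----------------------------------------------------------- classifiers ----


def test_knn_predicts_duplicated_training_point():
    # the duplicate's class holds the 3-neighbour majority around it
    X = np.array([[5.0, 5.0], [4.9, 5.0], [0.0, 0.0]])
    y = np.array(["DME", "DME", "normal"])
    clf = ol.train_classifier(X, y, ol.ClassifierSpec(family="knn"))
    assert clf.predict([[5.0, 5.0]])[0] == "DME"


def test_logistic_separates_linearly_separable_blobs():
    rng = np.random.default_rng(0)
    X = np.concatenate(
        [rng.normal(0, 0.2, (20, 4)), rng.normal(4, 0.2, (20, 4))]
    )
    y = np.array(["normal"] * 20 + ["DME"] * 20)
    clf = ol.train_classifier(X, y, ol.ClassifierSpec(family="logistic"))
    assert (clf.predict(X) == y).all()


def test_random_forest_deterministic_under_seed():
    rng = np.random.default_rng(1)
    X, y = rng.random((30, 5)), np.array(["DME", "normal"] * 15)
    spec = ol.ClassifierSpec(family="random_forest", seed=7)
    p1 = ol.train_classifier(X, y, spec).predict(X)
    p2 = ol.train_classifier(X, y, spec).predict(X)
    assert np.array_equal(p1, p2)


def test_single_class_training_set_raises():
    with pytest.raises(ValueError, match="single class"):
        ol.train_classifier(
            np.zeros((4, 2)), np.array(["DME"] * 4), ol.ClassifierSpec()
        )


def test_svm_spec_builds_grid_search():
    gs = make_classifier(ol.ClassifierSpec(family="svm_rbf"))
    assert len(gs.param_grid["C"]) == 11
    assert len(gs.param_grid["gamma"]) == 10


def test_classifier_spec_validation():
    with pytest.raises(ValueError):
        ol.ClassifierSpec(family="perceptron")
    with pytest.raises(ValueError):
        ol.ClassifierSpec(knn_k=4)


# ------------------------------------------------------------- evaluate ----


def test_evaluate_separable_cohort_is_perfect_and_deterministic():
    feats = _fake_features(n_per_class=4, shift=4.0)
    spec = ol.ClassifierSpec(family="logistic", seed=0)
    rep = ol.RepresentationSpec(kind="histogram", normalize=True)
    r1 = ol.evaluate(feats, spec, rep, seed=5)
    r2 = ol.evaluate(feats, spec, rep, seed=5)
    assert r1.metrics.acc == 1.0 and r1.metrics.f1 == 1.0
    assert [f["pred"] for f in r1.per_fold] == [f["pred"] for f in r2.per_fold]
    assert r1.config_fingerprint == r2.config_fingerprint
    assert r1.pooled.total == 8


def test_evaluate_bow_path_runs_with_fold_local_codebooks():
    feats = _fake_features(n_per_class=3, shift=4.0, n_elements=30)
    rep = ol.RepresentationSpec(kind="bow", k=4, normalize=True)
    report = ol.evaluate(
        feats, ol.ClassifierSpec(family="knn"), rep, seed=1
    )
    assert report.pooled.total == 6
    assert report.metrics.acc >= 0.5


def test_no_leakage_test_volumes_never_shape_training_descriptors():
    """Altering the held-out pair's element histograms must leave the
    training matrix and the fitted codebook untouched."""
    feats = _fake_features(n_per_class=3, shift=2.0, n_elements=20)
    by_id = {f.patient_id: f for f in feats}
    fold = Fold(
        test_ids=("d00", "n00"),
        train_ids=tuple(sorted(set(by_id) - {"d00", "n00"})),
    )
    rep = ol.RepresentationSpec(kind="bow", k=3)
    Xtr1, ytr1, _, cb1 = _fold_descriptors(by_id, fold, rep, seed=2)
    for pid in fold.test_ids:
        by_id[pid].elements.histograms = by_id[pid].elements.histograms * 100
    Xtr2, ytr2, _, cb2 = _fold_descriptors(by_id, fold, rep, seed=2)
    assert np.array_equal(Xtr1, Xtr2)
    assert np.array_equal(ytr1, ytr2)
    assert np.array_equal(cb1.words, cb2.words)


def test_duplicate_patient_ids_rejected():
    feats = _fake_features(n_per_class=2)
    feats.append(feats[0])
    with pytest.raises(ValueError, match="duplicate"):
        ol.evaluate(feats, ol.ClassifierSpec(family="knn"))


def test_metrics_recomputable_from_pooled_counts():
    feats = _fake_features(n_per_class=3, shift=1.0)
    report = ol.evaluate(
        feats,
        ol.ClassifierSpec(family="knn"),
        ol.RepresentationSpec(kind="histogram"),
        seed=0,
    )
    c = report.pooled
    assert report.metrics.se == pytest.approx(
        float(Fraction(c.TP, c.TP + c.FN))
    )
    assert report.metrics.acc == pytest.approx(
        float(Fraction(c.TP + c.TN, c.total))
    )
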
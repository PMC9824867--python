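"""Cross-validation folds and the confusion-matrix metric suite."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stagescreen as ss
from stagescreen.evaluation import CLASS_NAMES, ConfusionMatrix3
from .conftest import make_sessions

#: The published 3-class screening outcome (rows true, columns predicted):
#: every normal and ADHD child correct; 11 of 181 at-risk children split
#: 6 to normal and 5 to ADHD.
PUBLISHED_CM = ConfusionMatrix3(
    np.array([[349, 0, 0], [6, 170, 5], [0, 0, 66]])
)


# -- fold construction -------------------------------------------------------

def test_lopo_folds_each_subject_out_once():
    sessions = make_sessions(n_per_class=1)
    folds = ss.lopo_split(sessions)
    assert len(folds) == 3
    assert all(len(train) == 2 for train, _ in folds)
    held = {held.subject_id for _, held in folds}
    assert held == {s.subject_id for s in sessions}


def test_lopo_folds_are_disjoint_exhaustively():
    sessions = make_sessions(n_per_class=2) + make_sessions(
        n_per_class=2, seed=99
    )
    for i, s in enumerate(sessions):  # ensure unique ids across the two draws
        object.__setattr__(s, "subject_id", f"{s.subject_id}-{i}")
    folds = ss.lopo_split(sessions)
    assert len(folds) == len(sessions)
    for train, held in folds:
        train_ids = {t.subject_id for t in train}
        assert held.subject_id not in train_ids
        assert len(train_ids) == len(sessions) - 1


def test_lopo_requires_two_subjects():
    with pytest.raises(ValueError):
        ss.lopo_split(make_sessions(n_per_class=1)[:1])


# -- metric suite ------------------------------------------------------------

def test_published_confusion_reproduces_reported_metrics():
    """The published per-class table and the 98.15% overall accuracy follow
    from the confusion counts; three cells were printed truncated rather
    than rounded and are checked to one unit in the last printed digit."""
    report = ss.metrics_from_confusion(PUBLISHED_CM)
    assert report.overall_accuracy == pytest.approx(98.15, abs=0.005)

    normal = report.per_class["NORMAL"]
    assert round(normal.acc, 2) == 98.99
    assert normal.se == 100.0
    assert round(normal.sp, 2) == 97.57
    assert abs(normal.f1 - 99.14) <= 0.01  # truncated in print (exact 99.147)
    assert round(normal.fpr, 3) == 0.024
    assert abs(normal.fdr - 0.016) <= 0.001  # truncated (exact 0.0169)
    assert normal.fnr == 0.0

    risk = report.per_class["ADHD_RISK"]
    assert round(risk.acc, 2) == 98.15
    assert round(risk.se, 2) == 93.92
    assert risk.sp == 100.0
    assert abs(risk.f1 - 96.86) <= 0.01  # truncated (exact 96.866)
    assert risk.fpr == 0.0
    assert risk.fdr == 0.0
    assert round(risk.fnr, 2) == 0.06

    adhd = report.per_class["ADHD"]
    assert round(adhd.acc, 2) == 99.16
    assert adhd.se == 100.0
    assert round(adhd.sp, 2) == 99.06
    assert round(adhd.f1, 2) == 96.35
    assert round(adhd.fpr, 3) == 0.009
    assert round(adhd.fdr, 2) == 0.07
    assert adhd.fnr == 0.0


def test_perfect_classifier_metrics():
    report = ss.metrics_from_confusion(ConfusionMatrix3(np.diag([10, 10, 10])))
    assert report.overall_accuracy == 100.0
    for m in report.per_class.values():
        assert (m.se, m.sp, m.acc, m.f1) == (100.0, 100.0, 100.0, 100.0)
        assert (m.fpr, m.fdr, m.fnr) == (0.0, 0.0, 0.0)


def test_hand_worked_confusion_example():
    cm = ConfusionMatrix3(np.array([[2, 1, 0], [0, 3, 0], [1, 0, 2]]))
    normal = ss.metrics_from_confusion(cm).per_class["NORMAL"]
    # by hand: TP=2, FN=1, FP=1, TN=5
    assert normal.se == pytest.approx(100 * 2 / 3, abs=1e-9)
    assert normal.sp == pytest.approx(100 * 5 / 6, abs=1e-9)
    assert normal.f1 == pytest.approx(100 * 4 / 6, abs=1e-9)


def test_degenerate_flag_on_zero_denominator():
    # no predictions at all in class 3 -> FDR denominator 0
    cm = ConfusionMatrix3(np.array([[5, 0, 0], [0, 5, 0], [5, 0, 0]]))
    metrics = ss.metrics_from_confusion(cm).per_class["ADHD"]
    assert metrics.fdr == 0.0
    assert metrics.degenerate


def test_empty_confusion_rejected():
    with pytest.raises(ValueError):
        ss.metrics_from_confusion(ConfusionMatrix3(np.zeros((3, 3), int)))


def _brute_force_metrics(counts):
    """Independent oracle: expand the matrix into (true, pred) pairs and
    count one-vs-rest outcomes by explicit iteration."""
    pairs = []
    for t in range(3):
        for p in range(3):
            pairs.extend([(t, p)] * int(counts[t, p]))
    out = {}
    for k, name in enumerate(CLASS_NAMES):
        tp = sum(1 for t, p in pairs if t == k and p == k)
        fp = sum(1 for t, p in pairs if t != k and p == k)
        fn = sum(1 for t, p in pairs if t == k and p != k)
        tn = sum(1 for t, p in pairs if t != k and p != k)
        div = lambda a, b: a / b if b else 0.0
        out[name] = dict(
            acc=100 * div(tp + tn, len(pairs)),
            se=100 * div(tp, tp + fn),
            sp=100 * div(tn, tn + fp),
            f1=100 * div(2 * tp, 2 * tp + fp + fn),
            fpr=div(fp, fp + tn),
            fdr=div(fp, fp + tp),
            fnr=div(fn, fn + tp),
        )
    overall = 100 * sum(1 for t, p in pairs if t == p) / len(pairs)
    return out, overall


def test_metrics_agree_with_brute_force_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(100):
        counts = rng.integers(0, 30, size=(3, 3))
        if counts.sum() == 0:
            counts[0, 0] = 1
        cm = ConfusionMatrix3(counts)
        report = ss.metrics_from_confusion(cm)
        expected, overall = _brute_force_metrics(counts)
        assert report.overall_accuracy == pytest.approx(overall, abs=1e-9)
        for name in CLASS_NAMES:
            got = report.per_class[name]
            for key, val in expected[name].items():
                assert getattr(got, key) == pytest.approx(val, abs=1e-9), (
                    name, key, counts,
                )


def test_metrics_agree_with_sklearn_on_random_instances():
    from sklearn.metrics import f1_score, recall_score

    rng = np.random.default_rng(7)
    for _ in range(20):
        counts = rng.integers(1, 20, size=(3, 3))
        cm = ConfusionMatrix3(counts)
        y_true, y_pred = [], []
        for t in range(3):
            for p in range(3):
                y_true.extend([t] * counts[t, p])
                y_pred.extend([p] * counts[t, p])
        report = ss.metrics_from_confusion(cm)
        se = recall_score(y_true, y_pred, average=None, zero_division=0)
        f1 = f1_score(y_true, y_pred, average=None, zero_division=0)
        for k, name in enumerate(CLASS_NAMES):
            assert report.per_class[name].se == pytest.approx(
                100 * se[k], abs=1e-9
            )
            assert report.per_class[name].f1 == pytest.approx(
                100 * f1[k], abs=1e-9
            )


@settings(max_examples=50, deadline=None)
@given(
    counts=st.lists(
        st.integers(min_value=0, max_value=50), min_size=9, max_size=9
    ).filter(lambda c: sum(c) > 0)
)
def test_metric_identities_hold_prerounding(counts):
    cm = ConfusionMatrix3(np.array(counts).reshape(3, 3))
    report = ss.metrics_from_confusion(cm)
    for name in CLASS_NAMES:
        m = report.per_class[name]
        if not m.degenerate:
            assert m.se + 100 * m.fnr == pytest.approx(100.0, abs=1e-9)
            assert m.sp / 100 + m.fpr == pytest.approx(1.0, abs=1e-9)
    # trace identities
    tps = [cm.one_vs_rest(k)[0] for k in range(3)]
    assert sum(tps) == np.trace(cm.counts)
    assert sum(
        cm.one_vs_rest(k)[0] + cm.one_vs_rest(k)[2] for k in range(3)
    ) == cm.total


# -- end-to-end cross-validation ---------------------------------------------

def test_run_lopo_counts_and_determinism(tiny_sessions, tiny_config):
    res1 = ss.run_lopo(tiny_sessions, tiny_config)
    assert res1.confusion.total == 6
    assert len(res1.predictions) == 6
    assert len(res1.profiles) == 6
    res2 = ss.run_lopo(tiny_sessions, tiny_config)
    np.testing.assert_array_equal(res1.confusion.counts, res2.confusion.counts)
    for sid in res1.predictions:
        np.testing.assert_array_equal(
            res1.predictions[sid].probabilities,
            res2.predictions[sid].probabilities,
        )


def test_run_lopo_overall_accuracy_is_trace_over_total(
    tiny_sessions, tiny_config
):
    res = ss.run_lopo(tiny_sessions, tiny_config)
    expected = 100 * np.trace(res.confusion.counts) / res.confusion.total
    assert res.overall_accuracy == pytest.approx(expected)
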
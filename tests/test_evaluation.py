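"""Confusion-matrix panel, ROC/AUC, repeatability, size dimorphism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crownmorph as cm
from crownmorph.errors import InvalidInputError, PairingError
from crownmorph.procrustes import AlignedSample


class TestClassificationReport:
    def test_reference_worked_example(self):
        """A 56-scan test sample (31 F / 25 M) with 29 true and 8 false
        female calls reproduces the published panel at printed precision."""
        rep = cm.classification_report(cm.ConfusionMatrix(tp=29, fp=8, fn=2, tn=17))
        assert round(rep.accuracy, 4) == 0.8214
        assert round(rep.sensitivity, 4) == 0.9355
        assert round(rep.specificity, 4) == 0.6800
        assert round(rep.ppv, 4) == 0.7838
        assert round(rep.npv, 4) == 0.8947
        assert round(rep.nir, 4) == 0.5536
        assert round(rep.prevalence, 4) == 0.5536
        assert round(rep.kappa, 4) == 0.6301
        assert round(rep.detection_rate, 4) == 0.5179
        assert round(rep.detection_prevalence, 4) == 0.6607
        assert round(rep.balanced_accuracy, 4) == 0.8077
        assert round(rep.accuracy_ci[0], 3) == 0.696
        assert round(rep.accuracy_ci[1], 4) == 0.9109
        assert rep.p_acc_gt_nir == pytest.approx(2.302e-5, rel=5e-4)
        assert round(rep.p_mcnemar, 4) == 0.1138

    def test_perfect_classifier(self):
        rep = cm.classification_report(cm.ConfusionMatrix(tp=10, fp=0, fn=0, tn=20))
        for v in (rep.accuracy, rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert v == 1.0
        assert rep.kappa == 1.0

    def test_all_positive_predictor(self):
        rep = cm.classification_report(cm.ConfusionMatrix(tp=12, fp=18, fn=0, tn=0))
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0
        assert rep.detection_prevalence == 1.0
        assert math.isnan(rep.npv)  # undefined ratios are NaN, never 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            cm.ConfusionMatrix(tp=0, fp=0, fn=0, tn=0)

    def test_from_predictions(self):
        ref = ["F", "F", "M", "M", "F"]
        pred = ["F", "M", "M", "F", "F"]
        mat = cm.ConfusionMatrix.from_predictions(ref, pred)
        assert (mat.tp, mat.fp, mat.fn, mat.tn) == (2, 1, 1, 1)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
def test_report_identities(tp, fp, fn, tn):
    """Balanced accuracy, the accuracy decomposition and kappa <= accuracy
    hold for every non-empty confusion matrix."""
    if tp + fp + fn + tn == 0:
        return
    rep = cm.classification_report(cm.ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
    if not (math.isnan(rep.sensitivity) or math.isnan(rep.specificity)):
        assert rep.balanced_accuracy == pytest.approx((rep.sensitivity + rep.specificity) / 2)
        acc = rep.prevalence * rep.sensitivity + (1 - rep.prevalence) * rep.specificity
        assert rep.accuracy == pytest.approx(acc)
    if not math.isnan(rep.kappa):
        assert rep.kappa <= rep.accuracy + 1e-12
    assert rep.detection_rate <= rep.detection_prevalence + 1e-12
    assert rep.detection_rate <= rep.prevalence + 1e-12


class TestRoc:
    def test_perfect_and_reversed_separation(self):
        labels = ["F"] * 5 + ["M"] * 5
        good = [0.9, 0.8, 0.85, 0.95, 0.7, 0.1, 0.2, 0.3, 0.15, 0.25]
        assert cm.roc_auc(good, labels).auc == 1.0
        assert cm.roc_auc([1 - s for s in good], labels).auc == 0.0

    def test_auc_equals_pairwise_concordance(self, rng):
        scores = rng.uniform(size=40)
        labels = np.where(rng.uniform(size=40) < 0.45, "F", "M")
        if len(set(labels)) < 2:
            labels[0] = "F"; labels[1] = "M"
        auc = cm.roc_auc(scores, labels).auc
        pos = scores[labels == "F"]
        neg = scores[labels != "F"]
        conc = np.mean((pos[:, None] > neg[None]) + 0.5 * (pos[:, None] == neg[None]))
        assert auc == pytest.approx(conc, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(size=30)
        labels = ["F"] * 15 + ["M"] * 15
        a = cm.roc_auc(scores, labels).auc
        b = cm.roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            cm.roc_auc([0.3, 0.7], ["F", "F"])


def _aligned_from_shapes(shapes, ids, tooth=cm.Tooth.FP):
    shapes = np.asarray(shapes)
    return AlignedSample(
        tooth=tooth,
        specimen_ids=list(ids),
        aligned=shapes,
        mean_shape=shapes.mean(axis=0),
        centroid_sizes=np.ones(len(shapes)),
        iterations_used=1,
        converged=True,
        residual_history=np.array([0.0]),
    )


def _two_rounds(n=20, among=0.05, within=0.005, seed=0, n_pts=20):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n_pts, 3))
    base -= base.mean(axis=0)
    base /= np.linalg.norm(base)
    ids = [f"s{i}" for i in range(n)]
    r1, r2 = [], []
    for _ in ids:
        true = base + among * rng.normal(size=base.shape)
        r1.append(true + within * rng.normal(size=base.shape))
        r2.append(true + within * rng.normal(size=base.shape))
    return _aligned_from_shapes(r1, ids), _aligned_from_shapes(r2, ids)


class TestRepeatability:
    def test_identical_rounds(self):
        r1, _ = _two_rounds(seed=1)
        rep = cm.repeatability(r1, r1)
        assert rep.error_variance_fraction == 0.0
        assert rep.agreement == 1.0

    def test_swapped_identities_destroy_agreement(self):
        r1, r2 = _two_rounds(n=12, among=0.08, within=0.001, seed=2)
        rolled = _aligned_from_shapes(np.roll(r2.aligned, 1, axis=0), r2.specimen_ids)
        rep = cm.repeatability(r1, rolled)
        assert rep.agreement <= 1e-9

    def test_recovers_variance_shares(self):
        # within share = w^2/(w^2+a^2); one replicate sanity check
        r1, r2 = _two_rounds(n=30, among=0.03, within=0.003, seed=3)
        rep = cm.repeatability(r1, r2)
        assert rep.error_variance_fraction == pytest.approx(0.01, abs=0.006)

    def test_unpaired_specimen_rejected(self):
        r1, r2 = _two_rounds(n=5, seed=4)
        r2.specimen_ids[0] = "stranger"
        with pytest.raises(PairingError):
            cm.repeatability(r1, r2)


class TestSizeDimorphism:
    def test_identical_groups_p_one(self):
        sizes = np.concatenate([np.linspace(18, 22, 10)] * 2)
        labels = ["F"] * 10 + ["M"] * 10
        t, p = cm.centroid_size_dimorphism_test(sizes, labels)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_large_shift_is_significant(self, rng):
        f = np.exp(rng.normal(3.0, 0.02, size=50))
        m = np.exp(rng.normal(3.2, 0.02, size=50))  # 10 pooled sd shift in logs
        _, p = cm.centroid_size_dimorphism_test(
            np.concatenate([f, m]), ["F"] * 50 + ["M"] * 50
        )
        assert p < 1e-6

    def test_statistic_antisymmetric_in_labels(self, rng):
        sizes = np.exp(rng.normal(3.0, 0.1, size=30))
        labels = np.array(["F"] * 15 + ["M"] * 15)
        t1, p1 = cm.centroid_size_dimorphism_test(sizes, labels)
        t2, p2 = cm.centroid_size_dimorphism_test(sizes, np.where(labels == "F", "M", "F"))
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_single_sex_rejected(self):
        with pytest.raises(InvalidInputError):
            cm.centroid_size_dimorphism_test([20.0, 21.0], ["F", "F"])
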
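"""Classifier evaluation: metric identities, ROC oracles, CV contracts."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from noduletex.evaluate import (
    ConfusionCounts,
    KernelConfig,
    MetricsReport,
    auc_pvalue,
    compute_metrics,
    cross_validate,
    roc_auc,
    stratified_eval,
    train_rbf_svm,
)
from noduletex.smote import Dataset


def counts_for(sens, spec, n_pos=100, n_neg=100):
    a = round(sens * n_pos)
    c = round(spec * n_neg)
    return ConfusionCounts(a_tp=a, b_fn=n_pos - a, c_tn=c, d_fp=n_neg - c)


class TestComputeMetrics:
    def test_published_size_group_identities(self):
        # row B: sensitivity 0.92, specificity 0.65 -> Youden 0.57;
        # precision 0.84 with sensitivity 0.92 -> F = 0.88 at beta 1
        rep = compute_metrics(counts_for(0.92, 0.65))
        assert rep.youden == pytest.approx(0.57, abs=5e-3)
        f = compute_metrics(ConfusionCounts(a_tp=92, b_fn=8, c_tn=100,
                                            d_fp=round(92 / 0.84) - 92))
        assert f.precision == pytest.approx(0.84, abs=5e-3)
        assert f.f_measure == pytest.approx(0.88, abs=5e-3)
        # row A+B: 0.92 + 0.66 - 1 = 0.58
        rep = compute_metrics(counts_for(0.92, 0.66))
        assert rep.youden == pytest.approx(0.58, abs=5e-3)

    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(50, 0, 50, 0))
        for v in (rep.sensitivity, rep.specificity, rep.accuracy,
                  rep.precision, rep.youden, rep.f_measure):
            assert v == 1.0

    def test_identities_hold_exactly(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(1, 80, size=4)
            rep = compute_metrics(ConfusionCounts(int(a), int(b), int(c), int(d)))
            assert rep.youden == pytest.approx(
                rep.sensitivity + rep.specificity - 1, abs=1e-12)
            assert rep.f_measure == pytest.approx(
                2 * rep.precision * rep.sensitivity
                / (rep.precision + rep.sensitivity), abs=1e-12)

    def test_zero_denominator_is_flagged(self):
        with pytest.raises(ZeroDivisionError):
            compute_metrics(ConfusionCounts(0, 0, 10, 5))


class TestRocAuc:
    def test_trivial_cases(self):
        auc, pts = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert pts[0].tolist() == [0.0, 0.0] and pts[-1].tolist() == [1.0, 1.0]
        auc, _ = roc_auc([0.5] * 10, [1] * 5 + [0] * 5)
        assert auc == pytest.approx(0.5)
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.normal(size=200), 1)  # coarse -> many ties
        labels = rng.integers(0, 2, size=200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        auc, _ = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestAucPvalue:
    def test_null_centre(self):
        assert auc_pvalue(0.5, 100, 50) == pytest.approx(1.0)

    def test_patient_level_flags_match_study_table(self):
        # the study's per-feature AUC flags (P>0.05 at AUC 0.52/0.53) are
        # consistent with patient-level counts
        assert auc_pvalue(0.52, 252, 84) > 0.05
        assert auc_pvalue(0.53, 252, 84) > 0.05
        assert auc_pvalue(0.60, 252, 84) < 0.05

    def test_matches_permutation_oracle(self, rng):
        n = 10
        x = np.concatenate([np.ones(n), np.zeros(n)])  # AUC 1 arrangement
        # exact permutation p for AUC=1: probability that a random labelling
        # gives |U - mu| >= mu, i.e. U in {0, n^2}
        from math import comb
        p_exact = 2 / comb(2 * n, n)
        p_norm = auc_pvalue(1.0, n, n)
        # normal approximation is rough in the far tail; demand the same
        # order of magnitude and correct laterality
        assert p_norm < 0.01
        assert p_exact < 0.01


class TestSvm:
    def test_separable_toy(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [0.2, 0.2],
                      [5, 5], [5, 6], [6, 5], [5.2, 5.2]], dtype=float)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ds = Dataset(X=X, y=y, groups=np.array(["p"] * 8, dtype=object),
                     feature_names=["a", "b"])
        model = train_rbf_svm(ds)
        assert (model.predict(X) == y).all()
        rates = model.malignant_rate(X)
        assert ((rates >= 0) & (rates <= 1)).all()

    def test_no_information_limit(self):
        X = np.ones((12, 3))
        y = np.array([0] * 4 + [1] * 8)
        ds = Dataset(X=X, y=y, groups=np.array(["p"] * 12, dtype=object),
                     feature_names=["a", "b", "c"])
        model = train_rbf_svm(ds)
        assert (model.predict(X) == 1).all()  # majority class

    def test_single_class_rejected(self):
        ds = Dataset(X=np.random.default_rng(0).normal(size=(6, 2)),
                     y=np.ones(6, dtype=int),
                     groups=np.array(["p"] * 6, dtype=object),
                     feature_names=["a", "b"])
        with pytest.raises(ValueError):
            train_rbf_svm(ds)


def _signal_dataset(n=100, d=4, shift=2.0, seed=0, groups_per_class=None):
    rng = np.random.default_rng(seed)
    n2 = n // 2
    X = np.vstack([rng.normal(0, 1, size=(n2, d)),
                   rng.normal(shift, 1, size=(n2, d))])
    y = np.array([0] * n2 + [1] * n2)
    if groups_per_class:
        g = ([f"b{i % groups_per_class}" for i in range(n2)]
             + [f"m{i % groups_per_class}" for i in range(n2)])
    else:
        g = [f"p{i}" for i in range(n)]
    return Dataset(X=X, y=y, groups=np.array(g, dtype=object),
                   feature_names=[f"f{j}" for j in range(d)])


class TestCrossValidate:
    def test_every_sample_predicted_once(self):
        ds = _signal_dataset(100)
        rep = cross_validate(ds, KernelConfig(seed=1), folds=10)
        assert sum(f["n_test"] for f in rep.per_fold) == 100
        assert rep.n == 100
        assert rep.auc > 0.9  # clearly separable toy

    def test_reproducible(self):
        ds = _signal_dataset(80)
        r1 = cross_validate(ds, KernelConfig(seed=3), folds=5)
        r2 = cross_validate(ds, KernelConfig(seed=3), folds=5)
        assert r1.as_dict() == r2.as_dict()

    def test_patient_grouping_keeps_groups_together(self):
        ds = _signal_dataset(96, groups_per_class=8)
        rep = cross_validate(ds, KernelConfig(seed=0), folds=4,
                             grouping="patient")
        assert sum(f["n_test"] for f in rep.per_fold) == 96

    def test_too_many_folds_rejected(self):
        ds = _signal_dataset(20)
        with pytest.raises(ValueError):
            cross_validate(ds, folds=11)


def test_grid_search_returns_valid_config():
    from noduletex.evaluate import grid_search
    ds = _signal_dataset(60)
    cfg, auc = grid_search(ds, gammas=(None, 0.1), costs=(1.0,), folds=3)
    assert cfg.cost == 1.0 and 0 <= auc <= 1


class TestStratifiedEval:
    def test_interval_membership(self):
        # diameters 8 / 15 / 25 mm belong to groups A / B / C; 15 also to A+B
        from noduletex.evaluate import DIAMETER_GROUPS
        for d, grp in ((8, "A"), (15, "B"), (25, "C")):
            lo, hi = DIAMETER_GROUPS[grp]
            assert lo <= round(d) <= hi
        lo, hi = DIAMETER_GROUPS["A+B"]
        assert lo <= 15 <= hi

    def test_single_group_equals_unstratified(self):
        ds = _signal_dataset(60)
        diam = np.full(60, 15.0)
        rep_all = cross_validate(ds, KernelConfig(seed=2), folds=5)
        strat = stratified_eval(ds, diam, KernelConfig(seed=2), folds=5)
        assert set(strat) == {"B", "A+B"}
        assert strat["B"].as_dict() == rep_all.as_dict()

    def test_degenerate_group_absent(self):
        ds = _signal_dataset(60)
        diam = np.concatenate([np.full(57, 15.0), [8.0, 8.0, 8.0]])
        strat = stratified_eval(ds, diam, KernelConfig(seed=2), folds=5)
        assert "A" not in strat  # 3 samples cannot support 5 folds
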
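import numpy as np
import pytest

from pincom.classifier_layer import ClassifierSpec
from pincom.datatypes import PredictionRecord
from pincom.synthetic_data import MixtureConfig, generate, small_config
from pincom.validation_protocols import (
    CVConfig,
    apply_A2,
    cv_level0,
    double_cv,
    estimate_pins_A1,
    estimate_test_pr,
)

FAST_MODELS = [
    ClassifierSpec("gnb", "gnb", random_seed=1),
    ClassifierSpec("lda", "lda", random_seed=2),
]


@pytest.fixture(scope="module")
def small_train():
    return generate(small_config(seed=21, C=4, n_per_class=20, d=5))


class TestCvLevel0:
    def test_size_is_k_times_n(self, small_train):
        cfg = CVConfig(n_folds=5, K=3, seed=0)
        sets = cv_level0(FAST_MODELS, small_train, cfg)
        for cvs in sets.values():
            assert len(cvs.records) == 3 * small_train.n
            assert cvs.probs.shape == (3 * small_train.n, 4)

    def test_single_repeat_covers_each_instance_once(self, small_train):
        cfg = CVConfig(n_folds=5, K=1, seed=1)
        sets = cv_level0(FAST_MODELS, small_train, cfg)
        for cvs in sets.values():
            ids = [r.instance_id for r in cvs.records]
            assert sorted(ids) == sorted(small_train.instance_ids)

    def test_partitions_disjoint_within_each_repeat(self, small_train):
        cfg = CVConfig(n_folds=4, K=3, seed=2)
        sets = cv_level0(FAST_MODELS, small_train, cfg)
        cvs = sets["gnb"]
        for rep in range(3):
            ids = [r.instance_id for r, (k, _) in
                   zip(cvs.records, cvs.provenance) if k == rep]
            assert sorted(ids) == sorted(small_train.instance_ids)

    def test_paired_design_and_determinism(self, small_train):
        cfg = CVConfig(n_folds=5, K=2, seed=3)
        s1 = cv_level0(FAST_MODELS, small_train, cfg)
        s2 = cv_level0(FAST_MODELS, small_train, cfg)
        # identical partitions across models: same instance order
        assert [r.instance_id for r in s1["gnb"].records] == \
            [r.instance_id for r in s1["lda"].records]
        # identical rerun
        np.testing.assert_array_equal(s1["gnb"].probs, s2["gnb"].probs)
        assert [r.maxp for r in s1["lda"].records] == \
            [r.maxp for r in s2["lda"].records]

    def test_true_classes_attached(self, small_train):
        cfg = CVConfig(n_folds=5, K=1, seed=4)
        sets = cv_level0(FAST_MODELS, small_train, cfg)
        truth = dict(zip(small_train.instance_ids, small_train.labels))
        for r in sets["gnb"].records:
            assert r.true_class == truth[r.instance_id]

    def test_tiny_class_rejected(self):
        ds = generate(small_config(seed=5, C=3, n_per_class=4, d=3))
        ds.labels[ds.labels == ds.class_vocab[0]]  # noqa: B018
        sub = ds.subset([0, 4, 5, 6, 7, 8, 9, 10, 11])  # class 0 has 1 left
        with pytest.raises(ValueError, match="fewer than 2"):
            cv_level0(FAST_MODELS, sub, CVConfig(n_folds=2, K=1))


class TestEstimatePinsA1:
    def test_perfect_model_gets_constant_pin_one(self):
        ds = generate(small_config(seed=6, C=3, n_per_class=15, d=4,
                                   sigma=0.01))
        cfg = CVConfig(n_folds=5, K=2, seed=6)
        sets = cv_level0(FAST_MODELS, ds, cfg)
        a1 = estimate_pins_A1(sets, seed=6)
        f = a1.pin_functions["gnb"]
        np.testing.assert_allclose(f.values, 1.0)

    def test_chance_model_pin_near_overall_precision(self):
        # features carry no class signal: every learner is at chance
        rng = np.random.default_rng(7)
        from pincom.datatypes import LabeledDataset
        n, C = 200, 4
        labels = np.array([f"c{i % C}" for i in range(n)], dtype=object)
        ds = LabeledDataset([f"x{i}" for i in range(n)],
                            rng.normal(size=(n, 5)), labels,
                            [f"c{k}" for k in range(C)])
        cfg = CVConfig(n_folds=5, K=2, seed=7)
        sets = cv_level0([ClassifierSpec("gnb", "gnb")], ds, cfg)
        a1 = estimate_pins_A1(sets, seed=7)
        recs = sets["gnb"].records
        overall = np.mean([r.correct for r in recs])
        pins = [r.pin for r in a1.per_model_records["gnb"]]
        assert np.mean(pins) == pytest.approx(overall, abs=0.05)

    def test_identical_models_get_identical_pin_functions(self, small_train):
        models = [
            ClassifierSpec("a", "gnb", random_seed=1),
            ClassifierSpec("b", "gnb", random_seed=1),
        ]
        cfg = CVConfig(n_folds=5, K=2, seed=8)
        a1 = estimate_pins_A1(cv_level0(models, small_train, cfg), seed=8)
        np.testing.assert_array_equal(a1.pin_functions["a"].knots,
                                      a1.pin_functions["b"].knots)
        np.testing.assert_array_equal(a1.pin_functions["a"].values,
                                      a1.pin_functions["b"].values)

    def test_combined_records_have_maxpin(self, small_train):
        cfg = CVConfig(n_folds=5, K=1, seed=9)
        a1 = estimate_pins_A1(cv_level0(FAST_MODELS, small_train, cfg), seed=9)
        per = a1.per_model_records
        for i, c in enumerate(a1.combined):
            pins = [per[m][i].pin for m in per]
            assert c.max_pin == pytest.approx(max(pins))


class TestApplyA2:
    def test_extrapolation_clamps_to_top_knot(self, small_train):
        cfg = CVConfig(n_folds=5, K=1, seed=10)
        a1 = estimate_pins_A1(cv_level0(FAST_MODELS, small_train, cfg), seed=10)
        f = a1.pin_functions["gnb"]
        assert f(1.0) == pytest.approx(f.values[-1])

    def test_test_set_scored_and_combined(self, small_train):
        cfg = CVConfig(n_folds=5, K=1, seed=11)
        a1 = estimate_pins_A1(cv_level0(FAST_MODELS, small_train, cfg), seed=11)
        a2 = apply_A2(FAST_MODELS, small_train, small_train.features[:10],
                      a1.pin_functions, seed=11,
                      test_ids=small_train.instance_ids[:10],
                      pic_functions=a1.pic_functions)
        assert len(a2.combined_records) == 10
        for r in a2.combined_records:
            assert 0.0 <= r.pin <= 1.0
        for mid, recs in a2.per_model_records.items():
            f = a1.pin_functions[mid]
            for r in recs:
                assert r.pin == pytest.approx(f(r.maxp))

    def test_single_model_combined_equals_model(self, small_train):
        cfg = CVConfig(n_folds=5, K=1, seed=12)
        one = [FAST_MODELS[0]]
        a1 = estimate_pins_A1(cv_level0(one, small_train, cfg), seed=12)
        a2 = apply_A2(one, small_train, small_train.features[:5],
                      a1.pin_functions, seed=12)
        assert [r.predicted_class for r in a2.combined_records] == \
            [r.predicted_class for r in a2.per_model_records["gnb"]]


@pytest.fixture(scope="module")
def dcv():
    ds = generate(small_config(seed=13, C=4, n_per_class=15, d=4))
    cfg = CVConfig(n_folds=4, K=2, KK=2, seed=13)
    return ds, cfg, double_cv(FAST_MODELS, ds, cfg)


class TestDoubleCV:
    def test_size_is_kk_times_n(self, dcv):
        ds, cfg, res = dcv
        for recs in res.per_model_records.values():
            assert len(recs) == cfg.KK * ds.n
        assert len(res.combined_records) == cfg.KK * ds.n

    def test_no_leakage_between_calibration_and_holdout(self, dcv):
        _, _, res = dcv
        assert res.audit
        for entry in res.audit:
            assert not entry["calibration_ids"] & entry["holdout_ids"]

    def test_each_outer_repeat_covers_all_instances(self, dcv):
        ds, cfg, res = dcv
        recs = res.combined_records
        for kk in range(cfg.KK):
            ids = [r.instance_id for r, (k, _) in
                   zip(recs, res.provenance) if k == kk]
            assert sorted(ids) == sorted(ds.instance_ids)

    def test_seeded_rerun_identical(self):
        ds = generate(small_config(seed=14, C=3, n_per_class=12, d=3))
        cfg = CVConfig(n_folds=3, K=1, KK=1, seed=14)
        r1 = double_cv(FAST_MODELS, ds, cfg)
        r2 = double_cv(FAST_MODELS, ds, cfg)
        assert [r.pin for r in r1.combined_records] == \
            [r.pin for r in r2.combined_records]

    def test_calibrated_model_precision_near_bayes_accuracy(self):
        # gnb is the correct model family for the spherical mixture, so its
        # double-CV precision should track the analytic Bayes accuracy
        from pincom.synthetic_data import bayes_posterior
        cfg_mix = small_config(seed=15, C=4, n_per_class=50, d=4,
                               base_separation=2.0)
        ds = generate(cfg_mix)
        big = generate(MixtureConfig(sizes=(2500,) * 4, d=4,
                                     sigma=cfg_mix.sigma,
                                     means=cfg_mix.means,
                                     separability=cfg_mix.separability,
                                     base_separation=cfg_mix.base_separation,
                                     seed=99))
        post = bayes_posterior(cfg_mix, big.features)
        vocab = cfg_mix.class_vocab
        bayes_acc = np.mean(
            [vocab[j] == t for j, t in zip(np.argmax(post, axis=1), big.labels)]
        )
        cfg = CVConfig(n_folds=5, K=2, KK=2, seed=15)
        res = double_cv([ClassifierSpec("gnb", "gnb")], ds, cfg)
        recs = res.per_model_records["gnb"]
        prec = np.mean([r.correct for r in recs])
        se = np.sqrt(bayes_acc * (1 - bayes_acc) / ds.n)
        assert abs(prec - bayes_acc) < 3 * se + 0.02


class TestEstimateTestPr:
    def _xv_const(self, precision, n=50, pin=None):
        """CV records whose tail precision is constant = ``precision``."""
        recs = []
        for i in range(n):
            correct = i < int(round(precision * n))
            recs.append(PredictionRecord(
                f"v{i}", "m", "A" if correct else "B", "A",
                maxp=0.5, pin=0.5 if pin is None else pin, pic=0.5))
        return recs

    def test_multiplicative_estimate(self):
        xv = self._xv_const(0.7)
        test = [PredictionRecord(f"t{i}", "m", "A", None, maxp=0.9,
                                 pin=0.9, pic=0.9) for i in range(100)]
        df = estimate_test_pr(test, xv, thresholds=[0.2], score="pin")
        row = df.iloc[0]
        assert row["subset_size"] == 100
        assert row["est_correct"] == pytest.approx(70.0)
        assert row["P"] == pytest.approx(0.7)
        assert row["R"] == pytest.approx(0.7)

    def test_zero_threshold_full_set_identity(self):
        xv = self._xv_const(0.6)
        test = [PredictionRecord(f"t{i}", "m", "A", None, maxp=0.5,
                                 pin=0.1 + 0.8 * (i / 49), pic=0.5)
                for i in range(50)]
        df = estimate_test_pr(test, xv, thresholds=[0.0], score="pin")
        row = df.iloc[0]
        assert row["subset_size"] == 50
        assert row["R"] == pytest.approx(row["P"])

    def test_class_weighted_pic_estimate(self):
        # class A precision 0.9 (40 test predictions), class B 0.5 (60)
        xv = []
        for i in range(20):
            ok = i < 18  # 0.9
            xv.append(PredictionRecord(f"a{i}", "m", "A", "A" if ok else "B",
                                       maxp=0.5, pin=0.5, pic=0.6))
        for i in range(20):
            ok = i < 10  # 0.5
            xv.append(PredictionRecord(f"b{i}", "m", "B", "B" if ok else "A",
                                       maxp=0.5, pin=0.5, pic=0.6))
        test = (
            [PredictionRecord(f"ta{i}", "m", "A", None, maxp=0.5, pin=0.5,
                              pic=0.8) for i in range(40)]
            + [PredictionRecord(f"tb{i}", "m", "B", None, maxp=0.5, pin=0.5,
                                pic=0.8) for i in range(60)]
        )
        df = estimate_test_pr(test, xv, thresholds=[0.3], score="pic")
        row = df.iloc[0]
        assert row["est_correct"] == pytest.approx(66.0)
        assert row["P"] == pytest.approx(0.66)
        assert row["R"] == pytest.approx(0.66)

    def test_empty_subset_reported_undefined(self):
        xv = self._xv_const(0.7)
        test = [PredictionRecord("t0", "m", "A", None, maxp=0.5, pin=0.2,
                                 pic=0.2)]
        df = estimate_test_pr(test, xv, thresholds=[0.9], score="pin")
        assert df.iloc[0]["subset_size"] == 0
        assert np.isnan(df.iloc[0]["P"])
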
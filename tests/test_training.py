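"""Folds, Welch statistics, label handling, and the training loop contract."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from msgm.features import SegmentationConfig
from msgm.model import ModelConfig
from msgm.training import (TrainConfig, binarize_valence, make_folds,
                           prepare_features, train, welch_stats)


class TestBinarizeValence:
    def test_threshold_sides(self):
        assert binarize_valence(4.2) == "high"
        assert binarize_valence(1.0) == "low"

    def test_boundary_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            assert binarize_valence(3.0) is None

    def test_non_numeric_rejected(self):
        with pytest.raises((TypeError, ValueError)):
            binarize_valence("strong")


class TestMakeFolds:
    def test_loso_fifteen_subjects(self):
        plan = make_folds(range(15), "loso", seed=0)
        assert len(plan) == 15
        for fold in plan:
            assert len(fold.test_subjects) == 1
            # 14 remaining subjects split 8:2 -> 11 train / 3 validation
            assert len(fold.train_subjects) == 11
            assert len(fold.val_subjects) == 3
            assert not set(fold.test_subjects) & set(fold.train_subjects)
            assert not set(fold.test_subjects) & set(fold.val_subjects)
            assert not set(fold.train_subjects) & set(fold.val_subjects)

    def test_leave_n_out_eighty_subjects(self):
        plan = make_folds(range(80), "leave_n_out", n=8, seed=0)
        assert len(plan) == 10
        tested = [s for f in plan for s in f.test_subjects]
        assert sorted(tested) == list(range(80))

    def test_invalid_protocols(self):
        with pytest.raises(ValueError):
            make_folds(range(5), "leave_n_out", n=5)
        with pytest.raises(ValueError):
            make_folds([1], "loso")
        with pytest.raises(ValueError):
            make_folds(range(5), "bootstrap")

    def test_plans_reproducible_by_seed(self):
        a = make_folds(range(12), "leave_n_out", n=4, seed=3)
        b = make_folds(range(12), "leave_n_out", n=4, seed=3)
        assert a == b


class TestWelchStats:
    def test_identical_groups(self):
        r = welch_stats([70.0, 80.0, 90.0], [70.0, 80.0, 90.0])
        assert r.t == 0 and r.d == 0 and r.p == pytest.approx(1.0)

    def test_matches_scipy_from_stats(self, rng):
        for _ in range(20):
            ma, mb = rng.uniform(40, 90, 2)
            sa, sb = rng.uniform(2, 20, 2)
            na, nb = rng.integers(3, 30, 2)
            r = welch_stats((ma, sa, na), (mb, sb, nb))
            ref = sp_stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb,
                                                equal_var=False)
            assert r.t == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p == pytest.approx(ref.pvalue, abs=1e-10)
            assert r.d == pytest.approx((ma - mb) / np.sqrt((sa**2 + sb**2) / 2))

    def test_per_fold_lists_equal_summary_path(self, rng):
        a = rng.uniform(50, 100, 10)
        b = rng.uniform(50, 100, 12)
        r1 = welch_stats(a, b)
        r2 = welch_stats((a.mean(), a.std(ddof=1), 10),
                         (b.mean(), b.std(ddof=1), 12))
        assert r1.t == pytest.approx(r2.t)

    def test_zero_variance_flagged_infinite(self):
        with pytest.warns(RuntimeWarning):
            r = welch_stats((80.0, 0.0, 5), (70.0, 0.0, 5))
        assert np.isinf(r.t) and r.t > 0

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_stats([1.0], [2.0, 3.0])


class TestPrepareFeatures:
    def test_segment_bookkeeping(self, tiny_dataset, two_scale_seg_cfg):
        data = prepare_features(tiny_dataset, two_scale_seg_cfg)
        # 24 s trials -> floor((24-20)/4)+1 = 2 segments each
        assert len(data) == len(tiny_dataset) * 2
        assert data.n_k == (9, 4)
        assert set(data.class_names) == {"low", "high"}
        assert data.features[0].shape == (len(data), 9, 6, 7)
        # labels inherited from the parent trial
        per_subject = data.labels[data.subjects == 0]
        assert per_subject.size == 4

    def test_feature_type_variants(self, tiny_dataset, two_scale_seg_cfg):
        rpsd = prepare_features(tiny_dataset, two_scale_seg_cfg, feature_type="rpsd")
        psd = prepare_features(tiny_dataset, two_scale_seg_cfg, feature_type="psd")
        de = prepare_features(tiny_dataset, two_scale_seg_cfg, feature_type="de")
        np.testing.assert_allclose(rpsd.features[0].sum(axis=-1), 1.0, atol=1e-6)
        assert psd.features[0].max() > 1.0  # absolute power, microvolt^2 scale
        np.testing.assert_allclose(
            de.features[0], 0.5 * np.log(2 * np.pi * np.e * psd.features[0]),
            atol=1e-9)


@pytest.fixture(scope="module")
def tiny_run(tiny_dataset, two_scale_seg_cfg):
    data = prepare_features(tiny_dataset, two_scale_seg_cfg)
    cfg = ModelConfig(c=6, n_k=data.n_k, d_out=2, h=8, w_out=3)
    folds = make_folds(sorted(set(data.subjects)), "loso", seed=7)
    regions = np.array([0, 0, 0, 1, 1, 1])
    tcfg = TrainConfig(epochs=2, batch_size=4, seed=7)
    return data, cfg, folds, regions, tcfg


class TestTrainingLoop:
    def test_deterministic_given_seed(self, tiny_run):
        data, cfg, folds, regions, tcfg = tiny_run
        r1 = train(data, folds, cfg, regions, tcfg)
        r2 = train(data, folds, cfg, regions, tcfg)
        np.testing.assert_array_equal(r1.accuracies, r2.accuracies)
        np.testing.assert_array_equal(r1.f1s, r2.f1s)

    def test_report_ranges_and_summary(self, tiny_run):
        data, cfg, folds, regions, tcfg = tiny_run
        r = train(data, folds, cfg, regions, tcfg)
        assert len(r.fold_results) == 3
        assert np.all((r.accuracies >= 0) & (r.accuracies <= 100))
        assert np.all((r.f1s >= 0) & (r.f1s <= 100))
        assert r.sd_accuracy >= 0
        assert "loso" in r.summary()

    def test_checkpoint_roundtrip_preserves_predictions(self, tiny_run, tmp_path):
        from msgm.autodiff import no_grad
        from msgm.model import MSGMModel
        from msgm.training import load_checkpoint, save_checkpoint
        data, cfg, folds, regions, tcfg = tiny_run
        rng = np.random.default_rng(0)
        model = MSGMModel(cfg, regions, rng)
        batch = [f[:4] for f in data.features]
        model(batch, rng)  # training pass freezes graphs
        model.eval()
        with no_grad():
            before = model(batch).data
        save_checkpoint(model, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        back.eval()
        with no_grad():
            after = back(batch).data
        np.testing.assert_array_equal(before, after)

    def test_temporal_ablation_uses_single_scale(self, tiny_run):
        data, cfg, folds, regions, tcfg = tiny_run
        from dataclasses import replace
        cfg1 = replace(cfg, n_k=data.n_k, no_temporal_multiscale=True)
        r = train(data, folds, cfg1, regions, tcfg)
        assert len(r.fold_results) == 3  # runs end-to-end on the longest window
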
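"""Loss, metrics, augmentation, and the train/fine-tune protocol contracts."""

import numpy as np
import pytest

from braincam.errors import DomainError, ShapeError, ValidationError
from braincam.model import RegressionNet
from braincam.training import (
    AugmentSpec,
    TrainConfig,
    augment,
    compute_metrics,
    evaluate,
    fine_tune,
    mse_loss,
    train,
)
from braincam.volume_io import CohortTable, SubjectRecord, Volume


class TestMseLoss:
    @pytest.mark.parametrize(
        "p,t,expected",
        [([2, 2], [2, 2], 0.0), ([3], [1], 4.0), ([1, 2, 3], [0, 0, 0], 14 / 3)],
    )
    def test_values(self, p, t, expected):
        assert mse_loss(p, t) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            mse_loss([1, 2], [1])


class TestMetrics:
    def test_perfect_predictions(self):
        with pytest.warns(UserWarning):
            m = compute_metrics([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert (m.mae, m.stdae, m.rmse) == (0.0, 0.0, 0.0)
        assert m.pearson_r == 0.0  # constant-vector guard

    def test_simple_case(self):
        m = compute_metrics(true=[1, 2, 4], predicted=[1, 2, 3])
        assert m.mae == pytest.approx(1 / 3)
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))

    def test_against_independent_implementations(self, rng):
        """Cross-check against sklearn/scipy on 100 random pairs."""
        from scipy import stats
        from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

        t = rng.normal(26, 5, size=100)
        p = t + rng.normal(0, 2, size=100)
        m = compute_metrics(t, p)
        assert m.mae == pytest.approx(mean_absolute_error(t, p), abs=1e-10)
        assert m.rmse == pytest.approx(np.sqrt(mean_squared_error(t, p)), abs=1e-10)
        assert m.r_squared == pytest.approx(r2_score(t, p), abs=1e-10)
        assert m.pearson_r == pytest.approx(stats.pearsonr(t, p).statistic, abs=1e-10)
        assert m.stdae == pytest.approx(np.std(np.abs(t - p)), abs=1e-10)

    def test_rmse_dominates_mae(self, rng):
        for _ in range(20):
            t = rng.normal(size=10)
            p = rng.normal(size=10)
            m = compute_metrics(t, p)
            assert m.rmse >= m.mae >= 0.0
            assert -1.0 <= m.pearson_r <= 1.0

    def test_r2_equals_r_squared_for_affine_predictions(self, rng):
        t = rng.normal(26, 4, size=50)
        m = compute_metrics(t, 0.5 * t + 3.0)
        assert m.r_squared <= m.pearson_r**2 + 1e-12

    def test_too_few_pairs(self):
        with pytest.raises(DomainError):
            compute_metrics([1.0], [1.0])


class TestAugment:
    def _vol(self, rng, shape=(12, 12, 12)):
        return Volume(intensities=rng.normal(size=shape).astype(np.float32))

    def test_zero_bounds_identity(self, rng):
        vol = self._vol(rng)
        out = augment(vol, AugmentSpec(0.0, 0), seed=3)
        np.testing.assert_array_equal(out.intensities, vol.intensities)

    def test_pure_translation_matches_on_overlap(self, rng):
        vol = self._vol(rng)
        seed = 11
        out = augment(vol, AugmentSpec(0.0, 3), seed=seed)
        # recover the drawn shifts: same generator protocol as the implementation
        gen = np.random.default_rng(seed)
        shifts = gen.integers(-3, 4, size=3)
        src, dst = [], []
        for n, s in zip(vol.shape, shifts):
            s = int(s)
            if s >= 0:
                dst.append(slice(s, n))
                src.append(slice(0, n - s))
            else:
                dst.append(slice(0, n + s))
                src.append(slice(-s, n))
        np.testing.assert_array_equal(
            out.intensities[tuple(dst)], vol.intensities[tuple(src)]
        )

    def test_shape_preserved_and_deterministic(self, rng):
        vol = self._vol(rng)
        spec = AugmentSpec(5.0, 2)
        a = augment(vol, spec, seed=9)
        b = augment(vol, spec, seed=9)
        assert a.shape == vol.shape
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_rotation_bound_respected(self, rng):
        """A small rotation moves off-axis mass by at most tan(5°)·r voxels."""
        vol = Volume(intensities=np.zeros((21, 21, 21), dtype=np.float32))
        vol.intensities[10, 10, 18] = 1.0
        out = augment(vol, AugmentSpec(5.0, 0), seed=2)
        moved = np.argwhere(out.intensities > 0.1)
        assert len(moved) > 0
        # 5° at radius 8 displaces mass by ≤ 8·sin(5°) ≈ 0.7 voxels
        assert np.all(np.linalg.norm(moved - [10, 10, 18], axis=1) <= 2.0)

    def test_negative_bounds_rejected(self):
        with pytest.raises(DomainError):
            AugmentSpec(-1.0, 0)


def _toy_train_config(**kw):
    defaults = dict(epochs=3, batch_size=8, learning_rate=1e-3, dropout_rate=0.0, seed=5)
    defaults.update(kw)
    return TrainConfig(**defaults)


def _toy_net(spec, seed=0):
    from braincam.model import reference_config

    cfg = reference_config(input_shape=spec.volume_shape)
    cfg.blocks = cfg.blocks[:2]
    cfg.hidden_units = 8
    cfg.dropout_rate = 0.0
    # shrink channels so the toy protocol runs in seconds
    from braincam.model import BlockSpec

    cfg.blocks = [BlockSpec(3, 1, 4, True), BlockSpec(3, 4, 8, False)]
    return RegressionNet(cfg, seed=seed)


class TestTrainProtocol:
    def test_history_and_snapshot_restore(self, toy_cohort):
        train_set, val_set, _, spec = toy_cohort
        net = _toy_net(spec)
        cfg = _toy_train_config()
        res = train(net, train_set, val_set, cfg)
        assert len(res.history) == 3
        assert res.best_epoch in (1, 2, 3)
        maes = [h["val_mae"] for h in res.history]
        assert res.history[res.best_epoch - 1]["val_mae"] == min(maes)
        # restored snapshot reproduces the recorded best validation MAE
        m = evaluate(res.best_net, val_set)
        assert m.mae == pytest.approx(min(maes), rel=1e-5)

    def test_determinism(self, toy_cohort):
        train_set, val_set, _, spec = toy_cohort
        cfg = _toy_train_config()
        res1 = train(_toy_net(spec), train_set, val_set, cfg)
        res2 = train(_toy_net(spec), train_set, val_set, cfg)
        assert res1.history == res2.history

    def test_loss_decreases_on_clean_signal(self):
        from conftest import toy_phantom_spec
        from braincam.phantom import generate_cohort

        spec = toy_phantom_spec(seed=9, noise_sd=0.0)
        table, _ = generate_cohort(spec, 32)
        train_set = CohortTable(table.records[:24], "train")
        val_set = CohortTable(table.records[24:], "validation")
        net = _toy_net(spec)
        res = train(net, train_set, val_set, _toy_train_config(learning_rate=5e-3))
        assert res.history[-1]["train_loss"] < res.history[0]["train_loss"]

    def test_record_without_target_rejected(self, toy_cohort):
        train_set, val_set, _, spec = toy_cohort
        broken = CohortTable(
            train_set.records[:-1]
            + [
                SubjectRecord(
                    "untargeted",
                    train_set.records[-1].volume_ref,
                    50.0,
                    0,
                    None,
                )
            ],
            "train",
        )
        with pytest.raises(ValidationError, match="untargeted"):
            train(_toy_net(spec), broken, val_set, _toy_train_config())

    def test_empty_set_rejected(self, toy_cohort):
        train_set, val_set, _, spec = toy_cohort
        with pytest.raises(DomainError):
            train(_toy_net(spec), CohortTable([], "train"), val_set, _toy_train_config())


class TestFineTune:
    def test_degenerate_augmentation_equals_train(self, toy_cohort):
        """Fine-tuning with zero augmentation bounds reproduces plain training."""
        train_set, val_set, _, spec = toy_cohort
        cfg = _toy_train_config(epochs=2, augmentation=AugmentSpec(0.0, 0))
        pre1 = _toy_net(spec, seed=13)
        pre2 = _toy_net(spec, seed=13)
        res_ft = fine_tune(pre1, train_set, val_set, cfg)
        res_tr = train(pre2, train_set, val_set, cfg)
        assert res_ft.history == res_tr.history

    def test_fine_tune_starts_from_pretrained(self, toy_cohort):
        train_set, val_set, _, spec = toy_cohort
        cfg = _toy_train_config(epochs=2)
        pretrained = train(_toy_net(spec), train_set, val_set, cfg).best_net
        res = fine_tune(
            pretrained, train_set, val_set,
            _toy_train_config(epochs=1, augmentation=AugmentSpec(2.0, 1)),
        )
        assert len(res.history) == 1
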
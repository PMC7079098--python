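import numpy as np
import pytest

from propnet.errors import ConfigError, InputError, ShapeError
from propnet.network import (
    LossWeights,
    ModelState,
    OptimizerSettings,
    ProgressiveSchedule,
    UNetConfig,
    dvf_loss,
    forward,
    level_weights,
    overlap_loss,
    propagate,
    stl_warp,
    total_loss,
    train,
)
from propnet.phantom import make_training_sample
from propnet.transforms import DisplacementField, RigidTransform, to_dense_field, warp_mask
from propnet.volume import Volume3D


CFG = UNetConfig(levels=2, input_size=(16, 16, 16), base_features=4)


def tiny_state(seed=0):
    return ModelState.initialize(CFG, np.random.default_rng(seed))


class TestSchedule:
    def test_initial_weight_on_coarsest(self):
        s = ProgressiveSchedule(N=1000, M=2000)
        np.testing.assert_allclose(level_weights(s, 0, 5), [1, 0, 0, 0, 0])

    def test_first_ramp_midpoint(self):
        s = ProgressiveSchedule(N=1000, M=2000)
        np.testing.assert_allclose(level_weights(s, 2000, 5),
                                   [0.5, 0.5, 0, 0, 0])

    def test_finest_reached_exactly_at_15000(self):
        s = ProgressiveSchedule(N=1000, M=2000)
        assert s.total_length(5) == 15000
        np.testing.assert_allclose(level_weights(s, 15000, 5), [0, 0, 0, 0, 1])
        w = level_weights(s, 14999, 5)
        assert w[4] < 1.0

    def test_sum_one_and_adjacency(self):
        s = ProgressiveSchedule(N=7, M=13)
        for it in range(0, 200):
            w = level_weights(s, it, 4)
            assert w.sum() == pytest.approx(1.0)
            nz = np.flatnonzero(w > 0)
            assert len(nz) <= 2
            if len(nz) == 2:
                assert nz[1] == nz[0] + 1

    def test_piecewise_linear_ramps(self):
        s = ProgressiveSchedule(N=10, M=10)
        # ramp runs from iteration 10 to 20
        for t in range(10, 20):
            w = level_weights(s, t, 3)
            assert w[0] == pytest.approx(1 - (t - 10) / 10)
            assert w[1] == pytest.approx((t - 10) / 10)

    def test_invalid(self):
        with pytest.raises(ConfigError):
            ProgressiveSchedule(N=0)
        with pytest.raises(ConfigError):
            level_weights(ProgressiveSchedule(), -1, 5)


class TestLosses:
    def test_overlap_identical(self):
        m = np.zeros((6, 6, 6)); m[2:4, 2:4, 2:4] = 1
        assert overlap_loss(m, m) == pytest.approx(0.0, abs=1e-5)

    def test_overlap_disjoint(self):
        a = np.zeros((6, 6, 6)); a[:2, :2, :2] = 1
        b = np.zeros((6, 6, 6)); b[4:, 4:, 4:] = 1
        assert overlap_loss(a, b) == pytest.approx(1.0, abs=1e-5)

    def test_overlap_half_soft(self):
        pred = np.full((4, 4, 4), 0.5)
        truth = np.zeros((4, 4, 4)); truth[:2] = 1
        assert overlap_loss(pred, truth) == pytest.approx(0.5, abs=1e-4)

    def test_overlap_range_error(self):
        with pytest.raises(InputError):
            overlap_loss(np.full((3, 3, 3), 1.5), np.zeros((3, 3, 3)))

    def test_dvf_constant_offset_three(self):
        a = np.zeros((3, 5, 5, 5))
        b = np.ones((3, 5, 5, 5))
        assert dvf_loss(a, b) == pytest.approx(3.0)

    def test_dvf_brute_force(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(3, 4, 4, 4))
        b = rng.normal(size=(3, 4, 4, 4))
        acc = 0.0
        for idx in np.ndindex(4, 4, 4):
            acc += sum((a[c][idx] - b[c][idx]) ** 2 for c in range(3))
        assert dvf_loss(a, b) == pytest.approx(acc / 64, abs=1e-9)

    def test_presets(self):
        assert LossWeights.from_preset("overlap").k_dvf == 0.0
        assert LossWeights.from_preset("deformation").k_overlap == 0.0
        h = LossWeights.from_preset("hybrid")
        assert (h.k_overlap, h.k_dvf) == (1.0, 1.0)
        with pytest.raises(ConfigError):
            LossWeights.from_preset("nope")
        with pytest.raises(ConfigError):
            LossWeights(0.0, 0.0)

    def test_total_loss_arithmetic(self):
        assert total_loss(LossWeights(1, 0), 0.4, 7.0) == pytest.approx(0.4)
        assert total_loss(LossWeights(0, 1), 0.4, 7.0) == pytest.approx(7.0)
        assert total_loss(LossWeights(1, 1), 0.4, 7.0) == pytest.approx(7.4)


class TestForward:
    def test_fresh_model_outputs_zero_field(self):
        state = tiny_state()
        rng = np.random.default_rng(1)
        m = rng.random((16, 16, 16))
        f = rng.random((16, 16, 16))
        field = forward(state, m, f)
        assert field.u.shape == (3, 16, 16, 16)
        np.testing.assert_allclose(field.u, 0.0)

    def test_deterministic(self):
        state = tiny_state()
        # nonzero heads so determinism is tested on a nontrivial output
        for k in state.params:
            if k.startswith("outhead") and k.endswith(".w"):
                state.params[k] = np.random.default_rng(2).normal(
                    0, 0.1, state.params[k].shape).astype(np.float32)
        rng = np.random.default_rng(3)
        m, f = rng.random((16, 16, 16)), rng.random((16, 16, 16))
        a = forward(state, m, f)
        b = forward(state, m, f)
        np.testing.assert_array_equal(a.u, b.u)

    def test_input_validation(self):
        state = tiny_state()
        with pytest.raises(InputError):
            forward(state, np.zeros((8, 8, 8)), np.zeros((16, 16, 16)))
        with pytest.raises(InputError):
            forward(state, np.full((16, 16, 16), 2.0), np.zeros((16, 16, 16)))


class TestStlWarp:
    def test_zero_field_identity_both_modes(self):
        rng = np.random.default_rng(0)
        m = (rng.random((10, 10, 10)) > 0.5).astype(np.float64)
        f = DisplacementField(np.zeros((3, 10, 10, 10)))
        np.testing.assert_array_equal(stl_warp(m, f, "infer"), m)
        np.testing.assert_allclose(stl_warp(m, f, "train"), m, atol=1e-12)

    def test_integer_translation_matches_warp_mask(self):
        rng = np.random.default_rng(1)
        mask = Volume3D((rng.random((10, 10, 10)) > 0.5).astype(np.uint8),
                        is_mask=True)
        t = RigidTransform((0, 0, 0), (2.0, -1.0, 0.0), (10, 10, 10))
        f = to_dense_field(t, (10, 10, 10))
        np.testing.assert_array_equal(stl_warp(mask.data, f, "infer"),
                                      warp_mask(mask, f).data)

    def test_train_mode_soft_values(self):
        rng = np.random.default_rng(2)
        m = (rng.random((8, 8, 8)) > 0.5).astype(np.float64)
        f = DisplacementField(np.full((3, 8, 8, 8), 0.5))
        out = stl_warp(m, f, "train")
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert ((out > 0) & (out < 1)).any()

    def test_bad_mode_and_shape(self):
        f = DisplacementField(np.zeros((3, 8, 8, 8)))
        with pytest.raises(ConfigError):
            stl_warp(np.zeros((8, 8, 8)), f, "bogus")
        with pytest.raises(ShapeError):
            stl_warp(np.zeros((4, 4, 4)), f, "infer")


class TestTrainLoop:
    def test_zero_iterations_returns_init(self):
        state = tiny_state()
        before = {k: v.copy() for k, v in state.params.items()}
        out = train(state, iter([]), ProgressiveSchedule(N=5, M=5),
                    LossWeights.from_preset("hybrid"), iterations=0)
        for k in before:
            np.testing.assert_array_equal(out.params[k], before[k])

    def test_few_iterations_run_and_log(self, desk_phantom):
        img, msk = desk_phantom
        cfg = UNetConfig(levels=2, input_size=(32, 32, 32), base_features=4)
        state = ModelState.initialize(cfg, np.random.default_rng(0))

        def stream():
            i = 0
            while True:
                yield make_training_sample(img, msk, np.random.default_rng([9, i]))
                i += 1

        out = train(state, stream(), ProgressiveSchedule(N=2, M=2),
                    LossWeights.from_preset("hybrid"), iterations=4)
        assert out.iteration == 4
        assert len(out.loss_log) == 4
        assert all(np.isfinite(row[1]) for row in out.loss_log)


class TestCheckpoint:
    def test_save_load_bit_identical_forward(self, tmp_path):
        state = tiny_state(4)
        for k in state.params:
            if k.startswith("outhead") and k.endswith(".w"):
                state.params[k] = np.random.default_rng(5).normal(
                    0, 0.1, state.params[k].shape).astype(np.float32)
        path = tmp_path / "ckpt.npz"
        state.save(path)
        back = ModelState.load(path)
        rng = np.random.default_rng(6)
        m, f = rng.random((16, 16, 16)), rng.random((16, 16, 16))
        np.testing.assert_array_equal(forward(state, m, f).u,
                                      forward(back, m, f).u)
        assert back.iteration == state.iteration


class TestPropagate:
    def test_zero_field_model_returns_pre_mask(self):
        state = tiny_state()
        rng = np.random.default_rng(7)
        img = Volume3D(rng.random((16, 16, 16)))
        mask = Volume3D((rng.random((16, 16, 16)) > 0.5).astype(np.uint8),
                        is_mask=True)
        frac = Volume3D(rng.random((16, 16, 16)))
        out, field = propagate(state, img, mask, frac)
        np.testing.assert_array_equal(out.data, mask.data)
        assert out.is_mask
        np.testing.assert_allclose(field.u, 0.0)

    def test_requires_mask(self):
        state = tiny_state()
        rng = np.random.default_rng(8)
        img = Volume3D(rng.random((16, 16, 16)))
        with pytest.raises(InputError):
            propagate(state, img, img, img)
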
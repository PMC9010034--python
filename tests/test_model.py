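"""Network stages: shapes, siamese sharing, gate identities, pyramid pooling,
and the brute-force oracle for the cross-correlation fusion layer."""

import numpy as np
import pytest

from spfn import (
    Image2D,
    ImagePair,
    ModelConfig,
    channel_coupling,
    channel_gate,
    conv_stem,
    cross_correlation_fuse,
    decode,
    encode,
    fuse,
    init_parameters,
    load_checkpoint,
    save_checkpoint,
    spatial_pyramid_coupling,
)
from spfn.autodiff import Tensor

RNG = np.random.default_rng(123)


def brute_force_correlation(f_ct: np.ndarray, f_pet: np.ndarray, patch, stride, radius):
    """Quadruple-loop reference for the patch cross-correlation layer:
    response(d, i, j) = sum over the m x n patch of the channel-averaged
    product of f_ct and f_pet displaced by d (zero padding outside)."""
    _, h, w = f_ct.shape
    m, n = patch
    disps = list(range(-radius * stride, radius * stride + 1, stride))
    out = np.zeros((len(disps) ** 2, h, w))
    for k, (dy, dx) in enumerate((dy, dx) for dy in disps for dx in disps):
        for i in range(h):
            for j in range(w):
                total = 0.0
                for pi in range(-((m - 1) // 2), m - (m - 1) // 2):
                    for pj in range(-((n - 1) // 2), n - (n - 1) // 2):
                        yi, xj = i + pi, j + pj
                        ys, xs = yi + dy, xj + dx
                        if 0 <= yi < h and 0 <= xj < w and 0 <= ys < h and 0 <= xs < w:
                            total += np.mean(f_ct[:, yi, xj] * f_pet[:, ys, xs])
                out[k, i, j] = total
    return out


class TestInitParameters:
    def test_deterministic_and_seed_sensitive(self):
        cfg = ModelConfig()
        a = init_parameters(cfg, 5)
        b = init_parameters(cfg, 5)
        c = init_parameters(cfg, 6)
        for name, t in a.items():
            assert np.array_equal(t.data, b[name].data)
        assert any(not np.array_equal(t.data, c[name].data) for name, t in a.items())

    def test_glorot_variance_of_stem_weights(self):
        """Empirical variance of the stem kernel entries approaches
        2 / (fan_in + fan_out) = 2 / (9 + 144) for the 1->16 3x3 stem."""
        cfg = ModelConfig()
        samples = np.concatenate(
            [init_parameters(cfg, s)["stem.w"].data.ravel() for s in range(80)]
        )
        assert samples.size >= 10_000
        expected = 2.0 / (9 + 9 * 16)
        assert abs(samples.var() - expected) / expected < 0.2

    def test_biases_start_at_zero(self):
        params = init_parameters(ModelConfig(), 0)
        for name, t in params.items():
            if name.split(".")[-1].startswith("b"):
                assert not t.data.any()

    def test_correlation_layer_owns_no_parameters(self):
        params = init_parameters(ModelConfig(), 0)
        assert not any("corr" in name for name, _ in params.items())


class TestConvStem:
    def test_zero_image_gives_zero_features(self, small_model):
        cfg, params = small_model
        img = Image2D(np.zeros((16, 16)), normalized=True)
        out = conv_stem(img, params, cfg)
        assert not out.data.any()

    def test_output_shape(self, small_model):
        cfg, params = small_model
        out = conv_stem(Image2D(RNG.random((5, 5)), normalized=True), params, cfg)
        assert out.shape == (16, 5, 5)

    def test_ones_kernel_on_one_hot_gives_plateau(self):
        cfg = ModelConfig(stem_channels=1)
        params = init_parameters(cfg, 0)
        params["stem.w"].data[:] = 1.0
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = conv_stem(Image2D(img, normalized=True), params, cfg)
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1.0
        np.testing.assert_allclose(out.data[0], expected)

    def test_unnormalized_input_rejected(self, small_model):
        cfg, params = small_model
        with pytest.raises(ValueError):
            conv_stem(Image2D(np.full((8, 8), 100.0)), params, cfg)


class TestChannelCoupling:
    def test_zero_mlp_gives_half_gates(self, small_model):
        cfg, _ = small_model
        params = init_parameters(cfg, 1)
        for name in ("gate.w1", "gate.w2"):
            params[name].data[:] = 0.0
        f = Tensor(RNG.random((16, 8, 8)))
        out = channel_coupling(f, params, cfg)
        np.testing.assert_allclose(out.data, 0.5 * f.data)

    def test_gates_strictly_inside_unit_interval(self, small_model):
        cfg, params = small_model
        gate = channel_gate(Tensor(RNG.normal(size=(16, 8, 8))), params, cfg)
        assert np.all(gate.data > 0.0) and np.all(gate.data < 1.0)

    def test_constant_channels_match_numpy_mlp_oracle(self, small_model):
        """For a constant channel AvgPool = MaxPool, so the gate reduces to
        sigmoid(2 * MLP(c)); checked against a direct numpy evaluation."""
        cfg, params = small_model
        const = np.arange(16, dtype=float).reshape(16, 1, 1) / 16.0
        f = Tensor(np.broadcast_to(const, (16, 6, 6)).copy())
        gate = channel_gate(f, params, cfg).data.ravel()
        v = const.reshape(16, 1)
        w1, b1 = params["gate.w1"].data, params["gate.b1"].data
        w2, b2 = params["gate.w2"].data, params["gate.b2"].data
        mlp = w2 @ np.maximum(w1 @ v + b1, 0.0) + b2
        expected = 1.0 / (1.0 + np.exp(-2.0 * mlp.ravel()))
        np.testing.assert_allclose(gate, expected, atol=1e-12)


class TestSpatialPyramid:
    def test_output_channel_count_is_scales_times_branch(self, small_model):
        cfg, params = small_model
        out = spatial_pyramid_coupling(Tensor(RNG.random((16, 32, 32))), params, cfg)
        assert out.shape == (4 * cfg.spp_branch_channels, 32, 32)

    def test_too_small_input_names_the_remedy(self, small_model):
        cfg, params = small_model
        with pytest.raises(ValueError, match="spp_scales"):
            spatial_pyramid_coupling(Tensor(RNG.random((16, 8, 8))), params, cfg)

    def test_scale1_branch_of_constant_map_is_constant(self):
        """The 1x1 pyramid level pools the whole map to one value and
        broadcasts it back, so a constant input stays constant."""
        cfg = ModelConfig(spp_scales=(2, 1), stem_channels=2, spp_branch_channels=1)
        params = init_parameters(cfg, 3)
        f = Tensor(np.full((2, 16, 16), 0.7))
        out = spatial_pyramid_coupling(f, params, cfg)
        scale1 = out.data[-cfg.spp_branch_channels :]  # last branch is the 1x1 level
        for ch in range(scale1.shape[0]):
            np.testing.assert_allclose(scale1[ch], scale1[ch, 0, 0], atol=1e-12)


class TestEncode:
    def test_channel_arithmetic(self, small_model, phantom_pair_64):
        cfg, params = small_model
        out = encode(phantom_pair_64.ct, params, cfg)
        assert out.shape == (16 + 4 * 8 + 1, 64, 64)

    def test_zero_image_encodes_to_zero(self, small_model):
        cfg, params = small_model
        out = encode(Image2D(np.zeros((32, 32)), normalized=True), params, cfg)
        assert not out.data.any()

    def test_siamese_branches_share_parameters_bitwise(self, small_model, phantom_pair_64):
        cfg, params = small_model
        a = encode(phantom_pair_64.ct, params, cfg, branch="")
        b = encode(phantom_pair_64.ct, params, cfg, branch="")
        assert np.array_equal(a.data, b.data)

    def test_untied_branches_differ(self, phantom_pair_64):
        cfg = ModelConfig(untied=True)
        params = init_parameters(cfg, 0)
        a = encode(phantom_pair_64.ct, params, cfg, branch="")
        b = encode(phantom_pair_64.ct, params, cfg, branch="pet.")
        assert not np.array_equal(a.data, b.data)

    def test_weight_mutation_moves_both_branches_identically(self, phantom_pair_64):
        cfg = ModelConfig()
        params = init_parameters(cfg, 2)
        before = encode(phantom_pair_64.ct, params, cfg).data.copy()
        params["stem.w"].data += 0.05
        after_ct = encode(phantom_pair_64.ct, params, cfg, branch="")
        after_pet = encode(phantom_pair_64.ct, params, cfg, branch="")
        assert not np.array_equal(before, after_ct.data)
        assert np.array_equal(after_ct.data, after_pet.data)


class TestCrossCorrelation:
    def test_one_hot_self_correlation_peak(self):
        cfg = ModelConfig(corr_window_radius=0)
        x = np.zeros((1, 7, 7))
        x[0, 3, 3] = 1.0
        out = cross_correlation_fuse(Tensor(x), Tensor(x), cfg)
        assert out.shape == (1, 7, 7)
        assert out.data[0, 3, 3] == pytest.approx(1.0)
        # outside the 3x3 patch neighborhood of the hot pixel the response vanishes
        far = out.data[0].copy()
        far[2:5, 2:5] = 0.0
        assert not far.any()

    def test_zero_displacement_symmetry(self):
        cfg = ModelConfig(corr_window_radius=0)
        a = Tensor(RNG.normal(size=(3, 9, 9)))
        b = Tensor(RNG.normal(size=(3, 9, 9)))
        ab = cross_correlation_fuse(a, b, cfg)
        ba = cross_correlation_fuse(b, a, cfg)
        np.testing.assert_allclose(ab.data, ba.data, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        cfg = ModelConfig(corr_window_radius=1)
        a = RNG.normal(size=(1, 8, 8))
        b = RNG.normal(size=(1, 8, 8))
        out = cross_correlation_fuse(Tensor(a), Tensor(b), cfg)
        ref = brute_force_correlation(a, b, cfg.corr_patch, cfg.corr_stride, cfg.corr_window_radius)
        assert out.shape == (9, 8, 8)
        np.testing.assert_allclose(out.data, ref, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation_fuse(Tensor(np.ones((2, 4, 4))), Tensor(np.ones((2, 5, 5))))


class TestDecode:
    def test_unit_strides_preserve_spatial_size(self, small_model):
        cfg, params = small_model
        out = decode(Tensor(RNG.normal(size=(9, 20, 20))), params, cfg)
        assert out.shape == (1, 20, 20)

    def test_output_in_unit_interval(self, small_model):
        cfg, params = small_model
        out = decode(Tensor(10 * RNG.normal(size=(9, 12, 12))), params, cfg)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_zero_features_zero_biases_give_half(self, small_model):
        cfg, params = small_model
        fresh = init_parameters(cfg, 9)  # biases are zero at init
        out = decode(Tensor(np.zeros((9, 8, 8))), fresh, cfg)
        np.testing.assert_allclose(out.data, 0.5)


class TestFuse:
    def test_identical_inputs_invariant_to_branch_swap(self, small_model, identity_pair_32):
        cfg, params = small_model
        swapped = ImagePair(
            ct=identity_pair_32.pet, pet=identity_pair_32.ct, identifier="sw"
        )
        a = fuse(identity_pair_32, params, cfg)
        b = fuse(swapped, params, cfg)
        assert np.array_equal(a.values, b.values)

    def test_radius_zero_fusion_is_symmetric_in_modalities(self, small_model, phantom_pair_64):
        cfg = ModelConfig(corr_window_radius=0)
        params = init_parameters(cfg, 4)
        swapped = ImagePair(ct=phantom_pair_64.pet, pet=phantom_pair_64.ct, identifier="sw")
        a = fuse(phantom_pair_64, params, cfg)
        b = fuse(swapped, params, cfg)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_shape_and_range_contract(self, small_model, phantom_pair_64):
        cfg, params = small_model
        fused = fuse(phantom_pair_64, params, cfg)
        assert fused.shape == (64, 64)
        assert fused.modality == "FUSED" and fused.normalized

    @pytest.mark.parametrize("fill", ["zeros", "ones", "random"])
    def test_finite_outputs_at_every_stage(self, small_model, fill):
        cfg, params = small_model
        arr = {
            "zeros": np.zeros((32, 32)),
            "ones": np.ones((32, 32)),
            "random": RNG.random((32, 32)),
        }[fill]
        img = Image2D(arr, normalized=True)
        f = conv_stem(img, params, cfg)
        fc = channel_coupling(f, params, cfg)
        fs = spatial_pyramid_coupling(fc, params, cfg)
        enc = encode(img, params, cfg)
        corr = cross_correlation_fuse(enc, enc, cfg)
        out = decode(corr, params, cfg)
        for t in (f, fc, fs, enc, corr, out):
            assert np.all(np.isfinite(t.data))


def test_checkpoint_roundtrip_reproduces_fusion_bitwise(tmp_path, small_model, phantom_pair_64):
    cfg, params = small_model
    before = fuse(phantom_pair_64, params, cfg)
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, cfg)
    params2, cfg2 = load_checkpoint(path)
    assert cfg2 == cfg
    after = fuse(phantom_pair_64, params2, cfg2)
    assert np.array_equal(before.values, after.values)
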
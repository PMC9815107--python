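"""Channel/spatial attention and CBAM: closed-form cases and invariants."""

import numpy as np
import pytest
from scipy import signal

from msfnet.attention import (
    CBAM,
    ChannelAttention,
    SpatialAttention,
    cbam,
    channel_attention,
    spatial_attention,
    validate_feature_map,
)
from msfnet.errors import ConfigurationError, ValidationError
from msfnet.nn import Tensor


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


def zeroed(module):
    for p in module.parameters():
        p.data = np.zeros_like(p.data)
    return module


class TestChannelAttention:
    def test_zero_mlp_gives_half_everywhere(self, rng):
        """sigmoid(0) = 0.5 when the shared MLP is all zeros."""
        mod = zeroed(ChannelAttention(4, reduction_ratio=2, rng=rng))
        f = np.full((4, 3, 3), 2.5, dtype=np.float32)
        np.testing.assert_allclose(mod.attend(f), 0.5)

    def test_identity_mlp_closed_form(self):
        """Identity MLP on f=[[1],[3]]: weights = sigmoid([2, 6])."""
        mod = ChannelAttention(2, reduction_ratio=1)
        mod.fc1.weight.data = np.eye(2, dtype=np.float32)
        mod.fc2.weight.data = np.eye(2, dtype=np.float32)
        f = np.array([[[1.0]], [[3.0]]], dtype=np.float32)
        np.testing.assert_allclose(
            mod.attend(f), _sigmoid([2.0, 6.0]), rtol=1e-6
        )

    def test_weights_in_open_unit_interval(self, rng):
        f = rng.normal(0, 10, (5, 4, 6)).astype(np.float32)
        w = channel_attention(f, reduction_ratio=2, rng=rng)
        assert w.shape == (5,)
        assert np.all(w > 0) and np.all(w < 1)

    def test_permutation_equivariance(self, rng):
        """Permuting channels and MLP weights consistently permutes the output."""
        mod = ChannelAttention(3, reduction_ratio=1, rng=rng)
        f = rng.normal(0, 1, (3, 4, 4)).astype(np.float32)
        w = mod.attend(f)
        perm = np.array([2, 0, 1])
        mod2 = ChannelAttention(3, reduction_ratio=1)
        mod2.fc1.weight.data = mod.fc1.weight.data[perm, :]
        mod2.fc2.weight.data = mod.fc2.weight.data[:, perm]
        np.testing.assert_allclose(mod2.attend(f[perm]), w[perm], rtol=1e-5)

    def test_invalid_inputs_rejected(self, rng):
        with pytest.raises(ValidationError):
            channel_attention(np.full((2, 2, 2), np.nan))
        with pytest.raises(ConfigurationError):
            ChannelAttention(4, reduction_ratio=0)


class TestSpatialAttention:
    def test_spatially_constant_input_gives_uniform_interior(self, rng):
        """Translation symmetry holds away from the zero-padded border."""
        mod = SpatialAttention(3, rng=rng)
        f = np.tile(rng.normal(0, 1, (4, 1, 1)).astype(np.float32), (1, 7, 7))
        w = mod.attend(f)[1:-1, 1:-1]  # drop the k//2 border
        np.testing.assert_allclose(w, w[0, 0], rtol=1e-5)

    def test_zero_conv_gives_half(self, rng):
        mod = zeroed(SpatialAttention(7, rng=rng))
        f = rng.normal(0, 1, (3, 4, 6)).astype(np.float32)
        np.testing.assert_allclose(mod.attend(f), 0.5)

    def test_hand_set_kernel_matches_direct_convolution(self):
        """C=1: max and mean maps both equal f; brute-force 2-D correlation oracle."""
        f = np.eye(3, dtype=np.float32)[None] * 2.0
        mod = SpatialAttention(3)
        k_max = np.array([[0.0, 1.0, 0.0], [1.0, -2.0, 1.0], [0.0, 1.0, 0.0]])
        k_avg = np.array([[0.5, 0.0, 0.5], [0.0, 1.0, 0.0], [0.5, 0.0, 0.5]])
        mod.conv.weight.data = np.stack([k_max, k_avg])[None].astype(np.float32)
        expected = _sigmoid(
            signal.correlate2d(f[0], k_max, mode="same")
            + signal.correlate2d(f[0], k_avg, mode="same")
        )
        np.testing.assert_allclose(mod.attend(f), expected, rtol=1e-5, atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigurationError):
            SpatialAttention(4)


class TestCBAM:
    def test_zero_input_stays_zero(self, rng):
        mod = CBAM(3, reduction_ratio=2, spatial_kernel=3, rng=rng)
        out = mod.gate(np.zeros((3, 4, 4), dtype=np.float32))
        np.testing.assert_allclose(out, 0.0)

    def test_zero_parameters_quarter_input(self, rng):
        """Both gates at sigmoid(0)=0.5 gives 0.25 * f."""
        mod = zeroed(CBAM(3, reduction_ratio=2, spatial_kernel=3, rng=rng))
        f = rng.normal(0, 1, (3, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(mod.gate(f), 0.25 * f, rtol=1e-5, atol=1e-7)

    def test_matches_elementwise_oracle(self, rng):
        """2x4x4 instance recomputed step by step with plain numpy/scipy."""
        mod = CBAM(2, reduction_ratio=1, spatial_kernel=3, rng=rng)
        f = rng.normal(0, 1, (2, 4, 4)).astype(np.float32)

        w1 = mod.channel.fc1.weight.data.astype(np.float64)
        w2 = mod.channel.fc2.weight.data.astype(np.float64)
        f64 = f.astype(np.float64)

        def mlp(v):
            return np.maximum(v @ w1, 0.0) @ w2

        cw = _sigmoid(mlp(f64.mean(axis=(1, 2))) + mlp(f64.max(axis=(1, 2))))
        f1 = f64 * cw[:, None, None]
        stacked = np.stack([f1.max(axis=0), f1.mean(axis=0)])
        kern = mod.spatial.conv.weight.data.astype(np.float64)[0]
        sw = _sigmoid(
            signal.correlate2d(stacked[0], kern[0], mode="same")
            + signal.correlate2d(stacked[1], kern[1], mode="same")
        )
        expected = f1 * sw[None]
        np.testing.assert_allclose(mod.gate(f), expected, rtol=1e-4, atol=1e-5)

    @pytest.mark.parametrize("shape", [(1, 1, 1), (3, 5, 7), (8, 4, 4), (2, 9, 3)])
    def test_shape_preserved_and_gating_bounded(self, rng, shape):
        f = rng.normal(0, 3, shape).astype(np.float32)
        out = cbam(f, reduction_ratio=2, spatial_kernel=3, rng=rng)
        assert out.shape == f.shape
        assert np.all(np.abs(out) <= np.abs(f) + 1e-7)

    def test_batched_forward_matches_single(self, rng):
        mod = CBAM(3, reduction_ratio=2, spatial_kernel=3, rng=rng)
        f = rng.normal(0, 1, (2, 3, 4, 4)).astype(np.float32)
        batched = mod(Tensor(f)).data
        for i in range(2):
            np.testing.assert_allclose(batched[i], mod.gate(f[i]), rtol=2e-4, atol=1e-5)


def test_validate_feature_map_contract():
    with pytest.raises(ValidationError):
        validate_feature_map(np.zeros((2, 2)))
    with pytest.raises(ValidationError):
        validate_feature_map(np.full((1, 2, 2), np.inf))
    ok = validate_feature_map([[[1.0]]])
    assert ok.shape == (1, 1, 1)


def test_spatial_attention_functional_wrapper(rng):
    f = rng.normal(0, 1, (2, 5, 5)).astype(np.float32)
    w = spatial_attention(f, kernel_size=3, rng=rng)
    assert w.shape == (5, 5)
    assert np.all((w > 0) & (w < 1))
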
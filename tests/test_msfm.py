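"""Dilated-convolution geometry and the multi-scale fusion block."""

import numpy as np
import pytest
from scipy import signal

from msfnet.errors import ConfigurationError, ValidationError
from msfnet.msfm import (
    DilatedBranch,
    DilationSpec,
    MultiScaleFusion,
    dilated_branch,
    dilated_kernel_size,
    gradient_footprint_side,
    receptive_field_side,
)
from msfnet.nn import Tensor


def dilate_kernel(k: np.ndarray, rate: int) -> np.ndarray:
    kh, kw = k.shape
    out = np.zeros(((kh - 1) * rate + 1, (kw - 1) * rate + 1), dtype=k.dtype)
    out[::rate, ::rate] = k
    return out


class TestKernelGeometry:
    @pytest.mark.parametrize(
        "k,r,expected",
        [
            (3, 2, 5),   # dilation 2 spans the 5x5 window of a dense 5x5 kernel
            (3, 1, 3),   # rate 1 is ordinary convolution
            (5, 3, 13),
            (3, 4, 9),
        ],
    )
    def test_expanded_side_formula_and_footprint_agree(self, k, r, expected):
        assert dilated_kernel_size(k, r) == expected
        assert gradient_footprint_side(r, kernel_size=k) == expected

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValidationError):
            dilated_kernel_size(3, 0)
        with pytest.raises(ValidationError):
            dilated_kernel_size(0, 1)
        with pytest.raises(ValidationError):
            dilated_kernel_size(4, 2)  # even kernels unsupported

    def test_dilation_spec_derived_fields(self):
        spec = DilationSpec(k=3, r=2)
        assert spec.k_d == 5
        # the alternative receptive-field formula deliberately disagrees
        # with the tap bounding box; it is recorded, not used
        assert spec.r_f == receptive_field_side(3, 2) == 7


class TestDilatedBranch:
    def test_rate_one_equals_ordinary_same_convolution(self, rng):
        mod = DilatedBranch(2, 3, rate=1, norm_act=False, rng=rng)
        f = rng.normal(0, 1, (2, 7, 7)).astype(np.float32)
        out = dilated_branch(f, 3, 1, module=mod)
        for o in range(3):
            acc = sum(
                signal.correlate2d(f[c], mod.conv.weight.data[o, c], mode="same")
                for c in range(2)
            )
            np.testing.assert_allclose(out[o], acc, rtol=1e-4, atol=1e-5)

    def test_delta_footprint_is_nine_at_rate_four(self, rng):
        """Nonzero support of a delta response spans 3 + 2*3 = 9 pixels."""
        mod = DilatedBranch(1, 1, rate=4, norm_act=False, rng=rng)
        mod.conv.weight.data = np.ones_like(mod.conv.weight.data)
        f = np.zeros((1, 21, 21), dtype=np.float32)
        f[0, 10, 10] = 1.0
        out = dilated_branch(f, 1, 4, module=mod)[0]
        ys, xs = np.nonzero(np.abs(out) > 0)
        assert ys.max() - ys.min() + 1 == 9
        assert xs.max() - xs.min() + 1 == 9

    @pytest.mark.parametrize("rate", [1, 2, 4])
    def test_nine_weights_regardless_of_rate(self, rate, rng):
        mod = DilatedBranch(1, 1, rate=rate, norm_act=False, rng=rng)
        assert mod.num_parameters() == 9
        dense5 = np.zeros((1, 1, 5, 5))
        assert dense5.size == 25  # the dense kernel covering the same window at r=2

    @pytest.mark.parametrize("rate", [1, 2, 4])
    def test_spatial_extent_preserved(self, rng, rate):
        mod = DilatedBranch(3, 2, rate=rate, rng=rng)
        out = mod(Tensor(rng.normal(0, 1, (1, 3, 11, 13)).astype(np.float32)))
        assert out.shape == (1, 2, 11, 13)

    def test_invalid_rate(self, rng):
        with pytest.raises(ValidationError):
            DilatedBranch(1, 1, rate=0, rng=rng)


class TestMultiScaleFusion:
    def test_output_shape_and_zero_weights(self, rng):
        mod = MultiScaleFusion(3, out_channels=5, reduction_ratio=2,
                               spatial_kernel=3, rng=rng)
        f = rng.normal(0, 1, (3, 8, 8)).astype(np.float32)
        assert mod.apply_to(f).shape == (5, 8, 8)
        for p in mod.parameters():
            p.data = np.zeros_like(p.data)
        np.testing.assert_allclose(mod.apply_to(f), 0.0)

    def test_matches_composed_brute_force_oracle(self, rng):
        """4x8x8 instance: branches + concat + 1x1 reduce recomputed externally."""
        mod = MultiScaleFusion(
            4, branch_channels=2, out_channels=4, norm_act=False,
            reduction_ratio=2, spatial_kernel=3, rng=rng,
        )
        f = rng.normal(0, 1, (4, 8, 8)).astype(np.float32)
        g = mod.cbam.gate(f).astype(np.float64)  # CBAM itself has its own oracle test

        branch_maps = []
        for branch in mod.branches:
            w = branch.conv.weight.data.astype(np.float64)
            for o in range(2):
                acc = sum(
                    signal.correlate2d(g[c], dilate_kernel(w[o, c], branch.rate), mode="same")
                    for c in range(4)
                )
                branch_maps.append(acc)
        stacked = np.stack(branch_maps)  # (6, 8, 8) in branch-major order
        reduce_w = mod.reduce.weight.data.astype(np.float64)[:, :, 0, 0]
        expected = np.einsum("ok,khw->ohw", reduce_w, stacked)
        np.testing.assert_allclose(mod.apply_to(f), expected, rtol=1e-3, atol=1e-4)

    def test_sum_fusion_mode(self, rng):
        mod = MultiScaleFusion(3, fusion="sum", norm_act=False,
                               reduction_ratio=2, spatial_kernel=3, rng=rng)
        f = rng.normal(0, 1, (3, 6, 6)).astype(np.float32)
        g = mod.cbam.gate(f)
        expected = sum(dilated_branch(g, 3, b.rate, module=b) for b in mod.branches)
        np.testing.assert_allclose(mod.apply_to(f), expected, rtol=1e-4, atol=1e-5)

    def test_deterministic_given_parameters(self, rng):
        mod = MultiScaleFusion(2, reduction_ratio=2, spatial_kernel=3, rng=rng)
        mod.eval()
        f = rng.normal(0, 1, (2, 6, 6)).astype(np.float32)
        np.testing.assert_array_equal(mod.apply_to(f), mod.apply_to(f))

    def test_configuration_errors(self, rng):
        with pytest.raises(ConfigurationError):
            MultiScaleFusion(3, fusion="average", rng=rng)
        with pytest.raises(ConfigurationError):
            MultiScaleFusion(3, branch_channels=2, out_channels=3, fusion="sum", rng=rng)
        with pytest.raises(ValidationError):
            MultiScaleFusion(3, rng=rng).apply_to(np.zeros((2, 4, 4), dtype=np.float32))
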
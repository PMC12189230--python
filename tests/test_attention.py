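"""Channel/spatial/frequency attention against straight-line oracles,
plus the mask-range and linearity invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modnet import (FTCA, ChannelAttention, FrequencyAttention,
                    SpatialAttention, Tensor, ValidationError)
from oracles import (channel_attention_oracle, dft2_oracle,
                     frequency_attention_oracle, spatial_attention_oracle)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestChannelAttention:
    def test_constant_channels_make_avg_equal_max(self):
        ca = ChannelAttention(3, reduction=1, rng=_rng())
        v = np.array([0.3, -1.2, 2.0])
        f = np.broadcast_to(v[:, None, None], (3, 5, 5)).copy()
        mask, _ = ca(Tensor(f[None]))
        w0, w1 = ca.fc0.weight.data, ca.fc1.weight.data
        expected = 1 / (1 + np.exp(-2 * (w1 @ (w0 @ v))))
        assert np.allclose(mask.data.ravel(), expected, atol=1e-12)

    def test_zero_mlp_gives_half_mask(self, rng):
        ca = ChannelAttention(4, reduction=2, rng=_rng())
        ca.fc0.weight.data[...] = 0.0
        ca.fc1.weight.data[...] = 0.0
        f = rng.standard_normal((2, 4, 3, 3))
        mask, fp = ca(Tensor(f))
        assert np.allclose(mask.data, 0.5)
        assert np.allclose(fp.data, 0.5 * f)

    def test_matches_straight_line_oracle(self, rng):
        ca = ChannelAttention(2, reduction=1, rng=_rng(5))
        w0 = np.array([[0.2, -0.4], [0.5, 0.1]])
        w1 = np.array([[-0.3, 0.6], [0.7, -0.2]])
        ca.fc0.weight.data = w0.copy()
        ca.fc1.weight.data = w1.copy()
        f = rng.standard_normal((2, 2, 2))
        mask, fp = ca(Tensor(f[None]))
        om, ofp = channel_attention_oracle(f, w0, w1)
        assert np.abs(mask.data.ravel() - om).max() < 1e-6
        assert np.abs(fp.data[0] - ofp).max() < 1e-6

    def test_reduction_clamped_to_channel_count(self):
        ca = ChannelAttention(4, reduction=16, rng=_rng())
        assert ca.fc0.weight.shape == (1, 4)  # bottleneck floor of 1

    def test_rejects_nonfinite_and_wrong_width(self, rng):
        ca = ChannelAttention(4, rng=_rng())
        bad = np.full((1, 4, 2, 2), np.nan)
        with pytest.raises(ValidationError):
            ca(Tensor(bad))
        from modnet import ConfigurationError
        with pytest.raises(ConfigurationError):
            ca(Tensor(rng.standard_normal((1, 3, 2, 2))))


class TestSpatialAttention:
    def test_single_channel_pooling_identity(self, rng):
        f = rng.standard_normal((1, 1, 4, 4))
        sa = SpatialAttention(3, rng=_rng())
        avg = f.mean(axis=1)
        mx = f.max(axis=1)
        assert np.allclose(avg, mx)  # C=1: both maps are the input plane

    def test_zero_kernel_gives_half_mask(self, rng):
        sa = SpatialAttention(3, rng=_rng())
        sa.conv.weight.data[...] = 0.0
        f = rng.standard_normal((1, 3, 4, 4))
        mask, fd = sa(Tensor(f))
        assert np.allclose(mask.data, 0.5)
        assert np.allclose(fd.data, 0.5 * f)

    def test_matches_brute_force_convolution(self, rng):
        sa = SpatialAttention(3, rng=_rng(9))
        f = rng.standard_normal((2, 3, 3))
        mask, fd = sa(Tensor(f[None]))
        om, ofd = spatial_attention_oracle(f, sa.conv.weight.data[0])
        assert np.abs(mask.data[0, 0] - om).max() < 1e-6
        assert np.abs(fd.data[0] - ofd).max() < 1e-6

    def test_even_kernel_rejected(self):
        from modnet import ConfigurationError
        with pytest.raises(ConfigurationError):
            SpatialAttention(4)


class TestFrequencyAttention:
    def test_zero_input_gives_zero_output(self):
        fa = FrequencyAttention(4, rng=_rng())
        z = Tensor(np.zeros((1, 2, 4, 4)))
        y_l, y_g = fa.paths(z, z)
        assert np.allclose(y_l.data, 0.0) and np.allclose(y_g.data, 0.0)

    def test_identity_spectral_round_trip(self, rng):
        fa = FrequencyAttention(4, rng=_rng())
        cg = fa.c_global
        fa.f_spectral.weight.data = np.eye(2 * cg)[:, :, None, None].copy()
        fa.f_local.weight.data[...] = 0.0
        fa.f_local_to_global.weight.data[...] = 0.0
        fa.f_global_to_local.weight.data[...] = 0.0
        x_g = rng.standard_normal((1, cg, 6, 6))
        _, y_g = fa.paths(Tensor(np.zeros((1, fa.c_local, 6, 6))), Tensor(x_g))
        assert np.abs(y_g.data - x_g).max() < 1e-5

    def test_spectrum_matches_direct_dft(self, rng):
        from modnet.autograd import fft2_stack
        x = rng.standard_normal((1, 1, 4, 4))
        stacked = fft2_stack(Tensor(x)).data
        ref = dft2_oracle(x[0, 0])
        assert np.abs(stacked[0, 0] - ref.real).max() < 1e-6
        assert np.abs(stacked[0, 1] - ref.imag).max() < 1e-6

    def test_paths_match_composed_oracle(self, rng):
        fa = FrequencyAttention(4, rng=_rng(3))
        x_l = rng.standard_normal((2, 4, 4))
        x_g = rng.standard_normal((2, 4, 4))
        y_l, y_g = fa.paths(Tensor(x_l[None]), Tensor(x_g[None]))
        ol, og = frequency_attention_oracle(
            x_l, x_g, fa.f_local.weight.data, fa.f_spectral.weight.data,
            fa.f_local_to_global.weight.data, fa.f_global_to_local.weight.data)
        assert np.abs(y_l.data[0] - ol).max() < 1e-6
        assert np.abs(y_g.data[0] - og).max() < 1e-6

    def test_linearity_in_input(self, rng):
        fa = FrequencyAttention(6, rng=_rng(4))  # identity activation: linear
        f = rng.standard_normal((1, 6, 5, 5))
        out1 = fa(Tensor(f)).data
        out3 = fa(Tensor(3.0 * f)).data
        assert np.abs(out3 - 3.0 * out1).max() < 1e-5

    def test_single_channel_input_handled(self, rng):
        fa = FrequencyAttention(1, rng=_rng())
        out = fa(Tensor(rng.standard_normal((1, 1, 4, 4))))
        assert out.shape == (1, 1, 4, 4)

    def test_mismatched_spatial_sizes_rejected(self, rng):
        fa = FrequencyAttention(4, rng=_rng())
        with pytest.raises(ValidationError):
            fa.paths(Tensor(rng.standard_normal((1, 2, 4, 4))),
                     Tensor(rng.standard_normal((1, 2, 5, 5))))


class TestFTCA:
    def test_zero_attention_weights_quarter_frequency_output(self, rng):
        ftca = FTCA(4, reduction=2, spatial_kernel=3, rng=_rng(1))
        ftca.channel.fc0.weight.data[...] = 0.0
        ftca.channel.fc1.weight.data[...] = 0.0
        ftca.spatial.conv.weight.data[...] = 0.0
        f = rng.standard_normal((1, 4, 4, 4))
        freq_out = ftca.freq(Tensor(f)).data
        out = ftca(Tensor(f)).data
        assert np.abs(out - 0.25 * freq_out).max() < 1e-12

    @pytest.mark.parametrize("c,h,w", [(1, 4, 4), (2, 5, 3), (3, 8, 8), (8, 6, 6)])
    def test_output_shape_equals_input_shape(self, c, h, w, rng):
        ftca = FTCA(c, reduction=2, spatial_kernel=3, rng=_rng(c))
        out = ftca(Tensor(rng.standard_normal((2, c, h, w))))
        assert out.shape == (2, c, h, w)

    def test_matches_composed_suboracles(self, rng):
        ftca = FTCA(4, reduction=1, spatial_kernel=3, rng=_rng(6))
        f = rng.standard_normal((4, 4, 4))
        # frequency branch via oracle
        ol, og = frequency_attention_oracle(
            f[:2], f[2:], ftca.freq.f_local.weight.data,
            ftca.freq.f_spectral.weight.data,
            ftca.freq.f_local_to_global.weight.data,
            ftca.freq.f_global_to_local.weight.data)
        g = np.concatenate([ol, og], axis=0)
        _, gp = channel_attention_oracle(g, ftca.channel.fc0.weight.data,
                                         ftca.channel.fc1.weight.data)
        _, expected = spatial_attention_oracle(gp, ftca.spatial.conv.weight.data[0])
        out = ftca(Tensor(f[None])).data[0]
        assert np.abs(out - expected).max() < 1e-5

    def test_parallel_mode_is_mask_product(self, rng):
        ftca = FTCA(4, reduction=2, spatial_kernel=3, mode="parallel", rng=_rng(2))
        f = Tensor(rng.standard_normal((1, 4, 5, 5)))
        g = ftca.freq(f)
        mc, _ = ftca.channel(g)
        ms, _ = ftca.spatial(g)
        assert np.allclose(ftca(f).data, (mc * ms * g).data)

    def test_all_parameters_receive_gradient(self, rng):
        ftca = FTCA(4, reduction=2, spatial_kernel=3, rng=_rng(8))
        out = ftca(Tensor(rng.standard_normal((2, 4, 6, 6))))
        (out * Tensor(rng.standard_normal(out.shape))).sum().backward()
        for name, p in ftca.named_parameters():
            assert p.grad is not None and np.linalg.norm(p.grad) > 0, name


@settings(max_examples=20, deadline=None, derandomize=True)
@given(c=st.integers(1, 6), h=st.integers(2, 8), w=st.integers(2, 8),
       seed=st.integers(0, 100))
def test_masks_strictly_inside_unit_interval(c, h, w, seed):
    """Sigmoid gates are strictly in (0,1); gating can only shrink magnitudes."""
    rng = np.random.default_rng(seed)
    f = Tensor(rng.standard_normal((1, c, h, w)) * 3)
    ca = ChannelAttention(c, reduction=4, rng=rng)
    sa = SpatialAttention(3, rng=rng)
    mask_c, fp = ca(f)
    mask_s, fd = sa(fp)
    for m in (mask_c.data, mask_s.data):
        assert np.all(m > 0.0) and np.all(m < 1.0)
    assert np.all(np.abs(fp.data) <= np.abs(f.data) + 1e-15)
    assert np.all(np.abs(fd.data) <= np.abs(fp.data) + 1e-15)
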
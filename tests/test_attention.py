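"""Attention and pyramid-pooling transforms against brute-force loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedceph.attention import (
    ChannelAttentionParams,
    SEParams,
    SPPConfig,
    SpatialAttentionParams,
    adaptive_avg_pool,
    apply_block,
    channel_attention,
    se_excite,
    se_squeeze,
    spatial_attention,
    spp_pool,
)

from oracles import (
    adaptive_avg_pool_loop,
    channel_attention_loop,
    se_excite_loop,
    se_squeeze_loop,
    spatial_attention_loop,
    spp_loop,
)


def _random_fmap(rng, c=None, h=None, w=None):
    c = c or int(rng.integers(1, 5))
    h = h or int(rng.integers(1, 10))
    w = w or int(rng.integers(1, 10))
    return rng.normal(0, 1, (c, h, w))


class TestChannelAttention:
    def test_zero_params_give_half(self, rng):
        f = _random_fmap(rng, c=4)
        p = ChannelAttentionParams.zeros(4, reduction=2)
        assert np.allclose(channel_attention(f, p), 0.5)

    def test_constant_channels_collapse_pools(self, rng):
        v = rng.normal(0, 1, 3)
        f = np.broadcast_to(v[:, None, None], (3, 5, 6)).copy()
        p = ChannelAttentionParams.random(3, reduction=1, rng=rng)
        got = channel_attention(f, p)
        mlp = lambda x: p.w2 @ np.maximum(p.w1 @ x + p.b1, 0) + p.b2
        assert np.allclose(got, 1 / (1 + np.exp(-2 * mlp(v))))

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            f = _random_fmap(rng)
            p = ChannelAttentionParams.random(f.shape[0], reduction=1, rng=rng)
            np.testing.assert_allclose(
                channel_attention(f, p), channel_attention_loop(f, p), rtol=1e-6, atol=1e-12
            )

    def test_spatial_permutation_invariance(self, rng):
        f = _random_fmap(rng, c=3, h=6, w=6)
        p = ChannelAttentionParams.random(3, rng=rng)
        perm = rng.permutation(36)
        shuffled = f.reshape(3, 36)[:, perm].reshape(3, 6, 6)
        np.testing.assert_allclose(channel_attention(f, p), channel_attention(shuffled, p))

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            channel_attention(_random_fmap(rng, c=3), ChannelAttentionParams.zeros(4))


class TestSpatialAttention:
    def test_zero_kernel_gives_half(self, rng):
        f = _random_fmap(rng)
        out = spatial_attention(f, SpatialAttentionParams.zeros())
        assert out.shape == f.shape[1:]
        assert np.allclose(out, 0.5)

    def test_shape_preserved(self, rng):
        for _ in range(10):
            f = _random_fmap(rng)
            p = SpatialAttentionParams.random(rng)
            assert spatial_attention(f, p).shape == f.shape[1:]

    def test_matches_loop_oracle(self, rng):
        for _ in range(30):
            f = _random_fmap(rng, h=int(rng.integers(2, 10)), w=int(rng.integers(2, 10)))
            p = SpatialAttentionParams.random(rng)
            np.testing.assert_allclose(
                spatial_attention(f, p), spatial_attention_loop(f, p), rtol=1e-6, atol=1e-12
            )

    def test_translation_equivariance_interior(self, rng):
        f = _random_fmap(rng, c=2, h=20, w=20)
        p = SpatialAttentionParams.random(rng)
        shifted = np.roll(f, (2, 3), axis=(1, 2))
        a, b = spatial_attention(f, p), spatial_attention(shifted, p)
        # compare interior pixels only (7-pixel frame covers roll + kernel reach)
        np.testing.assert_allclose(
            np.roll(a, (2, 3), axis=(0, 1))[7:-7, 7:-7], b[7:-7, 7:-7], rtol=1e-9
        )

    def test_kernel_shape_enforced(self):
        with pytest.raises(ValueError, match="7, 7"):
            SpatialAttentionParams(kernel=np.zeros((2, 5, 5)))


class TestSqueezeExcitation:
    def test_squeeze_is_spatial_mean(self, rng):
        f = np.full((2, 3, 4), 7.0)
        assert np.allclose(se_squeeze(f), 7.0)
        f2 = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert se_squeeze(f2)[0] == pytest.approx(2.5)

    def test_zero_params_give_half(self):
        p = SEParams.zeros(4, reduction=2)
        assert np.allclose(se_excite(np.zeros(4), p), 0.5)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            f = _random_fmap(rng)
            c = f.shape[0]
            p = SEParams.random(c, reduction=1, rng=rng)
            np.testing.assert_allclose(se_squeeze(f), se_squeeze_loop(f), rtol=1e-9, atol=1e-12)
            z = se_squeeze(f)
            np.testing.assert_allclose(
                se_excite(z, p), se_excite_loop(z, p), rtol=1e-6, atol=1e-12
            )


class TestApplyBlock:
    def test_half_attention_halves_map(self, rng):
        f = _random_fmap(rng, c=4)
        for block, kw in [
            ("ca", dict(ca=ChannelAttentionParams.zeros(4))),
            ("sa", dict(sa=SpatialAttentionParams.zeros())),
            ("se", dict(se=SEParams.zeros(4))),
        ]:
            np.testing.assert_allclose(apply_block(f, block, **kw), 0.5 * f)

    def test_se_saturation_identity_limit(self, rng):
        f = _random_fmap(rng, c=3)
        p = SEParams.zeros(3)
        p.b2[:] = 1e3  # sigmoid saturates to 1
        np.testing.assert_allclose(apply_block(f, "se", se=p), f)

    def test_sa_se_composes_standalone_ops(self, rng):
        f = _random_fmap(rng, c=3, h=8, w=8)
        sa = SpatialAttentionParams.random(rng)
        se = SEParams.random(3, reduction=1, rng=rng)
        composed = apply_block(f, "sa_se", sa=sa, se=se)
        step = apply_block(apply_block(f, "sa", sa=sa), "se", se=se)
        np.testing.assert_allclose(composed, step, rtol=1e-12)

    def test_missing_params_error(self, rng):
        with pytest.raises(ValueError, match="not initialized"):
            apply_block(_random_fmap(rng), "ca")

    def test_attention_values_in_open_unit_interval(self, rng):
        for _ in range(50):
            f = _random_fmap(rng)
            c = f.shape[0]
            ca = channel_attention(f, ChannelAttentionParams.random(c, rng=rng))
            sa = spatial_attention(f, SpatialAttentionParams.random(rng))
            se = se_excite(se_squeeze(f), SEParams.random(c, rng=rng))
            for vals in (ca, sa.ravel(), se):
                assert np.all(vals > 0) and np.all(vals < 1)


class TestSPP:
    def test_constant_map_pools_to_constant(self):
        f = np.full((2, 10, 13), 7.0)
        assert np.allclose(spp_pool(f), 7.0)

    def test_fixed_length_contract(self, rng):
        cfg = SPPConfig((4, 8, 16))
        a = spp_pool(rng.normal(0, 1, (2, 10, 10)), cfg)
        b = spp_pool(rng.normal(0, 1, (2, 13, 7)), cfg)
        assert a.shape == b.shape == (2 * 336,)

    def test_length_1024_channels(self):
        f = np.zeros((1024, 2, 2))
        assert spp_pool(f, SPPConfig((4, 8, 16))).shape == (344064,)

    def test_matches_bin_oracle(self, rng):
        for _ in range(60):
            f = _random_fmap(rng, h=int(rng.integers(1, 20)), w=int(rng.integers(1, 20)))
            sizes = (2, 3)
            np.testing.assert_allclose(
                spp_pool(f, SPPConfig(sizes)), spp_loop(f, sizes), rtol=1e-6, atol=1e-12
            )
            np.testing.assert_allclose(
                adaptive_avg_pool(f, 4, 5), adaptive_avg_pool_loop(f, 4, 5), rtol=1e-9
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        c=st.integers(1, 4),
        h=st.integers(1, 64),
        w=st.integers(1, 64),
        seed=st.integers(0, 10_000),
    )
    def test_output_length_property(self, c, h, w, seed):
        f = np.random.default_rng(seed).normal(0, 1, (c, h, w))
        cfg = SPPConfig((4, 8, 16))
        assert spp_pool(f, cfg).shape == (c * cfg.bins_per_channel,)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SPPConfig(())
        with pytest.raises(ValueError):
            SPPConfig((4, 4))
        with pytest.raises(ValueError):
            SPPConfig((8, 4))
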
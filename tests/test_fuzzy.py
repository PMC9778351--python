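"""Fuzzy entropy, membership heads and the two uncertainty-reduction blocks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fuzzyseg import (ChannelFuzzyBlock, SpatialFuzzyBlock, Tensor, channel_reduce,
                      channel_uncertainty, fuzzy_entropy, spatial_reduce,
                      spatial_uncertainty)
from fuzzyseg.fuzzy import MembershipHead

from conftest import random_memberships


def entropy_oracle(mu, base=np.e):
    """Scalar-loop reference: -(1/log C) * sum mu_r log mu_r, 0*log0 = 0."""
    c = len(mu)
    total = 0.0
    for m in mu:
        if m > 0:
            total += m * (np.log(m) / np.log(base))
    return -total / (np.log(c) / np.log(base))


class TestFuzzyEntropy:
    @pytest.mark.parametrize("c", [2, 3, 5])
    def test_uniform_membership_is_maximally_uncertain(self, c):
        assert fuzzy_entropy(np.full(c, 1.0 / c)) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("c", [2, 3, 5])
    def test_one_hot_membership_is_certain(self, c):
        v = np.zeros(c)
        v[0] = 1.0
        assert fuzzy_entropy(v) == 0.0

    def test_hand_computed_example(self):
        # Frozen from the scalar oracle: H([0.5, 0.25, 0.25]) with natural log.
        assert fuzzy_entropy(np.array([0.5, 0.25, 0.25])) == pytest.approx(0.946394630357186, abs=1e-12)

    def test_matches_scalar_oracle_and_base_invariance(self, rng):
        for mu in random_memberships(rng, 50, 4):
            h = fuzzy_entropy(mu)
            assert h == pytest.approx(entropy_oracle(mu), abs=1e-12)
            assert h == pytest.approx(entropy_oracle(mu, base=2), abs=1e-10)
            assert h == pytest.approx(entropy_oracle(mu, base=10), abs=1e-10)

    @given(st.integers(2, 6), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_bounds_property(self, c, seed):
        mu = random_memberships(np.random.default_rng(seed), 1, c)[0]
        assert 0.0 <= fuzzy_entropy(mu) <= 1.0

    def test_binary_symmetry(self, rng):
        for p in rng.uniform(0, 1, 20):
            assert fuzzy_entropy(np.array([p, 1 - p])) == pytest.approx(
                fuzzy_entropy(np.array([1 - p, p])), abs=1e-12)

    def test_rejects_invalid_memberships(self):
        with pytest.raises(ValueError):
            fuzzy_entropy(np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            fuzzy_entropy(np.array([1.5, -0.5]))
        with pytest.raises(ValueError):
            fuzzy_entropy(np.array([1.0]))

    def test_tensor_path_matches_numpy_path(self, rng):
        mu = random_memberships(rng, 30, 5)
        h_t = fuzzy_entropy(Tensor(mu), axis=-1).data
        np.testing.assert_allclose(h_t, fuzzy_entropy(mu), atol=1e-9)


class TestUncertaintyMaps:
    def test_uniform_everywhere_gives_all_ones(self):
        mu = np.full((3, 3, 4), 0.25)
        np.testing.assert_allclose(spatial_uncertainty(mu), 1.0, atol=1e-12)

    def test_one_hot_everywhere_gives_all_zeros(self):
        mu = np.zeros((3, 3, 4))
        mu[..., 2] = 1.0
        np.testing.assert_array_equal(spatial_uncertainty(mu), 0.0)

    def test_spatial_matches_per_pixel_loop(self, rng):
        mu = random_memberships(rng, 9, 5).reshape(3, 3, 5)
        u = spatial_uncertainty(mu)
        for i in range(3):
            for j in range(3):
                assert u[i, j] == pytest.approx(entropy_oracle(mu[i, j]), abs=1e-12)

    def test_channel_matches_per_row_loop(self, rng):
        pi = random_memberships(rng, 8, 3)
        h = channel_uncertainty(pi)
        for j in range(8):
            assert h[j] == pytest.approx(entropy_oracle(pi[j]), abs=1e-12)


class TestReduction:
    def _conv(self, channels, seed):
        from fuzzyseg import nn
        return nn.Conv2d(channels, channels, 3, padding=1, rng=np.random.default_rng(seed))

    def test_zero_uncertainty_is_identity(self, rng):
        x = rng.normal(size=(2, 4, 5, 5))
        conv = self._conv(4, 0)
        out = spatial_reduce(Tensor(x), Tensor(np.zeros((2, 5, 5))), conv)
        np.testing.assert_array_equal(out.data, x)  # bit-exact
        out = channel_reduce(Tensor(x), Tensor(np.zeros(4)), conv)
        np.testing.assert_array_equal(out.data, x)

    def test_full_uncertainty_is_pure_convolution(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 5, 5)))
        conv = self._conv(4, 1)
        np.testing.assert_array_equal(
            spatial_reduce(x, Tensor(np.ones((2, 5, 5))), conv).data, conv(x).data)
        np.testing.assert_array_equal(
            channel_reduce(x, Tensor(np.ones(4)), conv).data, conv(x).data)

    def test_blend_matches_scalar_loop(self, rng):
        x = rng.normal(size=(2, 6, 5, 5))
        u = rng.uniform(0, 1, size=(2, 5, 5))
        h = rng.uniform(0, 1, size=(2, 6))
        conv = self._conv(6, 2)
        cx = conv(Tensor(x)).data
        out_s = spatial_reduce(Tensor(x), Tensor(u), conv).data
        out_c = channel_reduce(Tensor(x), Tensor(h), conv).data
        for n in range(2):
            for ch in range(6):
                for i in range(5):
                    for j in range(5):
                        w = u[n, i, j]
                        assert out_s[n, ch, i, j] == pytest.approx(
                            cx[n, ch, i, j] * w + x[n, ch, i, j] * (1 - w), abs=1e-5)
                        w = h[n, ch]
                        assert out_c[n, ch, i, j] == pytest.approx(
                            cx[n, ch, i, j] * w + x[n, ch, i, j] * (1 - w), abs=1e-5)

    def test_shape_mismatch_raises(self, rng):
        conv = self._conv(4, 3)
        with pytest.raises(ValueError):
            spatial_reduce(Tensor(rng.normal(size=(1, 4, 5, 5))),
                           Tensor(np.zeros((4, 4))), conv)
        with pytest.raises(ValueError):
            channel_reduce(Tensor(rng.normal(size=(1, 4, 5, 5))),
                           Tensor(np.zeros(3)), conv)


class TestMembershipHead:
    def test_outputs_are_probability_vectors(self, rng):
        head = MembershipHead(8, 5, rng)
        mu = head(Tensor(rng.normal(size=(2, 8, 4, 4)).astype(np.float32)))
        assert mu.shape == (2, 5, 4, 4)
        assert mu.data.min() >= 0 and mu.data.max() <= 1
        np.testing.assert_allclose(mu.data.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_uniform_memberships(self, rng):
        head = MembershipHead(8, 5, rng)
        for p in head.parameters():
            p.data = np.zeros_like(p.data)
        mu = head(Tensor(rng.normal(size=(1, 8, 3, 3)).astype(np.float32)))
        np.testing.assert_allclose(mu.data, 0.2, atol=1e-7)

    def test_channel_mismatch_raises(self, rng):
        head = MembershipHead(8, 5, rng)
        with pytest.raises(ValueError):
            head(Tensor(rng.normal(size=(1, 6, 4, 4))))


class TestBlocks:
    def test_spatial_block_composition_matches_suboperations(self, rng):
        block = SpatialFuzzyBlock(6, 5, rng)
        x = Tensor(rng.normal(size=(2, 6, 5, 5)).astype(np.float32))
        out, u = block(x)
        mu = block.membership(x)
        u_ref = spatial_uncertainty(mu.data)
        np.testing.assert_allclose(u.data, u_ref, atol=1e-6)
        ref = spatial_reduce(x, Tensor(u_ref.astype(np.float32)), block.reduce_conv)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-5)
        assert out.shape == x.shape

    def test_channel_block_composition_matches_suboperations(self, rng):
        block = ChannelFuzzyBlock(6, 5, (5, 5), rng)
        x = Tensor(rng.normal(size=(2, 6, 5, 5)).astype(np.float32))
        out, h = block(x)
        pi = block.memberships(x)
        assert pi.shape == (2, 6, 5)
        np.testing.assert_allclose(pi.data.sum(axis=-1), 1.0, atol=1e-6)
        h_ref = channel_uncertainty(pi.data)
        np.testing.assert_allclose(h.data, h_ref, atol=1e-6)
        ref = channel_reduce(x, Tensor(h_ref.astype(np.float32)), block.reduce_conv)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-5)
        assert out.shape == x.shape

    def test_channel_block_wrong_resolution_is_hard_error(self, rng):
        block = ChannelFuzzyBlock(6, 5, (8, 8), rng)
        with pytest.raises(ValueError, match="spatial size"):
            block(Tensor(rng.normal(size=(1, 6, 4, 4))))

    def test_forced_certain_memberships_make_block_identity(self, rng):
        # Huge first-layer bias -> saturated sigmoid -> one-hot softmax -> u = 0.
        block = SpatialFuzzyBlock(4, 5, rng)
        block.membership.conv2.weight.data[:] = 0.0
        block.membership.conv2.bias.data[:] = np.array([50.0, 0, 0, 0, 0], dtype=np.float32)
        x = rng.normal(size=(1, 4, 6, 6)).astype(np.float32)
        out, u = block(Tensor(x))
        np.testing.assert_allclose(u.data, 0.0, atol=1e-6)
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_all_block_parameters_receive_gradient(self, rng):
        for block in (SpatialFuzzyBlock(5, 4, rng), ChannelFuzzyBlock(5, 4, (6, 6), rng)):
            x = Tensor(rng.normal(size=(2, 5, 6, 6)).astype(np.float32), requires_grad=True)
            out, w = block(x)
            (out.pow(2).sum() + w.sum()).backward()
            for name, p in block.named_parameters():
                assert p.grad is not None and np.any(p.grad != 0), name
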
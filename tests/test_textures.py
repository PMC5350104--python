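"""Texture synthesis: parity constraints, blur, probes, ensemble statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from glidernet import textures as tx


class TestGliderParity:
    @pytest.mark.parametrize("cname", tx.CORRELATED_CLASSES)
    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_every_placement_satisfies_parity(self, cname, seed):
        spec = tx.GLIDER_LIBRARY[cname]
        grids = tx.generate_ensemble(cname, 20, seed)
        # glider_products averages over placements; all-ones iff every
        # placement has the target parity
        assert np.all(tx.glider_products(grids, spec) == spec.parity)

    def test_even_odd_two_by_two_products(self):
        even = tx.generate_texture("even", 3).grid.astype(int)
        odd = tx.generate_texture("odd", 3).grid.astype(int)
        for g, parity in ((even, 1), (odd, -1)):
            prods = g[:-1, :-1] * g[:-1, 1:] * g[1:, :-1] * g[1:, 1:]
            assert prods.shape == (15, 15)
            assert np.all(prods == parity)

    def test_same_seed_reproduces_identically(self):
        a = tx.generate_texture("wye", 42)
        b = tx.generate_texture("wye", 42)
        assert np.array_equal(a.grid, b.grid)

    def test_unknown_class_raises(self):
        with pytest.raises(KeyError, match="unknown texture class"):
            tx.generate_texture("stripes", 0)

    @given(seed=st.integers(0, 2**31 - 1), cname=st.sampled_from(tx.CORRELATED_CLASSES))
    @settings(max_examples=30, deadline=None)
    def test_parity_holds_for_arbitrary_seeds(self, seed, cname):
        spec = tx.GLIDER_LIBRARY[cname]
        grid = tx.generate_ensemble(cname, 1, seed)
        assert np.all(tx.glider_products(grid, spec) == spec.parity)

    def test_custom_glider_requires_origin_and_distinct_offsets(self):
        with pytest.raises(ValueError):
            tx.GliderSpec("custom", ((0, 1), (1, 0)), 1)
        with pytest.raises(ValueError):
            tx.GliderSpec("custom", ((0, 0), (0, 0)), 1)


class TestLowpass:
    def test_uniform_texture_maps_to_uniform_frame(self):
        frame = tx.lowpass(np.ones((16, 16)))
        assert np.allclose(frame, 1.0)
        assert np.allclose(tx.lowpass(-np.ones((16, 16))), 0.0)

    def test_impulse_response_is_normalized_gaussian_kernel(self):
        # reflect padding is irrelevant for a centred impulse on a large grid
        grid = np.zeros((33, 33))
        grid[16, 16] = 1.0
        resp = tx.lowpass(grid, sigma=2.0, remap=False)
        radius = int(4 * 2.0 + 0.5)
        x = np.arange(-radius, radius + 1)
        k = np.exp(-(x**2) / (2 * 2.0**2))
        k /= k.sum()
        expected = np.outer(k, k)
        window = resp[16 - radius : 16 + radius + 1, 16 - radius : 16 + radius + 1]
        assert np.allclose(window, expected, atol=1e-12)
        assert np.isclose(resp.sum(), 1.0)

    def test_blur_is_linear_pre_remap(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(16, 16))
        b = rng.normal(size=(16, 16))
        lhs = tx.lowpass(a, remap=False) + tx.lowpass(b, remap=False)
        rhs = tx.lowpass(a + b, remap=False) + tx.lowpass(np.zeros((16, 16)), remap=False)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_class_means_agree_after_blur(self):
        # blur is linear and both classes have vanishing first-order stats
        n = 4000
        even = tx.blur_ensemble(tx.generate_ensemble("even", n, 0)).mean(axis=0)
        rand = tx.blur_ensemble(tx.generate_ensemble("random", n, 1)).mean(axis=0)
        assert np.abs(even - rand).max() < 0.05

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            tx.lowpass(np.ones((16, 16)), sigma=0.0)


class TestOrientedNoise:
    def test_zero_angle_columns_constant_along_y(self):
        seq = tx.oriented_noise(0.0, seed=5)
        frame = seq.frames[0]
        assert np.allclose(frame, frame[0][None, :])

    def test_static_and_deterministic(self):
        a = tx.oriented_noise(40.0, seed=9)
        b = tx.oriented_noise(40.0, seed=9)
        assert np.array_equal(a.frames, b.frames)
        assert all(np.array_equal(a.frames[0], f) for f in a.frames)

    def test_ninety_degrees_matches_rotation_oracle(self):
        # at 90 deg the bilinear resampling grid lands on grid points, so the
        # pre-blur pattern must equal an exact quarter-turn of the 0-deg one
        rng_pattern = np.tile(
            np.random.default_rng(3).choice([-1.0, 1.0], size=16), (16, 1)
        )
        rotated = ndimage.rotate(
            rng_pattern, 90, reshape=False, order=1, mode="constant", cval=0.0
        )
        oracle = np.rot90(rng_pattern)
        assert np.allclose(rotated, oracle, atol=1e-12)
        # and the packaged probe at 90 deg has rows constant along x
        frame90 = tx.oriented_noise(90.0, seed=3).frames[0]
        assert np.allclose(frame90, frame90[:, :1], atol=1e-9)


class TestMotionSequences:
    def test_speed_zero_yields_identical_frames(self):
        for kind, direction in (("translation", "up"), ("rotation", "cw")):
            seq = tx.motion_sequence(kind, 0.0, direction, seed=2)
            assert all(np.array_equal(seq.frames[0], f) for f in seq.frames)

    def test_invalid_speed_and_kind_rejected(self):
        with pytest.raises(ValueError, match="speed"):
            tx.motion_sequence("translation", 3.0, "up", seed=0)
        with pytest.raises(ValueError, match="speed"):
            tx.motion_sequence("rotation", 5.0, "cw", seed=0)
        with pytest.raises(ValueError, match="kind"):
            tx.motion_sequence("looming", 1.0, "up", seed=0)

    def test_fastest_translation_decorrelates_frames(self):
        rs = []
        for seed in range(40):
            seq = tx.motion_sequence("translation", 16.0, "right", seed=seed)
            a, b = seq.frames[0].ravel(), seq.frames[1].ravel()
            rs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_cw_ccw_mirror_symmetry(self):
        canvas = tx.make_noise_canvas(seed=7)
        cw = tx.motion_sequence("rotation", 8.0, "cw", canvas=canvas)
        ccw = tx.motion_sequence("rotation", 8.0, "ccw", canvas=canvas[:, ::-1])
        for t in range(5):
            assert np.allclose(cw.frames[t][:, ::-1], ccw.frames[t], atol=1e-10)

    def test_translation_moves_window_across_canvas(self):
        canvas = tx.make_noise_canvas(seed=11)
        seq = tx.motion_sequence("translation", 2.0, "right", canvas=canvas)
        # frame t is the window at integer offset (t-2)*2: pure crops
        for t in range(5):
            off = (t - 2) * 2
            assert np.allclose(seq.frames[t], canvas[32:48, 32 + off : 48 + off])


class TestVerifyStatistics:
    def test_even_ensemble_statistics(self):
        rep = tx.verify_statistics(tx.generate_ensemble("even", 5000, 0))
        val, se = rep.glider_stats["even"]
        assert val == 1.0 and se == 0.0
        assert abs(rep.mean_stat) <= 4 * rep.mean_se
        for val, se in rep.pair_stats.values():
            assert (se == 0 and val == 0) or abs(val) <= 4 * se

    def test_triangle_parity_is_forced(self):
        rep = tx.verify_statistics(
            tx.generate_ensemble("white_triangle", 200, 1), specs=["white_triangle"]
        )
        assert rep.glider_stats["white_triangle"] == (1.0, 0.0)

    def test_random_ensemble_is_unstructured(self):
        rep = tx.verify_statistics(tx.generate_ensemble("random", 5000, 3))
        assert abs(rep.mean_stat) <= 4 * rep.mean_se
        for val, se in rep.pair_stats.values():
            assert abs(val) <= 4 * se
        for val, se in rep.glider_stats.values():
            assert abs(val) <= 4 * se

    def test_mixed_class_ensemble_rejected(self):
        texs = [tx.generate_texture("even", 0), tx.generate_texture("odd", 0)]
        with pytest.raises(ValueError, match="mixed"):
            tx.verify_statistics(texs)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tx.verify_statistics(np.empty((0, 16, 16)))


def test_stimulus_seed_streams_are_stable_and_distinct():
    a = tx.stimulus_seed(1, "train/even", 0).integers(0, 2**31, 4)
    b = tx.stimulus_seed(1, "train/even", 0).integers(0, 2**31, 4)
    c = tx.stimulus_seed(1, "test/even", 0).integers(0, 2**31, 4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
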
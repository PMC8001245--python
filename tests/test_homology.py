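import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis.extra import numpy as hnp

from bettipath import homology
from bettipath.imageops import binarize

from conftest import random_binary_images, random_gray_images
from oracles import betti_flood_fill, euler_bit_quads


def ring_mask(size=5):
    m = np.zeros((size, size), dtype=bool)
    m[1:-1, 1:-1] = True
    m[2:-2, 2:-2] = False
    return m


class TestBettiNumbers:
    def test_empty_foreground(self):
        assert tuple(homology.betti_numbers(np.zeros((6, 6), bool))) == (0, 0)

    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        assert tuple(homology.betti_numbers(m)) == (1, 0)

    def test_annulus(self):
        assert tuple(homology.betti_numbers(ring_mask(5))) == (1, 1)

    def test_two_disjoint_squares(self):
        m = np.zeros((9, 9), bool)
        m[0:3, 0:3] = True
        m[5:8, 5:8] = True
        assert tuple(homology.betti_numbers(m)) == (2, 0)

    def test_two_nested_separate_rings(self):
        """An 8x8 ring containing a smaller separate ring: verified against
        the independent flood-fill oracle, then frozen as (2, 2)."""
        m = np.zeros((8, 8), bool)
        m[0:8, 0:8] = True
        m[1:7, 1:7] = False  # outer ring of width 1
        m[2:6, 2:6] = True
        m[3:5, 3:5] = False  # inner ring of width 1
        assert betti_flood_fill(m) == (2, 2)
        assert tuple(homology.betti_numbers(m)) == (2, 2)

    def test_hole_open_to_border_is_not_a_hole(self):
        """A U-shape encloses nothing: its cavity reaches the border."""
        m = np.zeros((5, 5), bool)
        m[:, 0] = m[:, -1] = m[-1, :] = True
        assert tuple(homology.betti_numbers(m)) == (1, 0)

    def test_agrees_with_flood_fill_oracle_on_random_images(self):
        for mask in random_binary_images(300, max_side=64, seed=101):
            pair = homology.betti_numbers(mask)
            assert (pair.b0, pair.b1) == betti_flood_fill(mask)

    def test_euler_identity_on_random_images(self):
        """b0 - b1 equals the bit-quad Euler number (Gray's 8-connectivity
        formula) — only true under the dual connectivity pairing."""
        for mask in random_binary_images(300, max_side=64, seed=202):
            pair = homology.betti_numbers(mask)
            assert pair.b0 - pair.b1 == euler_bit_quads(mask)

    @given(hnp.arrays(np.bool_, (12, 12)))
    @settings(max_examples=100, deadline=None)
    def test_euler_identity_property(self, mask):
        pair = homology.betti_numbers(mask)
        assert pair.b0 - pair.b1 == euler_bit_quads(mask)


class TestSweep:
    def test_default_sweep_is_52_thresholds(self):
        sweep = homology.default_sweep()
        assert len(sweep) == 52
        assert sweep[:3] == (0, 5, 10)
        assert sweep[-3:] == (245, 250, 255)

    def test_make_sweep_always_ends_at_255(self):
        assert homology.make_sweep(0, 255, 15)[-1] == 255
        assert homology.make_sweep(0, 255, 5) == homology.default_sweep()

    def test_invalid_sweeps_rejected(self):
        with pytest.raises(ValueError):
            homology.betti_curve(np.zeros((4, 4), np.uint8), ())
        with pytest.raises(ValueError):
            homology.betti_curve(np.zeros((4, 4), np.uint8), (10, 5))
        with pytest.raises(ValueError):
            homology.betti_curve(np.zeros((4, 4), np.uint8), (0, 300))


class TestBettiCurve:
    def test_constant_black_image(self):
        curve = homology.betti_curve(np.zeros((8, 8), np.uint8))
        assert all(b0 == 1 for b0 in curve.b0_values)
        assert all(b1 == 0 for b1 in curve.b1_values)

    def test_constant_white_image(self):
        curve = homology.betti_curve(np.full((8, 8), 255, np.uint8))
        assert curve.b0_values[:-1] == (0,) * 51 and curve.b0_values[-1] == 1
        assert curve.b1_values == (0,) * 52

    def test_three_gray_disks_on_white(self):
        """Three disjoint gray-50 disks: b0 = 3 throughout [50, 254], b1 = 0,
        cross-checked against the flood-fill oracle at every threshold."""
        img = np.full((64, 64), 255, np.uint8)
        yy, xx = np.mgrid[0:64, 0:64]
        for cy, cx in [(14, 14), (14, 48), (48, 30)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= 36] = 50
        curve = homology.betti_curve(img)
        for t, b0, b1 in zip(curve.thresholds, curve.b0_values, curve.b1_values):
            assert (b0, b1) == betti_flood_fill(binarize(img, t))
            if 50 <= t <= 254:
                assert (b0, b1) == (3, 0)

    def test_all_foreground_at_final_threshold(self):
        for img in random_gray_images(10, side=24, seed=7):
            curve = homology.betti_curve(img, (120, 255))
            assert curve.b0_values[-1] == 1 and curve.b1_values[-1] == 0

    @pytest.mark.parametrize(
        "transform",
        [np.flipud, np.fliplr, np.rot90, lambda a: np.rot90(a, 2)],
        ids=["vflip", "hflip", "rot90", "rot180"],
    )
    def test_topological_invariance(self, transform):
        """Betti curves are exactly invariant under flips and rotations."""
        sweep = homology.make_sweep(0, 255, 15)
        for img in random_gray_images(25, side=40, seed=99):
            a = homology.betti_curve(img, sweep)
            b = homology.betti_curve(np.ascontiguousarray(transform(img)), sweep)
            assert a.b0_values == b.b0_values
            assert a.b1_values == b.b1_values


class TestHomologyFeatures:
    def test_feature_vector_lengths(self):
        img = np.random.default_rng(0).integers(0, 256, (128, 128)).astype(np.uint8)
        one = homology.homology_features(img, [(128, 128)])
        assert one.shape == (104,)  # 2 x 52
        four = homology.homology_features(
            img, [(128, 128), (64, 64), (32, 32), (16, 16)]
        )
        assert four.shape == (416,)  # 2 x 52 x 4

    def test_native_scale_prefix_matches_betti_curve(self):
        img = np.random.default_rng(1).integers(0, 256, (32, 32)).astype(np.uint8)
        vec = homology.homology_features(img, [(32, 32), (16, 16)])
        curve = homology.betti_curve(img)
        assert (vec[:52] == np.array(curve.b0_values)).all()
        assert (vec[52:104] == np.array(curve.b1_values)).all()

    def test_feature_names_align_and_encode_metadata(self):
        scales = [(64, 64), (32, 32)]
        sweep = homology.make_sweep(0, 255, 85)
        names = homology.homology_feature_names(scales, sweep)
        img = np.random.default_rng(2).integers(0, 256, (64, 64)).astype(np.uint8)
        vec = homology.homology_features(img, scales, sweep)
        assert len(names) == len(vec)
        assert names[0] == "HI_s64_t0_b0"
        assert "HI_s32_t170_b1" in names

    def test_scale_degeneracy_of_constant_image(self):
        img = np.full((64, 64), 90, np.uint8)
        vec = homology.homology_features(img, [(64, 64), (32, 32), (16, 16)])
        per_scale = vec.reshape(3, -1)
        assert (per_scale[0] == per_scale[1]).all()
        assert (per_scale[1] == per_scale[2]).all()

    def test_incompatible_scale_rejected(self):
        img = np.zeros((64, 64), np.uint8)
        with pytest.raises(ValueError, match="integer-factor"):
            homology.homology_features(img, [(48, 48)])
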
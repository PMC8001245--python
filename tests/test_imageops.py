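import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bettipath import imageops


class TestToGrayscale:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 255, 255), 255),  # white maps to white
            ((0, 0, 0), 0),  # black maps to black
            ((255, 0, 0), 76),  # pure red: round(0.299 * 255)
            ((0, 255, 0), 150),  # pure green: round(0.587 * 255)
            ((0, 0, 255), 29),  # pure blue: round(0.114 * 255)
        ],
    )
    def test_luma_of_uniform_image(self, rgb, expected):
        img = np.tile(np.array(rgb, dtype=np.uint8), (4, 5, 1))
        gray = imageops.to_grayscale(img)
        assert gray.shape == (4, 5)
        assert gray.dtype == np.uint8
        assert (gray == expected).all()

    def test_rejects_non_three_channel(self):
        with pytest.raises(ValueError, match="RGB"):
            imageops.to_grayscale(np.zeros((4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="RGB"):
            imageops.to_grayscale(np.zeros((4, 4, 4), dtype=np.uint8))

    @given(hnp.arrays(np.uint8, (6, 7)))
    @settings(max_examples=25, deadline=None)
    def test_identity_on_replicated_gray(self, gray):
        """A gray image replicated to 3 channels converts back to itself."""
        rgb = np.stack([gray] * 3, axis=-1)
        assert (imageops.to_grayscale(rgb) == gray).all()


class TestBinarize:
    def test_trivial_conventions(self):
        white = np.full((5, 5), 255, dtype=np.uint8)
        assert not imageops.binarize(white, 0).any()  # no pixel <= 0
        assert imageops.binarize(white, 255).all()  # every value <= 255
        field = np.full((6, 6), 255, dtype=np.uint8)
        field[2, 3] = 5
        mask = imageops.binarize(field, 10)
        assert mask.sum() == 1 and mask[2, 3]

    def test_threshold_out_of_range(self):
        img = np.zeros((3, 3), dtype=np.uint8)
        for t in (-1, 256):
            with pytest.raises(ValueError, match="threshold"):
                imageops.binarize(img, t)

    @given(
        hnp.arrays(np.uint8, (8, 8)),
        st.integers(0, 255),
        st.integers(0, 255),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, img, t1, t2):
        """The foreground mask grows monotonically with the threshold."""
        lo, hi = min(t1, t2), max(t1, t2)
        m_lo = imageops.binarize(img, lo)
        m_hi = imageops.binarize(img, hi)
        assert (m_hi | m_lo == m_hi).all()  # m_lo subset of m_hi


class TestDownsample:
    def test_constant_image_stays_constant(self):
        img = np.full((1024, 1024), 128, dtype=np.uint8)
        out = imageops.downsample(img, (512, 512))
        assert out.shape == (512, 512)
        assert (out == 128).all()

    def test_round_half_up_block_mean(self):
        img = np.array([[0, 0], [255, 255]], dtype=np.uint8)
        assert imageops.downsample(img, (1, 1))[0, 0] == 128  # round(127.5) up

    def test_factor_eight_public_resolution(self):
        img = np.zeros((768, 768), dtype=np.uint8)
        assert imageops.downsample(img, (96, 96)).shape == (96, 96)

    def test_rejects_non_integer_factor(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        with pytest.raises(ValueError, match="integer-factor"):
            imageops.downsample(img, (3, 3))

    def test_preserves_global_mean_within_rounding(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        for target in [(32, 32), (16, 16), (8, 8)]:
            out = imageops.downsample(img, target)
            assert abs(float(out.mean()) - float(img.mean())) <= 0.5


class TestSplitDataset:
    def test_exact_sizes_private_style(self):
        ids = [f"img{i}" for i in range(94)]
        spec = imageops.split_dataset(ids, None, (50, 20, 24), seed=0)
        assert spec.sizes() == {"train": 50, "validation": 20, "test": 24}

    def test_exact_sizes_public_style(self):
        ids = [f"img{i}" for i in range(15000)]
        spec = imageops.split_dataset(ids, None, (9000, 3000, 3000), seed=0)
        assert spec.sizes() == {"train": 9000, "validation": 3000, "test": 3000}

    def test_deterministic_and_seed_sensitive(self):
        ids = [f"s{i}" for i in range(30)]
        a = imageops.split_dataset(ids, None, (20, 5, 5), seed=7)
        b = imageops.split_dataset(ids, None, (20, 5, 5), seed=7)
        c = imageops.split_dataset(ids, None, (20, 5, 5), seed=8)
        assert a.assignment == b.assignment
        assert a.assignment != c.assignment

    def test_counts_must_sum_to_total(self):
        with pytest.raises(ValueError, match="sum"):
            imageops.split_dataset(["a", "b"], None, (2, 1, 0), seed=0)

    def test_stratified_keeps_all_classes_everywhere(self):
        ids = [f"s{i}" for i in range(60)]
        labels = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        spec = imageops.split_dataset(ids, labels, (30, 15, 15), seed=1, stratify=True)
        assert spec.sizes() == {"train": 30, "validation": 15, "test": 15}
        by_label = dict(zip(ids, labels))
        for split in ("train", "validation", "test"):
            present = {by_label[sid] for sid in spec.ids_in(split)}
            assert present == {"a", "b", "c"}


class TestExtractPatches:
    def test_patch_geometry(self, rng):
        img = rng.integers(0, 256, (1600, 1200, 3)).astype(np.uint8)
        pset = imageops.extract_patches(img, 10, 1024, rng, parent_id="x")
        assert len(pset) == 10
        assert all(p.shape == (1024, 1024, 3) for p in pset.patches)
        assert pset.parent_id == "x"

    def test_empty_patchset(self, rng):
        img = np.zeros((8, 8, 3), dtype=np.uint8)
        assert len(imageops.extract_patches(img, 0, 4, rng)) == 0

    def test_single_valid_corner_equals_source_up_to_flips(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        pset = imageops.extract_patches(img, 5, 16, rng)
        for patch, (vflip, hflip) in zip(pset.patches, pset.flips):
            expected = img
            if vflip:
                expected = expected[::-1]
            if hflip:
                expected = expected[:, ::-1]
            assert (patch == expected).all()

    def test_deterministic_under_fixed_rng(self):
        img = np.random.default_rng(3).integers(0, 256, (64, 64, 3)).astype(np.uint8)
        a = imageops.extract_patches(img, 6, 32, np.random.default_rng(5))
        b = imageops.extract_patches(img, 6, 32, np.random.default_rng(5))
        assert a.corners == b.corners and a.flips == b.flips
        assert all((pa == pb).all() for pa, pb in zip(a.patches, b.patches))

    def test_oversized_patch_rejected(self, rng):
        with pytest.raises(ValueError, match="patch size"):
            imageops.extract_patches(np.zeros((8, 8, 3), np.uint8), 1, 9, rng)


class TestRoundTripIO:
    def test_png_round_trip(self, tmp_path, rng):
        img = rng.integers(0, 256, (20, 30, 3)).astype(np.uint8)
        path = tmp_path / "x.png"
        imageops.write_image(path, img)
        assert (imageops.read_image(path) == img).all()

    def test_split_manifest_round_trip(self, tmp_path):
        ids = [f"s{i}" for i in range(10)]
        spec = imageops.split_dataset(ids, None, (6, 2, 2), seed=0)
        labels = {sid: "classA" for sid in ids}
        path = tmp_path / "splits.csv"
        imageops.write_split_manifest(path, spec, labels)
        loaded, loaded_labels = imageops.read_split_manifest(path)
        assert loaded.assignment == spec.assignment
        assert loaded_labels == labels
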
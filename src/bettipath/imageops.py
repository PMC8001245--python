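"""Image primitives: grayscale conversion, binarization, downsampling,
dataset splitting and patch extraction.

All images are plain :class:`numpy.ndarray` objects — ``uint8`` arrays of
shape ``(H, W, 3)`` for RGB and ``(H, W)`` for grayscale; binary images are
boolean arrays.  The binarization convention used throughout the package is
**foreground = intensity <= threshold**: with H&E staining the structures of
interest (nuclei, dense chromatin) are the *dark* pixels, so sweeping the
threshold upward grows the foreground from the darkest structures outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "FOREGROUND_CONVENTION",
    "PatchSet",
    "SplitSpec",
    "binarize",
    "downsample",
    "extract_patches",
    "read_image",
    "read_split_manifest",
    "split_dataset",
    "to_grayscale",
    "write_image",
    "write_split_manifest",
]

#: The fixed foreground convention for every binary image in this package.
FOREGROUND_CONVENTION = "intensity <= threshold is foreground"

SPLIT_NAMES = ("train", "validation", "test")

# ITU-R BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; image pipelines conventionally round half up.
    return np.floor(x + 0.5)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit grayscale (BT.601 luma).

    Each output pixel is ``round(0.299 R + 0.587 G + 0.114 B)`` with
    round-half-up, clamped to [0, 255].

    Parameters
    ----------
    img
        ``(H, W, 3)`` uint8-compatible array.

    Returns
    -------
    ``(H, W)`` uint8 array.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB image, got shape {img.shape}"
        )
    gray = _round_half_up(img.astype(np.float64) @ _LUMA)
    return np.clip(gray, 0, 255).astype(np.uint8)


def binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    """Binarize a grayscale image: foreground where ``intensity <= threshold``.

    Dark tissue (low intensity) becomes foreground, so the mask is monotone
    non-decreasing in the threshold.
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    return img <= threshold


def downsample(img: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Downsample a grayscale image to ``target=(h, w)`` by block averaging.

    The source dimensions must be integer multiples of the target dimensions;
    each output pixel is the round-half-up mean of its source block.  This is
    deterministic and interpolation-free, which keeps the threshold-sweep
    topology reproducible.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    H, W = img.shape
    h, w = target
    if h < 1 or w < 1 or H % h or W % w:
        raise ValueError(
            f"target {target} is not an integer-factor reduction of {(H, W)}"
        )
    fh, fw = H // h, W // w
    if fh == 1 and fw == 1:
        return img.copy()
    blocks = img.astype(np.float64).reshape(h, fh, w, fw)
    return np.clip(_round_half_up(blocks.mean(axis=(1, 3))), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test assignment at the parent-image level."""

    assignment: Mapping[str, str]
    seed: int

    def __post_init__(self) -> None:
        bad = {s for s in self.assignment.values() if s not in SPLIT_NAMES}
        if bad:
            raise ValueError(f"unknown split names: {sorted(bad)}")

    def ids_in(self, split: str) -> list[str]:
        return [sid for sid, s in self.assignment.items() if s == split]

    def sizes(self) -> dict[str, int]:
        return {s: len(self.ids_in(s)) for s in SPLIT_NAMES}

    def __getitem__(self, sample_id: str) -> str:
        return self.assignment[sample_id]


def split_dataset(
    sample_ids: Sequence[str],
    labels: Sequence | None,
    counts: tuple[int, int, int],
    seed: int,
    stratify: bool = False,
) -> SplitSpec:
    """Randomly partition sample IDs into train/validation/test of exact sizes.

    The partition is a seeded uniform shuffle (unstratified by default); with
    ``stratify=True`` the requested counts are apportioned per class by
    largest remainder, which keeps every class represented in every split.
    Deterministic for a fixed seed.
    """
    sample_ids = list(sample_ids)
    n_train, n_val, n_test = counts
    if n_train + n_val + n_test != len(sample_ids):
        raise ValueError(
            f"counts {counts} sum to {n_train + n_val + n_test}, "
            f"but there are {len(sample_ids)} samples"
        )
    if any(c < 0 for c in counts):
        raise ValueError(f"counts must be nonnegative, got {counts}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    if not stratify:
        order = rng.permutation(len(sample_ids))
        for rank, idx in enumerate(order):
            if rank < n_train:
                split = "train"
            elif rank < n_train + n_val:
                split = "validation"
            else:
                split = "test"
            assignment[sample_ids[idx]] = split
    else:
        if labels is None:
            raise ValueError("stratified splitting requires labels")
        labels = list(labels)
        classes = sorted(set(map(str, labels)))
        by_class = {c: [i for i, l in enumerate(labels) if str(l) == c] for c in classes}
        quotas = _apportion({c: len(ix) for c, ix in by_class.items()}, counts)
        for c in classes:
            idx = np.array(by_class[c])[rng.permutation(len(by_class[c]))]
            qt, qv, _ = quotas[c]
            for rank, i in enumerate(idx):
                if rank < qt:
                    split = "train"
                elif rank < qt + qv:
                    split = "validation"
                else:
                    split = "test"
                assignment[sample_ids[i]] = split
    # Preserve input order in the mapping.
    assignment = {sid: assignment[sid] for sid in sample_ids}
    return SplitSpec(assignment=assignment, seed=seed)


def _apportion(
    class_sizes: Mapping[str, int], counts: tuple[int, int, int]
) -> dict[str, tuple[int, int, int]]:
    """Largest-remainder apportionment of split counts across classes."""
    total = sum(class_sizes.values())
    quotas = {c: [0, 0, 0] for c in class_sizes}
    for k, target in enumerate(counts):
        exact = {c: target * n / total for c, n in class_sizes.items()}
        base = {c: int(np.floor(v)) for c, v in exact.items()}
        short = target - sum(base.values())
        order = sorted(class_sizes, key=lambda c: (-(exact[c] - base[c]), c))
        for c in order[:short]:
            base[c] += 1
        for c in class_sizes:
            quotas[c][k] = base[c]
    # Clamp per-class totals (rounding across the three splits can overshoot
    # by at most the remainder structure; fix by trimming the test quota).
    for c, n in class_sizes.items():
        excess = sum(quotas[c]) - n
        for k in (2, 1, 0):
            take = min(excess, quotas[c][k])
            quotas[c][k] -= take
            excess -= take
    return {c: tuple(q) for c, q in quotas.items()}


@dataclass
class PatchSet:
    """Patches cut from one parent image, with their flip flags.

    Every patch inherits the parent's label and split assignment; splitting is
    always done at the parent-image level so no patch-level leakage can occur.
    """

    patches: list[np.ndarray] = field(default_factory=list)
    parent_id: str = ""
    corners: list[tuple[int, int]] = field(default_factory=list)
    flips: list[tuple[bool, bool]] = field(default_factory=list)  # (vertical, horizontal)

    def __len__(self) -> int:
        return len(self.patches)


def extract_patches(
    img: np.ndarray,
    n: int,
    size: int,
    rng: np.random.Generator,
    parent_id: str = "",
) -> PatchSet:
    """Randomly extract ``n`` square patches of side ``size`` with random flips.

    Top-left corners are sampled uniformly over all valid positions (patches
    may overlap); each patch is independently flipped vertically with
    probability 1/2 and horizontally with probability 1/2.  Deterministic for
    a fixed generator state.
    """
    img = np.asarray(img)
    H, W = img.shape[:2]
    if size > H or size > W:
        raise ValueError(f"patch size {size} exceeds image size {(H, W)}")
    out = PatchSet(parent_id=parent_id)
    for _ in range(n):
        r = int(rng.integers(0, H - size + 1))
        c = int(rng.integers(0, W - size + 1))
        patch = img[r : r + size, c : c + size].copy()
        vflip = bool(rng.random() < 0.5)
        hflip = bool(rng.random() < 0.5)
        if vflip:
            patch = patch[::-1]
        if hflip:
            patch = patch[:, ::-1]
        out.patches.append(np.ascontiguousarray(patch))
        out.corners.append((r, c))
        out.flips.append((vflip, hflip))
    return out


# ---------------------------------------------------------------------------
# I/O

def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF/JPEG image as an (H, W, 3) uint8 RGB array."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 2:  # grayscale file: replicate to 3 channels
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: only 8-bit images are supported, got {arr.dtype}")
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an image (RGB or grayscale uint8) as PNG."""
    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def write_split_manifest(path: str | Path, spec: SplitSpec, labels: Mapping[str, object]) -> None:
    """Write a split manifest CSV with columns sample_id, label, split."""
    df = pd.DataFrame(
        {
            "sample_id": list(spec.assignment),
            "label": [labels[sid] for sid in spec.assignment],
            "split": [spec.assignment[sid] for sid in spec.assignment],
        }
    )
    df.to_csv(path, index=False)


def read_split_manifest(path: str | Path) -> tuple[SplitSpec, dict[str, str]]:
    """Read a split manifest CSV; returns (SplitSpec, labels dict)."""
    df = pd.read_csv(path, dtype=str)
    spec = SplitSpec(assignment=dict(zip(df["sample_id"], df["split"])), seed=-1)
    return spec, dict(zip(df["sample_id"], df["label"]))
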
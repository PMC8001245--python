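"""Betti numbers of binary images and threshold-sweep Betti-curve features.

The core quantities are the first two Betti numbers of the foreground of a
binary image viewed as a 2-D cubical complex:

* ``b0`` — number of connected foreground components (8-connectivity);
* ``b1`` — number of holes: background components, under the dual
  4-connectivity, that do not reach the image border.

Sweeping the binarization threshold over 0, 5, ..., 250, 255 produces a pair
of integer curves ``b0(t)``, ``b1(t)`` per image — a filtration profile of
the tissue's dark structures (nuclei merge, lumina close) that is invariant
under flips and rotations.  Computing the curves at several block-averaged
resolutions and concatenating them gives the multiscale homology feature
vector ("HI" features).

The 8-connected-foreground / 4-connected-background pairing is the standard
digital-topology dual; it is exactly the convention under which the Euler
number ``b0 - b1`` is computable locally by bit-quad counting, which the test
suite uses as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imageops import binarize, downsample

__all__ = [
    "DEFAULT_SWEEP",
    "BettiPair",
    "betti_curve",
    "betti_numbers",
    "default_sweep",
    "homology_feature_names",
    "homology_features",
    "make_sweep",
]

# 8-connectivity structuring element for the foreground.
_CONN8 = np.ones((3, 3), dtype=bool)
# 4-connectivity for the background (dual pairing).
_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class BettiPair:
    """(b0, b1) of one binary image: components and enclosed holes."""

    b0: int
    b1: int

    def __iter__(self):
        return iter((self.b0, self.b1))


def default_sweep() -> tuple[int, ...]:
    """The standard threshold sweep 0, 5, 10, ..., 245, 250, 255 (52 values)."""
    return tuple(range(0, 251, 5)) + (255,)


DEFAULT_SWEEP: tuple[int, ...] = default_sweep()


def make_sweep(start: int = 0, stop: int = 255, step: int = 5) -> tuple[int, ...]:
    """Build a threshold sweep ``start, start+step, ..., <=stop`` plus 255.

    The final threshold 255 is always included so the sweep ends with the
    all-foreground image (where b0 == 1, b1 == 0 by construction).
    """
    if not (0 <= start <= stop <= 255) or step < 1:
        raise ValueError(f"invalid sweep parameters ({start}, {stop}, {step})")
    values = list(range(start, stop + 1, step))
    if values[-1] != 255:
        values.append(255)
    return tuple(values)


def _validate_sweep(sweep: Sequence[int]) -> tuple[int, ...]:
    sweep = tuple(int(t) for t in sweep)
    if not sweep:
        raise ValueError("threshold sweep must be non-empty")
    if any(not 0 <= t <= 255 for t in sweep):
        raise ValueError("thresholds must lie in [0, 255]")
    if any(b <= a for a, b in zip(sweep, sweep[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return sweep


def betti_numbers(mask: np.ndarray) -> BettiPair:
    """Betti numbers (b0, b1) of a boolean foreground mask.

    b0 counts 8-connected foreground components.  b1 counts holes: pad the
    image with a one-pixel background frame, label the background with
    4-connectivity, and subtract the single border-connected component.
    An empty foreground is valid and yields (0, 0).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D binary image, got shape {mask.shape}")
    _, b0 = ndimage.label(mask, structure=_CONN8)
    padded = np.pad(mask, 1, constant_values=False)
    _, n_bg = ndimage.label(~padded, structure=_CONN4)
    # The frame guarantees >=1 background component; the rest are holes.
    b1 = n_bg - 1 if n_bg >= 1 else 0
    return BettiPair(b0=int(b0), b1=int(b1))


@dataclass(frozen=True)
class BettiCurve:
    """Per-threshold (b0, b1) sequences for one image at one scale."""

    thresholds: tuple[int, ...]
    b0_values: tuple[int, ...]
    b1_values: tuple[int, ...]
    scale: tuple[int, int]

    def __post_init__(self) -> None:
        n = len(self.thresholds)
        if len(self.b0_values) != n or len(self.b1_values) != n:
            raise ValueError("Betti value sequences must align with thresholds")


def betti_curve(
    gray: np.ndarray, sweep: Sequence[int] = DEFAULT_SWEEP
) -> BettiCurve:
    """Compute the Betti curves of a grayscale image over a threshold sweep.

    For each threshold t the image is binarized (foreground = intensity <= t)
    and the Betti pair computed; output order follows the sweep.
    """
    sweep = _validate_sweep(sweep)
    gray = np.asarray(gray)
    b0s, b1s = [], []
    for t in sweep:
        pair = betti_numbers(binarize(gray, t))
        b0s.append(pair.b0)
        b1s.append(pair.b1)
    return BettiCurve(
        thresholds=sweep,
        b0_values=tuple(b0s),
        b1_values=tuple(b1s),
        scale=(int(gray.shape[0]), int(gray.shape[1])),
    )


def homology_feature_names(
    scales: Sequence[tuple[int, int]], sweep: Sequence[int] = DEFAULT_SWEEP
) -> list[str]:
    """Feature names for :func:`homology_features` (scale-major order).

    Names look like ``HI_s512_t135_b1``: method prefix, scale (the height of
    the square working resolution), threshold, Betti index.
    """
    sweep = _validate_sweep(sweep)
    names = []
    for h, w in scales:
        tag = f"s{h}" if h == w else f"s{h}x{w}"
        for b in (0, 1):
            for t in sweep:
                names.append(f"HI_{tag}_t{t}_b{b}")
    return names


def homology_features(
    gray: np.ndarray,
    scales: Sequence[tuple[int, int]],
    sweep: Sequence[int] = DEFAULT_SWEEP,
) -> np.ndarray:
    """Multiscale Betti-curve feature vector.

    For each scale in order the image is block-average downsampled, the Betti
    curves computed, and the b0 then b1 sequences appended.  The result has
    length ``2 * len(sweep) * len(scales)``; names from
    :func:`homology_feature_names` align with it.
    """
    if not scales:
        raise ValueError("at least one scale is required")
    sweep = _validate_sweep(sweep)
    parts: list[np.ndarray] = []
    for scale in scales:
        at_scale = downsample(np.asarray(gray), tuple(scale))
        curve = betti_curve(at_scale, sweep)
        parts.append(np.asarray(curve.b0_values, dtype=np.float64))
        parts.append(np.asarray(curve.b1_values, dtype=np.float64))
    return np.concatenate(parts)
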
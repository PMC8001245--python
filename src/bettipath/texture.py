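"""Radiomics-style texture features on grayscale images.

Implements the six standard texture families directly, following the
IBSI-consistent feature definitions used by common radiomics toolkits:

========================================  =====
First Order statistics                      18
Gray Level Co-occurrence Matrix (GLCM)      23
Gray Level Run Length Matrix (GLRLM)        16
Gray Level Size Zone Matrix (GLSZM)         16
Gray Level Dependence Matrix (GLDM)         14
Neighboring Gray Tone Difference (NGTDM)     5
========================================  =====

for a total of 92 named features per scale.  The whole image is the region
of interest.  Gray levels are discretized with a fixed bin width (default
25 intensity units), matrix features use distance 1 and, for the directed
matrices (GLCM, GLRLM), the four 2-D directions with feature values averaged
over directions; GLCM matrices are symmetrized.

Degenerate (constant) images are well defined everywhere: variance-normalized
quantities fall back to fixed conventions (e.g. GLCM Correlation = 1,
First Order Skewness = 0) rather than dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .imageops import downsample

__all__ = [
    "FAMILY_COUNTS",
    "TextureConfig",
    "multiscale_texture",
    "texture_feature_names",
    "texture_features",
]

FAMILY_COUNTS = {
    "firstorder": 18,
    "glcm": 23,
    "glrlm": 16,
    "glszm": 16,
    "gldm": 14,
    "ngtdm": 5,
}

_EPS = np.finfo(np.float64).tiny

# Distance-1 2-D directions (the symmetric complements are implied).
_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass(frozen=True)
class TextureConfig:
    """Discretization and neighborhood settings for texture extraction."""

    bin_width: int = 25
    glcm_distance: int = 1
    directions: tuple[tuple[int, int], ...] = _DIRECTIONS

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        if not self.directions:
            raise ValueError("at least one direction is required")


def _discretize(img: np.ndarray, bin_width: int) -> tuple[np.ndarray, int]:
    """Map intensities to consecutive gray levels 1..Ng with fixed bin width.

    Level = floor(x / w) - floor(min / w) + 1; empty intermediate bins are
    kept so that level differences remain proportional to intensity
    differences.
    """
    img = np.asarray(img, dtype=np.float64)
    lo = np.floor(img.min() / bin_width)
    levels = (np.floor(img / bin_width) - lo + 1).astype(np.int64)
    return levels, int(levels.max())


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# First Order (18)

def _first_order(img: np.ndarray, cfg: TextureConfig) -> dict[str, float]:
    x = np.asarray(img, dtype=np.float64).ravel()
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if var > 0:
        m2 = var
        m3 = ((x - mean) ** 3).mean()
        m4 = ((x - mean) ** 4).mean()
        skew = m3 / m2**1.5
        kurt = m4 / m2**2  # non-excess (Fisher-uncorrected) kurtosis
    else:
        skew = 0.0
        kurt = 0.0
    levels, _ = _discretize(x, cfg.bin_width)
    p_hist = np.bincount(levels)[1:].astype(np.float64)
    p_hist /= p_hist.sum()
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float((x**2).sum()),  # unit pixel spacing
        "Entropy": _entropy2(p_hist),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Variance": float(var),
        "Uniformity": float((p_hist**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLCM (23)

def _cooccurrence(levels: np.ndarray, ng: int, offset: tuple[int, int]) -> np.ndarray:
    dr, dc = offset
    H, W = levels.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    a = levels[r0:r1, c0:c1].ravel()
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    P = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(P, (a - 1, b - 1), 1.0)
    P += P.T  # symmetric
    s = P.sum()
    return P / s if s else P


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float((px * i).sum())
    uy = float((py * i).sum())
    sx = float(np.sqrt((px * (i - ux) ** 2).sum()))
    sy = float(np.sqrt((py * (i - uy) ** 2).sum()))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng, dtype=np.float64)  # |i-j| in 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), P)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, P)

    hxy = _entropy2(P.ravel())
    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy = np.outer(px, py)
    mask = (P > 0) | (pxy > 0)
    hxy1 = float(-(P[mask] * np.log2(pxy[mask] + _EPS)).sum())
    hxy2 = float(-(pxy[mask] * np.log2(pxy[mask] + _EPS)).sum())
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if sx > 0 and sy > 0:
        corr = (float((P * ii * jj).sum()) - ux * uy) / (sx * sy)
    else:
        corr = 1.0  # constant image: perfectly correlated by convention

    # Maximal correlation coefficient via the Q matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = px[:, None] * py[None, :]
        Pn = np.where(denom > 0, P / np.where(denom > 0, denom, 1.0), 0.0)
    Q = Pn @ P.T  # Q[i,j] = sum_k P(i,k) P(j,k) / (px(i) py(k))
    if ng >= 2:
        eig = np.linalg.eigvals(Q).real
        eig.sort()
        mcc = float(np.sqrt(np.clip(eig[-2], 0.0, 1.0)))
    else:
        mcc = 1.0

    da = float((p_diff * k_diff).sum())
    off = np.abs(ii - jj) > 0
    return {
        "Autocorrelation": float((P * ii * jj).sum()),
        "JointAverage": ux,
        "ClusterProminence": float((P * (ii + jj - ux - uy) ** 4).sum()),
        "ClusterShade": float((P * (ii + jj - ux - uy) ** 3).sum()),
        "ClusterTendency": float((P * (ii + jj - ux - uy) ** 2).sum()),
        "Contrast": float((P * (ii - jj) ** 2).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "Id": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": float(imc1),
        "Imc2": float(imc2),
        "InverseVariance": float((P[off] / (ii - jj)[off] ** 2).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(P.max()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float((P * (ii - ux) ** 2).sum()),
    }


def _glcm(levels: np.ndarray, ng: int, cfg: TextureConfig) -> dict[str, float]:
    per_dir = []
    d = cfg.glcm_distance
    for dr, dc in cfg.directions:
        P = _cooccurrence(levels, ng, (dr * d, dc * d))
        per_dir.append(_glcm_features_single(P))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM (16)

def _lines(levels: np.ndarray, direction: tuple[int, int]):
    """All maximal lattice lines of the image along a direction."""
    if direction == (0, 1):
        yield from levels
    elif direction == (1, 0):
        yield from levels.T
    elif direction == (1, 1):
        H, W = levels.shape
        for k in range(-(H - 1), W):
            yield np.diagonal(levels, offset=k)
    elif direction == (1, -1):
        yield from _lines(levels[:, ::-1], (1, 1))
    else:
        raise ValueError(f"unsupported direction {direction}")


def _run_length_matrix(levels: np.ndarray, ng: int, direction: tuple[int, int]) -> np.ndarray:
    max_run = max(levels.shape)
    P = np.zeros((ng, max_run), dtype=np.float64)
    for line in _lines(levels, direction):
        if line.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(line) != 0)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [line.size - 1]))
        run_levels = line[starts]
        run_lengths = ends - starts + 1
        np.add.at(P, (run_levels - 1, run_lengths - 1), 1.0)
    return P


def _glrlm_features_single(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    nr = P.sum()
    if nr == 0:
        return {k: 0.0 for k in _GLRLM_NAMES}
    ng, rmax = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    r = np.arange(1, rmax + 1, dtype=np.float64)[None, :]
    p = P / nr
    mu_i = float((p * i).sum())
    mu_r = float((p * r).sum())
    return {
        "ShortRunEmphasis": float((P / r**2).sum() / nr),
        "LongRunEmphasis": float((P * r**2).sum() / nr),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((P.sum(axis=1) ** 2).sum() / nr**2),
        "RunLengthNonUniformity": float((P.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / nr**2),
        "RunPercentage": float(nr / n_pixels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (r - mu_r) ** 2).sum()),
        "RunEntropy": _entropy2(p.ravel()),
        "LowGrayLevelRunEmphasis": float((P / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((P * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (i**2 * r**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * i**2 / r**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * r**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * i**2 * r**2).sum() / nr),
    }


_GLRLM_NAMES = tuple(_glrlm_features_single(np.ones((1, 1)), 1))


def _glrlm(levels: np.ndarray, ng: int, cfg: TextureConfig) -> dict[str, float]:
    per_dir = [
        _glrlm_features_single(_run_length_matrix(levels, ng, d), levels.size)
        for d in _DIRECTIONS
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM (16)

_CONN8 = np.ones((3, 3), dtype=bool)


def _size_zone_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    sizes_by_level: list[np.ndarray] = []
    max_size = 1
    for g in range(1, ng + 1):
        lab, n = ndimage.label(levels == g, structure=_CONN8)
        if n:
            sizes = np.bincount(lab.ravel())[1:]
            sizes_by_level.append(sizes)
            max_size = max(max_size, int(sizes.max()))
        else:
            sizes_by_level.append(np.empty(0, dtype=np.int64))
    P = np.zeros((ng, max_size), dtype=np.float64)
    for g, sizes in enumerate(sizes_by_level):
        if sizes.size:
            np.add.at(P, (g, sizes - 1), 1.0)
    return P


def _glszm(levels: np.ndarray, ng: int, cfg: TextureConfig) -> dict[str, float]:
    P = _size_zone_matrix(levels, ng)
    nz = P.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nz
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    return {
        "SmallAreaEmphasis": float((P / s**2).sum() / nz),
        "LargeAreaEmphasis": float((P * s**2).sum() / nz),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((P.sum(axis=1) ** 2).sum() / nz**2),
        "SizeZoneNonUniformity": float((P.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / nz**2),
        "ZonePercentage": float(nz / levels.size),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": _entropy2(p.ravel()),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# GLDM (14)

def _gldm(levels: np.ndarray, ng: int, cfg: TextureConfig, alpha: int = 0) -> dict[str, float]:
    H, W = levels.shape
    dep = np.ones(levels.shape, dtype=np.int64)  # the center counts as dependent
    for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)):
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        dep[r0:r1, c0:c1] += (np.abs(a - b) <= alpha)
    nd_max = int(dep.max())
    P = np.zeros((ng, nd_max), dtype=np.float64)
    np.add.at(P, (levels.ravel() - 1, dep.ravel() - 1), 1.0)
    nz = P.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nd_max + 1, dtype=np.float64)[None, :]
    p = P / nz
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "SmallDependenceEmphasis": float((P / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((P.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((P.sum(axis=0) ** 2).sum() / nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": _entropy2(p.ravel()),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM (5)

def _ngtdm(levels: np.ndarray, ng: int, cfg: TextureConfig) -> dict[str, float]:
    lv = levels.astype(np.float64)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    nbr_sum = ndimage.convolve(lv, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(np.ones_like(lv), kernel, mode="constant", cval=0.0)
    A = nbr_sum / nbr_cnt
    diff = np.abs(lv - A)
    n_i = np.bincount(levels.ravel(), minlength=ng + 1)[1:].astype(np.float64)
    s_i = np.bincount(levels.ravel(), weights=diff.ravel(), minlength=ng + 1)[1:]
    npix = levels.size
    p_i = n_i / npix
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1, dtype=np.float64)

    coarse_den = float((p_i * s_i).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6

    if ngp > 1:
        pi_, pj_ = np.meshgrid(p_i, p_i, indexing="ij")
        ii, jj = np.meshgrid(i, i, indexing="ij")
        both = (pi_ > 0) & (pj_ > 0)
        contrast = (
            float((pi_ * pj_ * (ii - jj) ** 2)[both].sum())
            / (ngp * (ngp - 1))
            * float(s_i.sum())
            / npix
        )
        busy_den = float(np.abs(ii * pi_ - jj * pj_)[both].sum())
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            cplx = np.abs(ii - jj) * (pi_ * s_i[:, None] + pj_ * s_i[None, :]) / (pi_ + pj_)
        complexity = float(cplx[both].sum()) / npix
        strength_num = float(((pi_ + pj_) * (ii - jj) ** 2)[both].sum())
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": float(busyness),
        "Coarseness": float(coarseness),
        "Complexity": float(complexity),
        "Contrast": float(contrast),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# Public surface

_FAMILY_FUNCS = {
    "glcm": _glcm,
    "glrlm": _glrlm,
    "glszm": _glszm,
    "gldm": _gldm,
    "ngtdm": _ngtdm,
}


def texture_features(
    img: np.ndarray,
    cfg: TextureConfig | None = None,
    families: Sequence[str] | None = None,
) -> dict[str, float]:
    """All 92 texture features of a grayscale image, as an ordered mapping.

    Keys are ``<family>_<FeatureName>`` (e.g. ``glcm_Contrast``); the order
    is family order (firstorder, glcm, glrlm, glszm, gldm, ngtdm) with the
    feature order fixed within each family.  ``families`` restricts
    extraction to a subset of families (e.g. ``["firstorder"]`` for a
    histogram-only baseline).
    """
    cfg = cfg or TextureConfig()
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError(f"expected a grayscale image of at least 2x2, got {img.shape}")
    wanted = tuple(families) if families is not None else tuple(FAMILY_COUNTS)
    unknown = set(wanted) - set(FAMILY_COUNTS)
    if unknown:
        raise ValueError(f"unknown texture families {sorted(unknown)}")
    out: dict[str, float] = {}
    if "firstorder" in wanted:
        for name, value in _first_order(img, cfg).items():
            out[f"firstorder_{name}"] = value
    needs_levels = [f for f in wanted if f != "firstorder"]
    if needs_levels:
        levels, ng = _discretize(img, cfg.bin_width)
        for family in needs_levels:
            for name, value in _FAMILY_FUNCS[family](levels, ng, cfg).items():
                out[f"{family}_{name}"] = value
    counts = {fam: sum(k.startswith(fam + "_") for k in out) for fam in wanted}
    expected = {fam: FAMILY_COUNTS[fam] for fam in wanted}
    assert counts == expected, f"feature family counts drifted: {counts}"
    return out


def texture_feature_names(
    scales: Sequence[tuple[int, int]] | None = None,
    cfg: TextureConfig | None = None,
    families: Sequence[str] | None = None,
) -> list[str]:
    """Stable feature names, optionally scale-prefixed for multiscale use."""
    base = list(
        texture_features(np.arange(16, dtype=np.uint8).reshape(4, 4), cfg, families)
    )
    if scales is None:
        return [f"TA_{n}" for n in base]
    names = []
    for h, w in scales:
        tag = f"s{h}" if h == w else f"s{h}x{w}"
        names.extend(f"TA_{tag}_{n}" for n in base)
    return names


def multiscale_texture(
    img: np.ndarray,
    scales: Sequence[tuple[int, int]],
    cfg: TextureConfig | None = None,
    families: Sequence[str] | None = None,
) -> np.ndarray:
    """Concatenated 92-feature blocks at each scale (scale-major order)."""
    if not scales:
        raise ValueError("at least one scale is required")
    parts = []
    for scale in scales:
        at_scale = downsample(np.asarray(img), tuple(scale))
        parts.append(
            np.fromiter(
                texture_features(at_scale, cfg, families).values(), dtype=np.float64
            )
        )
    return np.concatenate(parts)
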
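"""End-to-end study workflow: images -> feature tables -> model selection.

Glue over the core modules; this is what the CLI and the example scripts
call.  Feature tables are pandas DataFrames indexed by sample_id with one
named column per feature, one table per working resolution, written to CSV
on request.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import homology, pipeline, texture
from .imageops import SplitSpec, downsample, extract_patches, split_dataset, to_grayscale
from .synthdata import SyntheticDataset

__all__ = [
    "compute_feature_tables",
    "patchify",
    "run_study",
]

logger = logging.getLogger(__name__)

_METHOD_FAMILIES = {
    "HI": None,
    "TA": None,
    "TA-firstorder": ("firstorder",),
}


def compute_feature_tables(
    images: Sequence[np.ndarray],
    sample_ids: Sequence[str],
    method: str,
    scales: Sequence[tuple[int, int]],
    sweep: Sequence[int] = homology.DEFAULT_SWEEP,
    cfg: texture.TextureConfig | None = None,
) -> dict[tuple[int, int], pd.DataFrame]:
    """Per-scale feature tables for a set of RGB (or grayscale) images.

    ``method`` is ``"HI"`` (multiscale Betti curves), ``"TA"`` (all 92
    texture features) or ``"TA-firstorder"`` (the 18 first-order features
    only, a histogram baseline).  Returns ``{scale: DataFrame}`` with rows
    aligned on ``sample_ids`` across scales.
    """
    if method not in _METHOD_FAMILIES:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHOD_FAMILIES)}")
    families = _METHOD_FAMILIES[method]
    scales = [tuple(s) for s in scales]
    rows: dict[tuple[int, int], list[np.ndarray]] = {s: [] for s in scales}
    for img in images:
        img = np.asarray(img)
        gray = to_grayscale(img) if img.ndim == 3 else img
        for scale in scales:
            at_scale = downsample(gray, scale)
            if method == "HI":
                curve = homology.betti_curve(at_scale, sweep)
                vec = np.concatenate(
                    [
                        np.asarray(curve.b0_values, dtype=np.float64),
                        np.asarray(curve.b1_values, dtype=np.float64),
                    ]
                )
            else:
                vec = np.fromiter(
                    texture.texture_features(at_scale, cfg, families).values(),
                    dtype=np.float64,
                )
            rows[scale].append(vec)
    prefix = "TA" if method.startswith("TA") else "HI"
    tables = {}
    for scale in scales:
        if method == "HI":
            names = homology.homology_feature_names([scale], sweep)
        else:
            names = texture.texture_feature_names([scale], cfg, families)
        tables[scale] = pd.DataFrame(
            np.vstack(rows[scale]), index=list(sample_ids), columns=names
        )
        tables[scale].index.name = "sample_id"
    return tables


def patchify(
    images: Sequence[np.ndarray],
    sample_ids: Sequence[str],
    labels: Sequence,
    split: SplitSpec,
    n_patches: int,
    patch_size: int,
    seed: int,
) -> tuple[list[np.ndarray], list[str], dict[str, object], SplitSpec]:
    """Extract flip-augmented patches; each inherits its parent's label/split.

    Returns (patch images, patch ids, patch labels, patch-level SplitSpec).
    The split stays a parent-level partition — every patch of one parent
    lands in that parent's split, so no patch-level leakage is possible.
    """
    rng = np.random.default_rng(seed)
    patch_imgs: list[np.ndarray] = []
    patch_ids: list[str] = []
    patch_labels: dict[str, object] = {}
    assignment: dict[str, str] = {}
    for img, sid, label in zip(images, sample_ids, labels):
        pset = extract_patches(img, n_patches, patch_size, rng, parent_id=sid)
        for k, patch in enumerate(pset.patches):
            pid = f"{sid}#p{k}"
            patch_imgs.append(patch)
            patch_ids.append(pid)
            patch_labels[pid] = label
            assignment[pid] = split[sid]
    return patch_imgs, patch_ids, patch_labels, SplitSpec(assignment=assignment, seed=seed)


def run_study(
    dataset: SyntheticDataset,
    counts: tuple[int, int, int],
    method: str,
    scales: Sequence[tuple[int, int]],
    sweep: Sequence[int] = homology.DEFAULT_SWEEP,
    seed: int = 0,
    n_patches: int = 0,
    patch_size: int = 0,
    algorithms: Sequence[int] = tuple(range(8)),
) -> dict:
    """Full study on one dataset: split, (optional) patching, features,
    exhaustive search, test evaluation of the best-validation configuration.

    Returns a dict with the split, the ranked results, the tied-best
    configurations, and the evaluated winner (first tie in enumeration
    order), whose ``test_accuracy`` and ``confusion_matrix`` are filled.
    """
    split = split_dataset(dataset.sample_ids, dataset.labels, counts, seed)
    labels: Mapping[str, object] = dict(zip(dataset.sample_ids, dataset.labels))
    images, ids = dataset.images, dataset.sample_ids
    if n_patches:
        images, ids, labels, split = patchify(
            dataset.images, dataset.sample_ids, dataset.labels, split,
            n_patches, patch_size, seed + 1,
        )
    tables = compute_feature_tables(images, ids, method, scales, sweep)
    results = pipeline.grid_search(tables, labels, split, scales, seed, algorithms)
    ties = pipeline.top_ties(results)
    best = pipeline.evaluate(ties[0].config, tables, labels, split, seed)
    logger.info(
        "best config %s: val=%.4f test=%.4f",
        best.config.describe(), best.validation_accuracy, best.test_accuracy,
    )
    return {
        "split": split,
        "tables": tables,
        "results": results,
        "ties": ties,
        "best": best,
    }
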
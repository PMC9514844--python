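"""Probabilistic tract ROI definition and weighted metric extraction.

A tract ROI starts from a probabilistic atlas map thresholded at a minimum
probability (default 25%), is refined per participant to voxels whose
white-matter probability is at least 90%, and contributes a weighted tract
mean in which voxels with higher white-matter probability count more:

    mean = sum(w_i * x_i) / sum(w_i),  w_i = white-matter probability.

Because the refinement depends on each participant's segmentation, ROI
voxel counts differ across participants and are recorded alongside every
extracted mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biophysics import GridMismatchError, VoxelMap

logger = logging.getLogger("tractvelocity")


class MaskEmptyError(ValueError):
    """Thresholding or refinement left no voxels."""


class ExtractionError(ValueError):
    """A weighted mean could not be computed."""


@dataclass(frozen=True)
class BinaryMask:
    """Voxel index set over a reference grid (indices are 0-based, (n, 3) int)."""

    indices: np.ndarray
    grid_shape: tuple[int, int, int]
    source: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp).reshape(-1, 3)
        idx = np.unique(idx, axis=0)
        if idx.size and (idx.min() < 0 or np.any(idx.max(axis=0) >= self.grid_shape)):
            raise ValueError("voxel indices outside grid bounds")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return self.indices.shape[0]


@dataclass(frozen=True)
class WeightedMask:
    """Refined tract ROI: voxel indices with white-matter-probability weights."""

    indices: np.ndarray
    weights: np.ndarray
    grid_shape: tuple[int, int, int]
    min_wm: float
    source: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp).reshape(-1, 3)
        w = np.asarray(self.weights, dtype=float).reshape(-1)
        if idx.shape[0] != w.shape[0]:
            raise ValueError("indices and weights length mismatch")
        if w.size and w.min() < self.min_wm:
            raise ValueError("all weights must be >= the refinement threshold")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "weights", w)

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]


def _as_probability(values: np.ndarray) -> np.ndarray:
    """Auto-detect 0-100 vs 0-1 probability scale (values > 1 anywhere => percent)."""
    finite = values[np.isfinite(values)]
    if finite.size and finite.max() > 1.0:
        return values / 100.0
    return values


def threshold_atlas(
    atlas_prob: VoxelMap, min_prob: float = 0.25, name: str = "tract"
) -> BinaryMask:
    """Voxels whose atlas probability is at least ``min_prob`` (inclusive).

    ``min_prob = 0`` selects strictly positive voxels, which admits binary
    0/1 tract masks from non-probabilistic atlases.  Probabilities on a
    0-100 scale are detected and rescaled.
    """
    if not (0 <= min_prob <= 1):
        raise ValueError(f"min_prob must be in [0, 1], got {min_prob}")
    prob = _as_probability(atlas_prob.values)
    with np.errstate(invalid="ignore"):
        keep = (prob > 0) if min_prob == 0 else (prob >= min_prob)
    keep &= np.isfinite(prob)
    idx = np.argwhere(keep)
    if idx.shape[0] == 0:
        raise MaskEmptyError(
            f"tract '{name}': no atlas voxels at or above probability {min_prob}"
        )
    return BinaryMask(idx, atlas_prob.shape, source=name)


def refine_with_wm(
    mask: BinaryMask, wm_prob: VoxelMap, min_wm: float = 0.90
) -> WeightedMask:
    """Restrict a tract mask to a participant's white matter.

    Keeps mask voxels whose white-matter probability is >= ``min_wm``; the
    retained probabilities become the extraction weights.
    """
    if wm_prob.shape != mask.grid_shape:
        raise GridMismatchError(
            f"white-matter map shape {wm_prob.shape} != mask grid {mask.grid_shape}"
        )
    if not (0 <= min_wm <= 1):
        raise ValueError(f"min_wm must be in [0, 1], got {min_wm}")
    wm = _as_probability(wm_prob.values)
    vals = wm[tuple(mask.indices.T)]
    with np.errstate(invalid="ignore"):
        keep = np.isfinite(vals) & (vals >= min_wm)
    if not keep.any():
        raise MaskEmptyError(
            f"tract '{mask.source}': refinement at WM probability {min_wm} left no voxels"
        )
    return WeightedMask(
        mask.indices[keep], vals[keep], mask.grid_shape, min_wm, source=mask.source
    )


def weighted_tract_mean(metric: VoxelMap, wmask: WeightedMask) -> float:
    """Probability-weighted tract mean of a metric map.

    Non-finite metric voxels are excluded from numerator and denominator
    (count logged).
    """
    if metric.shape != wmask.grid_shape:
        raise GridMismatchError(
            f"metric map shape {metric.shape} != mask grid {wmask.grid_shape}"
        )
    if wmask.n_voxels == 0:
        raise ExtractionError("empty weighted mask")
    x = metric.values[tuple(wmask.indices.T)]
    finite = np.isfinite(x)
    n_excluded = int((~finite).sum())
    if n_excluded:
        logger.info(
            "weighted_tract_mean: excluded %d non-finite voxels in '%s'",
            n_excluded,
            wmask.source,
        )
    if not finite.any():
        raise ExtractionError(
            f"tract '{wmask.source}': all metric values within the mask are non-finite"
        )
    w = wmask.weights[finite]
    return float(np.dot(w, x[finite]) / w.sum())


def extract_cohort(
    participants: dict[str, dict[str, VoxelMap]],
    tracts: list[tuple[str, VoxelMap]],
    metrics: list[str],
    min_prob: float = 0.25,
    min_wm: float = 0.90,
    wm_key: str = "wm_prob",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Run the extraction loop over participants x tracts x metrics.

    ``participants`` maps participant id to a dict of metric maps that must
    include the white-matter probability map under ``wm_key``.  Returns a
    tidy table (participant_id, tract, metric, value, n_voxels) ordered by
    (participant, tract, metric), plus a dict of per-participant error
    messages for participants that were skipped; extraction continues for
    the others.
    """
    tract_masks = [
        (name, threshold_atlas(atlas, min_prob, name=name)) for name, atlas in tracts
    ]
    rows: list[dict] = []
    errors: dict[str, str] = {}
    for pid in sorted(participants):
        maps = participants[pid]
        missing = [k for k in [wm_key, *metrics] if k not in maps]
        if missing:
            errors[pid] = f"missing maps: {', '.join(missing)}"
            continue
        try:
            for tract_name, bmask in tract_masks:
                wmask = refine_with_wm(bmask, maps[wm_key], min_wm)
                for metric in metrics:
                    rows.append(
                        {
                            "participant_id": pid,
                            "tract": tract_name,
                            "metric": metric,
                            "value": weighted_tract_mean(maps[metric], wmask),
                            "n_voxels": wmask.n_voxels,
                        }
                    )
        except (MaskEmptyError, ExtractionError, GridMismatchError) as exc:
            errors[pid] = str(exc)
            rows = [r for r in rows if r["participant_id"] != pid]
    if errors:
        logger.warning(
            "extract_cohort: %d participant(s) skipped: %s",
            len(errors),
            "; ".join(f"{p} ({m})" for p, m in errors.items()),
        )
    df = pd.DataFrame(rows, columns=["participant_id", "tract", "metric", "value", "n_voxels"])
    df = df.sort_values(["participant_id", "tract", "metric"], kind="stable").reset_index(drop=True)
    return df, errors


def cohort_to_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy extraction table to one row per participant.

    Columns are named ``<tract>__<metric>`` plus ``<tract>__n_voxels``.
    """
    wide = long_df.pivot_table(
        index="participant_id", columns=["tract", "metric"], values="value"
    )
    wide.columns = [f"{t}__{m}" for t, m in wide.columns]
    nv = long_df.drop_duplicates(["participant_id", "tract"]).pivot(
        index="participant_id", columns="tract", values="n_voxels"
    )
    nv.columns = [f"{t}__n_voxels" for t in nv.columns]
    return wide.join(nv).reset_index()
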
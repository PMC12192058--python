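"""Micro-CT vascular segmentation and density quantification.

Contrast-perfused vasculature is isolated by a global intensity threshold;
thresholds picked independently by several raters are averaged into a
consensus value (their agreement summarised by an intraclass correlation
coefficient).  Vascular density is segmented vascular volume divided by the
volume of the region of interest, in 3D or on an extracted 2D plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import VolumeGrid

__all__ = [
    "ThresholdDecision",
    "segment_vasculature",
    "consensus_threshold",
    "uct_density",
    "plane_density",
]


@dataclass
class ThresholdDecision:
    """Per-rater thresholds and their consensus (arithmetic mean)."""

    rater_values: np.ndarray
    consensus: float
    icc: float | None = None


def segment_vasculature(volume: VolumeGrid, threshold: float) -> VolumeGrid:
    """Binary vascular mask: voxels with intensity >= threshold.

    The comparison is inclusive (>=); a threshold outside the intensity
    range only triggers a warning, the result is then full or empty.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = volume.data
    lo, hi = float(data.min()), float(data.max())
    if threshold > hi or threshold < lo:
        warnings.warn(
            f"threshold {threshold} outside the volume intensity range [{lo}, {hi}]"
        )
    return volume.like(data >= threshold)


def consensus_threshold(
    rater_values: np.ndarray | list[float],
    rater_table: pd.DataFrame | None = None,
) -> ThresholdDecision:
    """Average per-rater thresholds for one scan.

    ``rater_table`` (long format: columns rater, scan, threshold) may be
    supplied to quantify inter-rater agreement over the whole study with an
    ICC(2,1); the consensus itself only uses this scan's values.
    """
    vals = np.asarray(rater_values, dtype=float)
    if vals.size < 2:
        warnings.warn("single rater: consensus is a passthrough of that value")
    icc = None
    if rater_table is not None:
        from .stats import icc_two_way

        icc = icc_two_way(rater_table, rater_col="rater", item_col="scan", value_col="threshold")
    return ThresholdDecision(vals, float(vals.mean()), icc)


def uct_density(vascular: VolumeGrid, roi: VolumeGrid) -> float:
    """Segmented vascular volume within the ROI divided by ROI volume."""
    if not vascular.same_grid(roi):
        raise ValueError("vascular mask and ROI are not on the same grid")
    r = roi.data.astype(bool)
    n_roi = int(r.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    return float((vascular.data.astype(bool) & r).sum() / n_roi)


def plane_density(intensity_plane: np.ndarray, roi_plane: np.ndarray, threshold: float) -> float:
    """2D analogue: threshold an extracted intensity plane, then density in ROI."""
    roi = np.asarray(roi_plane, dtype=bool)
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    vasc = np.asarray(intensity_plane) >= threshold
    return float((vasc & roi).sum() / n_roi)
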
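"""Super-resolution ultrasound (ULM) reconstruction from microbubble detections.

Microbubbles (MBs) are localized frame by frame in the imaging plane; tracks
are reconstructed by gated frame-to-frame linking with a constant-velocity
prediction, a track needing at least three consecutive frames to count.
Because linking is gated by a maximum per-frame displacement, the system has
a hard velocity ceiling of ``gate x frame_rate`` — MBs moving faster than
that are never linked.  Accepted tracks are accumulated onto a fine pixel
grid; pixels crossed by more than one detection form the binary vascular
map, dilated to the estimated track diameter.  Image resolution is
estimated by Fourier ring correlation between two interleaved half-datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DetectionSequence",
    "Track",
    "SRUSImage",
    "link_detections",
    "max_detectable_velocity",
    "estimate_track_velocities",
    "sample_vessel_velocities",
    "mean_detections_per_frame",
    "render_srus_image",
    "frc_curve",
    "estimate_resolution_frc",
    "srus_density",
]

DEFAULT_FRAME_RATE_HZ = 54.0
DEFAULT_GATE_MM = 0.28
DEFAULT_PIXEL_UM = 22.6
DEFAULT_TRACK_DIAMETER_UM = 42.25
DEFAULT_COUNT_THRESHOLD = 1          # pixels kept when count strictly exceeds this
MIN_TRACK_FRAMES = 3


@dataclass
class DetectionSequence:
    """Frame-indexed 2D MB localizations (mm) at a fixed frame rate."""

    detections: pd.DataFrame        # columns: frame, x_mm, z_mm [, traj_id]
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    duration_s: float | None = None

    def __post_init__(self) -> None:
        need = {"frame", "x_mm", "z_mm"}
        if not need.issubset(self.detections.columns):
            raise ValueError(f"detection table needs columns {sorted(need)}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if len(self.detections) and (self.detections["frame"] < 0).any():
            raise ValueError("frame indices must be nonnegative")
        if self.duration_s is None and len(self.detections):
            self.duration_s = (self.detections["frame"].max() + 1) / self.frame_rate_hz

    def n_frames(self) -> int:
        if self.duration_s is None:
            return 0
        return int(round(self.duration_s * self.frame_rate_hz))

    def to_csv(self, path: str) -> None:
        self.detections.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> "DetectionSequence":
        return cls(pd.read_csv(path), frame_rate_hz=frame_rate_hz)


@dataclass
class Track:
    """One reconstructed MB trajectory (>= 3 consecutive frames)."""

    frames: np.ndarray              # (n,)
    positions_mm: np.ndarray        # (n, 2) — (x, z)
    frame_rate_hz: float
    vessel_label: str | None = None
    step_speeds_mm_s: np.ndarray = field(init=False)
    mean_speed_mm_s: float = field(init=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        steps = np.linalg.norm(np.diff(self.positions_mm, axis=0), axis=1)
        dt = np.diff(self.frames) / self.frame_rate_hz
        self.step_speeds_mm_s = steps / dt
        self.mean_speed_mm_s = float(self.step_speeds_mm_s.mean()) if len(steps) else 0.0

    def __len__(self) -> int:
        return len(self.frames)


def max_detectable_velocity(gate_mm: float = DEFAULT_GATE_MM,
                            frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> float:
    """Hard ceiling on reconstructable MB speed: gate x frame rate (mm/s).

    An MB moving faster covers more than the gating distance between
    consecutive frames and can never be linked into a track.
    """
    if gate_mm <= 0 or frame_rate_hz <= 0:
        raise ValueError("gate_mm and frame_rate_hz must be positive")
    return gate_mm * frame_rate_hz


class _ActiveTrack:
    __slots__ = ("frames", "positions", "last_frame")

    def __init__(self, frame: int, pos: np.ndarray):
        self.frames = [frame]
        self.positions = [pos]
        self.last_frame = frame

    def predict(self, frame: int) -> np.ndarray:
        if len(self.positions) == 1:
            return self.positions[-1]
        v = self.positions[-1] - self.positions[-2]   # per-frame displacement
        return self.positions[-1] + v * (frame - self.last_frame)

    def extend(self, frame: int, pos: np.ndarray) -> None:
        self.frames.append(frame)
        self.positions.append(pos)
        self.last_frame = frame


def _assign(pred: np.ndarray, last: np.ndarray, det: np.ndarray,
            pred_gate: float, abs_gate: float) -> list[tuple[int, int]]:
    """Globally optimal gated matching between predictions and detections.

    A link must lie within ``pred_gate`` of the constant-velocity prediction
    AND within ``abs_gate`` of the track's last position: the absolute
    displacement limit is what makes ``gate x frame_rate`` a hard speed cap.
    """
    if len(pred) == 0 or len(det) == 0:
        return []
    cost = np.linalg.norm(pred[:, None, :] - det[None, :, :], axis=2)
    disp = np.linalg.norm(last[:, None, :] - det[None, :, :], axis=2)
    ok = (cost <= pred_gate) & (disp <= abs_gate)
    big = 1e6
    rows, cols = linear_sum_assignment(np.where(ok, cost, big))
    return [(r, c) for r, c in zip(rows, cols) if ok[r, c]]


def link_detections(
    seq: DetectionSequence,
    gate_mm: float = DEFAULT_GATE_MM,
    min_len: int = MIN_TRACK_FRAMES,
    strict_gate_mm: float | None = None,
) -> list[Track]:
    """Link frame-wise detections into MB tracks.

    Two-pass gated assignment per frame with a constant-velocity prediction:
    established tracks (>= 2 points, so a velocity estimate exists) claim
    detections first under the strict gate; remaining tracks and detections
    are matched in a second pass under the full gate.  Unmatched detections
    seed new tracks; a track ends the first frame it finds no match (no
    frame gaps allowed).  Tracks shorter than ``min_len`` frames are
    discarded.
    """
    if strict_gate_mm is None:
        strict_gate_mm = gate_mm / 2.0
    df = seq.detections
    tracks: list[Track] = []
    active: list[_ActiveTrack] = []

    def finish(trk: _ActiveTrack) -> None:
        if len(trk.frames) >= min_len:
            tracks.append(
                Track(np.array(trk.frames), np.array(trk.positions), seq.frame_rate_hz)
            )

    if len(df) == 0:
        return tracks
    by_frame = {int(f): g[["x_mm", "z_mm"]].to_numpy(float) for f, g in df.groupby("frame")}
    for frame in range(int(df["frame"].min()), int(df["frame"].max()) + 1):
        det = by_frame.get(frame, np.empty((0, 2)))
        # drop tracks that missed the previous frame (consecutive-frames rule)
        for trk in active:
            if trk.last_frame < frame - 1:
                finish(trk)
        active = [t for t in active if t.last_frame >= frame - 1]

        unmatched_det = np.ones(len(det), dtype=bool)
        matched_trk: set[int] = set()
        # pass 1: confident (established) tracks, strict gate
        est = [i for i, t in enumerate(active) if len(t.frames) >= 2]
        if est:
            preds = np.array([active[i].predict(frame) for i in est])
            lasts = np.array([active[i].positions[-1] for i in est])
            for r, c in _assign(preds, lasts, det, strict_gate_mm, gate_mm):
                active[est[r]].extend(frame, det[c])
                matched_trk.add(est[r])
                unmatched_det[c] = False
        # pass 2: everything left, full gate
        rest = [i for i in range(len(active)) if i not in matched_trk]
        det_idx = np.flatnonzero(unmatched_det)
        if rest and len(det_idx):
            preds = np.array([active[i].predict(frame) for i in rest])
            lasts = np.array([active[i].positions[-1] for i in rest])
            for r, c in _assign(preds, lasts, det[det_idx], gate_mm, gate_mm):
                active[rest[r]].extend(frame, det[det_idx[c]])
                matched_trk.add(rest[r])
                unmatched_det[det_idx[c]] = False
        # close tracks that found nothing this frame
        survivors = []
        for i, trk in enumerate(active):
            if i in matched_trk:
                survivors.append(trk)
            else:
                finish(trk)
        active = survivors
        # new tracks from leftover detections
        for c in np.flatnonzero(unmatched_det):
            active.append(_ActiveTrack(frame, det[c]))
    for trk in active:
        finish(trk)
    return tracks


def estimate_track_velocities(track: Track, frame_rate_hz: float | None = None) -> tuple[np.ndarray, float]:
    """Per-step and mean speed (mm/s) from finite differences of positions."""
    if len(track) < 2:
        raise ValueError("velocity estimation needs a track of at least 2 points")
    if frame_rate_hz is not None and frame_rate_hz != track.frame_rate_hz:
        track = Track(track.frames, track.positions_mm, frame_rate_hz)
    return track.step_speeds_mm_s, track.mean_speed_mm_s


def sample_vessel_velocities(tracks: list[Track], k: int = 3) -> dict[str, float | None]:
    """Per-vessel-class mean speed from ``k`` vessels, or exclusion.

    Each labelled track stands for one vessel.  A class present with fewer
    than ``k`` distinct vessels is excluded (None) — mirroring the rule of
    dropping scans with fewer than three vessels of a type.
    """
    out: dict[str, float | None] = {}
    by_class: dict[str, list[Track]] = {}
    for t in tracks:
        if t.vessel_label is not None:
            by_class.setdefault(t.vessel_label, []).append(t)
    for cls, ts in by_class.items():
        if len(ts) < k:
            out[cls] = None
        else:
            speeds = sorted(t.mean_speed_mm_s for t in ts)[:k]
            out[cls] = float(np.mean(speeds))
    return out


def mean_detections_per_frame(total_detections: int, duration_s: float,
                              frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ) -> float:
    """Total detections divided by total frames (duration x frame rate)."""
    if duration_s <= 0 or frame_rate_hz <= 0:
        raise ValueError("duration_s and frame_rate_hz must be positive")
    return total_detections / (duration_s * frame_rate_hz)


@dataclass
class SRUSImage:
    """Per-pixel detection counts plus the thresholded, dilated vascular map."""

    counts: np.ndarray              # (rows, cols) int
    vascular: np.ndarray            # (rows, cols) bool
    pixel_um: float = DEFAULT_PIXEL_UM
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))
    track_diameter_um: float = DEFAULT_TRACK_DIAMETER_UM


def _rasterize_counts(points_mm: np.ndarray, origin_mm: np.ndarray,
                      pixel_um: float, shape: tuple[int, int]) -> np.ndarray:
    pix_mm = pixel_um / 1000.0
    idx = np.floor((points_mm - origin_mm) / pix_mm).astype(int)
    ok = (
        (idx[:, 0] >= 0) & (idx[:, 0] < shape[0])
        & (idx[:, 1] >= 0) & (idx[:, 1] < shape[1])
    )
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (idx[ok, 0], idx[ok, 1]), 1)
    return counts


def render_srus_image(
    tracks: list[Track],
    pixel_um: float = DEFAULT_PIXEL_UM,
    diameter_um: float = DEFAULT_TRACK_DIAMETER_UM,
    count_threshold: int = DEFAULT_COUNT_THRESHOLD,
    origin_mm: np.ndarray | None = None,
    shape: tuple[int, int] | None = None,
) -> SRUSImage:
    """Render the binary super-resolved vascular map from accepted tracks.

    Detection counts accumulate one increment per (detection, pixel) hit;
    pixels with count strictly greater than ``count_threshold`` are kept,
    then dilated to the configured track diameter (square footprint of
    ceil(diameter / pixel) pixels).
    """
    if not tracks:
        warnings.warn("render_srus_image called with no tracks; returning empty image")
        return SRUSImage(np.zeros((1, 1), int), np.zeros((1, 1), bool), pixel_um,
                         np.zeros(2), diameter_um)
    pts = np.vstack([t.positions_mm for t in tracks])
    pix_mm = pixel_um / 1000.0
    if origin_mm is None:
        origin_mm = np.floor(pts.min(axis=0) / pix_mm) * pix_mm - 2 * pix_mm
    origin_mm = np.asarray(origin_mm, dtype=float)
    if shape is None:
        extent = pts.max(axis=0) - origin_mm
        shape = tuple(int(np.ceil(e / pix_mm)) + 3 for e in extent)
    counts = _rasterize_counts(pts, origin_mm, pixel_um, shape)
    kept = counts > count_threshold
    d_px = max(1, int(np.ceil(diameter_um / pixel_um)))
    vascular = ndimage.binary_dilation(kept, structure=np.ones((d_px, d_px), bool))
    return SRUSImage(counts, vascular, pixel_um, origin_mm, diameter_um)


def _radial_bin(img_shape: tuple[int, int]) -> np.ndarray:
    fy = np.fft.fftfreq(img_shape[0])[:, None]
    fx = np.fft.fftfreq(img_shape[1])[None, :]
    r = np.sqrt(fy**2 + fx**2)
    n_rings = min(img_shape) // 2
    return np.minimum((r * min(img_shape)).astype(int), n_rings), n_rings


def frc_curve(img1: np.ndarray, img2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier ring correlation of two images.

    Returns (ring spatial frequency in cycles/pixel, FRC values, ring pixel
    counts).  Ring 0 (DC) is excluded.
    """
    if img1.shape != img2.shape:
        raise ValueError("FRC images must share a shape")
    f1 = np.fft.fft2(img1)
    f2 = np.fft.fft2(img2)
    rings, n_rings = _radial_bin(img1.shape)
    num = np.real(f1 * np.conj(f2))
    d1 = np.abs(f1) ** 2
    d2 = np.abs(f2) ** 2
    frc = np.empty(n_rings)
    npix = np.empty(n_rings, dtype=int)
    for k in range(1, n_rings + 1):
        m = rings == k
        npix[k - 1] = m.sum()
        denom = np.sqrt(d1[m].sum() * d2[m].sum())
        frc[k - 1] = num[m].sum() / denom if denom > 0 else 0.0
    freqs = np.arange(1, n_rings + 1) / min(img1.shape)
    return freqs, frc, npix


def _half_bit_threshold(npix: np.ndarray) -> np.ndarray:
    sq = np.sqrt(np.maximum(npix, 1) / 2.0)   # effective asymmetric-unit count
    return (0.2071 + 1.9102 / sq) / (1.2071 + 0.9102 / sq)


def estimate_resolution_frc(
    seq: DetectionSequence,
    pixel_um: float = DEFAULT_PIXEL_UM,
    shape: tuple[int, int] = (256, 256),
    origin_mm: np.ndarray | None = None,
    min_detections: int = 50,
) -> float:
    """Estimate image resolution (µm) by Fourier ring correlation.

    Detections are split into two interleaved halves (odd/even order in the
    table), each rendered to a count image; the resolution is the inverse
    spatial frequency where the ring-averaged correlation first drops below
    the half-bit information threshold.  If the curve never crosses, the
    Nyquist floor ``2 x pixel`` is returned.
    """
    df = seq.detections
    if len(df) < max(2, min_detections):
        raise ValueError(f"need at least {max(2, min_detections)} detections for a stable FRC")
    pts = df[["x_mm", "z_mm"]].to_numpy(float)
    if origin_mm is None:
        origin_mm = pts.min(axis=0) - pixel_um / 1000.0
    a = _rasterize_counts(pts[0::2], origin_mm, pixel_um, shape)
    b = _rasterize_counts(pts[1::2], origin_mm, pixel_um, shape)
    freqs, frc, npix = frc_curve(a.astype(float), b.astype(float))
    thr = _half_bit_threshold(npix)
    below = np.flatnonzero(frc < thr)
    if len(below) == 0:
        return 2.0 * pixel_um
    f_cross = freqs[below[0]]                 # cycles per pixel
    return float(max(pixel_um / f_cross, 2.0 * pixel_um))


def srus_density(image: SRUSImage, roi: np.ndarray) -> float:
    """Vascular pixel fraction within a 2D region of interest."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.vascular.shape:
        raise ValueError("ROI and image grids do not match")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI is empty")
    return float((image.vascular & roi).sum() / n_roi)
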
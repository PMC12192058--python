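"""Kidney-mask partitioning and co-registered plane extraction.

The partitioning workflow fits a PCA-oriented bounding box to the kidney
mask, places an apex ("division point") shifted 20% of the way from the box
centre (point 0) toward the hilar box face (point 1), fans the kidney into
three equal 120° angular segments about that apex in the plane spanned by
the long axis and the hilus axis, and extrudes the labels along the third
principal axis.  Cortex/medulla regions of interest are derived by mask
subtraction, and co-registered 2D planes are extracted from volumes as a
maximum intensity projection over a slab around an arbitrarily posed plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid

__all__ = [
    "PrincipalBox",
    "ROISet",
    "PlanePose",
    "DIVISION_SHIFT_FRACTION",
    "SECTOR_SPAN_DEG",
    "fit_principal_box",
    "locate_division_point",
    "partition_segments",
    "sector_angular_spans",
    "derive_rois",
    "extract_plane_mip",
]

#: fraction of the centre-to-hilus-face distance at which the apex is placed
DIVISION_SHIFT_FRACTION = 0.20
#: angular span of each of the three kidney segments, degrees
SECTOR_SPAN_DEG = 120.0

SEGMENT_LABELS = {"cranial": 1, "central": 2, "caudal": 3}


@dataclass
class PrincipalBox:
    """PCA-oriented bounding box of a voxel mask.

    ``axes`` columns are the orthonormal principal directions, the first
    column being the long axis; ``half_extents`` are sorted descending to
    match.  ``point0`` is the box centre.  ``point1`` (the point on the box
    face toward the renal hilus) and ``division_point`` are filled in by
    :func:`locate_division_point`.
    """

    point0: np.ndarray           # (3,) mm
    axes: np.ndarray             # (3, 3), columns = unit axes
    half_extents: np.ndarray     # (3,) mm, descending
    point1: np.ndarray | None = None
    division_point: np.ndarray | None = None
    hilus_axis: np.ndarray | None = None   # signed unit short axis toward hilus

    @property
    def long_axis(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def completed(self) -> bool:
        return self.point1 is not None and self.division_point is not None


def fit_principal_box(mask: VolumeGrid) -> PrincipalBox:
    """Fit a PCA-oriented bounding box to the nonzero voxels of ``mask``.

    The box is the tight axis-aligned box in principal-component space
    around the voxel world coordinates; its centre is point 0.

    Raises
    ------
    ValueError
        if the mask has fewer than 10 voxels or its coordinate covariance
        is rank-deficient (coplanar or collinear masks).
    """
    pts = mask.mask_world_coords()
    if pts.shape[0] < 10:
        raise ValueError(f"mask has {pts.shape[0]} voxels; need >= 10 for a PCA box")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / (pts.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)          # ascending
    if evals[0] <= 1e-9 * max(evals[-1], 1e-30):
        raise ValueError(
            "mask coordinate covariance is rank-deficient (coplanar/degenerate mask); "
            f"eigenvalues {evals}"
        )
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order]
    # right-handed frame
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    proj = pts @ axes
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    centre_pc = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    point0 = axes @ centre_pc
    # extents follow eigenvalue order; re-sort defensively so half_extents descend
    order2 = np.argsort(half)[::-1]
    axes = axes[:, order2]
    half = half[order2]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return PrincipalBox(point0=point0, axes=axes, half_extents=half)


def locate_division_point(box: PrincipalBox, hilus_direction: np.ndarray) -> PrincipalBox:
    """Complete a box with point 1 and the division point.

    Point 1 sits on the bounding-box face nearest point 0 along the short
    axis best aligned with ``hilus_direction`` (point 0 itself lies on the
    long axis, so "shortest distance to the long axis" picks a short-axis
    face toward the hilus).  The division point is a 20% shift of point 0
    toward point 1.
    """
    h = np.asarray(hilus_direction, dtype=float)
    norm = np.linalg.norm(h)
    if norm == 0:
        raise ValueError("hilus_direction must be nonzero")
    h = h / norm
    # component orthogonal to the long axis must exist
    perp = h - (h @ box.long_axis) * box.long_axis
    if np.linalg.norm(perp) < 1e-9:
        raise ValueError("hilus_direction is parallel to the long axis; cannot pick a short axis")
    # choose the short axis (index 1 or 2) most aligned with the hilus direction
    dots = [h @ box.axes[:, i] for i in (1, 2)]
    i_short = 1 + int(np.argmax(np.abs(dots)))
    u = box.axes[:, i_short] * np.sign(dots[i_short - 1])
    half = box.half_extents[i_short]
    point1 = box.point0 + half * u
    division = box.point0 + DIVISION_SHIFT_FRACTION * (point1 - box.point0)
    return PrincipalBox(
        point0=box.point0,
        axes=box.axes,
        half_extents=box.half_extents,
        point1=point1,
        division_point=division,
        hilus_axis=u,
    )


def _partition_basis(box: PrincipalBox, cranial_direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane orthonormal basis (e_long signed cranial, e_hilus) of the fan plane."""
    if not box.completed:
        raise ValueError("PrincipalBox must be completed by locate_division_point first")
    c = np.asarray(cranial_direction, dtype=float)
    if np.linalg.norm(c) == 0:
        raise ValueError("cranial_direction must be nonzero")
    u = box.hilus_axis
    e_long = box.long_axis
    if abs(c @ e_long) < 1e-9:
        raise ValueError("cranial_direction has no component along the long axis")
    e_long = e_long * np.sign(c @ e_long)
    return e_long, u


def partition_segments(
    mask: VolumeGrid, box: PrincipalBox, cranial_direction: np.ndarray
) -> VolumeGrid:
    """Label each kidney voxel cranial (1), central (2) or caudal (3).

    Voxels are projected into the plane spanned by the long axis and the
    hilus axis; the 120° sector of their direction about the division point
    sets the label.  The central sector's bisector points away from the
    hilus (so the 20% apex shift enlarges the central, near-field share),
    and the point0→point1 axis is the cranial/caudal boundary.  Labels are
    extruded unchanged along the third principal axis.
    """
    e_long, u = _partition_basis(box, cranial_direction)
    idx = np.argwhere(mask.data)
    pts = mask.world_coords(idx)
    d = pts - box.division_point
    x = d @ e_long          # + toward cranial
    y = d @ u               # + toward hilus
    # angle from the central bisector (-u); positive toward cranial
    phi = np.degrees(np.arctan2(x, -y))
    labels = np.where(
        np.abs(phi) <= SECTOR_SPAN_DEG / 2.0,
        SEGMENT_LABELS["central"],
        np.where(phi > 0, SEGMENT_LABELS["cranial"], SEGMENT_LABELS["caudal"]),
    )
    # voxel exactly at the apex: direction undefined -> central (tie-break)
    at_apex = (x == 0) & (y == 0)
    labels[at_apex] = SEGMENT_LABELS["central"]
    out = np.zeros(mask.shape, dtype=np.uint8)
    out[tuple(idx.T)] = labels
    return mask.like(out)


def sector_angular_spans(
    labels: VolumeGrid, box: PrincipalBox, cranial_direction: np.ndarray
) -> dict[str, float]:
    """Measured in-plane angular span (degrees) of each segment label.

    Voxel directions about the division point are projected into the
    partition plane; each label's span is max−min of those angles measured
    from that sector's own bisector (so sectors crossing the ±180° wrap are
    handled).  On a dense mask every span approaches the nominal 120°.
    """
    e_long, u = _partition_basis(box, cranial_direction)
    bisectors = {"central": 0.0, "cranial": SECTOR_SPAN_DEG, "caudal": -SECTOR_SPAN_DEG}
    spans: dict[str, float] = {}
    for name, val in SEGMENT_LABELS.items():
        idx = np.argwhere(labels.data == val)
        if len(idx) == 0:
            spans[name] = 0.0
            continue
        d = labels.world_coords(idx) - box.division_point
        x, y = d @ e_long, d @ u
        ok = np.hypot(x, y) > 1e-9     # apex voxel has no direction
        phi = np.degrees(np.arctan2(x[ok], -y[ok]))
        rel = (phi - bisectors[name] + 180.0) % 360.0 - 180.0
        spans[name] = float(rel.max() - rel.min())
    return spans


@dataclass
class ROISet:
    """Total / cortex / medulla regions of interest on one voxel grid."""

    total: VolumeGrid
    cortex: VolumeGrid
    medulla: VolumeGrid


def derive_rois(
    kidney: VolumeGrid,
    arcuate_boundary: VolumeGrid,
    vasa_recta_boundary: VolumeGrid,
    pelvis: VolumeGrid,
) -> ROISet:
    """Derive the ROI set by mask subtraction.

    total = kidney; cortex = kidney minus the arcuate boundary mask;
    medulla = vasa recta boundary mask minus the pelvic mask.
    """
    for name, m in (
        ("arcuate_boundary", arcuate_boundary),
        ("vasa_recta_boundary", vasa_recta_boundary),
        ("pelvis", pelvis),
    ):
        if not kidney.same_grid(m):
            raise ValueError(f"{name} mask is not on the same grid as the kidney mask")
    k = kidney.data.astype(bool)
    cortex = k & ~arcuate_boundary.data.astype(bool)
    medulla = vasa_recta_boundary.data.astype(bool) & ~pelvis.data.astype(bool)
    if not medulla.any():
        warnings.warn("derived medulla ROI is empty (pelvis covers the vasa recta boundary)")
    return ROISet(
        total=kidney.like(k),
        cortex=kidney.like(cortex),
        medulla=kidney.like(medulla),
    )


@dataclass
class PlanePose:
    """Pose of an extraction plane: origin + two in-plane axes + normal.

    ``origin_mm`` is the world position of output pixel (0, 0); rows advance
    along ``v``, columns along ``u``; ``pixel_um`` is the output pixel pitch
    and ``shape`` is (rows, cols).
    """

    origin_mm: np.ndarray
    u: np.ndarray
    v: np.ndarray
    normal: np.ndarray
    pixel_um: float = 22.6
    shape: tuple[int, int] = (128, 128)

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        basis = np.stack([self.u, self.v, self.normal])
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-6):
            raise ValueError("plane basis (u, v, normal) must be orthonormal")

    def to_json(self) -> str:
        return json.dumps(
            {
                "origin_mm": self.origin_mm.tolist(),
                "u": self.u.tolist(),
                "v": self.v.tolist(),
                "normal": self.normal.tolist(),
                "pixel_um": self.pixel_um,
                "shape": list(self.shape),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PlanePose":
        d = json.loads(text)
        return cls(
            origin_mm=d["origin_mm"],
            u=d["u"],
            v=d["v"],
            normal=d["normal"],
            pixel_um=float(d["pixel_um"]),
            shape=tuple(d["shape"]),
        )


def _plane_points(pose: PlanePose) -> np.ndarray:
    rows, cols = pose.shape
    pix_mm = pose.pixel_um / 1000.0
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pts = (
        pose.origin_mm[None, None, :]
        + rr[..., None] * pix_mm * pose.v[None, None, :]
        + cc[..., None] * pix_mm * pose.u[None, None, :]
    )
    return pts  # (rows, cols, 3)


def extract_plane_mip(
    volume: VolumeGrid,
    pose: PlanePose,
    slab_width_mm: float = 2.0,
    labels: bool = False,
) -> np.ndarray:
    """Extract a 2D plane from a volume.

    For intensity volumes each output pixel is the maximum of trilinearly
    interpolated samples taken along the plane normal within
    ±``slab_width_mm``/2 (step: half the smallest voxel spacing, endpoints
    included).  Label volumes are sampled nearest-neighbour on the central
    plane only — a maximum over a slab is not meaningful for categorical
    data.

    Returns the (rows, cols) array; its pixel pitch is ``pose.pixel_um``.
    """
    if slab_width_mm <= 0:
        raise ValueError("slab_width_mm must be positive")
    base = _plane_points(pose)

    def sample(points: np.ndarray, order: int) -> np.ndarray:
        idx = volume.world_to_index(points.reshape(-1, 3))
        vals = ndimage.map_coordinates(
            volume.data.astype(float), idx.T, order=order, mode="constant", cval=0.0
        )
        return vals.reshape(points.shape[:2])

    if labels:
        out = sample(base, order=0)
        out = out.astype(volume.data.dtype)
    else:
        step = float(np.min(volume.spacing_mm)) / 2.0
        n = int(np.floor((slab_width_mm / 2.0) / step + 1e-12))
        offsets = np.arange(-n, n + 1) * step
        out = np.full(pose.shape, -np.inf)
        for off in offsets:
            out = np.maximum(out, sample(base + off * pose.normal, order=1))
        out[~np.isfinite(out)] = 0.0
    if not np.any(out):
        warnings.warn("extracted plane contains no signal (plane may lie outside the volume)")
    return out
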
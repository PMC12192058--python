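"""Synthetic kidney phantoms, vessel trees, microbubble streams and cohorts.

Every downstream stage of the pipeline is testable without real data:

* :func:`generate_kidney_phantom` builds a superellipsoid kidney mask with a
  concave hilar notch, three nested boundary masks (arcuate boundary, vasa
  recta boundary, pelvis), a random vessel tree rasterized into a contrast
  volume, and the exact per-ROI ground-truth vascular density;
* :func:`simulate_mb_detections` streams frame-wise 2D microbubble
  localizations moving along vessel centerlines at class-specific speeds,
  with localization noise and uniform false positives;
* :func:`generate_cohort` draws per-animal covariates (MAP, HR, anaesthesia
  time, age, strain) through a Gaussian copula with a controllable
  MAP–HR correlation and a linear detection-yield model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import derive_rois
from .grid import VolumeGrid
from .srus import DEFAULT_FRAME_RATE_HZ, DetectionSequence

__all__ = [
    "Branch",
    "VesselTree",
    "KidneyPhantom",
    "VesselParams",
    "DEFAULT_CLASS_SPEEDS_MM_S",
    "generate_kidney_phantom",
    "rasterize_tree",
    "simulate_mb_detections",
    "generate_cohort",
]

VESSEL_CLASSES = (
    "segmental_artery",
    "segmental_vein",
    "arcuate_artery",
    "arcuate_vein",
    "microvessel",
)

# Free parameters of the generator, chosen so that segmental arteries sit
# above and all veins below a 15 mm/s tracking cap; not measured values.
DEFAULT_CLASS_SPEEDS_MM_S = {
    "segmental_artery": 40.0,
    "segmental_vein": 12.0,
    "arcuate_artery": 8.0,
    "arcuate_vein": 4.0,
    "microvessel": 1.5,
}
DEFAULT_CLASS_RADII_UM = {
    "segmental_artery": 250.0,
    "segmental_vein": 300.0,
    "arcuate_artery": 120.0,
    "arcuate_vein": 150.0,
    "microvessel": 40.0,
}


@dataclass
class Branch:
    """One vessel: a polyline centerline with a radius, class and flow speed."""

    points_mm: np.ndarray           # (n, 3)
    radius_um: float
    vessel_class: str
    flow_speed_mm_s: float

    def __post_init__(self) -> None:
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm, dtype=float))
        if self.radius_um <= 0:
            raise ValueError("branch radius must be positive")
        if self.flow_speed_mm_s < 0:
            raise ValueError("flow speed must be nonnegative")
        if self.vessel_class not in VESSEL_CLASSES:
            raise ValueError(f"unknown vessel class {self.vessel_class!r}")

    def arclengths(self) -> np.ndarray:
        steps = np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def length_mm(self) -> float:
        return float(self.arclengths()[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Position at arclength s (mm) along the centerline."""
        cum = self.arclengths()
        s = float(np.clip(s, 0.0, cum[-1]))
        i = int(np.searchsorted(cum, s, side="right") - 1)
        i = min(i, len(cum) - 2)
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        return (1 - t) * self.points_mm[i] + t * self.points_mm[i + 1]


@dataclass
class VesselTree:
    branches: list[Branch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.branches)


@dataclass
class VesselParams:
    """Counts per vessel class plus speed/radius overrides."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "segmental_artery": 3,
            "segmental_vein": 3,
            "arcuate_artery": 5,
            "arcuate_vein": 5,
            "microvessel": 20,
        }
    )
    speeds_mm_s: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_SPEEDS_MM_S))
    radii_um: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_RADII_UM))


@dataclass
class KidneyPhantom:
    """Kidney mask + nested boundary masks + contrast volume + ground truth."""

    kidney_mask: VolumeGrid
    arcuate_boundary_mask: VolumeGrid
    vasa_recta_boundary_mask: VolumeGrid
    pelvis_mask: VolumeGrid
    contrast_volume: VolumeGrid
    hilus_direction: np.ndarray
    cranial_direction: np.ndarray
    true_density_by_roi: dict[str, float]
    background_intensity: float
    vessel_intensity: float


def _superellipsoid(coords_mm: tuple[np.ndarray, ...], centre: np.ndarray,
                    semi_axes: np.ndarray, exponent: float) -> np.ndarray:
    val = sum(
        (np.abs(c - c0) / a) ** exponent
        for c, c0, a in zip(coords_mm, centre, semi_axes)
    )
    return val <= 1.0


def generate_kidney_phantom(
    semi_axes_mm: tuple[float, float, float] = (8.0, 5.0, 4.0),
    spacing_um: float | tuple[float, float, float] = 200.0,
    exponent: float = 2.5,
    notch_fraction: float = 0.35,
    nested_scales: tuple[float, float, float] = (0.70, 0.50, 0.25),
    vessel_params: VesselParams | None = None,
    background_intensity: float = 50.0,
    vessel_intensity: float = 200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[KidneyPhantom, VesselTree]:
    """Build a kidney phantom with nested masks and a rasterized vessel tree.

    The kidney is a superellipsoid with a concave hilar notch carved out on
    the +hilus (+y) side; the long axis runs along x and the cranial
    direction is +x.  The arcuate-boundary, vasa-recta-boundary and pelvic
    masks are concentric scaled copies intersected with the kidney, so the
    subset chain pelvis ⊂ vasa recta ⊂ arcuate ⊂ kidney holds by
    construction.  Vascular voxels of the contrast volume take
    ``vessel_intensity``; kidney tissue takes ``background_intensity``.

    Returns the phantom together with the generated vessel tree.
    """
    rng = np.random.default_rng(seed)
    semi = np.asarray(semi_axes_mm, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing_um, dtype=float), (3,)).astype(float)
    if np.any(semi <= 0) or np.any(spacing <= 0):
        raise ValueError("semi-axes and spacing must be positive")
    if np.any(semi * 1000.0 / spacing < 3):
        raise ValueError("degenerate phantom: every semi-axis must span >= 3 voxels")

    margin_mm = 1.0
    shape = tuple(int(np.ceil((2 * s + 2 * margin_mm) / (sp / 1000.0))) + 1
                  for s, sp in zip(semi, spacing))
    origin = -(semi + margin_mm)
    grid = VolumeGrid(np.zeros(shape, dtype=np.uint8), spacing, origin)
    axes_mm = tuple(
        origin[d] + np.arange(shape[d]) * spacing[d] / 1000.0 for d in range(3)
    )
    coords = np.meshgrid(*axes_mm, indexing="ij", sparse=True)

    centre = np.zeros(3)
    kidney = _superellipsoid(coords, centre, semi, exponent)
    # concave hilar notch: carve an ellipsoid centred on the +y face
    notch_centre = np.array([0.0, semi[1], 0.0])
    notch_semi = semi * np.array([notch_fraction, notch_fraction * 1.4, notch_fraction])
    notch = _superellipsoid(coords, notch_centre, notch_semi, 2.0)
    kidney &= ~notch

    nested = []
    for s in nested_scales:
        m = _superellipsoid(coords, centre, semi * s, exponent) & kidney
        nested.append(m)
    arcuate, vasa, pelvis = nested

    vessel_params = vessel_params if vessel_params is not None else VesselParams()
    tree = _random_tree(vessel_params, semi, exponent, notch_centre, notch_semi, rng)
    vascular = rasterize_tree(tree, grid)
    vascular &= kidney

    contrast = np.zeros(shape, dtype=float)
    contrast[kidney] = background_intensity
    contrast[vascular] = vessel_intensity
    if noise_sd > 0:
        contrast += rng.normal(0.0, noise_sd, size=shape)

    kidney_g = grid.like(kidney)
    rois = derive_rois(kidney_g, grid.like(arcuate), grid.like(vasa), grid.like(pelvis))
    true_density = {}
    for name, roi in (("total", rois.total), ("cortex", rois.cortex), ("medulla", rois.medulla)):
        n = int(roi.data.sum())
        true_density[name] = float((vascular & roi.data).sum() / n) if n else 0.0

    phantom = KidneyPhantom(
        kidney_mask=kidney_g,
        arcuate_boundary_mask=grid.like(arcuate),
        vasa_recta_boundary_mask=grid.like(vasa),
        pelvis_mask=grid.like(pelvis),
        contrast_volume=grid.like(contrast),
        hilus_direction=np.array([0.0, 1.0, 0.0]),
        cranial_direction=np.array([1.0, 0.0, 0.0]),
        true_density_by_roi=true_density,
        background_intensity=background_intensity,
        vessel_intensity=vessel_intensity,
    )
    return phantom, tree


def _inside(p: np.ndarray, semi: np.ndarray, exponent: float,
            notch_centre: np.ndarray, notch_semi: np.ndarray, shrink: float = 0.92) -> bool:
    in_kidney = np.sum((np.abs(p) / (semi * shrink)) ** exponent) <= 1.0
    in_notch = np.sum(((p - notch_centre) / (notch_semi * 1.1)) ** 2) <= 1.0
    return bool(in_kidney and not in_notch)


def _random_tree(params: VesselParams, semi: np.ndarray, exponent: float,
                 notch_centre: np.ndarray, notch_semi: np.ndarray,
                 rng: np.random.Generator) -> VesselTree:
    """Random vessels: segmental vessels radiate from the hilar core toward the
    poles, arcuate vessels arc at mid-depth, microvessels scatter in the rim."""
    branches: list[Branch] = []
    for cls in VESSEL_CLASSES:
        n = params.n_per_class.get(cls, 0)
        for _ in range(n):
            for _attempt in range(50):
                if cls.startswith("segmental"):
                    p0 = rng.uniform(-0.15, 0.15, 3) * semi
                    d = rng.normal(size=3)
                    d[1] = -abs(d[1])            # away from the hilus
                    d /= np.linalg.norm(d)
                    p1 = p0 + d * rng.uniform(0.5, 0.8) * semi.min()
                    pts = np.linspace(p0, p1, 8)
                elif cls.startswith("arcuate"):
                    # arc at ~60% depth in a random meridional plane
                    phi0 = rng.uniform(0, 2 * np.pi)
                    span = rng.uniform(0.6, 1.2)
                    ts = np.linspace(phi0, phi0 + span, 10)
                    r = 0.6
                    pts = np.stack(
                        [
                            r * semi[0] * np.cos(ts) * 0.8,
                            -abs(r * semi[1] * np.sin(ts)) * 0.8,
                            np.full_like(ts, rng.uniform(-0.4, 0.4) * semi[2]),
                        ],
                        axis=1,
                    )
                else:  # microvessel: short straight segment in the outer rim
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    u[1] = -abs(u[1])
                    p0 = u * rng.uniform(0.6, 0.8) * semi
                    d = rng.normal(size=3)
                    d /= np.linalg.norm(d)
                    p1 = p0 + d * rng.uniform(0.3, 0.8)
                    pts = np.linspace(p0, p1, 4)
                if all(_inside(p, semi, exponent, notch_centre, notch_semi) for p in pts):
                    branches.append(
                        Branch(pts, params.radii_um[cls], cls, params.speeds_mm_s[cls])
                    )
                    break
    return VesselTree(branches)


def rasterize_tree(tree: VesselTree, grid: VolumeGrid) -> np.ndarray:
    """Boolean volume of voxels within each branch's radius of its centerline."""
    out = np.zeros(grid.shape, dtype=bool)
    if not tree.branches:
        return out
    step = float(np.min(grid.spacing_mm)) / 2.0
    by_radius: dict[float, list[Branch]] = {}
    for b in tree.branches:
        by_radius.setdefault(b.radius_um, []).append(b)
    for radius_um, branches in by_radius.items():
        seeds = np.zeros(grid.shape, dtype=bool)
        for b in branches:
            length = b.length_mm()
            n = max(2, int(np.ceil(length / step)) + 1)
            pts = np.array([b.point_at(s) for s in np.linspace(0, length, n)])
            idx = np.round(grid.world_to_index(pts)).astype(int)
            ok = np.all((idx >= 0) & (idx < np.array(grid.shape)), axis=1)
            seeds[tuple(idx[ok].T)] = True
        if not seeds.any():
            continue
        dist = ndimage.distance_transform_edt(~seeds, sampling=grid.spacing_mm)
        out |= dist <= radius_um / 1000.0
    return out


def simulate_mb_detections(
    tree: VesselTree,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    duration_s: float = 10.0,
    mb_budget: int = 10,
    noise_sigma_mm: float = 0.0,
    false_positive_rate: float = 0.0,
    field_bounds_mm: tuple[tuple[float, float], tuple[float, float]] | None = None,
    seed: int = 0,
) -> DetectionSequence:
    """Stream frame-wise 2D MB detections from a vessel tree.

    ``mb_budget`` microbubbles are kept in circulation: each advances along
    its branch centerline at the branch flow speed and is replaced (at a
    random position on a random branch, length-weighted) when it exits.
    Detections are the (x, z) projection of the 3D position plus isotropic
    Gaussian localization noise; false positives are Poisson per frame,
    uniform over the field.  True detections carry a trajectory id and the
    branch vessel class; false positives have ``traj_id = -1``.
    """
    if frame_rate_hz <= 0 or duration_s <= 0:
        raise ValueError("frame_rate_hz and duration_s must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate_hz))
    cols = {"frame": [], "x_mm": [], "z_mm": [], "traj_id": [], "vessel_class": []}
    if len(tree) == 0:
        if false_positive_rate <= 0 or field_bounds_mm is None:
            df = pd.DataFrame(cols)
            return DetectionSequence(df, frame_rate_hz, duration_s)
    lengths = np.array([b.length_mm() for b in tree.branches]) if len(tree) else np.array([])
    weights = lengths / lengths.sum() if lengths.sum() > 0 else None

    if field_bounds_mm is None and len(tree):
        allpts = np.vstack([b.points_mm for b in tree.branches])
        field_bounds_mm = (
            (allpts[:, 0].min() - 1, allpts[:, 0].max() + 1),
            (allpts[:, 2].min() - 1, allpts[:, 2].max() + 1),
        )

    next_id = 0
    # active MB: [branch index, arc position s, traj id]
    active: list[list] = []

    def spawn(s_random: bool) -> None:
        nonlocal next_id
        bi = int(rng.choice(len(tree.branches), p=weights))
        s0 = rng.uniform(0, lengths[bi]) if s_random else 0.0
        active.append([bi, s0, next_id])
        next_id += 1

    if len(tree):
        for _ in range(mb_budget):
            spawn(s_random=True)

    dt = 1.0 / frame_rate_hz
    for frame in range(n_frames):
        if len(tree):
            survivors = []
            for mb in active:
                bi, s, tid = mb
                if s <= lengths[bi]:
                    survivors.append(mb)
            active = survivors
            while len(active) < mb_budget:
                spawn(s_random=False)
            for mb in active:
                bi, s, tid = mb
                p = tree.branches[bi].point_at(s)
                x, z = p[0], p[2]
                if noise_sigma_mm > 0:
                    x += rng.normal(0, noise_sigma_mm)
                    z += rng.normal(0, noise_sigma_mm)
                cols["frame"].append(frame)
                cols["x_mm"].append(x)
                cols["z_mm"].append(z)
                cols["traj_id"].append(tid)
                cols["vessel_class"].append(tree.branches[bi].vessel_class)
                mb[1] = s + tree.branches[bi].flow_speed_mm_s * dt
        if false_positive_rate > 0 and field_bounds_mm is not None:
            (x0, x1), (z0, z1) = field_bounds_mm
            for _ in range(rng.poisson(false_positive_rate)):
                cols["frame"].append(frame)
                cols["x_mm"].append(rng.uniform(x0, x1))
                cols["z_mm"].append(rng.uniform(z0, z1))
                cols["traj_id"].append(-1)
                cols["vessel_class"].append("")
    df = pd.DataFrame(cols)
    return DetectionSequence(df, frame_rate_hz, duration_s)


def generate_cohort(
    n: int = 29,
    r_map_hr: float = 0.5324,
    slope_anaesthesia_yield: float = -0.004,
    slope_map_yield: float = 0.004,
    yield_noise_sd: float = 0.15,
    map_range: tuple[float, float] = (38.0, 119.0),
    hr_range: tuple[float, float] = (84.0, 346.0),
    anaesthesia_range: tuple[float, float] = (109.0, 263.0),
    ages_weeks: tuple[int, ...] = (12, 22, 40),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-animal covariate table through a Gaussian copula.

    MAP, HR and anaesthesia time get uniform marginals over the configured
    ranges; the latent normal correlation between MAP and HR is inflated to
    ``2 sin(pi r / 6)`` so the post-transform Pearson correlation matches
    the target ``r_map_hr``.  The latent detection-yield multiplier is
    linear in MAP and anaesthesia time (slopes per mmHg and per minute)
    plus Gaussian noise, centred at 1 and clipped to stay positive.
    """
    if n < 3:
        raise ValueError("cohort needs n >= 3")
    if abs(r_map_hr) >= 1:
        raise ValueError("|target correlation| must be < 1")
    rng = np.random.default_rng(seed)
    rho = 2.0 * np.sin(np.pi * r_map_hr / 6.0)
    corr = np.array([[1.0, rho, 0.0], [rho, 1.0, 0.0], [0.0, 0.0, 1.0]])
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise ValueError("infeasible correlation matrix (not positive definite)") from e
    z = rng.standard_normal((n, 3)) @ chol.T
    from scipy.stats import norm

    u = norm.cdf(z)
    map_v = map_range[0] + u[:, 0] * (map_range[1] - map_range[0])
    hr_v = hr_range[0] + u[:, 1] * (hr_range[1] - hr_range[0])
    ana_v = anaesthesia_range[0] + u[:, 2] * (anaesthesia_range[1] - anaesthesia_range[0])
    yield_mult = (
        1.0
        + slope_map_yield * (map_v - map_v.mean())
        + slope_anaesthesia_yield * (ana_v - ana_v.mean())
        + rng.normal(0, yield_noise_sd, n)
    )
    yield_mult = np.clip(yield_mult, 0.05, None)
    return pd.DataFrame(
        {
            "animal": [f"A{i:03d}" for i in range(n)],
            "MAP_mmHg": map_v,
            "HR_bpm": hr_v,
            "anaesthesia_min": ana_v,
            "age_weeks": rng.choice(ages_weeks, n),
            "strain": rng.choice(["ZL", "ZDF"], n),
            "yield_multiplier": yield_mult,
        }
    )
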
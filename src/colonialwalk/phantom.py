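"""Synthetic aortic-root phantoms with exact ground-truth landmarks.

The phantom emulates the appearance of a contrast-enhanced CT of the
aortic root at desk scale: a bright tubular lumen (ascending aorta) on a
noisy soft-tissue background, a less-enhanced outflow segment below the
annulus plane, three commissural ridges on the inner wall, two
contrast-filled coronary branches leaving the root at the right and left
sinuses, and optional high-intensity calcification blobs near the hinges.
The eight landmarks are placed analytically:

* ``h_r, h_n, h_l`` — 120 degrees apart on the annulus ring (the plane
  where the outflow/aorta intensity transition sits);
* ``c_rn, c_nl, c_lr`` — interleaved 60 degrees from the hinges, on a
  higher ring at ``commissure_height``;
* ``o_r, o_l`` — on the lumen boundary at the right/left sinus azimuths,
  ``ostium_height`` above the annulus plane, where the coronary branches
  exit.

The coronary branches break the 3-fold azimuthal symmetry (the
non-coronary sinus has no branch), so every landmark is identifiable from
intensities alone.  A rigid pose rotation about the X and Y axes is
applied by evaluating the analytic scene at inverse-rotated coordinates —
the exact limit of inverse-mapped trilinear resampling — while landmark
coordinates are transformed analytically, so ground truth carries no
resampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .volume import LANDMARK_NAMES, LandmarkSet, ValidationError, Volume

__all__ = [
    "PhantomConfig",
    "DatasetConfig",
    "PhantomSample",
    "rotation_matrix",
    "generate_phantom",
    "generate_dataset",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and nuisance parameters of one phantom.

    Lengths are voxels, intensities arbitrary CT-like stored units,
    rotation in degrees about the X and Y axes.  Defaults model a
    96 x 96 x 72 grid at (1, 1, 1.5) mm spacing — the in-plane/slice
    anisotropy of clinical CCTA — with an annulus radius of 12 voxels
    (24 mm diameter, an adult aortic annulus), commissures 7 voxels
    (10.5 mm) and coronary ostia 8 voxels (12 mm) above the annulus plane.
    """

    shape: tuple[int, int, int] = (96, 96, 72)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    lumen_intensity: float = 400.0
    wall_intensity: float = 140.0
    background_intensity: float = 60.0
    outflow_intensity: float = 280.0
    ridge_intensity: float = 190.0
    noise_sigma: float = 8.0
    annulus_radius: float = 12.0
    commissure_height: float = 7.0
    ostium_height: float = 8.0
    rotation: tuple[float, float] = (0.0, 0.0)
    n_blobs: int = 0
    blob_radius_range: tuple[float, float] = (2.0, 4.0)
    blob_intensity: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 16:
            raise ValidationError("phantom shape must be >= 16 per axis")
        if not (
            self.background_intensity
            < self.wall_intensity
            < self.lumen_intensity
            <= self.blob_intensity
        ):
            raise ValidationError(
                "intensities must satisfy background < wall < lumen <= calcification"
            )
        if self.noise_sigma < 0 or self.annulus_radius <= 0:
            raise ValidationError("noise_sigma >= 0 and annulus_radius > 0 required")


# Hinge azimuths (degrees) for the right-, non- and left-coronary cusps;
# commissures interleave at +60 degrees.  Arbitrary but fixed.
_HINGE_AZ = {"h_r": 0.0, "h_n": 120.0, "h_l": 240.0}
_COMMISSURE_AZ = {"c_rn": 60.0, "c_nl": 180.0, "c_lr": 300.0}
_OSTIUM_AZ = {"o_r": 0.0, "o_l": 240.0}

_WALL_THICKNESS = 2.0
_RIDGE_RADIUS = 2.0
_BRANCH_RADIUS = 2.5
_BRANCH_LENGTH = 10.0
_TUBE_BELOW = 14.0  # outflow extent below the annulus plane
_TUBE_ABOVE = 24.0  # ascending-aorta extent above it


def rotation_matrix(rx_deg: float, ry_deg: float) -> np.ndarray:
    """Rigid rotation: first about X by ``rx``, then about Y by ``ry``."""
    ax, ay = np.deg2rad([rx_deg, ry_deg])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return rot_y @ rot_x


def _canonical_landmarks(cfg: PhantomConfig) -> dict[str, np.ndarray]:
    """Landmarks in the unrotated frame; (cx, cy, z0) is the annulus center."""
    nx, ny, nz = cfg.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    z0 = round(0.45 * (nz - 1))
    pts = {}
    for name, az in _HINGE_AZ.items():
        a = np.deg2rad(az)
        pts[name] = np.array(
            [cx + cfg.annulus_radius * np.cos(a), cy + cfg.annulus_radius * np.sin(a), z0]
        )
    for name, az in _COMMISSURE_AZ.items():
        a = np.deg2rad(az)
        pts[name] = np.array(
            [
                cx + cfg.annulus_radius * np.cos(a),
                cy + cfg.annulus_radius * np.sin(a),
                z0 + cfg.commissure_height,
            ]
        )
    for name, az in _OSTIUM_AZ.items():
        a = np.deg2rad(az)
        pts[name] = np.array(
            [
                cx + cfg.annulus_radius * np.cos(a),
                cy + cfg.annulus_radius * np.sin(a),
                z0 + cfg.ostium_height,
            ]
        )
    return pts


def _render_canonical(cfg: PhantomConfig, coords: np.ndarray) -> np.ndarray:
    """Evaluate the analytic (unrotated) scene at arbitrary coordinates.

    ``coords`` has shape (..., 3); returns intensities of the same leading
    shape.  Later structures overwrite earlier ones, so ridges sit on the
    lumen and branches punch through the wall.
    """
    nx, ny, nz = cfg.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    z0 = round(0.45 * (nz - 1))
    radius = cfg.annulus_radius
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    r = np.hypot(x - cx, y - cy)
    out = np.full(coords.shape[:-1], cfg.background_intensity)

    in_tube_z = (z >= z0 - _TUBE_BELOW) & (z <= z0 + _TUBE_ABOVE)
    out[in_tube_z & (r <= radius + _WALL_THICKNESS)] = cfg.wall_intensity
    lumen = in_tube_z & (r <= radius)
    out[lumen & (z >= z0)] = cfg.lumen_intensity
    out[lumen & (z < z0)] = cfg.outflow_intensity

    for az in _COMMISSURE_AZ.values():
        a = np.deg2rad(az)
        px = cx + (radius - 1.0) * np.cos(a)
        py = cy + (radius - 1.0) * np.sin(a)
        near = (
            ((x - px) ** 2 + (y - py) ** 2 <= _RIDGE_RADIUS**2)
            & (z >= z0)
            & (z <= z0 + cfg.commissure_height + 2.0)
        )
        out[near] = cfg.ridge_intensity

    for az in _OSTIUM_AZ.values():
        a = np.deg2rad(az)
        ux, uy = np.cos(a), np.sin(a)
        t = (x - cx) * ux + (y - cy) * uy  # radial coordinate
        perp2 = ((x - cx) - t * ux) ** 2 + ((y - cy) - t * uy) ** 2 + (
            z - (z0 + cfg.ostium_height)
        ) ** 2
        branch = (t >= radius - 1.0) & (t <= radius + _BRANCH_LENGTH) & (
            perp2 <= _BRANCH_RADIUS**2
        )
        out[branch] = cfg.lumen_intensity
    return out


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, LandmarkSet]:
    """Render one phantom volume and its exact landmark coordinates."""
    nx, ny, nz = cfg.shape
    center = (np.asarray(cfg.shape, dtype=np.float64) - 1.0) / 2.0
    rot = rotation_matrix(*cfg.rotation)

    canon = _canonical_landmarks(cfg)
    points = {n: rot @ (p - center) + center for n, p in canon.items()}
    margin = 3.0
    for name, p in points.items():
        if np.any(p < margin) or np.any(p > np.asarray(cfg.shape) - 1 - margin):
            raise ValidationError(
                f"phantom geometry exceeds bounds: {name} at {p} for shape {cfg.shape}"
            )

    gx, gy, gz = np.meshgrid(
        np.arange(nx, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nz, dtype=np.float64),
        indexing="ij",
    )
    coords = np.stack([gx, gy, gz], axis=-1)
    inv_coords = (coords - center) @ rot + center  # row-vector form of rot.T @ v
    data = _render_canonical(cfg, inv_coords)

    rng = np.random.default_rng(cfg.seed)
    if cfg.n_blobs > 0:
        hinges = [canon[n] for n in ("h_r", "h_n", "h_l")]
        lo_r, hi_r = cfg.blob_radius_range
        for _ in range(cfg.n_blobs):
            anchor = hinges[rng.integers(len(hinges))]
            offset = rng.uniform(-1.0, 1.0, size=3)
            offset *= (1.5 * cfg.annulus_radius * rng.random()) / max(
                np.linalg.norm(offset), 1e-12
            )
            blob_c = anchor + offset
            blob_r = rng.uniform(lo_r, hi_r)
            d2 = ((inv_coords - blob_c) ** 2).sum(axis=-1)
            data[d2 <= blob_r**2] = cfg.blob_intensity
    if cfg.noise_sigma > 0:
        data = data + rng.normal(0.0, cfg.noise_sigma, size=data.shape)
    data = np.maximum(data, 1.0)  # intensity floor: feature denominators >= 1

    vol = Volume(
        data.astype(np.float32),
        cfg.spacing,
        origin_id=f"phantom(seed={cfg.seed},rot={cfg.rotation},blobs={cfg.n_blobs})",
    )
    lm = LandmarkSet(points, global_point=points["h_n"].copy())
    lm.validate_bounds(vol)
    return vol, lm


@dataclass(frozen=True)
class DatasetConfig:
    """Per-volume nuisance distribution for a phantom cohort.

    Rotations are drawn uniformly in ``[-rotation_max_deg, +rotation_max_deg]``
    about X and Y.  A volume is "TAVI-like" (heavily calcified, carrying
    ``n_blobs_tavi`` blobs) with probability ``tavi_fraction``; other
    volumes carry no calcification.
    """

    base: PhantomConfig = field(default_factory=PhantomConfig)
    rotation_max_deg: float = 8.0
    tavi_fraction: float = 0.0
    n_blobs_tavi: int = 4


@dataclass
class PhantomSample:
    volume: Volume
    landmarks: LandmarkSet
    config: PhantomConfig
    arm: str  # "tavi" or "non-tavi"

    def __iter__(self):
        return iter((self.volume, self.landmarks))


def generate_dataset(
    n: int, dist: DatasetConfig, master_seed: int
) -> list[PhantomSample]:
    """Draw ``n`` phantoms with per-volume nuisance parameters and seeds."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    streams = np.random.SeedSequence(master_seed).spawn(n)
    out = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        rx, ry = rng.uniform(-dist.rotation_max_deg, dist.rotation_max_deg, size=2)
        tavi = bool(rng.random() < dist.tavi_fraction)
        cfg = replace(
            dist.base,
            rotation=(float(rx), float(ry)),
            n_blobs=dist.n_blobs_tavi if tavi else 0,
            seed=int(rng.integers(2**31 - 1)),
        )
        vol, lm = generate_phantom(cfg)
        out.append(PhantomSample(vol, lm, cfg, "tavi" if tavi else "non-tavi"))
    return out
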
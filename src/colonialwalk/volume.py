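"""Volumes, landmark sets, and their on-disk formats.

Coordinate convention
---------------------
Voxel indices are 0-based integers in the order (X, Y, Z), where X runs
right-to-left, Y posterior-to-anterior and Z inferior-to-superior.  A
physical position in millimetres is ``index * spacing``; Z spacing (the
inter-slice distance) is typically larger than in-plane spacing.

Intensity floor
---------------
The voxel-difference feature divides by the intensity at the probe voxel,
and stored CT values can be zero or negative.  On load (and on phantom
generation) intensities are shifted by ``1 - min`` whenever the stored
minimum is below 1, so every denominator is >= 1.  The shift is recorded in
``Volume.origin_id``; the feature itself is invariant to any multiplicative
contrast change, and the constant shift is shared by every voxel of the
volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "Volume",
    "LandmarkSet",
    "ValidationError",
    "FormatError",
    "read_volume",
    "write_volume",
    "voxel_at",
    "read_landmarks",
    "write_landmarks",
]

#: Fixed landmark vocabulary: three hinge points (right-, non- and
#: left-coronary), the three commissures between adjacent hinges, and the
#: right and left coronary ostia.
LANDMARK_NAMES: tuple[str, ...] = (
    "h_r", "h_n", "h_l", "c_rn", "c_nl", "c_lr", "o_r", "o_l",
)


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValidationError):
    """A file is not in one of the supported formats."""


@dataclass
class Volume:
    """A 3-D scalar intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    data:
        3-D array indexed ``data[x, y, z]``; converted to float32.
    spacing:
        (sx, sy, sz) millimetres per voxel, all positive.
    origin_id:
        Free-text provenance label (file name, generator seed, applied
        intensity shift, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume must be 3-D, got {self.data.ndim}-D"
            )
        if min(self.data.shape) < 8:
            raise ValidationError(
                f"every volume axis must have >= 8 voxels, got {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3 or not all(
            np.isfinite(s) and s > 0 for s in self.spacing
        ):
            raise ValidationError(f"spacing must be 3 finite positives, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValidationError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def contains(self, pos) -> bool:
        """True when an (integer or fractional) position is inside bounds."""
        p = np.asarray(pos, dtype=float)
        return bool(np.all(p >= 0) and np.all(p <= np.array(self.shape) - 1))

    def floor_intensities(self) -> "Volume":
        """Return a copy shifted so the minimum intensity is >= 1."""
        lo = float(self.data.min())
        if lo >= 1.0:
            return self
        shift = 1.0 - lo
        tag = f"{self.origin_id}|shift=+{shift:g}" if self.origin_id else f"shift=+{shift:g}"
        return replace(self, data=self.data + np.float32(shift), origin_id=tag)


def clamp_positions(pos: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Clamp integer positions componentwise into ``[0, shape - 1]``."""
    pos = np.asarray(pos)
    hi = np.asarray(shape, dtype=pos.dtype) - 1
    return np.clip(pos, 0, hi)


def voxel_at(vol: Volume, pos) -> float:
    """Intensity at ``pos``, with out-of-bounds indices clamped to the border.

    Clamping (rather than zero-filling) keeps features finite and smooth for
    walkers probing past the volume border.
    """
    p = clamp_positions(np.asarray(pos, dtype=np.int64), vol.shape)
    return float(vol.data[p[0], p[1], p[2]])


@dataclass
class LandmarkSet:
    """The eight named aortic-valve points, plus an optional global point.

    ``points`` maps each name in :data:`LANDMARK_NAMES` to a 3-vector of
    voxel coordinates (fractional values are allowed for predictions and
    analytically placed ground truth).  ``global_point`` is the single
    representative valve point targeted by the global estimation phase.
    """

    points: dict[str, np.ndarray]
    global_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise ValidationError(f"missing landmark(s): {missing}")
        extra = [n for n in self.points if n not in LANDMARK_NAMES]
        if extra:
            raise ValidationError(f"unknown landmark name(s): {extra}")
        self.points = {
            n: np.asarray(self.points[n], dtype=float).reshape(3)
            for n in LANDMARK_NAMES
        }
        if self.global_point is not None:
            self.global_point = np.asarray(self.global_point, dtype=float).reshape(3)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    def __iter__(self) -> Iterator[str]:
        return iter(LANDMARK_NAMES)

    def as_array(self) -> np.ndarray:
        """(8, 3) array in the fixed :data:`LANDMARK_NAMES` order."""
        return np.stack([self.points[n] for n in LANDMARK_NAMES])

    def validate_bounds(self, vol: Volume) -> "LandmarkSet":
        for name in LANDMARK_NAMES:
            if not vol.contains(self.points[name]):
                raise ValidationError(
                    f"landmark {name} at {self.points[name]} outside volume "
                    f"bounds {vol.shape}"
                )
        return self


# ---------------------------------------------------------------------------
# Volume I/O: NIfTI-1 plus a raw little-endian fixture format
# ---------------------------------------------------------------------------

def _read_raw(path: Path) -> Volume:
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"raw volume {path} has no JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        shape = tuple(int(s) for s in meta["shape"])
        spacing = tuple(float(s) for s in meta["spacing"])
        dtype = np.dtype(meta["dtype"]).newbyteorder("<")
    except (KeyError, TypeError) as exc:
        raise FormatError(f"bad raw sidecar {sidecar}: {exc}") from exc
    if len(shape) != 3:
        raise ValidationError(f"raw volume {path} is {len(shape)}-D, expected 3-D")
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != int(np.prod(shape)):
        raise FormatError(
            f"raw block {path}: {raw.size} scalars for shape {shape}"
        )
    data = raw.reshape(shape, order="C")
    return Volume(data, spacing, origin_id=str(path))


def read_volume(path) -> Volume:
    """Load a volume from NIfTI (``.nii``/``.nii.gz``) or the raw format.

    The returned volume has the intensity floor applied: if the stored
    minimum is below 1 every intensity is shifted by ``1 - min``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # nibabel raises various types
            raise FormatError(f"unreadable NIfTI {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        if data.ndim != 3:
            raise ValidationError(f"{path}: expected a 3-D image, got {data.ndim}-D")
        zooms = img.header.get_zooms()[:3]
        vol = Volume(data, tuple(float(z) for z in zooms), origin_id=str(path))
    elif path.suffix == ".raw":
        vol = _read_raw(path)
    else:
        raise FormatError(f"unsupported volume format: {path}")
    return vol.floor_intensities()


def write_volume(vol: Volume, path) -> Path:
    """Write a volume as NIfTI (by extension) or raw block + JSON sidecar."""
    path = Path(path)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(vol.spacing) + [1.0])
        img = nib.Nifti1Image(vol.data, affine)
        img.header.set_zooms(vol.spacing)
        nib.save(img, str(path))
    elif path.suffix == ".raw":
        data = np.ascontiguousarray(vol.data, dtype="<f4")
        data.tofile(path)
        sidecar = {
            "shape": list(vol.shape),
            "spacing": list(vol.spacing),
            "dtype": "<f4",
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, sort_keys=True) + "\n"
        )
    else:
        raise FormatError(f"unsupported volume format: {path}")
    return path


# ---------------------------------------------------------------------------
# Landmark I/O: `name x y z` text lines, voxel units, 0-based
# ---------------------------------------------------------------------------

def read_landmarks(path, vol: Volume | None = None) -> LandmarkSet:
    """Read a landmark text file (one ``name x y z`` line per point).

    The eight canonical names are required; an ``x_g`` line, when present,
    is stored as the global point.  When ``vol`` is given, every point is
    validated against its bounds.
    """
    path = Path(path)
    points: dict[str, np.ndarray] = {}
    global_point = None
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: expected 'name x y z', got {line!r}")
        name, *coords = parts
        try:
            vec = np.array([float(c) for c in coords])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
        if name == "x_g":
            global_point = vec
        else:
            points[name] = vec
    lm = LandmarkSet(points, global_point)
    if vol is not None:
        lm.validate_bounds(vol)
    return lm


def write_landmarks(lm: LandmarkSet | Mapping[str, np.ndarray], path) -> Path:
    """Write landmarks in the ``name x y z`` text format (repr-exact floats)."""
    path = Path(path)
    if isinstance(lm, LandmarkSet):
        items = [(n, lm.points[n]) for n in LANDMARK_NAMES]
        if lm.global_point is not None:
            items.append(("x_g", lm.global_point))
    else:
        items = list(lm.items())
    lines = [
        f"{name} {float(p[0])!r} {float(p[1])!r} {float(p[2])!r}"
        for name, p in items
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
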
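"""Normalized voxel-difference features.

The feature at voxel ``x`` with offset pair ``(v1, v2)`` is::

    f(x) = (I(x + v1) - I(x + v2)) / I(x)

All three lookups clamp to the volume border, and the denominator is
guaranteed >= 1 by the load-time intensity floor.  Dividing by ``I(x)``
makes the feature invariant to a multiplicative change of intensity, e.g.
to the amount of contrast agent.  Offsets are integer voxel vectors drawn
uniformly from a phase-specific range box: a wide box for the coarse global
phase, a narrow one for the accurate local phase, with the Z bound smaller
than X/Y because slices are spaced further apart than in-plane voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume, ValidationError, clamp_positions

__all__ = [
    "FeatureParams",
    "OffsetRange",
    "GLOBAL_OFFSET_RANGE",
    "LOCAL_OFFSET_RANGE",
    "feature_value",
    "propose_params",
    "propose_param_array",
    "FeatureEvaluator",
]


@dataclass(frozen=True)
class OffsetRange:
    """Componentwise bounds ``|p_x| <= max_x`` etc. for offset proposals."""

    max_x: int
    max_y: int
    max_z: int

    def __post_init__(self) -> None:
        if min(self.max_x, self.max_y, self.max_z) < 0:
            raise ValidationError(f"offset bounds must be >= 0, got {self}")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.max_x, self.max_y, self.max_z], dtype=np.int64)

    def contains(self, offset) -> bool:
        return bool(np.all(np.abs(np.asarray(offset)) <= self.bounds))

    def scaled(self, factor: float) -> "OffsetRange":
        """Range shrunk/grown by ``factor`` (rounded, floor 1 per axis)."""
        b = np.maximum(1, np.rint(self.bounds * factor).astype(int))
        return OffsetRange(int(b[0]), int(b[1]), int(b[2]))


#: Full-scale offset ranges for the two pipeline phases (voxels).
GLOBAL_OFFSET_RANGE = OffsetRange(80, 80, 40)
LOCAL_OFFSET_RANGE = OffsetRange(40, 40, 20)


@dataclass(frozen=True)
class FeatureParams:
    """An offset pair ``theta = (v1, v2)`` in integer voxel units."""

    v1: tuple[int, int, int]
    v2: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "v1", tuple(int(c) for c in self.v1))
        object.__setattr__(self, "v2", tuple(int(c) for c in self.v2))


def feature_value(vol: Volume, pos, params: FeatureParams) -> float:
    """Evaluate the voxel-difference feature at one position."""
    p = np.asarray(pos, dtype=np.int64)
    v1 = np.asarray(params.v1, dtype=np.int64)
    v2 = np.asarray(params.v2, dtype=np.int64)
    a = clamp_positions(p + v1, vol.shape)
    b = clamp_positions(p + v2, vol.shape)
    c = clamp_positions(p, vol.shape)
    d = vol.data
    return float(
        (float(d[a[0], a[1], a[2]]) - float(d[b[0], b[1], b[2]]))
        / float(d[c[0], c[1], c[2]])
    )


def propose_param_array(
    offset_range: OffsetRange, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` offset pairs, shape (n, 2, 3), uniform per component."""
    b = offset_range.bounds
    return rng.integers(-b, b + 1, size=(n, 2, 3), dtype=np.int64)


def propose_params(offset_range: OffsetRange, rng: np.random.Generator) -> FeatureParams:
    """Draw one offset pair uniformly (componentwise) from the range box."""
    pair = propose_param_array(offset_range, 1, rng)[0]
    return FeatureParams(tuple(pair[0]), tuple(pair[1]))


class FeatureEvaluator:
    """Vectorized feature evaluation over many samples and offset pairs.

    Volumes sharing one shape are stacked into a single 4-D array so a
    feature batch is three fancy-indexed gathers regardless of how many
    volumes the samples span; mixed shapes fall back to a per-volume loop.
    """

    def __init__(self, volumes) -> None:
        if isinstance(volumes, Volume):
            volumes = [volumes]
        self.volumes: list[Volume] = list(volumes)
        if not self.volumes:
            raise ValidationError("need at least one volume")
        shapes = {v.shape for v in self.volumes}
        self._uniform = len(shapes) == 1
        if self._uniform:
            self.shape = self.volumes[0].shape
            nx, ny, nz = self.shape
            self._flat = np.concatenate([v.data.ravel() for v in self.volumes])
            self._strides = np.array([ny * nz, nz, 1], dtype=np.int32)
            self._vol_stride = np.int32(nx * ny * nz)
            self._hi = np.array(self.shape, dtype=np.int32) - 1
        else:
            self.shape = None
            self._flat = None

    def _gather(self, vidx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Intensities at clamped positions; pos shape (..., 3)."""
        if self._uniform:
            p = np.minimum(np.maximum(pos, 0), self._hi)
            flat_idx = p @ self._strides + vidx * self._vol_stride
            return self._flat[flat_idx]
        out = np.empty(pos.shape[:-1], dtype=np.float32)
        for i, vol in enumerate(self.volumes):
            m = vidx == i
            if not np.any(m):
                continue
            hi = np.array(vol.shape) - 1
            p = np.clip(pos[m], 0, hi)
            out[m] = vol.data[p[..., 0], p[..., 1], p[..., 2]]
        return out

    def features(self, vidx: np.ndarray, pos: np.ndarray, thetas: np.ndarray) -> np.ndarray:
        """Feature matrix, shape (n_theta, n_samples), float32.

        ``pos`` is (n, 3) int, ``vidx`` (n,) int, ``thetas`` (n_theta, 2, 3).
        """
        pos = np.asarray(pos, dtype=np.int32)
        vidx = np.asarray(vidx, dtype=np.int32)
        thetas = np.asarray(thetas, dtype=np.int32)
        denom = self._gather(vidx, pos)  # (n,)
        p1 = pos[None, :, :] + thetas[:, None, 0, :]  # (n_theta, n, 3)
        p2 = pos[None, :, :] + thetas[:, None, 1, :]
        vb = np.broadcast_to(vidx, p1.shape[:-1])
        i1 = self._gather(vb, p1)
        i2 = self._gather(vb, p2)
        return (i1 - i2) / denom[None, :]
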
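"""Random tree walks and the colonial walk.

A single walker starts at a voxel, looks up its leaf in the regression
tree, samples one of the leaf's clustered unit directions with its cluster
probability, and steps a fixed distance along it; after ``n_steps`` such
steps its estimate is the mean of the visited (rounded) positions.  The
walk variance — the sum over the three axes of the population variance of
those positions — measures how well-guided the walk was: a converged walk
hovers in a dense cloud around the target and has low variance, a
misguided one drifts and has high variance.

A colonial walk runs ``n_walkers`` independent walkers from random starts
and returns the mean position of the walker with minimum walk variance.
With ``n_walkers = 1`` it reduces exactly to the single random tree walk
(RTW) baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tree import RegressionTree
from .volume import ValidationError, Volume

__all__ = [
    "WalkConfig",
    "WalkResult",
    "walk_variance",
    "single_walk",
    "colonial_walk",
    "sample_init_points",
]


@dataclass(frozen=True)
class WalkConfig:
    """Colony parameters: size N, step length (voxels) and step count."""

    n_walkers: int = 200
    step_length: float = 4.0
    n_steps: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_walkers < 1:
            raise ValidationError("n_walkers must be >= 1")
        if self.step_length <= 0:
            raise ValidationError("step_length must be > 0")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")

    def with_(self, **kw) -> "WalkConfig":
        d = {
            "n_walkers": self.n_walkers,
            "step_length": self.step_length,
            "n_steps": self.n_steps,
            "seed": self.seed,
        }
        d.update(kw)
        return WalkConfig(**d)


@dataclass
class WalkResult:
    """Per-walker summaries plus the minimum-variance selection."""

    init_points: np.ndarray          # (N, 3) int
    means: np.ndarray                # (N, 3) mean stepped position per walker
    variances: np.ndarray            # (N,) walk variance per walker
    selected: int                    # index attaining the minimum variance
    estimate: np.ndarray             # (3,) = means[selected]
    traces: np.ndarray | None = None  # (N, n_steps, 3) rounded stepped positions

    def to_dict(self) -> dict:
        return {
            "init_points": self.init_points.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "selected": int(self.selected),
            "estimate": self.estimate.tolist(),
        }


def walk_variance(trace) -> float:
    """Sum of per-axis population variances of a position trace.

    Implemented as a single-pass streaming (Welford) update, matching the
    two-pass definition to 1e-9; the result is a moment of the visited
    point set, independent of step order.
    """
    trace = np.asarray(trace, dtype=np.float64).reshape(-1, 3)
    if len(trace) == 0:
        raise ValidationError("walk variance of an empty trace is undefined")
    mean = np.zeros(3)
    m2 = np.zeros(3)
    for i, x in enumerate(trace, start=1):
        delta = x - mean
        mean += delta / i
        m2 += delta * (x - mean)
    return float(m2.sum() / len(trace))


def _run_colony(
    tree: RegressionTree,
    vol: Volume,
    starts: np.ndarray,
    step_length: float,
    n_steps: int,
    uniforms: np.ndarray,
    keep_traces: bool,
):
    """Step all walkers in lockstep; returns (means, variances, traces).

    ``uniforms`` is an (N, n_steps) matrix of per-walker random numbers —
    one per step, drawn from that walker's own substream — so a colony is
    bit-reproducible and a single walker is independent of colony size.

    Positions are kept in a continuous accumulator clamped to the volume
    box; the rounded integer voxel is used for tree traversal and is what
    the mean/variance accumulate (the initial point is not included).
    """
    hi = np.asarray(vol.shape, dtype=np.float64) - 1.0
    pos = np.asarray(starts, dtype=np.float64).reshape(-1, 3).copy()
    n = len(pos)
    mean = np.zeros((n, 3))
    m2 = np.zeros((n, 3))
    traces = np.zeros((n, n_steps, 3), dtype=np.int64) if keep_traces else None
    for m in range(n_steps):
        x_int = np.rint(pos).astype(np.int64)
        leaves = tree.traverse_batch(vol, x_int)
        dirs = tree.sample_directions(leaves, uniforms[:, m])
        pos = np.clip(pos + dirs * step_length, 0.0, hi)
        stepped = np.rint(pos)
        if traces is not None:
            traces[:, m] = stepped.astype(np.int64)
        delta = stepped - mean
        mean += delta / (m + 1)
        m2 += delta * (stepped - mean)
    variances = m2.sum(axis=1) / n_steps
    return mean, variances, traces


def single_walk(
    tree: RegressionTree,
    vol: Volume,
    start,
    step_length: float,
    n_steps: int,
    rng: np.random.Generator,
    *,
    keep_trace: bool = False,
):
    """One random tree walk; returns (mean position, walk variance, trace)."""
    start = np.asarray(start, dtype=np.int64).reshape(3)
    if not vol.contains(start):
        raise ValidationError(f"start {start} outside volume bounds {vol.shape}")
    uniforms = rng.random((1, n_steps))
    means, variances, traces = _run_colony(
        tree, vol, start[None], step_length, n_steps, uniforms, keep_trace
    )
    return means[0], float(variances[0]), (traces[0] if traces is not None else None)


def colonial_walk(
    tree: RegressionTree,
    vol: Volume,
    init_points,
    config: WalkConfig,
    *,
    keep_traces: bool = False,
) -> WalkResult:
    """Run the colony and select the minimum-variance walker.

    ``init_points`` must contain exactly ``config.n_walkers`` in-bounds
    integer positions.  Variance ties select the lowest walker index.
    """
    init_points = np.asarray(init_points, dtype=np.int64).reshape(-1, 3)
    if len(init_points) != config.n_walkers:
        raise ValidationError(
            f"{len(init_points)} init points for a colony of {config.n_walkers}"
        )
    for p in init_points:
        if not vol.contains(p):
            raise ValidationError(f"init point {p} outside volume bounds {vol.shape}")
    children = np.random.SeedSequence(config.seed).spawn(config.n_walkers)
    uniforms = np.stack(
        [np.random.default_rng(c).random(config.n_steps) for c in children]
    )
    means, variances, traces = _run_colony(
        tree, vol, init_points, config.step_length, config.n_steps, uniforms, keep_traces
    )
    selected = int(np.argmin(variances))  # argmin keeps the lowest index on ties
    return WalkResult(
        init_points=init_points,
        means=means,
        variances=variances,
        selected=selected,
        estimate=means[selected].copy(),
        traces=traces,
    )


def sample_init_points(
    vol: Volume,
    region,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform integer start points from a region intersected with bounds.

    ``region`` is either the string ``"whole-volume"`` or a pair
    ``(center, box_extent)`` where ``box_extent`` is the half-extent per
    axis (0 collapses that axis onto the center).
    """
    hi = np.asarray(vol.shape, dtype=np.int64) - 1
    if isinstance(region, str):
        if region != "whole-volume":
            raise ValidationError(f"unknown region {region!r}")
        lo_b = np.zeros(3, dtype=np.int64)
        hi_b = hi
    else:
        center, extent = region
        center = np.asarray(np.rint(center), dtype=np.int64)
        extent = np.asarray(extent, dtype=np.int64)
        lo_b = np.maximum(center - extent, 0)
        hi_b = np.minimum(center + extent, hi)
        if np.any(lo_b > hi_b):
            raise ValidationError(f"region {region} does not intersect the volume")
    return rng.integers(lo_b, hi_b + 1, size=(n, 3), dtype=np.int64)
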
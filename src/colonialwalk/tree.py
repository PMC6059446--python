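"""Randomized direction-regression trees.

A tree maps a voxel of a CT volume to a small set of representative unit
directions toward a target point.  Training samples are voxels ``x`` paired
with the unit vector ``u = (p - x) / ||p - x||`` toward the target ``p`` of
their volume.  Each internal node stores a voxel-difference feature and a
threshold; a node is split by the candidate ``(theta, tau)`` minimizing the
summed within-child squared deviation of the unit directions

    E(phi) = sum_{s in {l, r}} sum_{u in Q_s} ||u - mean(Q_s)||^2

over randomly proposed candidates.  Splitting stops when the mean deviation
falls below ``min_variance``, the node holds fewer than ``min_samples``
samples, the depth cap is hit, or no proposal yields a non-degenerate
split.  Each leaf then stores k-means cluster centroids of its directions
(empty clusters dropped, centroids re-normalized to unit length) together
with cluster population probabilities — the distribution a random walker
samples its step direction from.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .features import (
    FeatureEvaluator,
    FeatureParams,
    OffsetRange,
    feature_value,
    propose_param_array,
)
from .volume import ValidationError, Volume, clamp_positions

__all__ = [
    "TrainingSample",
    "SampleSet",
    "SplitNode",
    "LeafNode",
    "RegressionTree",
    "ModelFormatError",
    "make_samples",
    "split_objective",
    "best_split",
    "kmeans_directions",
    "train_tree",
    "traverse",
    "save_model",
    "load_model",
]


class ModelFormatError(ValidationError):
    """A serialized model violates the schema or its invariants."""


class TrainingSample(NamedTuple):
    """One training voxel: volume index, position, unit direction to target."""

    v: int
    x: np.ndarray
    u_hat: np.ndarray


@dataclass
class SampleSet:
    """Array-backed collection of training samples.

    ``pos`` is (n, 3) integer voxel positions, ``vidx`` (n,) volume indices
    and ``u`` (n, 3) unit directions toward the per-volume target.
    """

    pos: np.ndarray
    vidx: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64).reshape(-1, 3)
        self.vidx = np.asarray(self.vidx, dtype=np.int64).reshape(-1)
        self.u = np.asarray(self.u, dtype=np.float64).reshape(-1, 3)
        if not (len(self.pos) == len(self.vidx) == len(self.u)):
            raise ValidationError("sample arrays disagree in length")

    def __len__(self) -> int:
        return len(self.pos)

    def __getitem__(self, i: int) -> TrainingSample:
        return TrainingSample(int(self.vidx[i]), self.pos[i].copy(), self.u[i].copy())

    def subset(self, mask: np.ndarray) -> "SampleSet":
        return SampleSet(self.pos[mask], self.vidx[mask], self.u[mask])

    @classmethod
    def concatenate(cls, parts: Sequence["SampleSet"]) -> "SampleSet":
        return cls(
            np.concatenate([p.pos for p in parts]),
            np.concatenate([p.vidx for p in parts]),
            np.concatenate([p.u for p in parts]),
        )


def make_samples(
    vol: Volume,
    target,
    stride: int = 1,
    *,
    vol_index: int = 0,
    box: tuple | None = None,
) -> SampleSet:
    """Build unit-direction samples on a stride grid of a volume.

    One sample is produced per voxel whose every coordinate is a multiple
    of ``stride`` (within ``box = (lo, hi)`` inclusive bounds when given,
    otherwise the whole volume).  The voxel coinciding with the target is
    excluded: its direction is undefined.
    """
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    target = np.asarray(target, dtype=np.float64).reshape(3)
    if not vol.contains(target):
        raise ValidationError(f"target {target} outside volume bounds {vol.shape}")
    if box is None:
        lo = np.zeros(3, dtype=np.int64)
        hi = np.asarray(vol.shape, dtype=np.int64) - 1
    else:
        lo = np.maximum(np.asarray(box[0], dtype=np.int64), 0)
        hi = np.minimum(np.asarray(box[1], dtype=np.int64), np.asarray(vol.shape) - 1)
        if np.any(lo > hi):
            raise ValidationError(f"sample box {box} does not intersect the volume")
    axes = [
        np.arange(-(-int(lo[i]) // stride) * stride, int(hi[i]) + 1, stride)
        for i in range(3)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pos = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    diff = target[None, :] - pos
    norm = np.linalg.norm(diff, axis=1)
    keep = norm > 0
    u = diff[keep] / norm[keep, None]
    pos = pos[keep]
    return SampleSet(pos, np.full(len(pos), vol_index), u)


# ---------------------------------------------------------------------------
# Split objective and search
# ---------------------------------------------------------------------------

def _sum_sq_dev(dirs: np.ndarray) -> float:
    """sum ||u - mean||^2 over a direction set (0.0 for an empty set)."""
    if len(dirs) == 0:
        return 0.0
    d = np.asarray(dirs, dtype=np.float64)
    s = d.sum(axis=0)
    return float((d * d).sum() - (s @ s) / len(d))


def split_objective(left, right) -> float:
    """Summed within-child squared deviation of unit directions."""
    left = np.asarray(left, dtype=np.float64).reshape(-1, 3)
    right = np.asarray(right, dtype=np.float64).reshape(-1, 3)
    if len(left) == 0 and len(right) == 0:
        raise ValidationError("split objective undefined for two empty sides")
    return _sum_sq_dev(left) + _sum_sq_dev(right)


def _candidate_search(
    ev: FeatureEvaluator,
    samples: SampleSet,
    offset_range: OffsetRange,
    n_theta: int,
    n_tau: int,
    rng: np.random.Generator,
):
    """Best (theta, tau) over the random candidate grid, or None.

    Candidates are enumerated theta-major then tau; ties keep the first
    seen.  Per theta the node's samples are sorted by feature value once,
    prefix sums of the directions then give the objective of any threshold
    in O(1).  Thresholds are drawn uniformly between the empirical 5th and
    95th feature percentiles (order statistics at ranks
    ``floor(q * (n - 1))``) so splits are never trivially degenerate.

    The random draws — ``n_theta`` offset pairs, then an
    ``(n_theta, n_tau)`` uniform matrix mapped onto the percentile
    interval — all happen up front, so the candidate set is a pure
    function of the rng state and can be replayed independently.
    """
    n = len(samples)
    thetas = propose_param_array(offset_range, n_theta, rng)
    tau_u = rng.random((n_theta, n_tau))
    # Chunk the theta axis so the (chunk, n, 3) work arrays stay small.
    chunk = max(1, min(n_theta, int(4e6 // max(n, 1)) or 1))
    best = (np.inf, -1, np.nan)  # objective, flat candidate index, tau
    flat_base = 0
    u = samples.u
    usq_row = (u * u).sum(axis=1)
    for start in range(0, n_theta, chunk):
        th = thetas[start : start + chunk]
        F = ev.features(samples.vidx, samples.pos, th)  # (c, n)
        order = np.argsort(F, axis=1, kind="stable")
        Fs = np.take_along_axis(F, order, axis=1)
        cs = np.cumsum(u[order], axis=1)  # (c, n, 3)
        csq = np.cumsum(usq_row[order], axis=1)  # (c, n)
        q5 = Fs[:, int(0.05 * (n - 1))]
        q95 = Fs[:, int(0.95 * (n - 1))]
        taus = q5[:, None] + (q95 - q5)[:, None] * tau_u[start : start + chunk]
        for r in range(len(th)):
            k = np.searchsorted(Fs[r], taus[r], side="left")  # |left| per tau
            valid = (k > 0) & (k < n)
            if not valid.any():
                continue
            kv = k[valid]
            sl = cs[r, kv - 1]  # (m, 3) left direction sums
            tot = cs[r, n - 1]
            ssl = csq[r, kv - 1] - (sl * sl).sum(axis=1) / kv
            sr = tot[None, :] - sl
            ssr = (csq[r, n - 1] - csq[r, kv - 1]) - (sr * sr).sum(axis=1) / (n - kv)
            obj = ssl + ssr
            j = int(np.argmin(obj))
            if obj[j] < best[0]:
                flat = flat_base + r * n_tau + int(np.flatnonzero(valid)[j])
                best = (float(obj[j]), flat, float(taus[r][valid][j]))
        flat_base += len(th) * n_tau
    if best[1] < 0:
        return None
    theta = thetas[best[1] // n_tau]
    tau = best[2]
    # Recompute the winning feature column to materialize the partition.
    f = ev.features(samples.vidx, samples.pos, theta[None])[0]
    left_mask = f < tau
    return theta, tau, left_mask, best[0]


def best_split(
    samples: SampleSet,
    volumes,
    offset_range: OffsetRange,
    n_theta: int,
    n_tau: int,
    rng: np.random.Generator,
):
    """Search random split candidates; return the argmin or None.

    Returns ``(FeatureParams, tau, left SampleSet, right SampleSet)``, or
    ``None`` when every candidate leaves one side empty (the caller turns
    the node into a leaf).
    """
    if len(samples) < 2:
        raise ValidationError("need at least 2 samples to split")
    ev = volumes if isinstance(volumes, FeatureEvaluator) else FeatureEvaluator(volumes)
    found = _candidate_search(ev, samples, offset_range, n_theta, n_tau, rng)
    if found is None:
        return None
    theta, tau, left_mask, _ = found
    params = FeatureParams(tuple(theta[0]), tuple(theta[1]))
    return params, tau, samples.subset(left_mask), samples.subset(~left_mask)


# ---------------------------------------------------------------------------
# Leaf model: k-means over unit directions
# ---------------------------------------------------------------------------

def kmeans_directions(
    dirs: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd's k-means over direction vectors.

    Initialized with ``k`` distinct samples chosen at random; empty
    clusters arising during the iterations are dropped; final centroids
    are re-normalized to unit length (walkers step a fixed distance along
    them, so their magnitude must be 1).  Returns ``(probs, centroids)``
    with probabilities proportional to final cluster populations.
    """
    dirs = np.asarray(dirs, dtype=np.float64).reshape(-1, 3)
    n = len(dirs)
    if n == 0:
        raise ValidationError("cannot cluster an empty direction set")
    k = min(k, n)
    cent = dirs[rng.choice(n, size=k, replace=False)].copy()
    assign = None
    for _ in range(n_iter):
        d2 = ((dirs[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        counts = np.bincount(new_assign, minlength=len(cent))
        keep = counts > 0
        sums = np.stack(
            [np.bincount(new_assign, weights=dirs[:, d], minlength=len(cent)) for d in range(3)],
            axis=1,
        )
        cent = sums[keep] / counts[keep, None]
        if len(cent) < len(counts):
            # Renumber assignments after dropping empty clusters.
            remap = np.cumsum(keep) - 1
            new_assign = remap[new_assign]
            counts = counts[keep]
        if assign is not None and len(new_assign) == len(assign) and np.array_equal(new_assign, assign):
            assign = new_assign
            break
        assign = new_assign
    counts = np.bincount(assign, minlength=len(cent))
    probs = counts / n
    norms = np.linalg.norm(cent, axis=1)
    # A centroid of opposing directions can have ~zero norm; fall back to
    # the direction of its first member so the unit-length contract holds.
    for j in np.flatnonzero(norms < 1e-9):
        cent[j] = dirs[np.flatnonzero(assign == j)[0]]
        norms[j] = np.linalg.norm(cent[j])
    cent = cent / norms[:, None]
    return probs, cent


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class SplitNode:
    params: FeatureParams
    tau: float
    left: int
    right: int


@dataclass
class LeafNode:
    """Cluster probabilities (k,) and unit centroid directions (k, 3)."""

    probs: np.ndarray
    dirs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64).reshape(-1)
        self.dirs = np.asarray(self.dirs, dtype=np.float64).reshape(-1, 3)
        if len(self.probs) != len(self.dirs) or len(self.probs) == 0:
            raise ValidationError("leaf clusters malformed")
        if abs(self.probs.sum() - 1.0) > 1e-9 or np.any(self.probs <= 0):
            raise ValidationError("leaf probabilities must be positive and sum to 1")
        if np.any(np.abs(np.linalg.norm(self.dirs, axis=1) - 1.0) > 1e-6):
            raise ValidationError("leaf centroids must be unit vectors")


@dataclass
class RegressionTree:
    """Binary direction-regression tree with preorder-indexed nodes."""

    nodes: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValidationError("tree has no nodes")
        self._finalize()

    def _finalize(self) -> None:
        n = len(self.nodes)
        self._is_leaf = np.zeros(n, dtype=bool)
        self._v1 = np.zeros((n, 3), dtype=np.int64)
        self._v2 = np.zeros((n, 3), dtype=np.int64)
        self._tau = np.zeros(n)
        self._left = np.zeros(n, dtype=np.int64)
        self._right = np.zeros(n, dtype=np.int64)
        k_pad = max(
            (len(nd.probs) for nd in self.nodes if isinstance(nd, LeafNode)), default=1
        )
        self._cum = np.ones((n, k_pad))
        self._dirs = np.zeros((n, k_pad, 3))
        for i, nd in enumerate(self.nodes):
            if isinstance(nd, LeafNode):
                self._is_leaf[i] = True
                k = len(nd.probs)
                self._cum[i, :k] = np.cumsum(nd.probs)
                self._cum[i, k - 1 :] = 1.0 + 1e-12  # guard fp shortfall
                self._dirs[i, :k] = nd.dirs
                self._dirs[i, k:] = nd.dirs[-1]
            elif isinstance(nd, SplitNode):
                self._v1[i] = nd.params.v1
                self._v2[i] = nd.params.v2
                self._tau[i] = nd.tau
                self._left[i] = nd.left
                self._right[i] = nd.right
            else:  # pragma: no cover - construction guards this
                raise ValidationError(f"unknown node type at index {i}")
        self._check_reachability()

    def _check_reachability(self) -> None:
        seen = np.zeros(len(self.nodes), dtype=bool)
        stack = [0]
        while stack:
            i = stack.pop()
            if i < 0 or i >= len(self.nodes) or seen[i]:
                raise ModelFormatError("tree node graph is not a valid binary tree")
            seen[i] = True
            if not self._is_leaf[i]:
                stack.extend((int(self._left[i]), int(self._right[i])))
        if not seen.all():
            raise ModelFormatError("unreachable nodes in the tree")

    @property
    def n_leaves(self) -> int:
        return int(self._is_leaf.sum())

    @property
    def max_k(self) -> int:
        return self._cum.shape[1]

    def traverse_batch(self, vol: Volume, pos: np.ndarray) -> np.ndarray:
        """Leaf node index for each (clamped) position; pos (m, 3) int."""
        pos = clamp_positions(np.asarray(pos, dtype=np.int64).reshape(-1, 3), vol.shape)
        data = vol.data
        hi = np.asarray(vol.shape) - 1
        node = np.zeros(len(pos), dtype=np.int64)
        active = ~self._is_leaf[node]
        while active.any():
            na = node[active]
            pa = pos[active]
            p1 = np.clip(pa + self._v1[na], 0, hi)
            p2 = np.clip(pa + self._v2[na], 0, hi)
            i1 = data[p1[:, 0], p1[:, 1], p1[:, 2]].astype(np.float64)
            i2 = data[p2[:, 0], p2[:, 1], p2[:, 2]].astype(np.float64)
            i0 = data[pa[:, 0], pa[:, 1], pa[:, 2]].astype(np.float64)
            f = (i1 - i2) / i0
            node[active] = np.where(f < self._tau[na], self._left[na], self._right[na])
            active = ~self._is_leaf[node]
        return node

    def sample_directions(
        self, leaf_idx: np.ndarray, r: np.ndarray
    ) -> np.ndarray:
        """Step directions for walkers at ``leaf_idx`` given uniforms ``r``."""
        cum = self._cum[leaf_idx]  # (m, k_pad)
        j = (r[:, None] >= cum).sum(axis=1)
        return self._dirs[leaf_idx, j]

    def leaf(self, idx: int) -> LeafNode:
        nd = self.nodes[idx]
        if not isinstance(nd, LeafNode):
            raise ValidationError(f"node {idx} is not a leaf")
        return nd


def traverse(tree: RegressionTree, vol: Volume, pos) -> LeafNode:
    """Descend from the root (left when feature < tau) to the reached leaf."""
    i = 0
    node = tree.nodes[i]
    while isinstance(node, SplitNode):
        f = feature_value(vol, pos, node.params)
        i = node.left if f < node.tau else node.right
        node = tree.nodes[i]
    return node


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_tree(
    samples: SampleSet,
    volumes,
    offset_range: OffsetRange,
    rng: np.random.Generator,
    *,
    min_variance: float = 0.05,
    min_samples: int = 20,
    k_max: int = 8,
    n_theta: int = 200,
    n_tau: int = 10,
    max_depth: int = 25,
    meta: dict | None = None,
) -> RegressionTree:
    """Grow a direction-regression tree by recursive randomized splitting.

    ``min_variance`` is the mean squared deviation of a node's unit
    directions below which it becomes a leaf (the deviation of unit
    vectors is bounded by 4, so 0.05 means near-consensus);
    ``min_samples`` is the smallest node worth splitting.  ``max_depth``
    caps pathological recursion.
    """
    if len(samples) == 0:
        raise ValidationError("cannot train on an empty sample set")
    ev = volumes if isinstance(volumes, FeatureEvaluator) else FeatureEvaluator(volumes)

    nodes: list = []
    depth_seen = 0

    def build(sub: SampleSet, depth: int) -> int:
        nonlocal depth_seen
        depth_seen = max(depth_seen, depth)
        idx = len(nodes)
        nodes.append(None)  # reserve preorder slot
        n = len(sub)
        mean_var = _sum_sq_dev(sub.u) / n
        split = None
        if n >= min_samples and mean_var >= min_variance and depth < max_depth:
            split = _candidate_search(ev, sub, offset_range, n_theta, n_tau, rng)
        if split is None:
            probs, cent = kmeans_directions(sub.u, k_max, rng)
            nodes[idx] = LeafNode(probs, cent)
            return idx
        theta, tau, left_mask, _ = split
        left = build(sub.subset(left_mask), depth + 1)
        right = build(sub.subset(~left_mask), depth + 1)
        nodes[idx] = SplitNode(FeatureParams(tuple(theta[0]), tuple(theta[1])), tau, left, right)
        return idx

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * max_depth + 100))
    try:
        build(samples, 0)
    finally:
        sys.setrecursionlimit(old_limit)

    info = {
        "stop": {"min_variance": min_variance, "min_samples": min_samples},
        "k_max": k_max,
        "offset_range": [offset_range.max_x, offset_range.max_y, offset_range.max_z],
        "n_theta": n_theta,
        "n_tau": n_tau,
        "max_depth": max_depth,
        "depth": depth_seen,
        "n_samples": len(samples),
    }
    if meta:
        info.update(meta)
    return RegressionTree(nodes, info)


# ---------------------------------------------------------------------------
# Serialization (JSON, preorder node list)
# ---------------------------------------------------------------------------

def _tree_to_dict(tree: RegressionTree) -> dict:
    out_nodes = []
    for nd in tree.nodes:
        if isinstance(nd, LeafNode):
            out_nodes.append(
                {
                    "type": "leaf",
                    "clusters": [
                        [float(p), float(d[0]), float(d[1]), float(d[2])]
                        for p, d in zip(nd.probs, nd.dirs)
                    ],
                }
            )
        else:
            out_nodes.append(
                {
                    "type": "split",
                    "v1": list(nd.params.v1),
                    "v2": list(nd.params.v2),
                    "tau": float(nd.tau),
                    "left": nd.left,
                    "right": nd.right,
                }
            )
    return {"meta": tree.meta, "nodes": out_nodes}


def save_model(tree: RegressionTree, path) -> Path:
    """Write the model JSON (sorted keys, so identical trees are byte-equal)."""
    path = Path(path)
    path.write_text(json.dumps(_tree_to_dict(tree), sort_keys=True) + "\n")
    return path


def load_model(path) -> RegressionTree:
    """Load a model JSON, re-validating every structural invariant."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
        raw_nodes = doc["nodes"]
        meta = doc.get("meta", {})
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ModelFormatError(f"bad model file {path}: {exc}") from exc
    nodes: list = []
    for i, nd in enumerate(raw_nodes):
        try:
            if nd["type"] == "leaf":
                clusters = np.asarray(nd["clusters"], dtype=np.float64)
                nodes.append(LeafNode(clusters[:, 0], clusters[:, 1:4]))
            elif nd["type"] == "split":
                nodes.append(
                    SplitNode(
                        FeatureParams(tuple(nd["v1"]), tuple(nd["v2"])),
                        float(nd["tau"]),
                        int(nd["left"]),
                        int(nd["right"]),
                    )
                )
            else:
                raise ModelFormatError(f"unknown node type {nd['type']!r}")
        except (KeyError, IndexError, TypeError, ValidationError) as exc:
            raise ModelFormatError(f"{path}: invalid node {i}: {exc}") from exc
    try:
        return RegressionTree(nodes, meta)
    except ValidationError as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
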
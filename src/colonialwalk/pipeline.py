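"""Two-phase landmark localization pipeline.

Phase 1 (global): one tree, trained on stride-sampled voxels of whole
volumes, learns directions to a single representative valve point ``x_g``
(by default the non-coronary hinge — every landmark lies within +-50
voxels of it at full scale).  A colonial walk started anywhere in a test
volume lands near ``x_g``; a 30-voxel error is tolerated here because the
estimate only seeds phase 2.

Phase 2 (local): eight trees, one per landmark, trained on the voxels of
a cuboid centered at the landmark (full-scale 160 x 160 x 80 — large
enough to contain the phase-1 estimate despite its error; clipped at
volume borders).  Colonial walks start from a small box scattered around
the phase-1 estimate and localize each landmark with its own tree.

The RTW baseline is the identical pipeline with colony size 1 at both
phases, consuming byte-identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import GLOBAL_OFFSET_RANGE, LOCAL_OFFSET_RANGE, OffsetRange
from .tree import (
    RegressionTree,
    SampleSet,
    load_model,
    make_samples,
    save_model,
    train_tree,
)
from .volume import LANDMARK_NAMES, LandmarkSet, ValidationError, Volume
from .walk import WalkConfig, WalkResult, colonial_walk, sample_init_points

__all__ = [
    "TreeConfig",
    "GlobalPhaseConfig",
    "LocalPhaseConfig",
    "PhaseConfig",
    "TwoPhaseModel",
    "train_two_phase",
    "localize",
    "localize_rtw",
    "evaluate_model",
    "step_sweep",
]

#: Full-scale cuboid (voxels) that bounds all eight landmarks.
LANDMARK_BOUNDING_CUBOID = (150, 150, 60)


@dataclass(frozen=True)
class TreeConfig:
    """Training hyperparameters shared by the trees of one phase."""

    min_variance: float = 0.05
    min_samples: int = 20
    k_max: int = 8
    n_theta: int = 200
    n_tau: int = 10
    max_depth: int = 25
    max_samples: int | None = None  # random cap on the training set size


@dataclass(frozen=True)
class GlobalPhaseConfig:
    target: str = "h_n"
    stride: int = 4
    offset_range: OffsetRange = GLOBAL_OFFSET_RANGE
    walk: WalkConfig = field(default_factory=WalkConfig)
    accept_radius: float = 30.0
    tree: TreeConfig = field(default_factory=TreeConfig)

    def __post_init__(self) -> None:
        if self.accept_radius <= 0:
            raise ValidationError("accept_radius must be > 0")
        if self.target not in LANDMARK_NAMES and self.target != "x_g":
            raise ValidationError(f"unknown global target {self.target!r}")


@dataclass(frozen=True)
class LocalPhaseConfig:
    cuboid: tuple[int, int, int] = (160, 160, 80)
    stride: int = 1
    offset_range: OffsetRange = LOCAL_OFFSET_RANGE
    init_box: tuple[int, int, int] = (10, 10, 5)  # half-extents around x_g'
    walk: WalkConfig = field(default_factory=WalkConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)

    def __post_init__(self) -> None:
        if any(
            c < b for c, b in zip(self.cuboid, LANDMARK_BOUNDING_CUBOID)
        ) and tuple(self.cuboid) != tuple(LANDMARK_BOUNDING_CUBOID):
            # Desk-scale volumes are smaller than the bounding cuboid itself;
            # the contract is that the cuboid never under-covers the
            # landmark spread, which border clipping preserves.
            raise ValidationError(
                f"local cuboid {self.cuboid} smaller than the landmark "
                f"bounding cuboid {LANDMARK_BOUNDING_CUBOID}"
            )


@dataclass(frozen=True)
class PhaseConfig:
    global_: GlobalPhaseConfig = field(default_factory=GlobalPhaseConfig)
    local_: LocalPhaseConfig = field(default_factory=LocalPhaseConfig)

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        def walk_d(w: WalkConfig) -> dict:
            return {
                "n_walkers": w.n_walkers,
                "step_length": w.step_length,
                "n_steps": w.n_steps,
                "seed": w.seed,
            }

        def tree_d(t: TreeConfig) -> dict:
            return {
                "min_variance": t.min_variance,
                "min_samples": t.min_samples,
                "k_max": t.k_max,
                "n_theta": t.n_theta,
                "n_tau": t.n_tau,
                "max_depth": t.max_depth,
                "max_samples": t.max_samples,
            }

        g, l = self.global_, self.local_
        return {
            "schema": 1,
            "global": {
                "target": g.target,
                "stride": g.stride,
                "offset_range": [g.offset_range.max_x, g.offset_range.max_y, g.offset_range.max_z],
                "accept_radius": g.accept_radius,
                "walk": walk_d(g.walk),
                "tree": tree_d(g.tree),
            },
            "local": {
                "cuboid": list(l.cuboid),
                "stride": l.stride,
                "offset_range": [l.offset_range.max_x, l.offset_range.max_y, l.offset_range.max_z],
                "init_box": list(l.init_box),
                "walk": walk_d(l.walk),
                "tree": tree_d(l.tree),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseConfig":
        known = {"schema", "global", "local"}
        bad = set(d) - known
        if bad:
            raise ValidationError(f"unknown config key(s): {sorted(bad)}")
        g = d.get("global", {})
        l = d.get("local", {})

        def check(sub: dict, allowed: set, ctx: str) -> None:
            bad = set(sub) - allowed
            if bad:
                raise ValidationError(f"unknown {ctx} config key(s): {sorted(bad)}")

        check(g, {"target", "stride", "offset_range", "accept_radius", "walk", "tree"}, "global")
        check(l, {"cuboid", "stride", "offset_range", "init_box", "walk", "tree"}, "local")
        gd, ld = GlobalPhaseConfig(), LocalPhaseConfig()
        g_walk = WalkConfig(**{**{
            "n_walkers": gd.walk.n_walkers, "step_length": gd.walk.step_length,
            "n_steps": gd.walk.n_steps, "seed": gd.walk.seed}, **g.get("walk", {})})
        l_walk = WalkConfig(**{**{
            "n_walkers": ld.walk.n_walkers, "step_length": ld.walk.step_length,
            "n_steps": ld.walk.n_steps, "seed": ld.walk.seed}, **l.get("walk", {})})
        g_tree = TreeConfig(**{**TreeConfig().__dict__, **g.get("tree", {})})
        l_tree = TreeConfig(**{**TreeConfig().__dict__, **l.get("tree", {})})
        return cls(
            global_=GlobalPhaseConfig(
                target=g.get("target", gd.target),
                stride=int(g.get("stride", gd.stride)),
                offset_range=OffsetRange(*g.get("offset_range", [80, 80, 40])),
                walk=g_walk,
                accept_radius=float(g.get("accept_radius", gd.accept_radius)),
                tree=g_tree,
            ),
            local_=LocalPhaseConfig(
                cuboid=tuple(l.get("cuboid", ld.cuboid)),
                stride=int(l.get("stride", ld.stride)),
                offset_range=OffsetRange(*l.get("offset_range", [40, 40, 20])),
                init_box=tuple(l.get("init_box", ld.init_box)),
                walk=l_walk,
                tree=l_tree,
            ),
        )


def desk_scale_config() -> PhaseConfig:
    """Study configuration for desk-scale (96 x 96 x 72) phantom volumes.

    Obtained by scaling the full-scale clinical geometry (512 x 512 x ~300
    voxels) by the same ~5x factor as the phantom grid: feature offset
    ranges 15/15/10 (global) and 8/8/5 (local) voxels, step lengths 4
    (global) and 2 (local) voxels with 64 steps, colony size 200, global
    stride 4 and local stride 3.  Candidate counts (40 x 8 global, 20 x 8
    local) and ``min_samples = 50`` keep training proportionate to the
    reduced sample counts.
    """
    return PhaseConfig(
        global_=GlobalPhaseConfig(
            target="h_n",
            stride=4,
            offset_range=OffsetRange(15, 15, 10),
            walk=WalkConfig(n_walkers=200, step_length=4.0, n_steps=64),
            accept_radius=30.0,
            tree=TreeConfig(min_samples=50, n_theta=40, n_tau=8, max_samples=200_000),
        ),
        local_=LocalPhaseConfig(
            cuboid=(160, 160, 80),
            stride=3,
            offset_range=OffsetRange(8, 8, 5),
            init_box=(10, 10, 5),
            walk=WalkConfig(n_walkers=200, step_length=2.0, n_steps=64),
            tree=TreeConfig(min_samples=50, n_theta=20, n_tau=8, max_samples=150_000),
        ),
    )


@dataclass
class TwoPhaseModel:
    """One global tree plus one local tree per landmark."""

    global_tree: RegressionTree
    local_trees: dict[str, RegressionTree]
    config: PhaseConfig

    def __post_init__(self) -> None:
        missing = [n for n in LANDMARK_NAMES if n not in self.local_trees]
        extra = [n for n in self.local_trees if n not in LANDMARK_NAMES]
        if missing or extra:
            raise ValidationError(
                f"local trees must cover exactly {LANDMARK_NAMES}; "
                f"missing={missing} extra={extra}"
            )

    def save(self, bundle_dir) -> Path:
        bundle_dir = Path(bundle_dir)
        bundle_dir.mkdir(parents=True, exist_ok=True)
        save_model(self.global_tree, bundle_dir / "global.json")
        for name, tree in self.local_trees.items():
            save_model(tree, bundle_dir / f"local_{name}.json")
        (bundle_dir / "phase_config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=True)
        )
        return bundle_dir

    @classmethod
    def load(cls, bundle_dir) -> "TwoPhaseModel":
        bundle_dir = Path(bundle_dir)
        config = PhaseConfig.from_dict(
            yaml.safe_load((bundle_dir / "phase_config.yaml").read_text())
        )
        global_tree = load_model(bundle_dir / "global.json")
        local_trees = {
            name: load_model(bundle_dir / f"local_{name}.json")
            for name in LANDMARK_NAMES
        }
        return cls(global_tree, local_trees, config)


def _dataset_pairs(dataset) -> list[tuple[Volume, LandmarkSet]]:
    pairs = []
    for item in dataset:
        vol, lm = item  # PhantomSample unpacks to (volume, landmarks)
        if not isinstance(lm, LandmarkSet):
            raise ValidationError(
                f"expected a LandmarkSet annotation, got {type(lm).__name__}"
            )
        lm.validate_bounds(vol)
        pairs.append((vol, lm))
    if not pairs:
        raise ValidationError("empty training dataset")
    return pairs


def local_sample_box(center: np.ndarray, cuboid) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive cuboid bounds around a landmark (before volume clipping)."""
    c = np.asarray(center, dtype=np.float64)
    half = np.asarray(cuboid, dtype=np.float64) / 2.0
    lo = np.ceil(c - half).astype(np.int64)
    hi = np.floor(c + half).astype(np.int64)
    return lo, hi


def _capped(samples: SampleSet, max_samples: int | None, rng) -> SampleSet:
    """Random subsample down to ``max_samples`` (keeps all when None)."""
    if max_samples is None or len(samples) <= max_samples:
        return samples
    idx = rng.choice(len(samples), size=max_samples, replace=False)
    idx.sort()
    return SampleSet(samples.pos[idx], samples.vidx[idx], samples.u[idx])


def train_two_phase(dataset, config: PhaseConfig, seed: int = 0) -> TwoPhaseModel:
    """Train the global tree and the eight local trees.

    ``dataset`` is a sequence of ``(Volume, LandmarkSet)`` pairs (or
    :class:`~colonialwalk.phantom.PhantomSample`).  Each of the nine trees
    trains from its own random substream derived from ``seed``.
    """
    pairs = _dataset_pairs(dataset)
    volumes = [v for v, _ in pairs]
    streams = np.random.SeedSequence(seed).spawn(1 + len(LANDMARK_NAMES))

    g = config.global_
    global_parts = []
    for i, (vol, lm) in enumerate(pairs):
        target = lm.global_point if g.target == "x_g" else lm[g.target]
        if target is None:
            raise ValidationError(f"volume {i} has no global point annotation")
        global_parts.append(make_samples(vol, target, g.stride, vol_index=i))
    gt = g.tree
    g_rng = np.random.default_rng(streams[0])
    global_tree = train_tree(
        _capped(SampleSet.concatenate(global_parts), gt.max_samples, g_rng),
        volumes,
        g.offset_range,
        g_rng,
        min_variance=gt.min_variance,
        min_samples=gt.min_samples,
        k_max=gt.k_max,
        n_theta=gt.n_theta,
        n_tau=gt.n_tau,
        max_depth=gt.max_depth,
        meta={"phase": "global", "target": g.target, "seed": seed, "stride": g.stride},
    )

    l = config.local_
    lt = l.tree
    local_trees = {}
    for j, name in enumerate(LANDMARK_NAMES):
        parts = []
        for i, (vol, lm) in enumerate(pairs):
            lo, hi = local_sample_box(lm[name], l.cuboid)
            parts.append(
                make_samples(vol, lm[name], l.stride, vol_index=i, box=(lo, hi))
            )
        l_rng = np.random.default_rng(streams[1 + j])
        local_trees[name] = train_tree(
            _capped(SampleSet.concatenate(parts), lt.max_samples, l_rng),
            volumes,
            l.offset_range,
            l_rng,
            min_variance=lt.min_variance,
            min_samples=lt.min_samples,
            k_max=lt.k_max,
            n_theta=lt.n_theta,
            n_tau=lt.n_tau,
            max_depth=lt.max_depth,
            meta={"phase": "local", "target": name, "seed": seed, "stride": l.stride},
        )
    return TwoPhaseModel(global_tree, local_trees, config)


def _derived_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def localize(
    model: TwoPhaseModel, vol: Volume, seed: int = 0
) -> tuple[LandmarkSet, dict]:
    """Run both phases; returns predicted landmarks and walk diagnostics.

    Always returns an estimate — failure is signalled diagnostically by a
    large minimum walk variance in the global phase, never by refusing to
    answer.
    """
    cfg = model.config
    streams = np.random.SeedSequence(seed).spawn(2 + 2 * len(LANDMARK_NAMES))

    g = cfg.global_
    init = sample_init_points(
        vol, "whole-volume", g.walk.n_walkers, np.random.default_rng(streams[0])
    )
    g_result = colonial_walk(
        model.global_tree, vol, init, g.walk.with_(seed=_derived_seed(streams[1]))
    )
    x_g_prime = np.rint(g_result.estimate).astype(np.int64)

    l = cfg.local_
    points: dict[str, np.ndarray] = {}
    local_diag: dict[str, WalkResult] = {}
    for j, name in enumerate(LANDMARK_NAMES):
        init_l = sample_init_points(
            vol,
            (x_g_prime, l.init_box),
            l.walk.n_walkers,
            np.random.default_rng(streams[2 + 2 * j]),
        )
        result = colonial_walk(
            model.local_trees[name],
            vol,
            init_l,
            l.walk.with_(seed=_derived_seed(streams[3 + 2 * j])),
        )
        points[name] = result.estimate
        local_diag[name] = result
    prediction = LandmarkSet(points, global_point=x_g_prime.astype(float))
    diagnostics = {
        "global": g_result,
        "x_g_prime": x_g_prime,
        "local": local_diag,
        "min_global_variance": float(g_result.variances.min()),
    }
    return prediction, diagnostics


def localize_rtw(
    model: TwoPhaseModel, vol: Volume, seed: int = 0
) -> tuple[LandmarkSet, dict]:
    """The single-walker (RTW) baseline: colony size 1 at both phases.

    Consumes the very same trees as :func:`localize` — the comparison is
    controlled: only the colony size and variance-based selection differ.
    """
    cfg = model.config
    rtw_cfg = PhaseConfig(
        global_=replace(cfg.global_, walk=cfg.global_.walk.with_(n_walkers=1)),
        local_=replace(cfg.local_, walk=cfg.local_.walk.with_(n_walkers=1)),
    )
    view = TwoPhaseModel(model.global_tree, model.local_trees, rtw_cfg)
    return localize(view, vol, seed)


# ---------------------------------------------------------------------------
# Dataset-level evaluation and the step-size sweep
# ---------------------------------------------------------------------------

def evaluate_model(
    model: TwoPhaseModel,
    dataset,
    seed: int = 0,
    method: str = "colonial",
) -> dict:
    """Localize every volume of a dataset and tabulate errors.

    Returns ``errors_mm`` and ``errors_vox`` DataFrames (volumes x the 8
    landmarks), the per-volume phase-1 error in voxels, and the raw
    diagnostics.
    """
    from .metrics import localization_error

    run = {"colonial": localize, "rtw": localize_rtw}[method]
    pairs = _dataset_pairs(dataset)
    streams = np.random.SeedSequence(seed).spawn(len(pairs))
    rows_mm, rows_vox, phase1, diags = [], [], [], []
    for (vol, lm), ss in zip(pairs, streams):
        pred, diag = run(model, vol, _derived_seed(ss))
        rows_mm.append(
            {n: localization_error(pred[n], lm[n], vol.spacing) for n in LANDMARK_NAMES}
        )
        rows_vox.append(
            {n: float(np.linalg.norm(pred[n] - lm[n])) for n in LANDMARK_NAMES}
        )
        target = lm.global_point if lm.global_point is not None else lm[model.config.global_.target]
        phase1.append(float(np.linalg.norm(diag["x_g_prime"] - target)))
        diags.append(diag)
    return {
        "errors_mm": pd.DataFrame(rows_mm),
        "errors_vox": pd.DataFrame(rows_vox),
        "phase1_error_vox": pd.Series(phase1, name="phase1_error_vox"),
        "diagnostics": diags,
    }


def step_sweep(
    model: TwoPhaseModel,
    dataset,
    step_lengths,
    step_counts,
    seed: int = 0,
    n_reps: int = 20,
    target: str = "h_n",
    init_half_extent: int = 20,
) -> pd.DataFrame:
    """Mean localization error of single local-phase walks over a
    (step_length x n_steps) grid.

    Walks use the ``target`` landmark's tree and start from random points
    within ``init_half_extent`` voxels of the true global point,
    emulating phase-2 initialization after an imperfect phase 1.  One row
    per grid cell with the mean, SD and variance of the per-walk error.
    """
    from .metrics import localization_error
    from .walk import single_walk

    pairs = _dataset_pairs(dataset)
    tree = model.local_trees[target]
    rows = []
    for sl in step_lengths:
        for ns in step_counts:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, int(round(sl * 8)), int(ns)])
            )
            errs = []
            for rep in range(n_reps):
                vol, lm = pairs[rep % len(pairs)]
                anchor = lm.global_point if lm.global_point is not None else lm[target]
                start = sample_init_points(
                    vol, (anchor, (init_half_extent,) * 3), 1, rng
                )[0]
                mean_pos, _, _ = single_walk(tree, vol, start, sl, int(ns), rng)
                errs.append(localization_error(mean_pos, lm[target], vol.spacing))
            errs = np.asarray(errs)
            rows.append(
                {
                    "step_length": float(sl),
                    "n_steps": int(ns),
                    "mean_error_mm": float(errs.mean()),
                    "sd_error_mm": float(errs.std(ddof=1)) if len(errs) > 1 else 0.0,
                    "var_error_mm": float(errs.var(ddof=1)) if len(errs) > 1 else 0.0,
                    "n_reps": len(errs),
                }
            )
    return pd.DataFrame(rows)
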
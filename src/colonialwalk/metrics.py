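"""Quantitative evaluation: localization errors, TAVI sizing geometry,
error distribution tails and the walk-variance diagnostic.

Localization error is the Euclidean distance in millimetres between a
predicted and a true landmark after scaling voxel indices by the voxel
spacing.  The sizing metrics follow standard TAVI planning practice: the
annulus diameter is the diameter of the circle through the three hinge
points, and the ostia distance is the mean unsigned distance of the two
coronary ostia from the hinge (annulus) plane.  View-plane agreement is
measured by the cosine distance between plane normals, taken
orientation-insensitively (a plane is unchanged by flipping its normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import LANDMARK_NAMES, ValidationError

__all__ = [
    "LANDMARK_GROUPS",
    "AnnulusGeometry",
    "ErrorReport",
    "localization_error",
    "annulus_from_hinges",
    "ostia_plane_distance",
    "plane_normal_cosine_distance",
    "summarize_errors",
    "error_ccdf",
    "variance_error_table",
]

#: Standard grouping of the eight landmarks for reporting.
LANDMARK_GROUPS: dict[str, tuple[str, ...]] = {
    "hinges": ("h_r", "h_n", "h_l"),
    "commissures": ("c_rn", "c_nl", "c_lr"),
    "ostia": ("o_r", "o_l"),
}


def localization_error(pred, truth, spacing) -> float:
    """Euclidean distance in mm between two voxel-coordinate points."""
    spacing = np.asarray(spacing, dtype=np.float64)
    if np.any(spacing <= 0):
        raise ValidationError(f"spacing must be positive, got {spacing}")
    d = (np.asarray(pred, dtype=np.float64) - np.asarray(truth, dtype=np.float64)) * spacing
    return float(np.linalg.norm(d))


# ---------------------------------------------------------------------------
# Annulus geometry
# ---------------------------------------------------------------------------

def _canonical_normal(n: np.ndarray) -> np.ndarray:
    """Sign convention: positive Z, ties broken by positive Y then X."""
    for axis in (2, 1, 0):
        if abs(n[axis]) > 1e-12:
            return n if n[axis] > 0 else -n
    return n


@dataclass(frozen=True)
class AnnulusGeometry:
    """Circumcircle of the three hinges and the plane they span (mm units)."""

    center: np.ndarray
    diameter: float
    normal: np.ndarray
    offset: float  # plane equation: normal . x = offset

    def plane_distance(self, point) -> float:
        return float(abs(np.dot(self.normal, np.asarray(point, dtype=np.float64)) - self.offset))


def annulus_from_hinges(h_r, h_n, h_l) -> AnnulusGeometry:
    """Exact circumcircle of the three hinge points (closed form).

    Diameter ``= abc / (2 * area)`` from the side lengths; the center is
    the circumcenter in barycentric coordinates
    ``a^2 (b^2 + c^2 - a^2) : b^2 (c^2 + a^2 - b^2) : c^2 (a^2 + b^2 - c^2)``.
    The irregularly elliptical real annulus is deliberately summarized by
    this circle fit, which averages the three hinge separations.
    """
    p = [np.asarray(v, dtype=np.float64).reshape(3) for v in (h_r, h_n, h_l)]
    a = np.linalg.norm(p[1] - p[2])  # side opposite h_r
    b = np.linalg.norm(p[2] - p[0])
    c = np.linalg.norm(p[0] - p[1])
    cross = np.cross(p[1] - p[0], p[2] - p[0])
    area2 = np.linalg.norm(cross)  # = 2 * triangle area
    if area2 < 1e-12 * max(a, b, c, 1.0) ** 2:
        raise ValidationError("hinges are collinear or coincident; no circumcircle")
    diameter = a * b * c / area2
    w = np.array(
        [
            a * a * (b * b + c * c - a * a),
            b * b * (c * c + a * a - b * b),
            c * c * (a * a + b * b - c * c),
        ]
    )
    center = (w[:, None] * np.stack(p)).sum(axis=0) / w.sum()
    normal = _canonical_normal(cross / area2)
    return AnnulusGeometry(
        center=center,
        diameter=float(diameter),
        normal=normal,
        offset=float(np.dot(normal, p[0])),
    )


def ostia_plane_distance(annulus: AnnulusGeometry, o_r, o_l) -> float:
    """Mean unsigned distance of the two coronary ostia from the annulus plane."""
    return 0.5 * (annulus.plane_distance(o_r) + annulus.plane_distance(o_l))


def plane_normal_cosine_distance(n1, n2) -> float:
    """Orientation-insensitive cosine distance ``1 - |n1 . n2|``.

    Antiparallel normals describe the same plane, hence the absolute
    value.  Inputs must be unit vectors (tolerance 1e-6).
    """
    n1 = np.asarray(n1, dtype=np.float64).reshape(3)
    n2 = np.asarray(n2, dtype=np.float64).reshape(3)
    for v in (n1, n2):
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValidationError(f"plane normal {v} is not unit length")
    return float(1.0 - abs(np.dot(n1, n2)))


# ---------------------------------------------------------------------------
# Error summaries
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    """Group-wise mean +- SD errors and an optional paired comparison."""

    group_stats: dict[str, tuple[float, float]]  # group -> (mean, sd), mm
    per_landmark: pd.Series                      # mean error per landmark, mm
    n_volumes: int
    p_value: float | None = None                 # None when undefined (NA)
    test: str | None = None

    def to_dict(self) -> dict:
        return {
            "groups": {
                g: {"mean": m, "sd": s} for g, (m, s) in self.group_stats.items()
            },
            "per_landmark": {k: float(v) for k, v in self.per_landmark.items()},
            "n_volumes": self.n_volumes,
            "p_value": self.p_value,
            "test": self.test,
        }


def _group_stats(errors: pd.DataFrame) -> dict[str, tuple[float, float]]:
    out = {}
    for group, names in LANDMARK_GROUPS.items():
        vals = errors[list(names)].to_numpy().ravel()
        out[group] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    allv = errors[list(LANDMARK_NAMES)].to_numpy().ravel()
    out["overall"] = (float(allv.mean()), float(allv.std(ddof=1)) if len(allv) > 1 else 0.0)
    return out


def summarize_errors(
    errors_a: pd.DataFrame,
    errors_b: pd.DataFrame | None = None,
    test: str = "wilcoxon",
) -> ErrorReport | tuple[ErrorReport, ErrorReport]:
    """Tabulate per-group mean +- SD errors; optionally a paired test.

    ``errors_a`` (and ``errors_b``) are volumes-by-landmark DataFrames in
    mm with the 8 canonical columns.  When two methods are given they must
    cover identical volumes; the paired two-sided test (Wilcoxon
    signed-rank by default — robust to the skewed error distributions of
    localization tasks — or ``"ttest"``) compares per-volume overall
    errors, and both reports carry the shared p-value.  Identical arms
    make the test statistic degenerate; this is flagged as ``p_value =
    None`` rather than a number.
    """
    for df in (errors_a,) if errors_b is None else (errors_a, errors_b):
        missing = [n for n in LANDMARK_NAMES if n not in df.columns]
        if missing:
            raise ValidationError(f"error table missing landmark column(s) {missing}")
    report_a = ErrorReport(
        _group_stats(errors_a),
        errors_a[list(LANDMARK_NAMES)].mean(),
        len(errors_a),
    )
    if errors_b is None:
        return report_a
    if len(errors_a) != len(errors_b) or not errors_a.index.equals(errors_b.index):
        raise ValidationError("paired comparison requires identical volume sets")
    report_b = ErrorReport(
        _group_stats(errors_b),
        errors_b[list(LANDMARK_NAMES)].mean(),
        len(errors_b),
    )
    pa = errors_a[list(LANDMARK_NAMES)].mean(axis=1).to_numpy()
    pb = errors_b[list(LANDMARK_NAMES)].mean(axis=1).to_numpy()
    diff = pa - pb
    p_value: float | None
    if np.allclose(diff, 0.0):
        p_value = None
    elif test == "wilcoxon":
        p_value = float(stats.wilcoxon(pa, pb).pvalue)
    elif test == "ttest":
        p_value = float(stats.ttest_rel(pa, pb).pvalue)
    else:
        raise ValidationError(f"unknown paired test {test!r}")
    report_a.p_value = report_b.p_value = p_value
    report_a.test = report_b.test = test if p_value is not None else None
    return report_a, report_b


def error_ccdf(errors, thresholds) -> np.ndarray:
    """Complementary CDF: for each threshold e, the fraction of errors >= e."""
    errors = np.asarray(errors, dtype=np.float64).ravel()
    if errors.size == 0:
        raise ValidationError("CCDF of an empty error list is undefined")
    thresholds = np.asarray(thresholds, dtype=np.float64).ravel()
    return (errors[None, :] >= thresholds[:, None]).mean(axis=1)


def variance_error_table(walk_result, truth, spacing) -> tuple[pd.DataFrame, float | None]:
    """Per-walker (log walk variance, error mm) pairs plus rank correlation.

    Walkers with zero variance have undefined log-variance; they are kept
    in the table (flagged ``-inf``) but excluded from the Spearman
    correlation.  The correlation is ``None`` (NA) with fewer than two
    usable walkers.
    """
    errors = np.array(
        [localization_error(m, truth, spacing) for m in walk_result.means]
    )
    variances = np.asarray(walk_result.variances, dtype=np.float64)
    with np.errstate(divide="ignore"):
        logv = np.log(variances, where=variances > 0, out=np.full_like(variances, -np.inf))
    table = pd.DataFrame(
        {
            "walker": np.arange(len(errors)),
            "variance": variances,
            "log_variance": logv,
            "error_mm": errors,
            "selected": np.arange(len(errors)) == walk_result.selected,
        }
    )
    usable = np.isfinite(logv)
    if usable.sum() < 2:
        return table, None
    rho = stats.spearmanr(logv[usable], errors[usable]).statistic
    return table, (None if np.isnan(rho) else float(rho))
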
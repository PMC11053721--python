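"""Form tolerances: best-fit planes, flatness, parallelism, perpendicularity.

Flatness follows the best-fit-plane convention (not the ISO minimum-zone
envelope): the error of a surface is the distance of its farthest point on
the positive side of the orthogonal least-squares plane plus the distance of
the farthest point on the negative side.  Parallelism and perpendicularity
are expressed in degrees against the base-plane datum: the acute angle
between a crown's horizontal plane and the base plane, and the absolute
deviation from 90 degrees for a vertical plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DEFAULT_SAMPLING_DENSITY, RegionPointSet, sample_regions
from .mesh import LabeledMesh

__all__ = [
    "PlaneFit",
    "FormMetricsSummary",
    "fit_plane",
    "flatness_error",
    "parallelism_error",
    "perpendicularity_error",
    "summarize_form_metrics",
]

HORIZONTAL = "horizontal"  # Plane O of a crown
VERTICAL = "vertical"  # Plane B / Plane L of a crown
BASE = "base"  # Plane Upper / Plane Lower


@dataclass(frozen=True)
class PlaneFit:
    """Orthogonal least-squares plane ``normal . p = offset``."""

    normal: np.ndarray
    offset: float
    region_name: str = ""
    orientation_class: str = ""
    x_positive: float = 0.0
    x_negative: float = 0.0
    n_points: int = 0

    def signed_distances(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.normal - self.offset


def fit_plane(
    points,
    region_name: str = "",
    orientation_class: str = "",
    orient_toward=None,
) -> PlaneFit:
    """Fit the orthogonal least-squares plane to a point set.

    The normal is the right singular vector of the centered points with the
    smallest singular value; the plane passes through the centroid.  If
    ``orient_toward`` is given the normal sign is chosen to align with it
    (the region's design normal).  Raises for fewer than three points or a
    collinear/degenerate configuration.
    """
    if isinstance(points, RegionPointSet):
        if not region_name:
            region_name = points.region_name
        points = points.points
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("plane fit needs at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear sets have a vanishing *second* singular value
    if s[1] <= max(1e-12, 1e-12 * s[0]):
        raise ValueError("degenerate point set: points are (nearly) collinear")
    normal = vt[2]
    if orient_toward is not None and np.dot(normal, orient_toward) < 0:
        normal = -normal
    offset = float(normal @ centroid)
    d = centered @ normal
    return PlaneFit(
        normal=normal,
        offset=offset,
        region_name=region_name,
        orientation_class=orientation_class,
        x_positive=float(max(d.max(), 0.0)),
        x_negative=float(max(-d.min(), 0.0)),
        n_points=len(pts),
    )


def flatness_error(fit: PlaneFit, points=None) -> float:
    """Flatness = x_positive + x_negative (mm).

    With ``points`` given, the extremes are re-evaluated on that set;
    otherwise the extremes stored at fit time are used.
    """
    if points is not None:
        if isinstance(points, RegionPointSet):
            points = points.points
        d = fit.signed_distances(points)
        return float(max(d.max(), 0.0) + max(-d.min(), 0.0))
    return fit.x_positive + fit.x_negative


def _acute_angle_deg(n1: np.ndarray, n2: np.ndarray) -> float:
    c = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))


def parallelism_error(plane: PlaneFit, base: PlaneFit) -> float:
    """Acute angle (degrees) between a horizontal crown plane and the base."""
    if plane.orientation_class != HORIZONTAL:
        raise ValueError(
            f"parallelism needs a horizontal plane, got "
            f"{plane.orientation_class!r} ({plane.region_name})"
        )
    if base.orientation_class != BASE:
        raise ValueError("datum must be the base plane")
    return _acute_angle_deg(plane.normal, base.normal)


def perpendicularity_error(plane: PlaneFit, base: PlaneFit) -> float:
    """|angle - 90| (degrees) between a vertical crown plane and the base."""
    if plane.orientation_class != VERTICAL:
        raise ValueError(
            f"perpendicularity needs a vertical plane, got "
            f"{plane.orientation_class!r} ({plane.region_name})"
        )
    if base.orientation_class != BASE:
        raise ValueError("datum must be the base plane")
    return abs(_acute_angle_deg(plane.normal, base.normal) - 90.0)


@dataclass
class FormMetricsSummary:
    """Per-jaw aggregation: 42 flatness, 14 parallelism, 28 perpendicularity."""

    per_plane: pd.DataFrame  # region, class, flatness, angle_metric
    flatness_mean: float
    flatness_sd: float
    flatness_horizontal_mean: float
    flatness_vertical_mean: float
    parallelism_mean: float
    parallelism_sd: float
    perpendicularity_mean: float
    perpendicularity_sd: float


_SURFACE_CLASS = {"occlusal": HORIZONTAL, "buccal": VERTICAL, "lingual": VERTICAL}


def summarize_form_metrics(
    lm: LabeledMesh,
    density: float = DEFAULT_SAMPLING_DENSITY,
    seed: int = 0,
    base_region: str = "base:upper",
) -> FormMetricsSummary:
    """Fit all 42 crown planes plus the base plane and aggregate the errors.

    The mesh must carry the full label set of one jaw (14 crowns with
    occlusal/buccal/lingual regions, plus the base upper surface).  Standard
    deviations use the n-1 (sample) convention.
    """
    crowns = sorted(
        {
            name.split(":")[0]
            for name in lm.regions
            if ":" in name and not name.startswith("base")
        }
    )
    needed = [f"{c}:{s}" for c in crowns for s in _SURFACE_CLASS] + [base_region]
    missing = [r for r in needed if r not in lm.regions]
    if missing:
        raise ValueError(f"missing regions for form metrics: {missing}")
    if len(crowns) != 14:
        raise ValueError(f"expected 14 crowns, found {len(crowns)}: {crowns}")

    samples = {
        ps.region_name: ps
        for ps in sample_regions(lm, needed, density=density, seed=seed)
    }
    base_fit = fit_plane(samples[base_region], orientation_class=BASE)

    rows = []
    for crown in crowns:
        for surface, klass in _SURFACE_CLASS.items():
            region = f"{crown}:{surface}"
            fit = fit_plane(samples[region], orientation_class=klass)
            flat = flatness_error(fit)
            if klass == HORIZONTAL:
                angle = parallelism_error(fit, base_fit)
            else:
                angle = perpendicularity_error(fit, base_fit)
            rows.append(
                {
                    "region": region,
                    "orientation_class": klass,
                    "flatness_mm": flat,
                    "angle_deg": angle,
                    "normal_x": fit.normal[0],
                    "normal_y": fit.normal[1],
                    "normal_z": fit.normal[2],
                }
            )
    df = pd.DataFrame(rows)
    flat = df["flatness_mm"].to_numpy()
    horiz = df[df.orientation_class == HORIZONTAL]
    vert = df[df.orientation_class == VERTICAL]
    assert len(flat) == 42 and len(horiz) == 14 and len(vert) == 28
    return FormMetricsSummary(
        per_plane=df,
        flatness_mean=float(flat.mean()),
        flatness_sd=float(flat.std(ddof=1)),
        flatness_horizontal_mean=float(horiz["flatness_mm"].mean()),
        flatness_vertical_mean=float(vert["flatness_mm"].mean()),
        parallelism_mean=float(horiz["angle_deg"].mean()),
        parallelism_sd=float(horiz["angle_deg"].std(ddof=1)),
        perpendicularity_mean=float(vert["angle_deg"].mean()),
        perpendicularity_sd=float(vert["angle_deg"].std(ddof=1)),
    )
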
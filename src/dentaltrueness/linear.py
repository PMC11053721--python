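"""Virtual-caliper linear measurements, relative errors, and ICC reliability.

Each of the 96 feature sizes is defined by two labeled surfaces and a
measurement direction (in the occlusal plane for MD/BL and arch dimensions,
along the occlusogingival axis for crown heights).  Like a hand-held
caliper on a physical model, the virtual caliper is *intrinsic*: it needs
no registration.  The occlusogingival datum is the test mesh's own
best-fit base-plane normal; occlusal-plane measurements live in the plane
orthogonal to it.  The caliper jaws contact each defining surface at its
area-weighted mean point (the surface's orthogonal least-squares plane
evaluated at its centroid); for MD/BL the measurement direction is taken
from the two opposing faces' own fitted normals, for crown heights it is
the base normal, and for arch dimensions the in-plane direction connecting
the two contact points.  These conventions make the measurement exact on
the designed geometry, exactly invariant under rigid motion of the model,
exactly equivariant under in-plane/axial scaling, and unbiased under
zero-mean surface/scan noise — which is what lets the closed-loop
deformation experiments recover printing-error parameters.

Relative error of a feature is (measured - designed) / designed * 100%;
positive values are dimensional enlargement.  The occlusal-plane error of a
jaw is the mean relative error of its 34 in-plane dimensions; the
occlusogingival direction error is the mean over its 14 crown heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generator import FeatureEntry, FeatureSizeSchema
from .mesh import LabeledMesh

__all__ = [
    "FeatureSize",
    "LinearSummary",
    "MeasurementError",
    "virtual_caliper",
    "measure_features",
    "relative_error",
    "summarize_linear",
    "average_repeats",
    "icc",
]

OCCLUSAL_PLANE_COUNT = 34
OCCLUSOGINGIVAL_COUNT = 14


class MeasurementError(RuntimeError):
    """A caliper measurement could not be taken (e.g. negative raw span)."""


@dataclass(frozen=True)
class FeatureSize:
    """One measured linear dimension."""

    id: str
    jaw: str
    axis_class: str
    designed_value: float  # x1, mm
    measured_value: float  # x2, mm

    @property
    def relative_error(self) -> float:
        return relative_error(self.designed_value, self.measured_value)


def base_plane_normal(lm: LabeledMesh, base_region: str = "base:upper") -> np.ndarray:
    """Unit normal of the base upper surface, oriented toward the crowns.

    This is the mesh's own occlusogingival datum; on the reference design
    it equals +Z exactly.
    """
    from .form import fit_plane  # local import to avoid a cycle

    pts = lm.region_vertices(base_region)
    fit = fit_plane(pts, region_name=base_region)
    others = [n for n in lm.regions if n != base_region]
    if others:
        crowns = np.mean([lm.region_centroid(n) for n in others], axis=0)
        if np.dot(fit.normal, crowns - pts.mean(axis=0)) < 0:
            return -fit.normal
    return fit.normal


def _region_normal(lm: LabeledMesh, name: str) -> np.ndarray:
    """Area-weighted mean outward face normal of a region."""
    idx = lm.region_faces(name)
    areas = lm.mesh.area_faces[idx][:, None]
    n = (lm.mesh.face_normals[idx] * areas).sum(axis=0)
    return n / np.linalg.norm(n)


def virtual_caliper(
    lm: LabeledMesh, entry: FeatureEntry, base_normal: np.ndarray | None = None
) -> float:
    """Measure one feature on a labeled mesh, in mm.

    The caliper jaws contact each defining surface at its area-weighted
    mean point ``c_a`` / ``c_b``.  The span is measured along the
    occlusogingival datum (the mesh's own base-plane normal ``n``) for
    crown heights, along the in-plane direction of the two opposing face
    normals for MD/BL, and along the in-plane component of ``c_b - c_a``
    for arch dimensions.  A negative raw span means the defining surfaces
    overlap along the measurement axis and is flagged as a failure.
    """
    for region in (entry.region_a, entry.region_b):
        if region not in lm.regions:
            raise KeyError(f"feature {entry.id}: region {region!r} not on mesh")
    if base_normal is None:
        base_normal = base_plane_normal(lm)
    n = base_normal
    ca = lm.region_centroid(entry.region_a)
    cb = lm.region_centroid(entry.region_b)
    delta = cb - ca
    if entry.axis_class == "occlusogingival":
        span = float(np.dot(n, delta))
    else:
        in_plane = delta - np.dot(delta, n) * n
        same_crown = (
            entry.region_a.split(":")[0] == entry.region_b.split(":")[0]
        )
        if same_crown:  # MD / BL: direction from the opposing faces' normals
            d = _region_normal(lm, entry.region_b) - _region_normal(
                lm, entry.region_a
            )
            d = d - np.dot(d, n) * n
            d /= np.linalg.norm(d)
            span = float(np.dot(d, in_plane))
        else:  # arch dimension: in-plane distance between the contact points
            span = float(np.linalg.norm(in_plane))
    if span < 0:
        raise MeasurementError(
            f"feature {entry.id}: negative span ({span:.4f} mm); "
            "defining surfaces overlap along the measurement axis"
        )
    return span


def measure_features(
    lm: LabeledMesh, schema: FeatureSizeSchema | list[FeatureEntry],
    jaw: str | None = None,
) -> list[FeatureSize]:
    """Run the virtual caliper over (a jaw's slice of) the schema."""
    entries = list(schema)
    if jaw is not None:
        entries = [e for e in entries if e.jaw == jaw]
    base_normal = base_plane_normal(lm) if entries else None
    return [
        FeatureSize(
            id=e.id,
            jaw=e.jaw,
            axis_class=e.axis_class,
            designed_value=e.designed_value,
            measured_value=virtual_caliper(lm, e, base_normal),
        )
        for e in entries
    ]


def relative_error(x1: float, x2: float) -> float:
    """(x2 - x1) / x1 * 100, in percent; x1 is the designed dimension."""
    if x1 <= 0:
        raise ValueError("designed dimension must be positive")
    return (x2 - x1) / x1 * 100.0


@dataclass
class LinearSummary:
    """Per-jaw aggregates of the relative errors, percent (mean ± sample SD)."""

    jaw: str
    occlusal_plane_mean: float
    occlusal_plane_sd: float
    occlusogingival_mean: float
    occlusogingival_sd: float
    n_occlusal_plane: int = OCCLUSAL_PLANE_COUNT
    n_occlusogingival: int = OCCLUSOGINGIVAL_COUNT


def summarize_linear(features: list[FeatureSize], jaw: str) -> LinearSummary:
    """Aggregate one jaw's 48 features into the two directional errors."""
    feats = [f for f in features if f.jaw == jaw]
    occl = [f.relative_error for f in feats if f.axis_class == "occlusal-plane"]
    ging = [f.relative_error for f in feats if f.axis_class == "occlusogingival"]
    if len(occl) != OCCLUSAL_PLANE_COUNT or len(ging) != OCCLUSOGINGIVAL_COUNT:
        ids = {f.id for f in feats}
        raise ValueError(
            f"incomplete feature set for {jaw}: "
            f"{len(occl)}/{OCCLUSAL_PLANE_COUNT} occlusal-plane and "
            f"{len(ging)}/{OCCLUSOGINGIVAL_COUNT} occlusogingival "
            f"measurements present (ids: {sorted(ids)})"
        )
    occl = np.asarray(occl)
    ging = np.asarray(ging)
    return LinearSummary(
        jaw=jaw,
        occlusal_plane_mean=float(occl.mean()),
        occlusal_plane_sd=float(occl.std(ddof=1)),
        occlusogingival_mean=float(ging.mean()),
        occlusogingival_sd=float(ging.std(ddof=1)),
    )


def features_to_dataframe(features: list[FeatureSize]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [f.id for f in features],
            "jaw": [f.jaw for f in features],
            "axis_class": [f.axis_class for f in features],
            "designed_mm": [f.designed_value for f in features],
            "measured_mm": [f.measured_value for f in features],
            "relative_error_pct": [f.relative_error for f in features],
        }
    )


def average_repeats(measurements) -> float | dict:
    """Arithmetic mean of repeated measurements of a feature.

    Accepts a sequence of repeats (returns the mean) or a mapping
    ``feature id -> repeats`` (returns a mapping of means).
    """
    if isinstance(measurements, dict):
        return {k: average_repeats(v) for k, v in measurements.items()}
    arr = np.asarray(list(measurements), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("need at least one repeat")
    return float(arr.mean())


def icc(matrix, mode: str = "inter") -> float:
    """Intraclass correlation coefficient, two-way random effects,
    absolute agreement, single measures (ICC(2,1)).

    ``matrix`` is features x raters (inter-examiner) or features x repeated
    sessions (intra-examiner); the same estimator serves both modes, ``mode``
    is accepted for bookkeeping.  The matrix must be complete.
    """
    if mode not in ("inter", "intra"):
        raise ValueError("mode must be 'inter' or 'intra'")
    X = np.asarray(
        matrix.values if isinstance(matrix, pd.DataFrame) else matrix,
        dtype=np.float64,
    )
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("ICC needs at least 2 features and 2 raters")
    if not np.isfinite(X).all():
        raise ValueError("ICC requires a complete matrix (no missing cells)")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0  # all cells identical
    return float((msr - mse) / denom)
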
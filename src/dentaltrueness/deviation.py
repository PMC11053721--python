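"""Signed surface deviations, overall RMS, and the 21-segment color map.

The overall 3D deviation of a printed model is the root mean square of
signed point-to-surface distances, evaluated from points sampled on the
registered test mesh against the reference design surface over the selected
regions (base upper surface plus the occlusal, buccal and lingual crown
faces).  The sign is positive when a test point lies on the outward-normal
side of the reference surface (material excess / expansion) and negative
for contraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from ._geometry import SurfaceIndex
from .io import DEFAULT_SAMPLING_DENSITY, sample_regions
from .mesh import LabeledMesh
from .transforms import RigidTransform

__all__ = [
    "DeviationField",
    "ColorMapSpec",
    "signed_deviation",
    "rms",
    "overall_value",
    "color_bins",
    "colormap_legend",
    "export_colormap_ply",
    "export_colormap_csv",
]


@dataclass
class DeviationField:
    """Signed deviations of sampled test points, registered frame."""

    points: np.ndarray  # (n, 3) on the registered test mesh
    distances: np.ndarray  # (n,) signed, mm
    regions: np.ndarray  # (n,) region name per point

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if len(self.distances) == 0:
            raise ValueError("deviation field must contain at least one sample")

    @property
    def n(self) -> int:
        return len(self.distances)

    @property
    def rms(self) -> float:
        return rms(self.distances)


@dataclass(frozen=True)
class ColorMapSpec:
    """Color spectrum parameters: 21 segments, ±0.50 mm critical, ±0.05 nominal."""

    segments: int = 21
    critical: float = 0.50  # mm
    nominal: float = 0.05  # mm

    def __post_init__(self):
        if self.segments < 3 or self.segments % 2 == 0:
            raise ValueError("segments must be an odd number >= 3")
        if not 0 < self.nominal < self.critical:
            raise ValueError("nominal band must lie strictly inside critical band")

    @property
    def side_bins(self) -> int:
        return (self.segments - 1) // 2

    @property
    def bin_width(self) -> float:
        return (self.critical - self.nominal) / self.side_bins


def signed_deviation(
    test: LabeledMesh,
    reference: LabeledMesh,
    region_names,
    transform: RigidTransform | None = None,
    density: float = DEFAULT_SAMPLING_DENSITY,
    seed: int = 0,
) -> DeviationField:
    """Sample the test regions and measure signed distances to the reference.

    ``region_names`` must exist on both meshes (on the test side they come
    from its own sidecar or from label transfer).  ``transform`` maps the
    test mesh into the reference frame (output of registration).
    """
    region_names = list(region_names)
    if not region_names:
        raise ValueError("no regions selected for deviation analysis")
    if transform is None:
        transform = RigidTransform.identity()
    samples = sample_regions(test, region_names, density=density, seed=seed)
    index = SurfaceIndex(reference.mesh, reference.faces_of(region_names))
    pts_list, dist_list, reg_list = [], [], []
    for ps in samples:
        pts = transform.apply(ps.points)
        closest, dist, tri = index.query(pts)
        normals = reference.mesh.face_normals[tri]
        sign = np.where(((pts - closest) * normals).sum(axis=1) >= 0, 1.0, -1.0)
        pts_list.append(pts)
        dist_list.append(sign * dist)
        reg_list.append(np.full(len(pts), ps.region_name, dtype=object))
    return DeviationField(
        np.concatenate(pts_list),
        np.concatenate(dist_list),
        np.concatenate(reg_list),
    )


def rms(values) -> float:
    """Root mean square of the deviations: sqrt(sum d_i^2 / n)."""
    if isinstance(values, DeviationField):
        values = values.distances
    d = np.asarray(values, dtype=np.float64)
    if d.size == 0:
        raise ValueError("RMS of an empty sample is undefined")
    return float(np.sqrt(np.mean(d * d)))


def overall_value(rms_maxillary: float, rms_mandibular: float) -> float:
    """Overall 3D deviation: arithmetic mean of the two jaw RMS values.

    Units follow the inputs (e.g. overall_value(47, 43) um -> 45 um).
    """
    if rms_maxillary < 0 or rms_mandibular < 0:
        raise ValueError("RMS values must be non-negative")
    return (rms_maxillary + rms_mandibular) / 2.0


def color_bins(field, spec: ColorMapSpec = ColorMapSpec()) -> np.ndarray:
    """Assign each deviation to one of the color segments (0..segments-1).

    The middle bin covers the closed nominal band [-nominal, +nominal]; each
    side splits into equal-width bins out to the critical value; deviations
    beyond the critical value clamp to the end bins.  The assignment is
    monotone non-decreasing in the deviation value.
    """
    d = field.distances if isinstance(field, DeviationField) else np.asarray(field)
    d = np.asarray(d, dtype=np.float64)
    mid = spec.side_bins
    bins = np.full(d.shape, mid, dtype=np.int64)
    w = spec.bin_width
    neg = d < -spec.nominal
    pos = d > spec.nominal
    k_neg = np.ceil((-spec.nominal - d[neg]) / w)
    k_pos = np.ceil((d[pos] - spec.nominal) / w)
    bins[neg] = mid - np.minimum(k_neg, spec.side_bins).astype(np.int64)
    bins[pos] = mid + np.minimum(k_pos, spec.side_bins).astype(np.int64)
    return bins


def colormap_legend(spec: ColorMapSpec = ColorMapSpec()) -> pd.DataFrame:
    """Bin boundaries and colors: blue = contraction, yellow/red = expansion."""
    from matplotlib import colormaps
    from matplotlib.colors import to_hex

    mid = spec.side_bins
    edges_neg = np.linspace(-spec.critical, -spec.nominal, spec.side_bins + 1)
    edges_pos = np.linspace(spec.nominal, spec.critical, spec.side_bins + 1)
    rows = []
    for b in range(spec.segments):
        if b < mid:
            lo, hi = edges_neg[b], edges_neg[b + 1]
            lo = -np.inf if b == 0 else lo
        elif b == mid:
            lo, hi = -spec.nominal, spec.nominal
        else:
            lo, hi = edges_pos[b - mid - 1], edges_pos[b - mid]
            hi = np.inf if b == spec.segments - 1 else hi
        rows.append({"bin": b, "lower_mm": lo, "upper_mm": hi})
    colors = colormaps["jet"](np.linspace(0.0, 1.0, spec.segments))
    legend = pd.DataFrame(rows)
    legend["color"] = [to_hex(c) for c in colors]
    return legend


def _bin_colors(bins: np.ndarray, spec: ColorMapSpec) -> np.ndarray:
    from matplotlib import colormaps

    colors = colormaps["jet"](np.linspace(0.0, 1.0, spec.segments))
    rgba = (np.asarray(colors)[bins] * 255).astype(np.uint8)
    return rgba


def export_colormap_ply(
    field: DeviationField, path, spec: ColorMapSpec = ColorMapSpec()
) -> None:
    """Write the deviation samples as a colored PLY point cloud."""
    bins = color_bins(field, spec)
    cloud = trimesh.PointCloud(field.points, colors=_bin_colors(bins, spec))
    data = cloud.export(file_type="ply", encoding="ascii")
    with open(path, "w") as fh:
        fh.write(data if isinstance(data, str) else data.decode())


def export_colormap_csv(
    field: DeviationField, path, spec: ColorMapSpec = ColorMapSpec()
) -> None:
    bins = color_bins(field, spec)
    pd.DataFrame(
        {
            "x_mm": field.points[:, 0],
            "y_mm": field.points[:, 1],
            "z_mm": field.points[:, 2],
            "region": field.regions,
            "deviation_mm": field.distances,
            "bin": bins,
        }
    ).to_csv(path, index=False)
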
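"""Synthetic print-like deformations: the closed-loop fixture generator.

Printed photopolymer models deviate from their design in characteristic
ways: in-plane (X-Y) expansion or shrinkage, a distinct Z-axis scale error,
bowl-like warpage of the base from polymerization shrinkage stress, and
surface/scan noise.  This module applies those modes with *known*
parameters to a reference mesh, so the entire evaluation pipeline can be
tested end-to-end: feed a fixture with xy_scale 0.99 through registration
and the virtual caliper and the occlusal-plane error must read -1.00%.

Deformations are applied in a fixed order: anisotropic scale about the
vertex centroid, then warp (z += k * r^2, r = in-plane distance from the
centroid axis), then Gaussian noise along vertex normals, then a small
rigid jitter.  Region labels ride along unchanged.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .generator import export_model
from .mesh import LabeledMesh
from .transforms import RigidTransform

__all__ = ["DeformationParams", "apply_deformation", "generate_fixture_suite"]


@dataclass(frozen=True)
class DeformationParams:
    """Known ground-truth deformation of one fixture.

    xy_scale / z_scale are dimensionless (0.99 = 1% shrinkage); warp_k is
    the basal bowing coefficient in mm^-1; noise_sd the Gaussian
    along-normal displacement in mm; rigid_jitter the SD of the jitter
    rotation angle (degrees) and of each translation component (mm).
    """

    xy_scale: float = 1.0
    z_scale: float = 1.0
    warp_k: float = 0.0  # mm^-1
    noise_sd: float = 0.0  # mm
    rigid_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("xy_scale", "z_scale"):
            v = getattr(self, name)
            if not 0.5 < v < 1.5:
                raise ValueError(f"{name}={v} outside the plausible (0.5, 1.5)")
        if self.noise_sd < 0 or self.rigid_jitter < 0:
            raise ValueError("noise_sd and rigid_jitter must be >= 0")


def apply_deformation(lm: LabeledMesh, params: DeformationParams) -> LabeledMesh:
    """Return a deformed copy of the mesh; deterministic given params.seed."""
    v = np.array(lm.mesh.vertices, dtype=np.float64)
    centroid = v.mean(axis=0)
    # 1. anisotropic scale about the centroid
    if params.xy_scale != 1.0 or params.z_scale != 1.0:
        rel = v - centroid
        rel[:, :2] *= params.xy_scale
        rel[:, 2] *= params.z_scale
        v = centroid + rel
    # 2. basal warp about the centroid axis
    if params.warp_k != 0.0:
        r2 = ((v[:, :2] - centroid[:2]) ** 2).sum(axis=1)
        v[:, 2] += params.warp_k * r2
    # 3. Gaussian noise along the (deformed) vertex normals
    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        tmp = trimesh.Trimesh(v, lm.mesh.faces, process=False)
        normals = np.asarray(tmp.vertex_normals)
        v = v + normals * rng.normal(0.0, params.noise_sd, (len(v), 1))
    # 4. rigid jitter (rotation about the centroid + translation)
    if params.rigid_jitter > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.normal(0.0, params.rigid_jitter)
        t = rng.normal(0.0, params.rigid_jitter, 3)
        jitter = RigidTransform.from_axis_angle(axis, angle, t, center=centroid)
        v = jitter.apply(v)
    mesh = trimesh.Trimesh(v, lm.mesh.faces.copy(), process=False)
    return LabeledMesh(mesh, {k: idx.copy() for k, idx in lm.regions.items()}, lm.frame)


#: the minimum set of deformation cases a fixture suite covers
DEFAULT_CASES: dict[str, dict] = {
    "xy_shrink": {"xy_scale": 0.99},
    "z_shrink": {"z_scale": 0.995},
    "warp": {"warp_k": 5e-5},
    "combined": {"xy_scale": 0.99, "z_scale": 0.995, "warp_k": 5e-5},
    "noisy": {
        "xy_scale": 0.99,
        "z_scale": 0.995,
        "warp_k": 5e-5,
        "noise_sd": 0.02,
        "rigid_jitter": 0.1,
    },
}


def generate_fixture_suite(
    references: dict[str, LabeledMesh],
    out_dir,
    cases: dict[str, dict] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write deformed STL fixtures + sidecars + a ground-truth manifest.

    ``references`` maps jaw name to its reference mesh.  Each (jaw, case)
    pair gets a derived deterministic seed, an STL, a region sidecar, and a
    manifest row recording the true parameters.  Returns the manifest (also
    written as ``manifest.csv`` and ``manifest.json``).
    """
    if cases is None:
        cases = DEFAULT_CASES
    if not cases or not references:
        raise ValueError("fixture suite needs at least one case and one reference")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, (jaw, ref) in enumerate(sorted(references.items())):
        for i, (case, overrides) in enumerate(cases.items()):
            fixture_seed = (seed + 1000 * j + i) % (2**31 - 1)
            params = DeformationParams(seed=fixture_seed, **overrides)
            deformed = apply_deformation(ref, params)
            name = f"{jaw}_{case}"
            stl = out_dir / f"{name}.stl"
            export_model(deformed, stl)
            row = {"fixture": name, "jaw": jaw, "case": case, **asdict(params)}
            row["stl"] = stl.name
            row["sidecar"] = f"{name}.regions.json"
            rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "manifest.json").write_text(
        json.dumps(rows, indent=1, default=float)
    )
    return manifest
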
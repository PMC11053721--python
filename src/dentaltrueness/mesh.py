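"""Labeled triangle meshes: geometry plus named measurement surfaces.

A :class:`LabeledMesh` wraps a :class:`trimesh.Trimesh` (coordinates in mm,
occlusal plane parallel to X-Y, occlusogingival direction along +Z) together
with a mapping from region names (``"UL-FM:occlusal"``, ``"base:upper"`` ...)
to face-index sets.  Region face sets are pairwise disjoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .transforms import RigidTransform

__all__ = ["LabeledMesh", "FRAME_NOTE"]

#: Coordinate convention shared by every mesh this package produces.
FRAME_NOTE = "units mm; occlusal plane = X-Y; occlusogingival direction = +Z"


@dataclass
class LabeledMesh:
    mesh: trimesh.Trimesh
    regions: dict[str, np.ndarray] = field(default_factory=dict)
    frame: str = FRAME_NOTE

    def __post_init__(self):
        self.regions = {
            name: np.asarray(idx, dtype=np.int64) for name, idx in self.regions.items()
        }

    # -- basic accessors ---------------------------------------------------

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def faces(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def n_faces(self) -> int:
        return len(self.mesh.faces)

    def region_names(self) -> list[str]:
        return sorted(self.regions)

    def region_faces(self, name: str) -> np.ndarray:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(f"unknown region {name!r}") from None

    def faces_of(self, names) -> np.ndarray:
        """Union of face indices over several region names."""
        parts = [self.region_faces(n) for n in names]
        return np.unique(np.concatenate(parts)) if parts else np.empty(0, np.int64)

    # -- per-region geometry ----------------------------------------------

    def region_area(self, name: str) -> float:
        return float(self.mesh.area_faces[self.region_faces(name)].sum())

    def region_centroid(self, name: str) -> np.ndarray:
        """Area-weighted centroid of a region's surface."""
        idx = self.region_faces(name)
        areas = self.mesh.area_faces[idx]
        centers = self.mesh.triangles[idx].mean(axis=1)
        total = areas.sum()
        if total <= 0:
            raise ValueError(f"region {name!r} has zero area")
        return (centers * areas[:, None]).sum(axis=0) / total

    def region_vertices(self, name: str) -> np.ndarray:
        """Coordinates of the unique vertices used by a region's faces."""
        idx = self.region_faces(name)
        vids = np.unique(self.mesh.faces[idx])
        return self.mesh.vertices[vids]

    def face_region_lut(self) -> np.ndarray:
        """Per-face region name (``""`` for unlabeled faces)."""
        lut = np.full(self.n_faces, "", dtype=object)
        for name, idx in self.regions.items():
            lut[idx] = name
        return lut

    # -- transforms / copies ----------------------------------------------

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            self.mesh.copy(),
            {k: v.copy() for k, v in self.regions.items()},
            self.frame,
        )

    def transformed(self, transform: RigidTransform) -> "LabeledMesh":
        """Rigidly move the mesh; labels are untouched."""
        m = trimesh.Trimesh(
            transform.apply(self.mesh.vertices),
            self.mesh.faces.copy(),
            process=False,
        )
        return LabeledMesh(m, {k: v.copy() for k, v in self.regions.items()}, self.frame)

    # -- validation --------------------------------------------------------

    def validate(self, require_watertight: bool = False) -> None:
        n = self.n_faces
        seen = np.zeros(n, dtype=bool)
        for name, idx in self.regions.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"region {name!r} has out-of-range face indices")
            if seen[idx].any():
                raise ValueError(f"region {name!r} overlaps another region")
            seen[idx] = True
        if require_watertight and not self.mesh.is_watertight:
            raise ValueError("mesh is not watertight")

    # -- sidecar I/O -------------------------------------------------------

    def write_sidecar(self, path) -> None:
        payload = {
            "frame": self.frame,
            "n_faces": self.n_faces,
            "regions": {k: self.regions[k].tolist() for k in sorted(self.regions)},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def read_sidecar(path) -> dict[str, np.ndarray]:
        payload = json.loads(Path(path).read_text())
        return {k: np.asarray(v, dtype=np.int64) for k, v in payload["regions"].items()}
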
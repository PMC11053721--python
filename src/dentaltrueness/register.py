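"""Best-fit rigid registration of a test mesh to the reference design mesh.

Registration is region-restricted, mirroring the measurement protocol: only
the base upper surface and the occlusal, buccal and lingual crown faces take
part (mesial and distal faces are excluded because the narrow interproximal
gaps scan poorly).  The algorithm is point-to-plane ICP on area-weighted
surface samples of the test regions against the reference surface, seeded
by a principal-axes pre-alignment.  Scale is never adjusted — a rigid fit
must not absorb the shrinkage the method is built to measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from ._geometry import SurfaceIndex
from .io import sample_regions
from .mesh import LabeledMesh
from .transforms import RigidTransform

__all__ = [
    "RegistrationOptions",
    "RegistrationResult",
    "registration_regions",
    "initialize_alignment",
    "best_fit_register",
]

_REGISTRATION_SURFACES = ("occlusal", "buccal", "lingual")


def registration_regions(lm: LabeledMesh) -> list[str]:
    """The region names taking part in registration on this mesh."""
    names = [
        r
        for r in lm.region_names()
        if r == "base:upper" or r.split(":")[-1] in _REGISTRATION_SURFACES
    ]
    return names


@dataclass(frozen=True)
class RegistrationOptions:
    sample_count: int = 3000
    seed: int = 0
    max_iterations: int = 200
    tolerance: float = 1e-7  # mm change in RMS between iterations
    initialize: bool = True  # principal-axes pre-alignment


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms: float  # final RMS point-to-surface residual, mm
    iterations: int
    converged: bool

    @property
    def matrix(self) -> np.ndarray:
        return self.transform.matrix


def _moments(vertices: np.ndarray):
    c = vertices.mean(axis=0)
    centered = vertices - c
    cov = centered.T @ centered / len(vertices)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return c, evals[order], evecs[:, order], centered


def initialize_alignment(
    test: LabeledMesh | trimesh.Trimesh,
    reference: LabeledMesh | trimesh.Trimesh,
) -> RigidTransform:
    """Coarse pre-alignment: centroid translation + principal axes.

    Axis signs are disambiguated by matching the third central moment
    (skewness) of the vertex distribution along the two minor axes — for a
    dental model these capture the anterior/posterior asymmetry of the
    horseshoe and the base-heavy height distribution — with the remaining
    sign fixed by requiring a proper rotation.  Degenerate inertia falls
    back to the identity with a warning.
    """
    vt = (test.mesh if isinstance(test, LabeledMesh) else test).vertices
    vr = (reference.mesh if isinstance(reference, LabeledMesh) else reference).vertices
    if len(vt) < 3 or len(vr) < 3:
        warnings.warn("too few vertices for principal-axes alignment; using identity")
        return RigidTransform.identity()
    ct, et, Et, centt = _moments(np.asarray(vt, dtype=np.float64))
    cr, er, Er, centr = _moments(np.asarray(vr, dtype=np.float64))
    if et[0] < 1e-12 or et[1] / et[0] > 0.999 and et[2] / et[0] > 0.999:
        warnings.warn("degenerate principal axes; using identity pre-alignment")
        return RigidTransform.identity()
    for i in (1, 2):  # match skewness sign on the two minor axes
        st = np.mean((centt @ Et[:, i]) ** 3)
        sr = np.mean((centr @ Er[:, i]) ** 3)
        if st * sr < 0:
            Et[:, i] = -Et[:, i]
    if np.linalg.det(Er @ Et.T) < 0:
        Et[:, 0] = -Et[:, 0]
    R = Er @ Et.T
    return RigidTransform.from_rotation(R, cr - R @ ct)


def _valid_pairs(dist, dots):
    """Correspondence rejection: orientation compatibility + distance trim.

    Points whose (rotated) source normal disagrees with the matched surface
    normal (e.g. base-bottom samples matched to the base top when the test
    mesh is unlabeled) are discarded, as are gross distance outliers.
    """
    ok = dots > 0.5
    if ok.sum() >= 6:
        med = np.median(dist[ok])
        ok &= dist <= max(5.0 * med, 0.5)
    if ok.sum() < 6:
        return np.ones(len(dist), dtype=bool)
    return ok


def _icp_point_to_plane(points, point_normals, index, init, max_iterations,
                        tolerance):
    T = init
    rms_prev = np.inf
    rms_val = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        p = T.apply(points)
        closest, dist, tri = index.query(p)
        normals = index.mesh.face_normals[tri]
        dots = ((point_normals @ T.rotation.T) * normals).sum(axis=1)
        ok = _valid_pairs(dist, dots)
        rms_val = float(np.sqrt(np.mean(dist[ok] ** 2)))
        if abs(rms_prev - rms_val) < tolerance:
            return T, rms_val, it, True
        rms_prev = rms_val
        r = ((p[ok] - closest[ok]) * normals[ok]).sum(axis=1)
        A = np.hstack([np.cross(p[ok], normals[ok]), normals[ok]])
        x, *_ = np.linalg.lstsq(A, -r, rcond=None)
        omega, t = x[:3], x[3:]
        angle = np.linalg.norm(omega)
        if angle < 1e-16:
            delta = RigidTransform(np.eye(3), t)
        else:
            delta = RigidTransform.from_axis_angle(
                omega / angle, np.degrees(angle), t
            )
        T = delta.compose(T)
    return T, rms_val, it, False


def best_fit_register(
    test: LabeledMesh,
    reference: LabeledMesh,
    region_names=None,
    options: RegistrationOptions = RegistrationOptions(),
) -> RegistrationResult:
    """Region-restricted best-fit (ICP) registration, test -> reference frame.

    Test points are sampled from the test mesh's own copies of the selected
    regions when present (fixtures and labeled scans), otherwise from its
    whole surface.  Non-convergence within the iteration cap is flagged on
    the result, never silent.
    """
    if test.n_faces == 0 or reference.n_faces == 0:
        raise ValueError("registration needs non-empty meshes")
    if region_names is None:
        region_names = registration_regions(reference)
    region_names = list(region_names)
    if not region_names:
        raise ValueError("empty region selection for registration")
    ref_faces = reference.faces_of(region_names)
    if ref_faces.size == 0:
        raise ValueError("selected regions have no faces on the reference")

    have_all = all(r in test.regions for r in region_names)
    rng_seed = options.seed
    if have_all:
        areas = [test.region_area(r) for r in region_names]
        total = sum(areas)
        pts, fids = [], []
        for r, a in zip(region_names, areas):
            frac = max(1, int(round(options.sample_count * a / total)))
            ps = sample_regions(test, [r], density=frac / a, seed=rng_seed)[0]
            pts.append(ps.points)
            fids.append(ps.source_face)
        points = np.vstack(pts)
        point_normals = test.mesh.face_normals[np.concatenate(fids)]
    else:
        points, face_idx = trimesh.sample.sample_surface(
            test.mesh, options.sample_count, seed=rng_seed
        )
        points = np.asarray(points, dtype=np.float64)
        point_normals = test.mesh.face_normals[face_idx]

    init = (
        initialize_alignment(test, reference)
        if options.initialize
        else RigidTransform.identity()
    )
    index = SurfaceIndex(reference.mesh, ref_faces)
    T, rms_val, iters, converged = _icp_point_to_plane(
        points, point_normals, index, init,
        options.max_iterations, options.tolerance,
    )
    if not converged:
        warnings.warn(
            f"ICP did not converge within {options.max_iterations} iterations "
            f"(final RMS {rms_val:.3e} mm)"
        )
    return RegistrationResult(T, rms_val, iters, converged)
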
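"""Plane fitting, flatness, parallelism/perpendicularity, and aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dentaltrueness import (
    DeformationParams,
    PlaneFit,
    RigidTransform,
    apply_deformation,
    fit_plane,
    flatness_error,
    parallelism_error,
    perpendicularity_error,
    summarize_form_metrics,
)
from dentaltrueness.form import BASE, HORIZONTAL, VERTICAL


def _eigh_plane_oracle(points):
    """Independent plane fit: smallest eigenvector of the covariance matrix."""
    pts = np.asarray(points, dtype=float)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    evals, evecs = np.linalg.eigh(cov)
    n = evecs[:, 0]
    return n, float(n @ c)


def test_fit_plane_trivial_cases():
    pts = np.array([[0, 0, 3], [1, 0, 3], [0, 1, 3], [2, 2, 3]], dtype=float)
    fit = fit_plane(pts, orient_toward=[0, 0, 1])
    assert np.allclose(fit.normal, [0, 0, 1], atol=1e-12)
    assert np.isclose(fit.offset, 3.0, atol=1e-12)
    assert fit.x_positive < 1e-12 and fit.x_negative < 1e-12
    square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    fit = fit_plane(square)
    assert np.allclose(np.abs(fit.normal), [0, 0, 1], atol=1e-12)
    assert flatness_error(fit) < 1e-12


def test_fit_plane_matches_independent_oracle(rng):
    base = rng.random((400, 2)) * 20.0
    normal = np.array([0.3, -0.4, 0.866])
    normal /= np.linalg.norm(normal)
    u = np.array([1.0, 0.0, 0.0])
    u -= normal * (u @ normal)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    pts = (
        np.outer(base[:, 0], u)
        + np.outer(base[:, 1], v)
        + np.outer(rng.normal(0, 0.05, 400), normal)
    )
    fit = fit_plane(pts)
    n_o, off_o = _eigh_plane_oracle(pts)
    if np.dot(n_o, fit.normal) < 0:
        n_o, off_o = -n_o, -off_o
    assert np.allclose(fit.normal, n_o, atol=1e-9)
    assert np.isclose(fit.offset, off_o, atol=1e-9)


def test_fit_plane_rejects_degenerate_input():
    with pytest.raises(ValueError):
        fit_plane(np.array([[0, 0, 0], [1, 1, 1]]))
    line = np.outer(np.linspace(0, 1, 17), [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        fit_plane(line)


def test_flatness_of_symmetric_corrugation_is_peak_to_peak():
    """A balanced ±0.1 mm checkerboard has best-fit mid-plane, flatness 0.2."""
    xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
    z = 0.1 * (-1.0) ** (xs + ys)
    pts = np.column_stack([xs.ravel(), ys.ravel(), z.ravel()])
    fit = fit_plane(pts)
    assert np.allclose(np.abs(fit.normal), [0, 0, 1], atol=1e-12)
    assert np.isclose(flatness_error(fit), 0.2, atol=1e-12)


@given(
    arrays(
        float,
        (10, 3),
        elements=st.floats(-5, 5, allow_nan=False, allow_infinity=False),
    )
)
def test_nonplanar_sets_have_extremes_on_both_sides(pts):
    """The LSQ plane passes through the centroid, so any nonzero residual
    forces points on both sides."""
    try:
        fit = fit_plane(pts)
    except ValueError:
        return  # degenerate draws are rejected by fit_plane itself
    d = fit.signed_distances(pts)
    if np.abs(d).max() > 1e-9:
        assert fit.x_positive > 0 and fit.x_negative > 0
    assert abs(d.sum()) < 1e-7


def _plane(normal, klass):
    n = np.asarray(normal, dtype=float)
    return PlaneFit(n / np.linalg.norm(n), 0.0, orientation_class=klass)


def test_parallelism_analytic_cases():
    base = _plane([0, 0, 1], BASE)
    assert parallelism_error(_plane([0, 0, 1], HORIZONTAL), base) == 0.0
    a = np.deg2rad(0.5)
    tilted = _plane([0, np.sin(a), np.cos(a)], HORIZONTAL)
    assert np.isclose(parallelism_error(tilted, base), 0.5, atol=1e-9)
    assert parallelism_error(_plane([0, 0, -1], HORIZONTAL), base) == 0.0


def test_perpendicularity_analytic_cases():
    base = _plane([0, 0, 1], BASE)
    assert perpendicularity_error(_plane([1, 0, 0], VERTICAL), base) == 0.0
    a = np.deg2rad(89.2)
    plane = _plane([np.sin(a), 0, np.cos(a)], VERTICAL)
    assert np.isclose(perpendicularity_error(plane, base), 0.8, atol=1e-9)
    assert np.isclose(
        perpendicularity_error(_plane([0, 0, 1], VERTICAL), base), 90.0
    )


def test_angle_metrics_share_one_acute_angle_definition(rng):
    base = _plane([0, 0, 1], BASE)
    n = rng.normal(size=3)
    acute = np.degrees(
        np.arccos(abs(n[2]) / np.linalg.norm(n))
    )
    assert np.isclose(
        parallelism_error(_plane(n, HORIZONTAL), base), acute, atol=1e-9
    )
    assert np.isclose(
        perpendicularity_error(_plane(n, VERTICAL), base), abs(acute - 90), atol=1e-9
    )


def test_orientation_class_is_enforced():
    base = _plane([0, 0, 1], BASE)
    with pytest.raises(ValueError):
        parallelism_error(_plane([1, 0, 0], VERTICAL), base)
    with pytest.raises(ValueError):
        perpendicularity_error(_plane([0, 0, 1], HORIZONTAL), base)
    with pytest.raises(ValueError):
        parallelism_error(_plane([0, 0, 1], HORIZONTAL), _plane([0, 0, 1], HORIZONTAL))


def test_summary_counts_and_zero_errors_on_reference(ref_mand):
    summary = summarize_form_metrics(ref_mand, density=4.0, seed=0)
    assert len(summary.per_plane) == 42
    assert (summary.per_plane.orientation_class == HORIZONTAL).sum() == 14
    assert (summary.per_plane.orientation_class == VERTICAL).sum() == 28
    assert summary.flatness_mean < 1e-9
    assert summary.parallelism_mean < 1e-9 and summary.parallelism_sd < 1e-9
    assert summary.perpendicularity_mean < 1e-9


def test_summary_statistics_match_direct_arithmetic(ref_max_coarse):
    warped = apply_deformation(
        ref_max_coarse, DeformationParams(warp_k=1e-4, seed=0)
    )
    summary = summarize_form_metrics(warped, density=4.0, seed=1)
    flat = summary.per_plane.flatness_mm.to_numpy()
    assert np.isclose(summary.flatness_mean, flat.mean(), rtol=1e-12)
    assert np.isclose(summary.flatness_sd, flat.std(ddof=1), rtol=1e-12)
    horiz = summary.per_plane[summary.per_plane.orientation_class == HORIZONTAL]
    assert np.isclose(
        summary.parallelism_mean, horiz.angle_deg.mean(), rtol=1e-12
    )


def test_summary_rigid_motion_invariance(ref_max_coarse):
    warped = apply_deformation(
        ref_max_coarse, DeformationParams(warp_k=5e-5, xy_scale=0.995, seed=0)
    )
    moved = warped.transformed(
        RigidTransform.from_axis_angle([0.2, -0.5, 1.0], 25.0, [8.0, 3.0, -6.0])
    )
    a = summarize_form_metrics(warped, density=4.0, seed=2)
    b = summarize_form_metrics(moved, density=4.0, seed=2)
    assert np.isclose(a.flatness_mean, b.flatness_mean, atol=1e-9)
    assert np.isclose(a.parallelism_mean, b.parallelism_mean, atol=1e-9)
    assert np.isclose(a.perpendicularity_mean, b.perpendicularity_mean, atol=1e-9)


def test_missing_region_is_reported_by_name(ref_max_coarse):
    broken = ref_max_coarse.copy()
    del broken.regions["UL-FM:lingual"]
    with pytest.raises(ValueError, match="UL-FM:lingual"):
        summarize_form_metrics(broken, density=2.0)
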
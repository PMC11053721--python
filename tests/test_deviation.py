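"""RMS deviation, sign conventions, aggregation, and the color map."""

import math

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st

from dentaltrueness import (
    ColorMapSpec,
    DeviationField,
    LabeledMesh,
    RigidTransform,
    color_bins,
    colormap_legend,
    overall_value,
    rms,
    signed_deviation,
)
from dentaltrueness.deviation import export_colormap_csv, export_colormap_ply

finite = st.floats(
    min_value=-1.0, max_value=1.0, allow_nan=False, allow_infinity=False
)


@pytest.fixture()
def slab():
    """A labeled box whose top face is the measurement region."""
    mesh = trimesh.creation.box((20.0, 20.0, 2.0))
    top = np.flatnonzero(mesh.face_normals[:, 2] > 0.9)
    return LabeledMesh(mesh, {"top": top})


def test_rms_hand_evaluated_examples():
    assert rms([0.0, 0.0, 0.0]) == 0.0
    # sqrt((0.03^2 + 0.04^2) / 2), evaluated by hand
    assert np.isclose(rms([0.03, 0.04]), 0.03535533905932738, rtol=1e-12)


@given(st.lists(finite, min_size=1, max_size=30), st.floats(0.0, 10.0))
def test_rms_properties(values, scale):
    # permutation invariance and linear scaling
    assert np.isclose(rms(values), rms(values[::-1]), rtol=1e-12)
    assert np.isclose(
        rms([scale * v for v in values]), scale * rms(values), rtol=1e-9, atol=1e-12
    )


@given(finite)
def test_rms_of_antisymmetric_pair_is_magnitude(d):
    assert np.isclose(rms([d, -d]), abs(d), rtol=1e-12, atol=1e-15)


@given(st.lists(finite, min_size=1, max_size=50))
def test_rms_matches_brute_force_formula(values):
    brute = math.sqrt(sum(v * v for v in values) / len(values))
    assert np.isclose(rms(values), brute, rtol=1e-12, atol=1e-15)


def test_rms_rejects_empty_sample():
    with pytest.raises(ValueError):
        rms([])
    with pytest.raises(ValueError):
        DeviationField(np.empty((0, 3)), np.empty(0), np.empty(0, dtype=object))


def test_overall_value_is_the_jaw_mean():
    assert overall_value(47.0, 43.0) == 45.0
    assert overall_value(98.0, 72.0) == 85.0
    assert overall_value(3.3, 3.3) == 3.3
    with pytest.raises(ValueError):
        overall_value(-1.0, 2.0)


def test_signed_deviation_zero_on_identical_meshes(slab):
    field = signed_deviation(slab, slab, ["top"], density=2.0, seed=0)
    assert np.abs(field.distances).max() < 1e-9
    assert field.rms < 1e-9


@pytest.mark.parametrize("offset", [0.1, -0.1])
def test_signed_deviation_sign_follows_outward_normal(slab, offset):
    moved = LabeledMesh(
        trimesh.Trimesh(
            slab.mesh.vertices + np.array([0.0, 0.0, offset]),
            slab.mesh.faces.copy(),
            process=False,
        ),
        {"top": slab.regions["top"].copy()},
    )
    field = signed_deviation(moved, slab, ["top"], density=2.0, seed=0)
    assert np.allclose(field.distances, offset, atol=1e-9)


def test_deviation_respects_registration_transform(slab):
    t = RigidTransform.from_axis_angle([0, 0, 1], 30.0, [5.0, -2.0, 1.0])
    moved = LabeledMesh(
        trimesh.Trimesh(
            t.inverse().apply(slab.mesh.vertices),
            slab.mesh.faces.copy(),
            process=False,
        ),
        {"top": slab.regions["top"].copy()},
    )
    field = signed_deviation(moved, slab, ["top"], transform=t, density=2.0, seed=0)
    assert np.abs(field.distances).max() < 1e-9


def test_color_bin_worked_examples():
    spec = ColorMapSpec()
    assert color_bins(np.array([0.0]), spec)[0] == 10
    assert color_bins(np.array([0.6]), spec)[0] == 20  # clamped past critical
    assert color_bins(np.array([-0.6]), spec)[0] == 0
    # first negative bin below the nominal band spans (-0.095, -0.05]
    assert color_bins(np.array([-0.06]), spec)[0] == 9
    assert color_bins(np.array([-0.05, 0.05]), spec).tolist() == [10, 10]
    assert color_bins(np.array([0.051]), spec)[0] == 11


@given(st.lists(st.floats(-1.0, 1.0, allow_nan=False), min_size=2, max_size=40))
def test_color_bins_monotone_in_deviation(values):
    spec = ColorMapSpec()
    order = np.argsort(values)
    bins = color_bins(np.asarray(values)[order], spec)
    assert (np.diff(bins) >= 0).all()


def test_colormap_legend_structure():
    spec = ColorMapSpec()
    legend = colormap_legend(spec)
    assert len(legend) == 21
    mid = legend.iloc[10]
    assert mid.lower_mm == -0.05 and mid.upper_mm == 0.05
    # ten equal-width segments per side out to the critical value
    inner = legend.iloc[1:10]
    widths = (inner.upper_mm - inner.lower_mm).to_numpy()
    assert np.allclose(widths, 0.045)
    assert legend.iloc[1].lower_mm == pytest.approx(-0.455)
    assert np.isneginf(legend.iloc[0].lower_mm)
    assert np.isposinf(legend.iloc[20].upper_mm)
    # blue end = contraction, red end = expansion
    assert legend.color.iloc[0].lower() in ("#000080", "#00007f")
    assert legend.color.iloc[20].lower() in ("#800000", "#7f0000")


def test_colormap_spec_validation():
    with pytest.raises(ValueError):
        ColorMapSpec(segments=20)
    with pytest.raises(ValueError):
        ColorMapSpec(nominal=0.6)


def test_colormap_exports(tmp_path, slab):
    field = signed_deviation(slab, slab, ["top"], density=1.0, seed=0)
    ply = tmp_path / "map.ply"
    csv = tmp_path / "map.csv"
    export_colormap_ply(field, ply)
    export_colormap_csv(field, csv)
    assert ply.read_text().startswith("ply")
    assert "deviation_mm" in csv.read_text().splitlines()[0]
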
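"""Virtual caliper, relative errors, directional aggregation, and ICC."""

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st

from dentaltrueness import (
    FeatureSize,
    LabeledMesh,
    MeasurementError,
    RigidTransform,
    average_repeats,
    icc,
    measure_features,
    relative_error,
    summarize_linear,
    virtual_caliper,
)
from dentaltrueness.generator import FeatureEntry


def _scaled(lm, sx, sy, sz):
    v = lm.mesh.vertices * np.array([sx, sy, sz])
    return LabeledMesh(
        trimesh.Trimesh(v, lm.mesh.faces.copy(), process=False),
        {k: idx.copy() for k, idx in lm.regions.items()},
    )


def test_reference_caliper_returns_every_designed_value(ref_max, ref_mand, schema):
    for lm, jaw in ((ref_max, "maxillary"), (ref_mand, "mandibular")):
        for f in measure_features(lm, schema, jaw):
            assert abs(f.measured_value - f.designed_value) < 1e-9, f.id
            assert abs(f.relative_error) < 1e-9


def test_caliper_designed_examples(ref_max, ref_mand, schema):
    assert np.isclose(
        virtual_caliper(ref_max, schema.by_id("MD-UL-C")), 8.0, atol=1e-9
    )
    assert np.isclose(
        virtual_caliper(ref_mand, schema.by_id("CH-LR-SM")), 12.0, atol=1e-9
    )
    assert np.isclose(
        virtual_caliper(ref_max, schema.by_id("MD-UR-FM")), 10.0, atol=1e-9
    )


def test_caliper_scaling_laws(ref_max, schema):
    inplane = _scaled(ref_max, 1.01, 1.01, 1.0)
    for f in measure_features(inplane, schema, "maxillary"):
        if f.axis_class == "occlusal-plane":
            assert np.isclose(f.measured_value, 1.01 * f.designed_value, atol=1e-9)
            assert np.isclose(f.relative_error, 1.0, atol=1e-9)
        else:
            assert np.isclose(f.measured_value, f.designed_value, atol=1e-9)
    axial = _scaled(ref_max, 1.0, 1.0, 0.98)
    for f in measure_features(axial, schema, "maxillary"):
        if f.axis_class == "occlusogingival":
            assert np.isclose(f.relative_error, -2.0, atol=1e-9)
        else:
            assert np.isclose(f.relative_error, 0.0, atol=1e-9)


def test_caliper_is_rigid_motion_invariant(ref_max, schema):
    moved = ref_max.transformed(
        RigidTransform.from_axis_angle([1.0, 0.4, -0.7], 40.0, [12.0, -8.0, 30.0])
    )
    a = measure_features(ref_max, schema, "maxillary")
    b = measure_features(moved, schema, "maxillary")
    for fa, fb in zip(a, b):
        assert abs(fa.measured_value - fb.measured_value) < 1e-9


def test_caliper_flags_overlapping_surfaces(ref_max, schema):
    e = schema.by_id("CH-UL-FM")
    inverted = FeatureEntry(
        "CH-inverted", e.jaw, e.axis_class, e.region_b, e.region_a,
        e.direction, e.designed_value,
    )
    with pytest.raises(MeasurementError):
        virtual_caliper(ref_max, inverted)
    missing = FeatureEntry(
        "MD-missing", e.jaw, "occlusal-plane", "UL-XX:mesial", "UL-XX:distal",
        np.array([1.0, 0, 0]), 1.0,
    )
    with pytest.raises(KeyError):
        virtual_caliper(ref_max, missing)


def test_relative_error_worked_examples():
    # 0.02% is a 2 um discrepancy on a 10 mm feature
    assert np.isclose(relative_error(10.0, 10.002), 0.02, rtol=1e-12)
    assert relative_error(7.5, 7.5) == 0.0
    assert np.isclose(relative_error(8.0, 7.92), -1.0, rtol=1e-12)
    with pytest.raises(ValueError):
        relative_error(0.0, 1.0)


@given(
    st.floats(0.5, 50.0, allow_nan=False),
    st.floats(-0.4, 0.4, allow_nan=False),
)
def test_relative_error_antisymmetry(x1, delta):
    assert np.isclose(
        relative_error(x1, x1 + delta), -relative_error(x1, x1 - delta),
        rtol=1e-9, atol=1e-12,
    )


def _fake_features(jaw, occl_value, ging_value):
    feats = []
    for i in range(34):
        feats.append(
            FeatureSize(f"O{i}", jaw, "occlusal-plane", 10.0, 10.0 * (1 + occl_value / 100))
        )
    for i in range(14):
        feats.append(
            FeatureSize(f"G{i}", jaw, "occlusogingival", 10.0, 10.0 * (1 + ging_value / 100))
        )
    return feats


def test_summarize_linear_uniform_errors():
    s = summarize_linear(_fake_features("maxillary", 1.0, -0.5), "maxillary")
    assert np.isclose(s.occlusal_plane_mean, 1.0, atol=1e-9)
    assert np.isclose(s.occlusal_plane_sd, 0.0, atol=1e-9)
    assert np.isclose(s.occlusogingival_mean, -0.5, atol=1e-9)


def test_summarize_linear_matches_direct_arithmetic():
    feats = _fake_features("mandibular", 0.0, 0.0)
    # give three features known distinct errors, recompute mean/sd by hand
    feats[0] = FeatureSize("O0", "mandibular", "occlusal-plane", 10.0, 10.01)
    feats[1] = FeatureSize("O1", "mandibular", "occlusal-plane", 10.0, 10.05)
    feats[2] = FeatureSize("O2", "mandibular", "occlusal-plane", 10.0, 9.98)
    s = summarize_linear(feats, "mandibular")
    vals = np.array([0.1, 0.5, -0.2] + [0.0] * 31)
    assert np.isclose(s.occlusal_plane_mean, vals.mean(), rtol=1e-12)
    assert np.isclose(s.occlusal_plane_sd, vals.std(ddof=1), rtol=1e-12)


def test_summarize_linear_requires_complete_jaw():
    feats = _fake_features("maxillary", 0.0, 0.0)[:-1]
    with pytest.raises(ValueError, match="incomplete"):
        summarize_linear(feats, "maxillary")


def test_average_repeats():
    assert average_repeats([10.0] * 5) == 10.0
    assert np.isclose(average_repeats([9.98, 10.00, 10.02, 10.01, 9.99]), 10.0)
    assert average_repeats([7.3]) == 7.3
    assert average_repeats({"MD": [1.0, 3.0]}) == {"MD": 2.0}
    with pytest.raises(ValueError):
        average_repeats([])


def test_icc_perfect_agreement_is_one(rng):
    col = rng.normal(10, 1, size=20)
    X = np.column_stack([col, col, col])
    assert np.isclose(icc(X), 1.0, atol=1e-12)


def test_icc_pure_noise_is_near_zero(rng):
    X = rng.normal(0.0, 1.0, size=(600, 3))  # no feature variance at all
    assert abs(icc(X)) < 0.1


def test_icc_recovers_known_variance_components(rng):
    n, k = 3000, 3
    sf, sr, se = 1.0, 0.3, 0.5  # feature, rater, error SDs
    truth = sf**2 / (sf**2 + sr**2 + se**2)
    X = (
        rng.normal(0, sf, (n, 1))
        + rng.normal(0, sr, (1, k))
        + rng.normal(0, se, (n, k))
    )
    assert abs(icc(X) - truth) < 0.05


def test_icc_matches_anova_oracle(rng):
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    n, k = 12, 3
    X = rng.normal(10, 1, (n, 1)) + rng.normal(0, 0.3, (n, k))
    long = pd.DataFrame(
        {
            "targets": np.repeat(np.arange(n), k),
            "raters": np.tile(np.arange(k), n),
            "scores": X.ravel(),
        }
    )
    oracle = pingouin.intraclass_corr(
        long, targets="targets", raters="raters", ratings="scores"
    )
    # two-way random, absolute agreement, single measures
    icc2 = float(oracle.loc[oracle.Type == "ICC(A,1)", "ICC"].iloc[0])
    assert np.isclose(icc(X), icc2, atol=1e-9)


def test_icc_input_validation():
    with pytest.raises(ValueError):
        icc(np.array([[1.0, 2.0]]))  # single feature
    bad = np.array([[1.0, 2.0], [3.0, np.nan]])
    with pytest.raises(ValueError):
        icc(bad)
    with pytest.raises(ValueError):
        icc(np.zeros((3, 3)), mode="sideways")
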
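"""Structurized-model generation: crown dimensions, layout, labels, export."""

import numpy as np
import pytest

from dentaltrueness import (
    LabeledMesh,
    MeshParseError,
    build_model,
    default_spec,
    enumerate_feature_sizes,
    export_model,
    read_labeled,
    read_stl,
    spec_from_config,
)
from dentaltrueness.generator import (
    TOOTH_CODES,
    LayoutError,
    ModelSpec,
    SDCDimensions,
    _box_mesh,
)

# designed crown dimensions (MD, BL, CH) in mm
TABLE_DIMS = {
    "maxillary": {
        "CI": (8, 7, 10), "LI": (7, 6, 9), "C": (8, 8, 11),
        "FP": (7, 9, 10), "SP": (7, 9, 10), "FM": (10, 11, 8), "SM": (9, 11, 5),
    },
    "mandibular": {
        "CI": (5, 6, 8), "LI": (6, 6, 8), "C": (7, 7, 8),
        "FP": (7, 8, 7), "SP": (7, 8, 7), "FM": (11, 10, 10), "SM": (11, 10, 12),
    },
}


@pytest.mark.parametrize("jaw", ["maxillary", "mandibular"])
def test_default_spec_matches_designed_crown_dimensions(jaw):
    spec = default_spec(jaw)
    for code in TOOTH_CODES:
        md, bl, ch = TABLE_DIMS[jaw][code]
        d = spec.sdc_dims[code]
        assert (d.md, d.bl, d.ch) == (md, bl, ch)
    assert len(spec.placements) == 14


def test_jaws_differ_in_every_incisor_dimension():
    mx, md = default_spec("maxillary"), default_spec("mandibular")
    for code in ("CI", "LI"):
        a, b = mx.sdc_dims[code], md.sdc_dims[code]
        for attr in ("md", "bl", "ch"):
            assert getattr(a, attr) != getattr(b, attr) or (code, attr) == ("LI", "bl")
    # the lateral incisor BL happens to agree; every other incisor dim differs
    assert mx.sdc_dims["CI"].md != md.sdc_dims["CI"].md


def test_invalid_inputs_are_rejected():
    with pytest.raises(ValueError):
        default_spec("cranial")
    with pytest.raises(ValueError):
        SDCDimensions("canine", -1.0, 8.0, 11.0)
    # an absurdly wide central incisor collides with its mirror twin
    with pytest.raises(LayoutError):
        default_spec("maxillary", sdc_dims={"CI": (8.0, 40.0, 10.0)})


def test_build_model_geometry(ref_max, spec_max):
    assert ref_max.mesh.is_watertight
    assert ref_max.mesh.is_winding_consistent
    assert ref_max.mesh.volume > 0
    # 14 crowns x 6 faces + base:upper
    assert len(ref_max.regions) == 85
    ref_max.validate(require_watertight=True)
    # occlusal face of UL-FM sits at z = base thickness + crown height
    z = ref_max.region_vertices("UL-FM:occlusal")[:, 2]
    expect = spec_max.base.thickness + spec_max.sdc_dims["FM"].ch
    assert np.allclose(z, expect, atol=1e-12)


def test_every_occlusal_face_is_crown_height_above_base(ref_mand, spec_mand):
    t = spec_mand.base.thickness
    for p in spec_mand.placements:
        z = ref_mand.region_vertices(p.region("occlusal"))[:, 2]
        g = ref_mand.region_vertices(p.region("gingival"))[:, 2]
        assert np.allclose(z - t, spec_mand.dims_for(p).ch, atol=1e-12)
        assert np.allclose(g, t, atol=1e-12)


def test_single_crown_matches_hand_constructed_cuboid():
    """One coarse SDC cell reduces to the 8-corner cuboid-on-slab case."""
    dims = SDCDimensions("canine", 8.0, 8.0, 11.0)
    verts, faces, labels = _box_mesh(
        np.array([1.0, 2.0, 0.0]),
        np.array([1.0, 0.0, 0.0]),
        np.array([0.0, 1.0, 0.0]),
        dims, z0=5.0, patch_mm=20.0,
    )
    assert len(verts) == 8 and len(faces) == 12
    assert sorted(labels) == sorted(
        ["occlusal", "buccal", "lingual", "mesial", "distal", "gingival"]
    )
    expected_corners = {
        (1 + sx * 4.0, 2 + sy * 4.0, 5.0 + sz * 11.0)
        for sx in (-1, 1) for sy in (-1, 1) for sz in (0, 1)
    }
    got = {tuple(np.round(v, 9)) for v in verts}
    assert got == expected_corners


def test_bilateral_mirror_symmetry(ref_max, spec_max):
    """Reflecting x -> -x maps each right crown exactly onto its left twin."""
    flip = np.array([-1.0, 1.0, 1.0])
    for code in TOOTH_CODES:
        for surface in ("occlusal", "mesial", "distal", "buccal", "lingual"):
            right = ref_max.region_vertices(f"UR-{code}:{surface}") * flip
            left = ref_max.region_vertices(f"UL-{code}:{surface}")
            r = sorted(map(tuple, np.round(right, 9)))
            l = sorted(map(tuple, np.round(left, 9)))
            assert r == l, f"UR/UL {code}:{surface} not mirrored"
    # the base outline is symmetric as well
    bx = ref_max.region_vertices("base:upper")[:, 0]
    assert abs(bx.max() + bx.min()) < 1e-9


def test_schema_counts_and_designed_values(schema):
    assert len(schema) == 96
    for jaw in ("maxillary", "mandibular"):
        entries = schema.for_jaw(jaw)
        assert len(entries) == 48
        occl = [e for e in entries if e.axis_class == "occlusal-plane"]
        ging = [e for e in entries if e.axis_class == "occlusogingival"]
        assert len(occl) == 34 and len(ging) == 14
        assert all(e.id.startswith("CH-") for e in ging)
        assert all(abs(e.direction[2]) < 1e-12 for e in occl)
    assert schema.by_id("MD-UL-C").designed_value == 8.0
    assert schema.by_id("MD-UR-FM").designed_value == 10.0
    assert schema.by_id("CH-LR-SM").designed_value == 12.0
    # arch features are assigned to the correct jaws
    for fid in ("L1", "L2", "L3", "L4", "L5", "L11"):
        assert schema.by_id(fid).jaw == "maxillary"
    for fid in ("L6", "L7", "L8", "L9", "L10", "L12"):
        assert schema.by_id(fid).jaw == "mandibular"


def test_spec_from_config_overrides_dims():
    spec = spec_from_config("maxillary", {"maxillary": {"dims": {"C": [8.5, 8, 11]}}})
    assert spec.sdc_dims["C"].md == 8.5
    with pytest.raises(ValueError):
        spec_from_config("maxillary", {"units": "inch"})


def test_export_round_trip(tmp_path, ref_mand):
    stl = tmp_path / "mand.stl"
    export_model(ref_mand, stl)
    again = read_labeled(stl)
    assert len(again.faces) == ref_mand.n_faces
    assert set(again.regions) == set(ref_mand.regions)
    for name in ref_mand.regions:
        assert np.array_equal(again.regions[name], ref_mand.regions[name])


def test_export_empty_mesh_fails(tmp_path):
    import trimesh

    empty = LabeledMesh(trimesh.Trimesh())
    with pytest.raises(ValueError):
        export_model(empty, tmp_path / "x.stl")
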
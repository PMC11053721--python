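"""Generate the structurized dental models and their measurement schema.

Builds the maxillary and mandibular reference models (horseshoe base plus
14 cuboid simulated dental crowns per jaw), exports STL + region sidecars,
and prints the 96-entry feature-size schema summary.  The designed values
printed below are what the virtual caliper must reproduce exactly on these
meshes — they are the ground truth every trueness metric is measured
against.
"""

from pathlib import Path

from dentaltrueness import (
    build_model,
    default_spec,
    enumerate_feature_sizes,
    export_model,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

specs = {jaw: default_spec(jaw) for jaw in ("maxillary", "mandibular")}
for jaw, spec in specs.items():
    model = build_model(spec)
    export_model(model, out / f"{jaw}.stl")
    print(
        f"{jaw}: {model.n_faces} faces, {len(model.regions)} labeled regions, "
        f"watertight={model.mesh.is_watertight}"
    )

schema = enumerate_feature_sizes(specs["maxillary"], specs["mandibular"])
df = schema.to_dataframe()
df.to_csv(out / "feature_sizes.csv", index=False)
print(f"\nfeature-size schema: {len(schema)} entries")
print(df.groupby(["jaw", "axis_class"]).size().to_string())
print("\nexamples of designed values (mm):")
for fid in ("MD-UL-FM", "BL-UR-C", "CH-LR-SM", "L3", "L11"):
    e = schema.by_id(fid)
    print(f"  {fid:10s} {e.designed_value:8.3f}  ({e.region_a} -> {e.region_b})")
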
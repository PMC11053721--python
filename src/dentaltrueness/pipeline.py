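"""End-to-end evaluation: register, label, deviate, fit, measure, summarize.

This is the programmatic equivalent of the study workflow: a test mesh (a
scan of a printed model, or a synthetic fixture) is best-fit registered to
the reference design, region labels are established on the test mesh, and
the 3D form errors and the 96 virtual-caliper feature sizes are computed
and aggregated into a :class:`~dentaltrueness.report.TruenessReport`.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from . import __version__
from .deviation import ColorMapSpec, DeviationField, overall_value, signed_deviation
from .form import FormMetricsSummary, summarize_form_metrics
from .generator import FeatureSizeSchema
from .io import DEFAULT_SAMPLING_DENSITY, DEFAULT_TRANSFER_CUTOFF, transfer_labels
from .linear import LinearSummary, measure_features, summarize_linear
from .mesh import LabeledMesh
from .register import (
    RegistrationOptions,
    RegistrationResult,
    best_fit_register,
    registration_regions,
)
from .report import TruenessReport, config_hash

__all__ = ["EvaluationConfig", "JawResult", "evaluate_jaw", "evaluate_pair"]


@dataclass(frozen=True)
class EvaluationConfig:
    units: str = "mm"
    seed: int = 0
    registration_sample_count: int = 3000
    registration_max_iterations: int = 200
    registration_tolerance: float = 1e-7
    deviation_density: float = DEFAULT_SAMPLING_DENSITY  # points per mm^2
    form_density: float = DEFAULT_SAMPLING_DENSITY
    label_transfer_cutoff: float = DEFAULT_TRANSFER_CUTOFF  # mm
    colormap: ColorMapSpec = field(default_factory=ColorMapSpec)

    def registration_options(self) -> RegistrationOptions:
        return RegistrationOptions(
            sample_count=self.registration_sample_count,
            seed=self.seed,
            max_iterations=self.registration_max_iterations,
            tolerance=self.registration_tolerance,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class JawResult:
    jaw: str
    registration: RegistrationResult
    deviation: DeviationField
    rms_mm: float
    form: FormMetricsSummary
    features: list
    linear: LinearSummary


def evaluate_jaw(
    reference: LabeledMesh,
    test: LabeledMesh,
    schema: FeatureSizeSchema,
    jaw: str,
    config: EvaluationConfig = EvaluationConfig(),
) -> JawResult:
    """Evaluate one jaw's test mesh against its reference design mesh.

    If the test mesh carries no region labels they are transferred from the
    reference by nearest-face correspondence after registration.
    """
    reg_regions = registration_regions(reference)
    reg = best_fit_register(
        test, reference, reg_regions, options=config.registration_options()
    )
    if not test.regions:
        test = transfer_labels(
            reference, test, reg.transform, cutoff=config.label_transfer_cutoff
        )
    field_ = signed_deviation(
        test,
        reference,
        reg_regions,
        transform=reg.transform,
        density=config.deviation_density,
        seed=config.seed,
    )
    form = summarize_form_metrics(
        test, density=config.form_density, seed=config.seed
    )
    # the virtual caliper is intrinsic (registration-free), like a physical
    # hand caliper on the printed model
    features = measure_features(test, schema, jaw=jaw)
    linear = summarize_linear(features, jaw)
    return JawResult(
        jaw=jaw,
        registration=reg,
        deviation=field_,
        rms_mm=field_.rms,
        form=form,
        features=features,
        linear=linear,
    )


def evaluate_pair(
    references: dict[str, LabeledMesh],
    tests: dict[str, LabeledMesh],
    schema: FeatureSizeSchema,
    config: EvaluationConfig = EvaluationConfig(),
    provenance: dict | None = None,
) -> TruenessReport:
    """Evaluate one or both jaws and assemble the trueness report.

    ``references`` and ``tests`` map jaw names ("maxillary"/"mandibular") to
    meshes; the overall 3D deviation (mean of the jaw RMS values) is only
    reported when both jaws are present.
    """
    if not tests:
        raise ValueError("nothing to evaluate")
    unknown = set(tests) - {"maxillary", "mandibular"}
    if unknown:
        raise ValueError(f"unknown jaw name(s): {sorted(unknown)}")
    results = {}
    for jaw, test in sorted(tests.items()):
        if jaw not in references:
            raise ValueError(f"no reference mesh given for {jaw}")
        results[jaw] = evaluate_jaw(references[jaw], test, schema, jaw, config)
    overall = None
    if {"maxillary", "mandibular"} <= set(results):
        overall = overall_value(
            results["maxillary"].rms_mm * 1000.0,
            results["mandibular"].rms_mm * 1000.0,
        )
    prov = {
        "tool": "dentaltrueness",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": config_hash(config.to_dict()),
        "units": config.units,
    }
    if provenance:
        prov.update(provenance)
    return TruenessReport(
        jaws=results, overall_3d_deviation_um=overall, provenance=prov
    )
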
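"""Trueness report: assembly, serialization and text rendering.

Raw metrics are kept at full precision in the JSON; the display block
mirrors the conventional reporting precision (RMS in integer micrometres,
millimetre and degree metrics to 3 decimals, percentages to 2 decimals).
No timestamps are embedded, so identical inputs + seed give byte-identical
reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["TruenessReport", "config_hash"]


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jaw_block(jr) -> dict[str, Any]:
    form = jr.form
    lin = jr.linear
    return {
        "registration": {
            "matrix": jr.registration.matrix.tolist(),
            "residual_rms_mm": jr.registration.rms,
            "iterations": jr.registration.iterations,
            "converged": jr.registration.converged,
        },
        "overall_3d_deviation_um": jr.rms_mm * 1000.0,
        "n_deviation_points": int(jr.deviation.n),
        "flatness_mm": {
            "mean": form.flatness_mean,
            "sd": form.flatness_sd,
            "horizontal_mean": form.flatness_horizontal_mean,
            "vertical_mean": form.flatness_vertical_mean,
        },
        "parallelism_deg": {"mean": form.parallelism_mean, "sd": form.parallelism_sd},
        "perpendicularity_deg": {
            "mean": form.perpendicularity_mean,
            "sd": form.perpendicularity_sd,
        },
        "occlusal_plane_error_pct": {
            "mean": lin.occlusal_plane_mean,
            "sd": lin.occlusal_plane_sd,
            "n": lin.n_occlusal_plane,
        },
        "occlusogingival_error_pct": {
            "mean": lin.occlusogingival_mean,
            "sd": lin.occlusogingival_sd,
            "n": lin.n_occlusogingival,
        },
    }


@dataclass
class TruenessReport:
    """Full evaluation result for one or two jaws."""

    jaws: dict[str, Any]  # jaw name -> JawResult
    overall_3d_deviation_um: float | None
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"provenance": dict(self.provenance)}
        out["jaws"] = {jaw: _jaw_block(jr) for jaw, jr in sorted(self.jaws.items())}
        out["overall_3d_deviation_um"] = self.overall_3d_deviation_um
        out["display"] = self._display_block()
        return out

    def _display_block(self) -> dict[str, Any]:
        disp: dict[str, Any] = {}
        for jaw, jr in sorted(self.jaws.items()):
            form, lin = jr.form, jr.linear
            disp[jaw] = {
                "overall_3d_deviation_um": int(round(jr.rms_mm * 1000.0)),
                "flatness_mm": f"{form.flatness_mean:.3f} ± {form.flatness_sd:.3f}",
                "flatness_horizontal_mm": f"{form.flatness_horizontal_mean:.3f}",
                "flatness_vertical_mm": f"{form.flatness_vertical_mean:.3f}",
                "parallelism_deg": f"{form.parallelism_mean:.3f} ± {form.parallelism_sd:.3f}",
                "perpendicularity_deg": (
                    f"{form.perpendicularity_mean:.3f} ± {form.perpendicularity_sd:.3f}"
                ),
                "occlusal_plane_error_pct": (
                    f"{lin.occlusal_plane_mean:.2f} ± {lin.occlusal_plane_sd:.2f}"
                ),
                "occlusogingival_error_pct": (
                    f"{lin.occlusogingival_mean:.2f} ± {lin.occlusogingival_sd:.2f}"
                ),
            }
        if self.overall_3d_deviation_um is not None:
            disp["overall_3d_deviation_um"] = int(
                round(self.overall_3d_deviation_um)
            )
        return disp

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, default=_np_default)
        if path is not None:
            Path(path).write_text(text)
        return text

    def render_text(self) -> str:
        lines = ["Spatial trueness report", "======================="]
        d = self._display_block()
        for jaw in sorted(self.jaws):
            b = d[jaw]
            lines += [
                "",
                f"{jaw.capitalize()} model",
                f"  overall 3D deviation (RMS): {b['overall_3d_deviation_um']} um",
                f"  flatness error:             {b['flatness_mm']} mm "
                f"(horizontal {b['flatness_horizontal_mm']}, "
                f"vertical {b['flatness_vertical_mm']})",
                f"  parallelism error:          {b['parallelism_deg']} deg",
                f"  perpendicularity error:     {b['perpendicularity_deg']} deg",
                f"  occlusal plane error:       {b['occlusal_plane_error_pct']} %",
                f"  occlusogingival error:      {b['occlusogingival_error_pct']} %",
            ]
        if self.overall_3d_deviation_um is not None:
            lines += [
                "",
                f"Overall 3D deviation (both jaws): "
                f"{d['overall_3d_deviation_um']} um",
            ]
        else:
            lines += ["", "Overall 3D deviation: skipped (single jaw evaluated)"]
        return "\n".join(lines)


def _np_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
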
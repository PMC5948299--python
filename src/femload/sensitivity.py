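"""One-at-a-time parameter sensitivity of the joint load prediction.

The default design varies nine parameters, two levels each, around the
reference configuration: segmentation threshold, load-patch area, nodal
force distribution, bone and cartilage moduli, number of unit loads, unit
load location, optimisation region of interest and the remodelling
equilibrium stimulus (19 runs in total including the reference). Strain
energy fields are cached, so variations that only change the optimisation
stage (stimulus, ROI) re-use the reference FE solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .image import VoxelImage
from .image_pipeline import AnatomicalFrame
from .load_prediction import frontal_inclination
from .pipeline import PipelineConfig, PipelineResult, run_pipeline

__all__ = [
    "ParameterVariation",
    "SensitivityRun",
    "SensitivityReport",
    "default_design",
    "run_sensitivity",
    "save_design",
    "load_design",
]

# parameter vocabulary -> PipelineConfig field
_PARAM_FIELD = {
    "threshold": "threshold",
    "load_area": "load_area_mm2",
    "force_distribution": "distribution",
    "bone_modulus": "bone_modulus_MPa",
    "cartilage_modulus": "cartilage_modulus_MPa",
    "n_unit_loads": "n_unit_loads",
    "load_location": "rotation_offset_deg",
    "roi": "roi_reduction_mm",
    "equilibrium_stimulus": "equilibrium_stimulus_MPa",
}


@dataclass(frozen=True)
class ParameterVariation:
    """One varied parameter with its reference value and two variations."""

    name: str
    reference: object
    variation_1: object
    variation_2: object

    def __post_init__(self) -> None:
        if self.name not in _PARAM_FIELD:
            raise ValueError(
                f"unknown parameter {self.name!r}; valid names: {sorted(_PARAM_FIELD)}"
            )

    def levels(self) -> list[tuple[str, object]]:
        return [("variation_1", self.variation_1), ("variation_2", self.variation_2)]


def default_design() -> list[ParameterVariation]:
    """The nine-parameter, two-variation design around the reference.

    Moduli are in MPa, areas in mm^2, the stimulus in MPa, the load
    location offset in degrees about the AP axis and the ROI reduction in
    mm from the lateral/distal boundaries. The reference load area is the
    natural 40-degree-cone patch (``None`` = no area override); the
    variations prescribe absolute target areas realised by solving for the
    cone angle on the articular sphere.
    """
    return [
        ParameterVariation("threshold", 3000.0, 3300.0, 2700.0),
        ParameterVariation("load_area", None, 121.5, 54.2),
        ParameterVariation("force_distribution", "uniform_normal",
                           "uniform_parallel", "hertz_parallel"),
        ParameterVariation("bone_modulus", 10_000.0, 5_000.0, 20_000.0),
        ParameterVariation("cartilage_modulus", 10.0, 100.0, 1000.0),
        ParameterVariation("n_unit_loads", 4, 7, 13),
        ParameterVariation("load_location", 0.0, 10.0, -10.0),
        ParameterVariation("roi", 0.0, 5.0, 10.0),
        ParameterVariation("equilibrium_stimulus", 0.02, 0.01, 0.04),
    ]


@dataclass
class SensitivityRun:
    parameter: str
    level: str  # "reference" | "variation_1" | "variation_2"
    value: object
    alpha: np.ndarray
    inclinations_deg: np.ndarray
    peak_vector: np.ndarray
    mean_vector: np.ndarray
    cov_opt: float
    n_new_solves: int

    @property
    def peak_magnitude(self) -> float:
        return float(np.linalg.norm(self.peak_vector))

    @property
    def peak_inclination(self) -> float:
        return frontal_inclination(self.peak_vector)

    @property
    def mean_magnitude(self) -> float:
        return float(np.linalg.norm(self.mean_vector))

    @property
    def mean_inclination(self) -> float:
        return frontal_inclination(self.mean_vector)


@dataclass
class SensitivityReport:
    reference: SensitivityRun
    runs: list[SensitivityRun] = field(default_factory=list)

    @property
    def all_runs(self) -> list[SensitivityRun]:
        return [self.reference, *self.runs]

    def to_frame(self) -> pd.DataFrame:
        ref = self.reference
        rows = []
        for r in self.all_runs:
            rows.append({
                "parameter": r.parameter,
                "level": r.level,
                "value": r.value,
                "peak_N": r.peak_magnitude,
                "peak_deg": r.peak_inclination,
                "mean_N": r.mean_magnitude,
                "mean_deg": r.mean_inclination,
                "cov_opt_pct": r.cov_opt,
                "n_new_solves": r.n_new_solves,
                "d_peak_N": r.peak_magnitude - ref.peak_magnitude,
                "d_peak_deg": r.peak_inclination - ref.peak_inclination,
                "d_mean_N": r.mean_magnitude - ref.mean_magnitude,
                "d_mean_deg": r.mean_inclination - ref.mean_inclination,
                "alpha": " ".join(f"{a:.4f}" for a in r.alpha),
            })
        return pd.DataFrame(rows)


def _as_run(parameter: str, level: str, value, res: PipelineResult) -> SensitivityRun:
    p = res.prediction
    return SensitivityRun(
        parameter=parameter, level=level, value=value,
        alpha=p.alpha, inclinations_deg=res.inclinations_deg,
        peak_vector=p.peak_vector, mean_vector=p.mean_vector,
        cov_opt=p.cov_opt, n_new_solves=res.n_new_solves,
    )


def run_sensitivity(
    image: VoxelImage,
    design: list[ParameterVariation] | None = None,
    base_config: PipelineConfig | None = None,
    frame: AnatomicalFrame | None = None,
) -> SensitivityReport:
    """Execute the one-at-a-time design: 1 reference + 2 runs per parameter.

    Every variation starts from the reference configuration; the reference
    FE solution is solved once and re-used by all runs whose variation
    does not alter the FE stage.
    """
    design = design if design is not None else default_design()
    base_config = base_config or PipelineConfig()
    for v in design:  # validate the whole design before any solve
        if not isinstance(v, ParameterVariation):
            raise TypeError("design entries must be ParameterVariation instances")

    cache: dict = {}
    ref_res = run_pipeline(image, base_config, frame=frame, cache=cache)
    report = SensitivityReport(reference=_as_run("reference", "reference", None, ref_res))
    for v in design:
        fld = _PARAM_FIELD[v.name]
        for level, value in v.levels():
            cfg = replace(base_config, **{fld: value})
            res = run_pipeline(image, cfg, frame=frame, cache=cache)
            report.runs.append(_as_run(v.name, level, value, res))
    return report


def save_design(design: list[ParameterVariation], path: str | Path) -> None:
    payload = [
        {"parameter": v.name, "reference": v.reference,
         "variation_1": v.variation_1, "variation_2": v.variation_2}
        for v in design
    ]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_design(path: str | Path) -> list[ParameterVariation]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        ParameterVariation(d["parameter"], d.get("reference"),
                           d["variation_1"], d["variation_2"])
        for d in payload
    ]
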
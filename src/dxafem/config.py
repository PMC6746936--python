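"""Pipeline configuration.

Every tunable quantity of the pipeline lives here, grouped by stage, with
validated ranges.  Unknown keys are rejected so that a typo in a config file
fails loudly instead of silently running with defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class CalibrationConfig(_Section):
    #: minimum-BMD fraction f: the line intercept is f * mean ROI aBMD.
    #: 0.20 is the value judged optimal of the five trial fractions
    #: {0.10, 0.15, 0.20, 0.25, 0.30}; any value in [0, 1) is accepted.
    fraction_f: float = Field(0.20, ge=0.0, lt=1.0)


class MeshConfig(_Section):
    #: target element edge length in mm.
    element_size_mm: float = Field(0.5, gt=0.0)


class ThicknessConfig(_Section):
    #: how the constant plate thickness is derived from the neck width w.
    #: "area" matches the cross-section area of a circle of diameter w
    #: (t = pi*w/4); "inertia" matches its bending inertia (t = 3*pi*w/16);
    #: "mean" averages the two (a rectangle cannot satisfy both at once).
    method: Literal["area", "inertia", "mean"] = "mean"


class MaterialConfig(_Section):
    n_bins: int = Field(35, ge=1)
    #: mineral (ash) fraction converting volumetric mineral density to
    #: apparent wet density: rho_app = rho_vol / ash_fraction.
    ash_fraction: float = Field(0.6, gt=0.0, le=1.0)
    poisson: float = Field(0.3, ge=0.0, lt=0.5)
    # density-modulus power law (MPa, g/cm^3): two branches switching at
    # rho_switch, E = c * rho_app ** p.
    morgan_c_low: float = 15010.0
    morgan_p_low: float = 2.18
    morgan_c_high: float = 6850.0
    morgan_p_high: float = 1.49
    morgan_rho_switch: float = 0.28


class ImpactConfig(_Section):
    #: fraction of body mass participating in the impact.
    effective_mass_fraction: float = Field(0.5, gt=0.0, le=1.0)
    #: fall height as a fraction of body height H; impact speed is
    #: v = sqrt(2 g * fall_height_fraction * H).
    fall_height_fraction: float = Field(0.51, gt=0.0, le=1.0)
    #: trochanteric soft-tissue contact stiffness, N/m.
    contact_stiffness_k: float = Field(5.0e4, gt=0.0)
    #: damping ratio of the 1-DOF impact oscillator; 0 <= zeta < 1.
    damping_ratio_zeta: float = Field(0.0, ge=0.0, lt=1.0)
    gravity_g: float = Field(9.81, gt=0.0)


class BoundaryConfig(_Section):
    #: total translational stiffness of the head-to-ground springs, N/mm,
    #: split uniformly over the head boundary nodes, isotropic in-plane.
    head_spring_total_n_per_mm: float = Field(10000.0, gt=0.0)
    #: force inclination, degrees counter-clockwise from the axis
    #: perpendicular to the shaft, in the image frontal plane.
    force_angle_deg: float = 30.0
    #: fraction of the lateral trochanteric boundary arc receiving the
    #: impact force (1.0 = the whole lateral arc inside the trochanter ROI).
    troch_arc_fraction: float = Field(1.0, gt=0.0, le=1.0)
    #: in-plane direction of the medial side; "+x" for scans with the
    #: femoral head towards increasing x, "-x" for mirrored scans.
    medial_direction: Literal["+x", "-x"] = "+x"


class RiskConfig(_Section):
    #: tensile / compressive yield strain limits of the principal-strain
    #: fracture criterion (dimensionless strain).
    tensile_limit: float = Field(0.0073, gt=0.0)
    compressive_limit: float = Field(0.0104, gt=0.0)
    #: "max_ratio": RF = max(eps1+/limit_t, |eps3-|/limit_c);
    #: "max_magnitude": the larger-|.| principal strain over its own limit.
    prevailing_rule: Literal["max_ratio", "max_magnitude"] = "max_ratio"
    #: cohort percentiles reported alongside the prognostic threshold.
    report_percentiles: tuple[float, float, float] = (90.0, 98.0, 99.9)


class StatsConfig(_Section):
    vif_threshold: float = Field(10.0, gt=1.0)
    #: use the small-sample corrected criterion (AICc) instead of plain AIC.
    use_aicc: bool = False
    max_exhaustive_p: int = Field(15, ge=1, le=20)


class PipelineConfig(_Section):
    """Full layered configuration with the documented defaults."""

    calibration: CalibrationConfig = CalibrationConfig()
    mesh: MeshConfig = MeshConfig()
    thickness: ThicknessConfig = ThicknessConfig()
    material: MaterialConfig = MaterialConfig()
    impact: ImpactConfig = ImpactConfig()
    bc: BoundaryConfig = BoundaryConfig()
    risk: RiskConfig = RiskConfig()
    stats: StatsConfig = StatsConfig()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a JSON config file; keys absent in the file keep defaults."""
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")
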
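"""Principal-strain Risk of Fracture and cohort-level classification.

Each element's Risk of Fracture (RF) is the prevailing principal strain
divided by the corresponding yield limit (tensile limit for the tensile
principal strain, compressive limit for the compressive one).  The patient
statistic RF^ is the maximum RF outside the head and trochanteric regions,
which sit next to the boundary conditions and would otherwise dominate
spuriously.  At cohort level, a patient is flagged at risk when RF^ exceeds
the 99.9th percentile of the pooled per-element RF of the whole cohort, or
trivially when RF^ >= 1 (strain beyond the yield limit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RiskConfig


@dataclass(frozen=True)
class FractureCriterion:
    tensile_limit: float = 0.0073
    compressive_limit: float = 0.0104
    prevailing_rule: str = "max_ratio"   # or "max_magnitude"

    def __post_init__(self) -> None:
        if self.tensile_limit <= 0 or self.compressive_limit <= 0:
            raise ValueError("strain limits must be > 0")
        if self.prevailing_rule not in ("max_ratio", "max_magnitude"):
            raise ValueError(f"unknown prevailing rule {self.prevailing_rule!r}")

    @classmethod
    def from_config(cls, cfg: RiskConfig) -> "FractureCriterion":
        return cls(cfg.tensile_limit, cfg.compressive_limit, cfg.prevailing_rule)


def element_rf(
    eps1: np.ndarray | float,
    eps3: np.ndarray | float,
    criterion: FractureCriterion = FractureCriterion(),
) -> np.ndarray | float:
    """Per-element Risk of Fracture from principal strains (eps1 >= eps3)."""
    e1 = np.asarray(eps1, dtype=float)
    e3 = np.asarray(eps3, dtype=float)
    if np.any(e1 < e3):
        raise ValueError("principal strains must satisfy eps1 >= eps3")
    tens = np.maximum(e1, 0.0) / criterion.tensile_limit
    comp = np.maximum(-e3, 0.0) / criterion.compressive_limit
    if criterion.prevailing_rule == "max_ratio":
        rf = np.maximum(tens, comp)
    else:  # max_magnitude: the larger-|.| principal strain over its own limit
        use_tens = np.abs(e1) >= np.abs(e3)
        rf = np.where(use_tens, tens, comp)
    if np.ndim(eps1) == 0 and np.ndim(eps3) == 0:
        return float(rf)
    return rf


@dataclass
class RiskField:
    rf: np.ndarray               # per-element RF, >= 0
    excluded: np.ndarray         # boolean, head + trochanter elements

    def __post_init__(self) -> None:
        if self.rf.shape != self.excluded.shape:
            raise ValueError("rf and exclusion mask shapes differ")


@dataclass(frozen=True)
class RFHat:
    """Per-patient maximum RF outside the excluded regions."""

    value: float
    element_id: int
    location_label: str          # "intracapsular" | "extracapsular"


def extract_rf_hat(risk: RiskField, neck_elements: np.ndarray) -> RFHat:
    """Maximum RF over eligible elements; ties break to the lowest element id.

    The location label is "intracapsular" when the RF^ element lies in the
    neck ROI and "extracapsular" otherwise (a documented heuristic).
    """
    eligible = ~risk.excluded
    if not eligible.any():
        raise ValueError("all elements excluded; RF^ undefined")
    rf_eligible = np.where(eligible, risk.rf, -np.inf)
    elem = int(np.argmax(rf_eligible))           # argmax: first (lowest id) max
    label = "intracapsular" if bool(neck_elements[elem]) else "extracapsular"
    return RFHat(value=float(risk.rf[elem]), element_id=elem, location_label=label)


@dataclass
class CohortClassification:
    thresholds: dict[str, float]          # e.g. {"p90": ..., "p98": ..., "p99.9": ...}
    prognostic_threshold: float           # the 99.9th percentile
    at_risk: np.ndarray                   # boolean per patient
    rf_hat: np.ndarray                    # per patient


def cohort_classify(
    pooled_rf: np.ndarray,
    rf_hat_per_patient: np.ndarray,
    percentiles: tuple[float, ...] = (90.0, 98.0, 99.9),
) -> CohortClassification:
    """Percentile thresholds on the pooled per-element RF and at-risk flags.

    Percentiles use linear interpolation between order statistics (the
    numpy default).  A patient is at risk iff RF^ exceeds the 99.9th pooled
    percentile or RF^ >= 1.
    """
    pooled = np.asarray(pooled_rf, dtype=float).ravel()
    if pooled.size == 0:
        raise ValueError("pooled RF set is empty")
    rf_hat = np.asarray(rf_hat_per_patient, dtype=float)
    if rf_hat.size < 2:
        import warnings

        warnings.warn("fewer than 2 patients: cohort thresholds are degenerate")
    values = np.percentile(pooled, percentiles)
    thresholds = {f"p{p:g}": float(v) for p, v in zip(percentiles, values)}
    prognostic = float(np.percentile(pooled, 99.9))
    at_risk = (rf_hat > prognostic) | (rf_hat >= 1.0)
    return CohortClassification(
        thresholds=thresholds,
        prognostic_threshold=prognostic,
        at_risk=at_risk,
        rf_hat=rf_hat,
    )
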
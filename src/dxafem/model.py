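"""Model/Results facade over the pipeline.

:class:`FemurFallModel` wraps one patient's inputs (image, masks, ROI mean
BMDs, metadata); ``fit()`` runs calibration, meshing, material mapping, the
impact estimate and the plane-stress solve, and returns a
:class:`FemurFallResults` carrying the calibrated line, the plate thickness,
the impact force, the strain and risk fields, the patient RF^ and a
``summary()`` table.

:class:`HSARankingModel` wraps the cohort HSA table and a per-patient risk
response; ``fit()`` performs VIF collinearity pruning and exhaustive-subset
AIC ranking, returning :class:`HSARankingResults`.

``run_cohort`` chains the two over a list of patients and applies the
cohort-percentile prognostic rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from .config import PipelineConfig
from .fall import LoadCase, build_load_case, solve_fall
from .impact import ImpactParameters, impact_force
from .io import PatientBundle, read_patient
from .materials import MaterialField, build_material_field, plate_thickness
from .meshing import PlanarMesh, build_mesh, elements_in_mask, nearest_pixel
from .phantom import (
    LABEL_HEAD,
    LABEL_INTER,
    LABEL_NECK,
    LABEL_TROCH,
    PhantomPatient,
    estimate_axes,
)
from .risk import (
    CohortClassification,
    FractureCriterion,
    RFHat,
    RiskField,
    cohort_classify,
    element_rf,
    extract_rf_hat,
)
from .solver import SolveResult
from .stats import AICRanking, VIFResult, aic_rank, vif_filter

logger = logging.getLogger(__name__)


def measured_neck_width(
    femur: np.ndarray, labels: np.ndarray, spacing_mm: float
) -> float:
    """Narrowest across-axis width of the neck corridor, from the masks.

    Fallback for bundles without an HSA table: fits the neck axis and scans
    perpendicular slab widths over the extent of the neck ROI.
    """
    axes = estimate_axes(femur, labels, spacing_mm)
    d = axes["neck_dir"]
    origin = axes["neck_centroid"]
    n_rows = femur.shape[0]
    r, c = np.nonzero(femur)
    x = (c + 0.5) * spacing_mm
    y = (n_rows - r - 0.5) * spacing_mm
    t = (x - origin[0]) * d[0] + (y - origin[1]) * d[1]
    s = -(x - origin[0]) * d[1] + (y - origin[1]) * d[0]
    rn, cn = np.nonzero(labels == LABEL_NECK)
    xn = (cn + 0.5) * spacing_mm
    yn = (n_rows - rn - 0.5) * spacing_mm
    tn = (xn - origin[0]) * d[0] + (yn - origin[1]) * d[1]
    widths = []
    for tv in np.linspace(tn.min(), tn.max(), 40):
        sel = np.abs(t - tv) <= spacing_mm / 2
        if sel.any():
            widths.append(s[sel].max() - s[sel].min() + spacing_mm)
    if not widths:
        raise ValueError("could not measure the neck width from the masks")
    return float(np.min(widths))


@dataclass
class FemurFallResults:
    """Per-patient fitted state of the fall model."""

    patient_id: str
    config: PipelineConfig
    line: cal.CalibrationLine
    bmd_map: np.ndarray
    neck_width_mm: float
    thickness_mm: float
    mesh: PlanarMesh
    materials: MaterialField
    impact_params: ImpactParameters
    impact_force_n: float
    load_case: LoadCase
    solution: SolveResult
    risk_field: RiskField
    rf_hat: RFHat
    axes: dict = field(repr=False, default_factory=dict)
    at_risk: bool | None = None      # set by the cohort rule

    def to_report(self) -> dict:
        """JSON-serializable per-patient report (units in the key names)."""
        return {
            "patient_id": self.patient_id,
            "calibration": {
                "intercept_b_g_cm2": self.line.intercept_b,
                "slope_m_g_cm2_per_gray": self.line.slope_m,
                "fraction_f": self.line.fraction_f,
            },
            "neck_width_mm": self.neck_width_mm,
            "plate_thickness_mm": self.thickness_mm,
            "impact": {
                "force_n": self.impact_force_n,
                "velocity_m_s": self.impact_params.impact_velocity,
                "effective_mass_kg": self.impact_params.effective_mass,
            },
            "mesh": {
                "n_nodes": self.mesh.n_nodes,
                "n_elements": self.mesh.n_elements,
                "element_size_mm": self.mesh.elem_size_mm,
            },
            "materials": {
                "n_distinct_moduli": self.materials.n_distinct,
                "e_min_mpa": float(self.materials.e_mpa.min()),
                "e_max_mpa": float(self.materials.e_mpa.max()),
            },
            "solution": {
                "equilibrium_residual": self.solution.equilibrium_residual,
                "solver_residual": self.solution.solver_residual,
            },
            "rf_hat": {
                "value": self.rf_hat.value,
                "element_id": self.rf_hat.element_id,
                "location_label": self.rf_hat.location_label,
                "at_risk": self.at_risk,
            },
        }

    def summary(self) -> str:
        rep = self.to_report()
        lines = [
            f"Sideways-fall plate model -- patient {self.patient_id}",
            "=" * 56,
            f"calibration line    aBMD = {self.line.intercept_b:.4f} "
            f"+ {self.line.slope_m:.3e} * gray   (f = {self.line.fraction_f:g})",
            f"neck width          {self.neck_width_mm:8.2f} mm",
            f"plate thickness     {self.thickness_mm:8.2f} mm "
            f"({self.config.thickness.method})",
            f"impact force        {self.impact_force_n:8.1f} N "
            f"(v = {self.impact_params.impact_velocity:.2f} m/s)",
            f"mesh                {self.mesh.n_elements} elements / "
            f"{self.mesh.n_nodes} nodes @ {self.mesh.elem_size_mm} mm",
            f"moduli              {self.materials.n_distinct} distinct values, "
            f"E in [{rep['materials']['e_min_mpa']:.0f}, "
            f"{rep['materials']['e_max_mpa']:.0f}] MPa",
            f"equilibrium resid   {self.solution.equilibrium_residual:.2e}",
            f"RF^                 {self.rf_hat.value:.4f} "
            f"({self.rf_hat.location_label}, element {self.rf_hat.element_id})",
        ]
        if self.at_risk is not None:
            lines.append(f"at risk             {self.at_risk}")
        return "\n".join(lines)

    def to_vtk(self, path: str | Path) -> Path:
        from .vtk import write_vtk

        u = self.solution.u.reshape(-1, 2)
        rf = self.risk_field.rf
        floor = np.percentile(rf, 90.0)   # visualization floor (90th pct)
        return write_vtk(
            path,
            self.mesh,
            point_data={"displacement_mm": u},
            cell_data={
                "E_mpa": self.materials.e_mpa,
                "rho_app_g_cm3": self.materials.rho_app,
                "bin_id": self.materials.bin_id,
                "eps1": self.solution.eps1,
                "eps3": self.solution.eps3,
                "rf": rf,
                "rf_above_p90": np.where(rf >= floor, rf, 0.0),
                "excluded": self.risk_field.excluded.astype(float),
            },
        )

    def plot_rf(self, ax=None, floor: float | None = None):
        """RF contour map over the element grid, floored for display."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 5))
        grid = np.full(self.mesh.grid_shape, np.nan)
        cells = self.mesh.elem_cells
        rf = self.risk_field.rf
        if floor is None:
            floor = float(np.percentile(rf, 90.0))
        shown = np.where(rf >= floor, rf, np.nan)
        grid[cells[:, 0], cells[:, 1]] = shown
        im = ax.imshow(grid, cmap="inferno", interpolation="nearest")
        ax.set_title(f"RF >= {floor:.2f}")
        ax.axis("off")
        return ax, im


class FemurFallModel:
    """Patient-specific 2D plate model of a sideways fall.

    Parameters mirror the on-disk bundle: a gray image, the femur mask, the
    ROI label map, the three ROI mean aBMDs, and the patient metadata
    (height, weight, optional T-score).  ``fit()`` runs the whole chain.
    """

    def __init__(self, bundle: PatientBundle, config: PipelineConfig | None = None):
        self.bundle = bundle
        self.config = config or PipelineConfig()

    @classmethod
    def from_patient_dir(
        cls, directory: str | Path, config: PipelineConfig | None = None
    ) -> "FemurFallModel":
        return cls(read_patient(directory), config)

    @classmethod
    def from_phantom(
        cls, patient: PhantomPatient, config: PipelineConfig | None = None
    ) -> "FemurFallModel":
        bundle = PatientBundle(
            patient_id=patient.patient_id,
            image=patient.image,
            femur_mask=patient.femur_mask,
            labels=patient.labels,
            roi_means=patient.roi_means,
            metadata=patient.metadata,
            hsa=patient.hsa,
        )
        return cls(bundle, config)

    def fit(self) -> FemurFallResults:
        b = self.bundle
        cfg = self.config
        labels = b.labels

        rois = {
            name: cal.RoiMeasurement(
                name=name,
                mask=labels == lab,
                mean_abmd=b.roi_means[name],
            )
            for name, lab in (
                ("neck", LABEL_NECK),
                ("trochanter", LABEL_TROCH),
                ("intertrochanter", LABEL_INTER),
            )
        }
        line = cal.calibrate(b.image, rois, cfg.calibration.fraction_f)
        bmd_map = cal.apply_calibration(b.image, line, b.femur_mask)

        if b.hsa and "NN_W" in b.hsa:
            neck_width = float(b.hsa["NN_W"])
        else:
            neck_width = measured_neck_width(
                b.femur_mask, labels, b.image.spacing_mm
            )
        thickness = plate_thickness(neck_width, cfg.thickness.method)

        mesh = build_mesh(
            b.femur_mask,
            b.image.spacing_mm,
            cfg.mesh.element_size_mm,
            thickness_t=thickness,
        )
        pix = nearest_pixel(
            mesh.element_centroids(), b.image.spacing_mm, bmd_map.shape
        )
        abmd_elem = np.nan_to_num(bmd_map[pix[:, 0], pix[:, 1]], nan=0.0)
        materials = build_material_field(abmd_elem, thickness, cfg.material)

        params = ImpactParameters.from_config(
            b.metadata["height_m"], b.metadata["weight_kg"], cfg.impact
        )
        force_n = impact_force(params)

        axes = estimate_axes(b.femur_mask, labels, b.image.spacing_mm)
        head_el = elements_in_mask(mesh, labels == LABEL_HEAD, b.image.spacing_mm)
        troch_el = elements_in_mask(mesh, labels == LABEL_TROCH, b.image.spacing_mm)
        neck_el = elements_in_mask(mesh, labels == LABEL_NECK, b.image.spacing_mm)
        load = build_load_case(
            mesh, head_el, troch_el, axes["shaft_up"], force_n, cfg.bc
        )
        solution = solve_fall(mesh, materials, load)
        logger.info(
            "%s: F = %.1f N over %d nodes, %d spring / %d hinge nodes, "
            "equilibrium residual %.2e",
            b.patient_id,
            force_n,
            load.load_nodes.size,
            load.spring_nodes.size,
            load.hinge.slave_nodes.size,
            solution.equilibrium_residual,
        )

        criterion = FractureCriterion.from_config(cfg.risk)
        rf = np.asarray(
            element_rf(solution.eps1, solution.eps3, criterion), dtype=float
        )
        risk_field = RiskField(rf=rf, excluded=head_el | troch_el)
        rf_hat = extract_rf_hat(risk_field, neck_el)

        return FemurFallResults(
            patient_id=b.patient_id,
            config=cfg,
            line=line,
            bmd_map=bmd_map,
            neck_width_mm=neck_width,
            thickness_mm=thickness,
            mesh=mesh,
            materials=materials,
            impact_params=params,
            impact_force_n=force_n,
            load_case=load,
            solution=solution,
            risk_field=risk_field,
            rf_hat=rf_hat,
            axes=axes,
        )


@dataclass
class HSARankingResults:
    vif: VIFResult
    ranking: AICRanking
    n_patients: int

    @property
    def table(self) -> pd.DataFrame:
        """Two-column ranking table: variable, cumulative Akaike weight."""
        return self.ranking.cumulative_weights.rename("cumulative_weight").rename_axis(
            "variable"
        ).reset_index()

    def summary(self) -> str:
        lines = [
            f"HSA predictor ranking ({self.n_patients} patients)",
            "=" * 48,
            f"VIF pruning: {len(self.vif.retained)} retained of "
            f"{len(self.vif.retained) + len(self.vif.removed)} "
            f"(removed: {', '.join(n for n, _ in self.vif.removed) or 'none'})",
            f"best model: {', '.join(self.ranking.best_model)}",
            "",
            "variable        cumulative weight",
        ]
        for name, w in self.ranking.cumulative_weights.items():
            lines.append(f"{name:<15s} {w:8.3f}")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


class HSARankingModel:
    """Rank HSA geometric variables against a per-patient risk response."""

    def __init__(
        self,
        hsa: pd.DataFrame,
        response: pd.Series | np.ndarray,
        config: PipelineConfig | None = None,
    ):
        self.hsa = hsa
        self.response = np.asarray(response, dtype=float)
        self.config = config or PipelineConfig()
        if np.any(~np.isfinite(self.response)):
            raise ValueError("response contains missing values")
        bad = hsa.columns[hsa.isna().any()]
        if len(bad):
            rows = hsa.index[hsa[bad].isna().any(axis=1)]
            warnings.warn(f"rows with incomplete HSA dropped: {list(rows)}")
            keep = ~hsa.isna().any(axis=1)
            self.hsa = hsa.loc[keep]
            self.response = self.response[np.asarray(keep)]

    def fit(self) -> HSARankingResults:
        scfg = self.config.stats
        vif = vif_filter(self.hsa, threshold=scfg.vif_threshold)
        ranking = aic_rank(
            self.hsa[vif.retained],
            self.response,
            use_aicc=scfg.use_aicc,
            max_exhaustive_p=scfg.max_exhaustive_p,
        )
        return HSARankingResults(vif=vif, ranking=ranking, n_patients=len(self.hsa))


@dataclass
class CohortResults:
    patients: dict[str, FemurFallResults]
    classification: CohortClassification
    table: pd.DataFrame
    ranking: HSARankingResults | None = None
    failed: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        th = self.classification.thresholds
        lines = [
            f"Cohort of {len(self.patients)} patients",
            "=" * 48,
            "pooled RF percentiles: "
            + ", ".join(f"{k} = {v:.3f}" for k, v in th.items()),
            f"prognostic threshold (99.9th pct): "
            f"{self.classification.prognostic_threshold:.3f}",
            f"patients at risk: {int(self.table['at_risk'].sum())} "
            f"of {len(self.table)}",
        ]
        if self.failed:
            lines.append(f"failed patients: {sorted(self.failed)}")
        if self.ranking is not None:
            lines += ["", self.ranking.summary()]
        return "\n".join(lines)


def run_cohort(
    bundles: list[PatientBundle],
    config: PipelineConfig | None = None,
    hsa: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> CohortResults:
    """Fit every patient, apply the cohort prognostic rule, rank HSA.

    A failing patient is skipped with a warning; the cohort still completes.
    When ``out_dir`` is given, per-patient JSON reports, VTK exports, the
    cohort CSV and ``ranking.csv`` are written there.
    """
    import json

    config = config or PipelineConfig()
    if not bundles:
        raise ValueError("no patient bundles given")
    results: dict[str, FemurFallResults] = {}
    failed: dict[str, str] = {}
    pooled = []
    for bundle in bundles:
        try:
            res = FemurFallModel(bundle, config).fit()
        except Exception as exc:  # noqa: BLE001 - isolate per-patient failures
            warnings.warn(f"patient {bundle.patient_id} failed: {exc}")
            failed[bundle.patient_id] = str(exc)
            continue
        results[bundle.patient_id] = res
        pooled.append(res.risk_field.rf)
    if not results:
        raise ValueError("every patient failed")

    ids = list(results)
    rf_hat = np.array([results[i].rf_hat.value for i in ids])
    classification = cohort_classify(
        np.concatenate(pooled), rf_hat, config.risk.report_percentiles
    )
    for i, pid in enumerate(ids):
        results[pid].at_risk = bool(classification.at_risk[i])

    meta = {b.patient_id: b.metadata for b in bundles}
    table = pd.DataFrame(
        {
            "patient_id": ids,
            "rf_hat": rf_hat,
            "location": [results[i].rf_hat.location_label for i in ids],
            "t_score": [meta[i].get("t_score", np.nan) for i in ids],
            "at_risk": classification.at_risk,
        }
    ).set_index("patient_id")

    ranking = None
    if hsa is not None:
        ranking = HSARankingModel(
            hsa.loc[ids], pd.Series(rf_hat, index=ids), config
        ).fit()

    out = CohortResults(
        patients=results,
        classification=classification,
        table=table,
        ranking=ranking,
        failed=failed,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, res in results.items():
            (out_dir / f"{pid}.json").write_text(
                json.dumps(res.to_report(), indent=2, sort_keys=True) + "\n"
            )
            res.to_vtk(out_dir / f"{pid}.vtk")
        table.to_csv(out_dir / "cohort.csv")
        (out_dir / "thresholds.json").write_text(
            json.dumps(classification.thresholds, indent=2, sort_keys=True) + "\n"
        )
        if ranking is not None:
            ranking.to_csv(out_dir / "ranking.csv")
    return out
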
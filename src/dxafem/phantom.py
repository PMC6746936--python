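"""Synthetic DXA-like proximal-femur phantoms with known ground truth.

No public DXA dataset accompanies the pipeline, so every downstream stage is
exercised on parametric phantoms: the femur silhouette is a union of simple
primitives (vertical shaft rectangle, inclined neck corridor, head disc and a
greater-trochanter bulge), the per-pixel "true" areal BMD map is defined as
an exact affine function of an integer gray field, and the scanner-style
sidecar values (per-ROI mean aBMD, HSA table, patient metadata) are derived
from that ground truth.  Calibration, meshing, mechanics and statistics can
therefore all be checked against known answers.

Coordinate convention: physical frame is millimetres, y-up, medial side
towards +x (femoral head up-right, greater trochanter on the left); images
are row-major with row 0 at the top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import GrayImage

# label values of the region map
LABEL_NECK = 1
LABEL_TROCH = 2
LABEL_INTER = 3
LABEL_HEAD = 4
LABEL_SHAFT = 5

#: effective mineral density of fully mineralised bone tissue used when
#: converting BMD line profiles to HSA cross-sectional quantities (g/cm^3)
HSA_TISSUE_DENSITY = 1.05

HSA_COLUMNS = ["NSA", "HAL"] + [
    f"{site}_{q}"
    for site in ("NN", "IT", "FS")
    for q in ("W", "BR", "CSMI", "CSA", "Z", "ACT")
]


@dataclass(frozen=True)
class FemurShapeParams:
    """Geometric parameters of the parametric femur silhouette."""

    neck_shaft_angle_deg: float = 125.0
    neck_width_mm: float = 32.0
    hip_axis_length_mm: float = 100.0
    head_radius_mm: float = 24.0
    shaft_width_mm: float = 30.0
    image_spacing_mm: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "neck_width_mm",
            "hip_axis_length_mm",
            "head_radius_mm",
            "shaft_width_mm",
            "image_spacing_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (90.0 <= self.neck_shaft_angle_deg <= 160.0):
            raise ValueError("neck-shaft angle must lie in [90, 160] degrees")
        if self.neck_width_mm >= 2.0 * self.head_radius_mm:
            raise ValueError(
                "degenerate geometry: neck wider than the head diameter"
            )


@dataclass
class PhantomTruth:
    """Everything the generator knows that a real scanner would not tell."""

    true_bmd_map: np.ndarray            # g/cm^2, NaN outside the femur
    roi_mean_bmd: dict[str, float]      # exact mask-wise means
    hsa_row: dict[str, float]
    gray_to_bmd_line: tuple[float, float, float]   # (intercept, slope, fraction)
    params: FemurShapeParams
    geometry: dict[str, np.ndarray | float] = field(default_factory=dict)


@dataclass
class PhantomPatient:
    """One synthetic patient: image, masks, sidecar values and the truth."""

    patient_id: str
    image: GrayImage
    femur_mask: np.ndarray
    labels: np.ndarray                  # uint8 region map (values above)
    roi_means: dict[str, float]
    metadata: dict[str, float]
    hsa: dict[str, float]
    truth: PhantomTruth

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _geometry(params: FemurShapeParams, margin_mm: float = 3.0) -> dict:
    """Analytic layout of the primitives in the y-up mm frame."""
    ws = params.shaft_width_mm
    wn = params.neck_width_mm
    rh = params.head_radius_mm
    theta = math.radians(params.neck_shaft_angle_deg - 90.0)
    d_neck = np.array([math.cos(theta), math.sin(theta)])

    x_shaft = margin_mm + ws            # lateral troch tip lands at the margin
    y_junction = margin_mm + 45.0
    junction = np.array([x_shaft, y_junction])

    g_center = junction + np.array([-0.45 * ws, 0.35 * ws])
    g_radius = 0.55 * ws
    # extent of bone behind the junction along the (backwards) neck axis
    back = float(np.dot(junction - g_center, d_neck) + g_radius)
    neck_len = params.hip_axis_length_mm - rh - back
    if neck_len <= rh:
        raise ValueError(
            "degenerate geometry: hip axis length too short for this head"
        )
    head_center = junction + neck_len * d_neck
    return {
        "margin": margin_mm,
        "x_shaft": x_shaft,
        "junction": junction,
        "d_neck": d_neck,
        "neck_len": neck_len,
        "head_center": head_center,
        "g_center": g_center,
        "g_radius": g_radius,
    }


def _pixel_centers(n_rows: int, n_cols: int, h: float):
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x = (cols + 0.5) * h
    y = (n_rows - rows - 0.5) * h
    return x, y


def _rasterize(params: FemurShapeParams, geo: dict):
    h = params.image_spacing_mm
    ws, wn, rh = params.shaft_width_mm, params.neck_width_mm, params.head_radius_mm
    jx, jy = geo["junction"]
    cx, cy = geo["head_center"]
    margin = geo["margin"]

    width_mm = max(cx + rh, geo["g_center"][0] + geo["g_radius"]) + margin
    height_mm = cy + rh + margin
    n_cols = int(math.ceil(width_mm / h))
    n_rows = int(math.ceil(height_mm / h))
    x, y = _pixel_centers(n_rows, n_cols, h)

    shaft = (np.abs(x - geo["x_shaft"]) <= ws / 2) & (y >= margin) & (y <= jy)
    dxn = x - jx
    dyn = y - jy
    t = dxn * geo["d_neck"][0] + dyn * geo["d_neck"][1]       # along-axis coord
    s = -dxn * geo["d_neck"][1] + dyn * geo["d_neck"][0]      # across-axis coord
    neck = (np.abs(s) <= wn / 2) & (t >= 0.0) & (t <= geo["neck_len"])
    head = (x - cx) ** 2 + (y - cy) ** 2 <= rh**2
    troch = (x - geo["g_center"][0]) ** 2 + (y - geo["g_center"][1]) ** 2 <= geo[
        "g_radius"
    ] ** 2
    femur = shaft | neck | head | troch

    # region labels (disjoint, priority: head > neck band > trochanter > inter)
    labels = np.zeros(femur.shape, dtype=np.uint8)
    labels[head] = LABEL_HEAD
    t_lo = 0.15 * geo["neck_len"]
    t_hi = geo["neck_len"] - rh - 2.0
    neck_band = neck & (t >= t_lo) & (t <= t_hi) & (labels == 0)
    labels[neck_band] = LABEL_NECK
    labels[troch & (labels == 0) & femur] = LABEL_TROCH
    inter = (
        femur
        & (labels == 0)
        & (y >= jy - 0.4 * ws)
        & (y <= jy + 0.2 * ws)
    )
    labels[inter] = LABEL_INTER
    labels[femur & (labels == 0)] = LABEL_SHAFT

    geo.update(
        {
            "t": t,
            "s": s,
            "x": x,
            "y": y,
            "neck_t_band": (t_lo, t_hi),
            "shape": femur.shape,
        }
    )
    return femur, labels


def _bmd_shape_field(
    femur: np.ndarray,
    labels: np.ndarray,
    h: float,
    profile: str,
    region_factors: dict[int, float] | None = None,
):
    """Dimensionless density pattern in (0, 1] on the foreground.

    ``region_factors`` maps label values to multiplicative density factors,
    emulating the site-specific cortical variation seen across real
    patients (neck thinning need not track shaft thinning).
    """
    if profile == "uniform":
        phi = np.full(femur.shape, 0.6)
    elif profile == "cortical":
        # denser shell near the periosteal boundary, like the projected cortex
        dist = ndimage.distance_transform_edt(femur) * h
        phi = 0.40 + 0.45 * np.exp(-dist / 4.0)
        phi += 0.10 * (labels == LABEL_SHAFT)     # diaphysis reads denser
        phi -= 0.08 * (labels == LABEL_NECK)      # narrow neck reads thinner
    else:
        raise ValueError(f"unknown bmd profile {profile!r}")
    if region_factors:
        for lab, factor in region_factors.items():
            phi = np.where(labels == lab, phi * factor, phi)
    return np.clip(phi, 0.05, 1.0)


def _hsa_profile_metrics(
    bmd: np.ndarray,
    femur: np.ndarray,
    center: np.ndarray,
    direction: np.ndarray,
    h: float,
    half_span_mm: float,
    cortical_fraction: float = 0.6,
) -> dict[str, float]:
    """Width / CSA / CSMI / Z / ACT / BR of one cross-section line.

    The aBMD profile along the section (direction = unit vector across the
    bone) is integrated the way Hip Structural Analysis does: CSA is the
    mass-per-length profile over the tissue density, CSMI its second moment
    about the profile centroid, Z = CSMI / c with c the half-width, and the
    annulus model turns CSA + outer width into cortical thickness (ACT) and
    buckling ratio (BR = r_outer / ACT); only ``cortical_fraction`` of the
    section mass is attributed to the cortical shell (the rest is trabecular
    and does not thicken the shell), an independent biological parameter.
    """
    n_rows, n_cols = femur.shape
    steps = np.arange(-half_span_mm, half_span_mm + h / 2, h)
    px = center[0] + steps * direction[0]
    py = center[1] + steps * direction[1]
    col = np.clip((px / h).astype(int), 0, n_cols - 1)
    row = np.clip((n_rows - py / h).astype(int), 0, n_rows - 1)
    inside = femur[row, col]
    if not inside.any():
        raise ValueError("cross-section line misses the femur")
    vals = np.where(inside, np.nan_to_num(bmd[row, col], nan=0.0), 0.0)
    idx = np.nonzero(inside)[0]
    width_mm = (idx.max() - idx.min() + 1) * h
    dx_cm = h / 10.0
    mass = vals * dx_cm                     # g/cm per sample, integrated
    csa = float(mass.sum() / HSA_TISSUE_DENSITY)             # cm^2
    pos_cm = steps / 10.0
    if mass.sum() > 0:
        centroid = float((mass * pos_cm).sum() / mass.sum())
    else:
        centroid = 0.0
    csmi = float(((pos_cm - centroid) ** 2 * mass).sum() / HSA_TISSUE_DENSITY)  # cm^4
    r_out = width_mm / 20.0                 # cm
    z = csmi / r_out if r_out > 0 else 0.0
    r_in_sq = max(r_out**2 - cortical_fraction * csa / math.pi, 0.0)
    act = r_out - math.sqrt(r_in_sq)
    br = r_out / act if act > 0 else np.inf
    return {
        "W": float(width_mm),
        "BR": float(br),
        "CSMI": csmi,
        "CSA": csa,
        "Z": float(z),
        "ACT": float(act * 10.0),           # back to mm
    }


def neck_width_profile(
    femur: np.ndarray, geo: dict, n_samples: int = 60
) -> tuple[np.ndarray, np.ndarray]:
    """Across-axis widths of the neck corridor between trochanter and head.

    Returns (t_values, width_mm); the minimum is the narrow-neck width.
    """
    t, s = geo["t"], geo["s"]
    h = float(geo["x"][0, 1] - geo["x"][0, 0])
    t_lo, t_hi = geo["neck_t_band"]
    ts = np.linspace(t_lo, t_hi, n_samples)
    widths = np.empty(n_samples)
    for i, tv in enumerate(ts):
        slab = femur & (np.abs(t - tv) <= h / 2)
        sv = s[slab]
        widths[i] = (sv.max() - sv.min() + h) if sv.size else np.nan
    return ts, widths


def measure_hsa(
    femur: np.ndarray,
    labels: np.ndarray,
    bmd: np.ndarray,
    params: FemurShapeParams,
    geo: dict,
    cortical_fractions: dict[str, float] | None = None,
) -> dict[str, float]:
    """Derive the 20-variable HSA row from the phantom ground truth."""
    h = params.image_spacing_mm
    d_neck = geo["d_neck"]
    perp = np.array([-d_neck[1], d_neck[0]])
    t_lo, t_hi = geo["neck_t_band"]
    cf = {"NN": 0.6, "IT": 0.6, "FS": 0.75}
    if cortical_fractions:
        cf.update(cortical_fractions)

    ts, widths = neck_width_profile(femur, geo)
    ok = np.isfinite(widths)
    i_min = int(np.nanargmin(widths))
    nn_center = geo["junction"] + ts[i_min] * d_neck
    nn = _hsa_profile_metrics(
        bmd, femur, nn_center, perp, h, params.neck_width_mm, cf["NN"]
    )
    nn["W"] = float(widths[ok].min())

    jy = geo["junction"][1]
    ws = params.shaft_width_mm
    it_center = np.array([geo["x_shaft"] - 0.2 * ws, jy - 0.1 * ws])
    it = _hsa_profile_metrics(
        bmd, femur, it_center, np.array([1.0, 0.0]), h, 2.2 * ws, cf["IT"]
    )
    fs_center = np.array([geo["x_shaft"], max(jy - 1.2 * ws, geo["margin"] + 4.0)])
    fs = _hsa_profile_metrics(
        bmd, femur, fs_center, np.array([1.0, 0.0]), h, 1.2 * ws, cf["FS"]
    )

    # hip axis length measured on the mask: extent along the neck axis line
    t_axis = geo["t"][femur & (np.abs(geo["s"]) <= h)]
    hal = float(t_axis.max() - t_axis.min() + h) if t_axis.size else float("nan")

    row = {"NSA": params.neck_shaft_angle_deg, "HAL": hal}
    for site, metrics in (("NN", nn), ("IT", it), ("FS", fs)):
        for key, val in metrics.items():
            row[f"{site}_{key}"] = val
    return row


def generate_femur_image(
    params: FemurShapeParams = FemurShapeParams(),
    bmd_profile: str = "cortical",
    noise_sd: float = 0.0,
    seed: int = 0,
    mean_abmd: float = 0.85,
    intercept_fraction: float = 0.20,
    region_density_factors: dict[int, float] | None = None,
    cortical_fractions: dict[str, float] | None = None,
) -> tuple[GrayImage, dict[str, np.ndarray], PhantomTruth]:
    """Generate one phantom image, its masks and the ground truth.

    The noiseless integer gray field is synthesised first; the true BMD map
    is *defined* as an exact affine function of it, with the line chosen so
    that the femur-wide mean aBMD equals ``mean_abmd`` and the minimum BMD is
    ``intercept_fraction`` of the mean (so calibrating the whole femur as a
    single ROI with the same fraction recovers the synthesis line exactly).
    Gaussian gray noise (sd in gray units, truncated at 0) is then added on
    top for the emitted image.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    geo = _geometry(params)
    femur, labels = _rasterize(params, geo)
    phi = _bmd_shape_field(
        femur, labels, params.image_spacing_mm, bmd_profile, region_density_factors
    )

    g_lo, g_hi = 2000.0, 50000.0
    gray_clean = np.zeros(femur.shape, dtype=np.float64)
    gray_clean[femur] = np.round(g_lo + phi[femur] * (g_hi - g_lo))

    g_bar = float(gray_clean[femur].mean())
    intercept = intercept_fraction * mean_abmd
    slope = mean_abmd * (1.0 - intercept_fraction) / g_bar
    bmd = np.full(femur.shape, np.nan)
    bmd[femur] = intercept + slope * gray_clean[femur]

    gray_out = gray_clean.copy()
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=int(femur.sum()))
        gray_out[femur] = np.round(np.clip(gray_clean[femur] + noise, 0, 65535))

    roi_means = {
        "neck": float(np.nanmean(bmd[labels == LABEL_NECK])),
        "trochanter": float(np.nanmean(bmd[labels == LABEL_TROCH])),
        "intertrochanter": float(np.nanmean(bmd[labels == LABEL_INTER])),
    }
    hsa_row = measure_hsa(femur, labels, bmd, params, geo, cortical_fractions)

    image = GrayImage(pixels=gray_out, spacing_mm=params.image_spacing_mm)
    masks = {
        "femur": femur,
        "labels": labels,
        "neck": labels == LABEL_NECK,
        "trochanter": labels == LABEL_TROCH,
        "intertrochanter": labels == LABEL_INTER,
        "head": labels == LABEL_HEAD,
    }
    truth = PhantomTruth(
        true_bmd_map=bmd,
        roi_mean_bmd=roi_means,
        hsa_row=hsa_row,
        gray_to_bmd_line=(intercept, slope, intercept_fraction),
        params=params,
        geometry={k: geo[k] for k in ("junction", "d_neck", "neck_len", "head_center")},
    )
    return image, masks, truth


def estimate_axes(
    femur: np.ndarray, labels: np.ndarray, spacing_mm: float
) -> dict[str, np.ndarray]:
    """Fit the shaft and neck axes from the masks alone.

    Shaft: per-row centroids of the distal half of the silhouette below the
    intertrochanteric band, direction pointing proximally.  Neck: the line
    from the neck-ROI centroid to the head centroid (both lie on the true
    axis of a symmetric corridor).  Used both by the load-direction logic and
    as the geometric oracle for the neck-shaft angle.
    """
    n_rows = femur.shape[0]
    ys = (n_rows - np.arange(n_rows) - 0.5) * spacing_mm

    inter_rows = np.nonzero((labels == LABEL_INTER).any(axis=1))[0]
    row_start = inter_rows.max() + 1 if inter_rows.size else n_rows // 2
    pts = []
    for r in range(row_start, n_rows):
        cols = np.nonzero(femur[r])[0]
        if cols.size:
            pts.append(((cols.mean() + 0.5) * spacing_mm, ys[r]))
    pts = np.asarray(pts)
    if len(pts) < 5:
        raise ValueError("too little distal shaft to fit an axis")
    # fit x(y): the shaft is near-vertical
    slope = np.polyfit(pts[:, 1], pts[:, 0], 1)[0]
    shaft_up = np.array([slope, 1.0])
    shaft_up /= np.linalg.norm(shaft_up)

    def _centroid(mask: np.ndarray) -> np.ndarray:
        r, c = np.nonzero(mask)
        return np.array([(c.mean() + 0.5) * spacing_mm, (n_rows - r - 0.5).mean() * spacing_mm])

    head_c = _centroid(labels == LABEL_HEAD)
    neck_c = _centroid(labels == LABEL_NECK)
    d_neck = head_c - neck_c
    d_neck /= np.linalg.norm(d_neck)
    nsa = math.degrees(math.acos(float(np.clip(np.dot(d_neck, -shaft_up), -1, 1))))
    return {
        "shaft_up": shaft_up,
        "neck_dir": d_neck,
        "head_centroid": head_c,
        "neck_centroid": neck_c,
        "nsa_deg": nsa,
    }


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: Hologic-style young-adult femoral-neck reference used for the synthetic
#: T-score: T = (neck aBMD - ref_mean) / ref_sd
TSCORE_REF_MEAN = 0.858
TSCORE_REF_SD = 0.120

DEFAULT_EFFECT_SPEC = {"NSA": 0.6, "NN_BR": 0.6}


@dataclass
class CohortBundle:
    patients: list[PhantomPatient]
    hsa: pd.DataFrame                   # one row per patient, HSA_COLUMNS
    metadata: pd.DataFrame              # height_m, weight_kg, t_score, ...
    truth: dict


def _sample_params(rng: np.random.Generator) -> FemurShapeParams:
    return FemurShapeParams(
        neck_shaft_angle_deg=float(np.clip(rng.normal(125.0, 5.0), 110.0, 145.0)),
        neck_width_mm=float(np.clip(rng.normal(32.0, 2.5), 25.0, 40.0)),
        hip_axis_length_mm=float(np.clip(rng.normal(100.0, 6.0), 85.0, 118.0)),
        head_radius_mm=float(np.clip(rng.normal(24.0, 1.5), 20.0, 28.0)),
        shaft_width_mm=float(np.clip(rng.normal(30.0, 2.0), 24.0, 36.0)),
        image_spacing_mm=0.5,
    )


def generate_cohort(
    n: int = 28,
    effect_spec: dict[str, float] | None = None,
    seed: int = 0,
    noise_sd: float = 150.0,
    r2_target: float = 0.6,
    bmd_profile: str = "cortical",
) -> CohortBundle:
    """Generate a cohort of phantom patients with a known risk structure.

    ``effect_spec`` maps HSA variable names to linear effect sizes on a
    synthetic reference risk score (standardized predictors); Gaussian noise
    is added so that the signal explains about ``r2_target`` of its variance.
    The spec is recorded in the truth block for parameter-recovery tests.
    The default emulates a post-menopausal female screening cohort: heights
    around 1.61 m, weights around 65 kg, femoral-neck aBMD mostly in the
    osteopenic range.
    """
    if n < 3:
        raise ValueError("cohort statistics are undefined for n < 3")
    effect_spec = DEFAULT_EFFECT_SPEC if effect_spec is None else dict(effect_spec)
    rng = np.random.default_rng(seed)

    patients: list[PhantomPatient] = []
    for i in range(n):
        params = _sample_params(rng)
        mean_abmd = float(np.clip(rng.normal(0.80, 0.10), 0.50, 1.05))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        # independent site-specific cortical variation (see _bmd_shape_field)
        factors = {
            lab: float(np.exp(rng.normal(0.0, 0.15)))
            for lab in (LABEL_NECK, LABEL_TROCH, LABEL_INTER, LABEL_HEAD, LABEL_SHAFT)
        }
        image, masks, truth = generate_femur_image(
            params,
            bmd_profile=bmd_profile,
            noise_sd=noise_sd,
            seed=sub_seed,
            mean_abmd=mean_abmd,
            region_density_factors=factors,
        )
        height = float(np.clip(rng.normal(1.61, 0.06), 1.45, 1.80))
        weight = float(np.clip(rng.normal(65.0, 10.0), 42.0, 95.0))
        t_score = (truth.roi_mean_bmd["neck"] - TSCORE_REF_MEAN) / TSCORE_REF_SD
        meta = {
            "height_m": height,
            "weight_kg": weight,
            "t_score": float(t_score),
            "spacing_mm": params.image_spacing_mm,
        }
        patients.append(
            PhantomPatient(
                patient_id=f"patient_{i:03d}",
                image=image,
                femur_mask=masks["femur"],
                labels=masks["labels"],
                roi_means=truth.roi_mean_bmd,
                metadata=meta,
                hsa=truth.hsa_row,
                truth=truth,
            )
        )

    hsa = pd.DataFrame([p.hsa for p in patients], index=[p.patient_id for p in patients])
    hsa = hsa[HSA_COLUMNS]
    # scanner-style measurement imprecision, multiplicative with the
    # variable-specific short-term precision reported for HSA outputs
    # (widths are sharp, ~1-2% CV; moments ~5%; the edge-detection-driven
    # cortical thickness and buckling ratio are the noisiest, ~8-10% CV);
    # the angle gets ~1 degree.  Without it the within-site quantities are
    # deterministic functions of each other, which no real scanner produces.
    cv = {"W": 0.015, "CSA": 0.02, "CSMI": 0.025, "Z": 0.015, "ACT": 0.015, "BR": 0.12}
    for col in HSA_COLUMNS:
        if col == "NSA":
            hsa[col] = hsa[col] + rng.normal(0.0, 1.5, size=n)
        elif col == "HAL":
            hsa[col] = hsa[col] * np.exp(rng.normal(0.0, 0.01, size=n))
        else:
            sd = cv[col.split("_")[1]]
            hsa[col] = hsa[col] * np.exp(rng.normal(0.0, sd, size=n))
    metadata = pd.DataFrame(
        [p.metadata for p in patients], index=[p.patient_id for p in patients]
    )

    unknown = set(effect_spec) - set(HSA_COLUMNS)
    if unknown:
        raise ValueError(f"effect_spec names unknown HSA variables: {sorted(unknown)}")
    z = (hsa - hsa.mean()) / hsa.std(ddof=1)
    signal = sum(coef * z[var] for var, coef in effect_spec.items())
    signal = np.asarray(signal, dtype=float)
    sd_signal = float(signal.std(ddof=1))
    sd_noise = sd_signal * math.sqrt((1.0 - r2_target) / r2_target)
    response = signal + rng.normal(0.0, sd_noise, size=n)
    # map onto a plausible RF^ scale (dimensionless, most patients < 1)
    rf_hat_true = 0.6 + 0.18 * (response - response.mean()) / max(response.std(ddof=1), 1e-12)

    truth_block = {
        "effect_spec": effect_spec,
        "drivers": sorted(effect_spec),
        "r2_target": r2_target,
        "noise_sd_gray": noise_sd,
        "seed": seed,
        "rf_hat_true": {p.patient_id: float(v) for p, v in zip(patients, rf_hat_true)},
    }
    return CohortBundle(patients=patients, hsa=hsa, metadata=metadata, truth=truth_block)
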
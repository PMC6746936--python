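"""Density chain: areal BMD -> volumetric -> apparent density -> Young's modulus.

The proximal femur is modelled as a plate of constant patient-specific
thickness t derived from the femoral neck width.  Areal BMD (g/cm^2) divided
by t gives a volumetric mineral density (g/cm^3); dividing by the ash
fraction gives the apparent wet-tissue density entering the empirical
density-modulus power law.  Moduli are finally grouped into a fixed number of
equal-width bins and each element receives the median raw modulus of its bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import MaterialConfig


@dataclass(frozen=True)
class MorganLaw:
    """Two-branch power law E(MPa) = c * rho_app(g/cm^3) ** p."""

    c_low: float = 15010.0
    p_low: float = 2.18
    c_high: float = 6850.0
    p_high: float = 1.49
    rho_switch: float = 0.28

    @classmethod
    def from_config(cls, cfg: MaterialConfig) -> "MorganLaw":
        return cls(
            c_low=cfg.morgan_c_low,
            p_low=cfg.morgan_p_low,
            c_high=cfg.morgan_c_high,
            p_high=cfg.morgan_p_high,
            rho_switch=cfg.morgan_rho_switch,
        )


@dataclass
class MaterialField:
    """Per-element material state of the plate model."""

    e_mpa: np.ndarray          # binned Young's modulus per element
    e_raw_mpa: np.ndarray      # pre-binning modulus per element
    rho_app: np.ndarray        # apparent density per element, g/cm^3
    bin_id: np.ndarray         # 1-based bin index per element
    nu: float                  # Poisson ratio, uniform

    @property
    def n_distinct(self) -> int:
        return len(np.unique(self.e_mpa))


def plate_thickness(neck_width_w: float, method: str = "mean") -> float:
    """Constant plate thickness t (mm) equivalent to a circular neck section.

    A rectangle t x w matching a circle of diameter w gives t = pi*w/4 by
    area and t = 3*pi*w/16 by bending inertia about the out-of-plane axis
    (t*w^3/12 = pi*w^4/64); both cannot hold at once, so "mean" averages them.
    """
    if neck_width_w <= 0:
        raise ValueError("neck width must be > 0")
    t_area = math.pi * neck_width_w / 4.0
    t_inertia = 3.0 * math.pi * neck_width_w / 16.0
    if method == "area":
        return t_area
    if method == "inertia":
        return t_inertia
    if method == "mean":
        return 0.5 * (t_area + t_inertia)
    raise ValueError(f"unknown thickness method {method!r}")


def abmd_to_volumetric(abmd: np.ndarray | float, thickness_t: float) -> np.ndarray | float:
    """rho_vol (g/cm^3) = aBMD (g/cm^2) / t (cm); t is given in mm."""
    if thickness_t <= 0:
        raise ValueError("thickness must be > 0")
    return np.asarray(abmd, dtype=float) / (thickness_t / 10.0)


def volumetric_to_apparent(
    rho_vol: np.ndarray | float, ash_fraction: float = 0.6
) -> np.ndarray | float:
    """rho_app = rho_vol / ash_fraction (mineral is ~60% of dry bone mass)."""
    if not (0.0 < ash_fraction <= 1.0):
        raise ValueError("ash_fraction must lie in (0, 1]")
    return np.asarray(rho_vol, dtype=float) / ash_fraction


def morgan_modulus(
    rho_app: np.ndarray | float, law: MorganLaw = MorganLaw()
) -> np.ndarray | float:
    """Evaluate the two-branch density-modulus law; low branch at the switch."""
    rho = np.asarray(rho_app, dtype=float)
    if np.any(rho < 0):
        raise ValueError("apparent density must be >= 0")
    low = rho <= law.rho_switch
    e = np.where(
        low,
        law.c_low * np.power(rho, law.p_low, where=rho > 0, out=np.zeros_like(rho)),
        law.c_high * np.power(rho, law.p_high, where=rho > 0, out=np.zeros_like(rho)),
    )
    if np.isscalar(rho_app) or np.ndim(rho_app) == 0:
        return float(e)
    return e


def bin_moduli(
    e_raw: np.ndarray,
    rho_app: np.ndarray | None = None,
    n_bins: int = 35,
    nu: float = 0.3,
) -> MaterialField:
    """Group element moduli into equal-width bins and assign bin medians.

    Bins span [min E, max E]; a value exactly on an interior edge goes to the
    lower bin.  Each element's output modulus is the median raw modulus of
    the members of its bin, so at most ``n_bins`` distinct values survive.
    """
    e_raw = np.asarray(e_raw, dtype=float)
    if e_raw.size == 0:
        raise ValueError("no elements to bin")
    e_min, e_max = float(e_raw.min()), float(e_raw.max())
    if e_max == e_min:
        bin_id = np.ones(e_raw.shape, dtype=int)
        e_binned = e_raw.copy()
    else:
        edges = np.linspace(e_min, e_max, n_bins + 1)
        # (a, b] intervals via right=True: edge ties fall into the lower bin
        bin_id = np.digitize(e_raw, edges[1:-1], right=True) + 1
        e_binned = np.empty_like(e_raw)
        for b in np.unique(bin_id):
            members = bin_id == b
            e_binned[members] = np.median(e_raw[members])
    rho = np.zeros_like(e_raw) if rho_app is None else np.asarray(rho_app, float)
    return MaterialField(
        e_mpa=e_binned, e_raw_mpa=e_raw, rho_app=rho, bin_id=bin_id, nu=nu
    )


def build_material_field(
    abmd_per_element: np.ndarray,
    thickness_t: float,
    cfg: MaterialConfig = MaterialConfig(),
) -> MaterialField:
    """Full chain from per-element areal BMD to the binned modulus field."""
    rho_vol = abmd_to_volumetric(abmd_per_element, thickness_t)
    rho_app = volumetric_to_apparent(rho_vol, cfg.ash_fraction)
    e_raw = morgan_modulus(rho_app, MorganLaw.from_config(cfg))
    # strictly positive floor: a zero-density element would make the
    # stiffness matrix singular; use a negligible but positive modulus
    e_raw = np.maximum(np.asarray(e_raw, dtype=float), 1e-6)
    return bin_moduli(e_raw, rho_app=rho_app, n_bins=cfg.n_bins, nu=cfg.poisson)
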
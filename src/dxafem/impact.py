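"""Patient-specific sideways-fall impact force.

A 1-degree-of-freedom spring-mass(-damper) model of the fall: an effective
mass (a fraction of body mass) hits the trochanteric soft tissue, modelled
as a linear contact spring, with the impact speed of a fall from a fraction
of body height.  The peak spring force is the force applied to the femur.

For the undamped case the peak force has the classic closed form
``F = v * sqrt(k * m_eff)``; for an underdamped oscillator the peak of
``x(t) = (v / w_d) exp(-zeta w_n t) sin(w_d t)`` is also closed-form, and a
time-integration route is provided as an independent numerical check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .config import ImpactConfig


@dataclass(frozen=True)
class ImpactParameters:
    body_height_m: float
    body_mass_kg: float
    effective_mass_fraction: float = 0.5
    fall_height_fraction: float = 0.51
    contact_stiffness_k: float = 5.0e4    # N/m
    damping_ratio_zeta: float = 0.0
    gravity_g: float = 9.81

    def __post_init__(self) -> None:
        if self.body_height_m <= 0 or self.body_mass_kg <= 0:
            raise ValueError("height and mass must be > 0")
        if self.contact_stiffness_k <= 0:
            raise ValueError("contact stiffness must be > 0")
        if not (0.0 <= self.damping_ratio_zeta < 1.0):
            raise ValueError("damping ratio must satisfy 0 <= zeta < 1 "
                             "(overdamped impact is out of scope)")
        for frac in (self.effective_mass_fraction, self.fall_height_fraction):
            if not (0.0 < frac <= 1.0):
                raise ValueError("fractions must lie in (0, 1]")

    @classmethod
    def from_config(
        cls, height_m: float, mass_kg: float, cfg: ImpactConfig
    ) -> "ImpactParameters":
        return cls(
            body_height_m=height_m,
            body_mass_kg=mass_kg,
            effective_mass_fraction=cfg.effective_mass_fraction,
            fall_height_fraction=cfg.fall_height_fraction,
            contact_stiffness_k=cfg.contact_stiffness_k,
            damping_ratio_zeta=cfg.damping_ratio_zeta,
            gravity_g=cfg.gravity_g,
        )

    @property
    def impact_velocity(self) -> float:
        """v = sqrt(2 g h_fall) with h_fall = fall_height_fraction * H, m/s."""
        return float(
            np.sqrt(2.0 * self.gravity_g * self.fall_height_fraction * self.body_height_m)
        )

    @property
    def effective_mass(self) -> float:
        return self.effective_mass_fraction * self.body_mass_kg


def impact_force(params: ImpactParameters) -> float:
    """Peak contact-spring force in N (closed form).

    zeta = 0:  F = v sqrt(k m).  0 < zeta < 1:  the first displacement peak
    of the underdamped free oscillator started at velocity v gives
    ``F = v sqrt(k m) * exp(-zeta * phi / sqrt(1 - zeta^2))`` with
    ``phi = atan2(sqrt(1 - zeta^2), zeta)``.
    """
    v = params.impact_velocity
    m = params.effective_mass
    k = params.contact_stiffness_k
    zeta = params.damping_ratio_zeta
    f0 = v * np.sqrt(k * m)
    if zeta == 0.0:
        return float(f0)
    root = np.sqrt(1.0 - zeta**2)
    phi = np.arctan2(root, zeta)
    return float(f0 * np.exp(-zeta * phi / root))


def impact_force_numeric(params: ImpactParameters, rtol: float = 1e-10) -> float:
    """Peak spring force by time integration of the same oscillator.

    Independent numerical route (used to validate the closed form): integrate
    m x'' + c x' + k x = 0, x(0) = 0, x'(0) = v over the first half period
    and take k * max(x).
    """
    m = params.effective_mass
    k = params.contact_stiffness_k
    zeta = params.damping_ratio_zeta
    v = params.impact_velocity
    wn = np.sqrt(k / m)
    c = 2.0 * zeta * np.sqrt(k * m)

    def rhs(_t, y):
        return [y[1], -(c * y[1] + k * y[0]) / m]

    t_end = np.pi / wn  # half an undamped period covers the first peak
    sol = solve_ivp(
        rhs, (0.0, t_end), [0.0, v], rtol=rtol, atol=1e-14, dense_output=True
    )
    ts = np.linspace(0.0, t_end, 20001)
    x = sol.sol(ts)[0]
    return float(k * x.max())
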
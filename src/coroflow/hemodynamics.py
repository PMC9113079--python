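"""Reduced-order steady haemodynamics of a stenosed vessel.

The trans-segment pressure drop is split into a linear viscous part obtained
by Poiseuille quadrature of the area profile and, per lesion, a nonlinear
post-stenotic expansion (Borda-Carnot) loss through an effective vena
contracta.  The segment couples to a lumped microvascular resistance outlet;
the unique operating flow follows from a bracketed scalar root-find, and the
virtual FFR is the outlet-to-inlet pressure ratio Pd/Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .geometry import (
    AreaProfile,
    LesionSpec,
    LongitudinalProfile,
    Taper,
)

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "LossModelParams",
    "FlowSolution",
    "SolverError",
    "viscous_resistance",
    "expansion_loss",
    "expansion_loss_coefficient",
    "total_pressure_drop",
    "solve_flow",
    "vffr_sensitivity_mvr",
]

MM = 1e-3  # mm -> m

#: residual tolerance of the outlet pressure balance, relative to Pa
RESIDUAL_RTOL = 1e-8


class SolverError(RuntimeError):
    """Raised when the flow solve fails to converge; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as an incompressible Newtonian fluid."""

    viscosity_Pa_s: float = 0.0035
    density_kg_m3: float = 1056.0

    def __post_init__(self) -> None:
        if self.viscosity_Pa_s <= 0 or self.density_kg_m3 <= 0:
            raise ValueError("viscosity and density must be positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet pressure, venous pressure and microvascular outlet resistance."""

    inlet_pressure_Pa: float = 13332.2  # 100 mmHg
    venous_pressure_Pa: float = 0.0
    outlet_mvr_Pa_s_m3: float = 8.721e9

    def __post_init__(self) -> None:
        if self.venous_pressure_Pa < 0:
            raise ValueError("venous_pressure_Pa must be >= 0")
        if self.inlet_pressure_Pa <= self.venous_pressure_Pa:
            raise ValueError("inlet pressure must exceed venous pressure")
        if self.outlet_mvr_Pa_s_m3 <= 0:
            raise ValueError("outlet_mvr_Pa_s_m3 must be > 0")


@dataclass(frozen=True)
class LossModelParams:
    """Coefficients of the lesion loss model.

    ``kt`` weights the Borda-Carnot expansion loss.  The contraction
    coefficients shrink the anatomical minimal area to the effective vena
    contracta area, by lesion outline: sharp-edged (rectangular) lesions
    contract hardest, long uniform throats exit with a developed velocity
    profile and contract moderately, short rounded focal throats hardly at
    all.  Values are frozen for the whole study sweep.
    """

    kt: float = 1.0
    cc_rounded: float = 1.0
    cc_uniform: float = 0.70
    cc_rectangular: float = 0.68

    def __post_init__(self) -> None:
        if self.kt < 0:
            raise ValueError("kt must be >= 0")
        for name in ("cc_rounded", "cc_uniform", "cc_rectangular"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.cc_rectangular > self.cc_uniform or self.cc_uniform > self.cc_rounded:
            raise ValueError("require cc_rectangular <= cc_uniform <= cc_rounded")

    def contraction_coefficient(self, lesion: LesionSpec) -> float:
        if lesion.profile is LongitudinalProfile.RECTANGULAR:
            return self.cc_rectangular
        if lesion.taper is Taper.UNIFORM:
            return self.cc_uniform
        return self.cc_rounded


@dataclass(frozen=True)
class FlowSolution:
    """Converged steady state of one vessel segment."""

    flow_m3_s: float
    pressure_curve_x_mm: np.ndarray
    pressure_curve_Pa: np.ndarray
    outlet_pressure_Pa: float
    vffr: float
    q_normal_m3_s: float
    converged: bool
    residual: float
    viscous_resistance_Pa_s_m3: float
    lesion_resistances_Pa_s_m3: tuple[float, ...] = field(default_factory=tuple)

    @property
    def stenosis_resistance_Pa_s_m3(self) -> float:
        """Secant resistance dP_total/Q of the whole segment at the operating point."""
        return self.viscous_resistance_Pa_s_m3 + sum(self.lesion_resistances_Pa_s_m3)


def viscous_resistance(profile: AreaProfile, fluid: FluidProperties) -> float:
    """Poiseuille resistance R_v = (128 mu / pi) * int dx / d_eff(x)^4 [Pa.s/m^3]."""
    d_eff_m = profile.d_eff_mm * MM
    integrand = 1.0 / d_eff_m**4
    if not np.all(np.isfinite(integrand)):
        raise ValueError("non-finite viscous integrand; invalid area profile")
    integral = np.trapezoid(integrand, profile.x_mm * MM)
    return float(128.0 * fluid.viscosity_Pa_s / np.pi * integral)


def _lesion_min_area_m2(profile: AreaProfile, lesion: LesionSpec) -> float:
    mask = (profile.x_mm >= lesion.start_mm) & (profile.x_mm <= lesion.end_mm)
    if not np.any(mask):
        raise ValueError(
            f"lesion extent [{lesion.start_mm}, {lesion.end_mm}] mm not covered "
            "by the profile grid"
        )
    a_min = float(np.min(profile.area_mm2[mask]))
    if a_min <= 0.0:
        raise ValueError("minimal lesion area must be positive")
    return a_min * MM**2


def expansion_loss_coefficient(
    profile: AreaProfile,
    lesion: LesionSpec,
    params: LossModelParams,
    fluid: FluidProperties,
) -> float:
    """Quadratic loss coefficient ``a`` such that dP_t = a * Q * |Q|.

    ``a = kt * rho / 2 * (1 / (cc_eff * A_min) - 1 / A_ref)^2`` with the
    effective contraction coefficient relaxed towards 1 as the narrowing
    vanishes (Weisbach-type interpolation), so a zero-severity lesion incurs
    no loss.
    """
    a_min = _lesion_min_area_m2(profile, lesion)
    a_ref = profile.reference_area_mm2 * MM**2
    cc = params.contraction_coefficient(lesion)
    cc_eff = cc + (1.0 - cc) * (a_min / a_ref) ** 3
    jet = 1.0 / (cc_eff * a_min) - 1.0 / a_ref
    if jet <= 0.0:
        return 0.0
    return params.kt * fluid.density_kg_m3 / 2.0 * jet * jet


def expansion_loss(
    profile: AreaProfile,
    lesion: LesionSpec,
    params: LossModelParams,
    fluid: FluidProperties,
    flow_m3_s: float,
) -> float:
    """Post-stenotic expansion pressure drop [Pa] at flow ``Q``; sign follows Q."""
    if not np.isfinite(flow_m3_s):
        raise ValueError("flow must be finite")
    a = expansion_loss_coefficient(profile, lesion, params, fluid)
    return a * flow_m3_s * abs(flow_m3_s)


def total_pressure_drop(
    profile: AreaProfile,
    lesions: Sequence[LesionSpec],
    params: LossModelParams,
    fluid: FluidProperties,
    flow_m3_s: float,
) -> float:
    """Total trans-segment pressure drop R_v*Q + sum of lesion expansion losses [Pa]."""
    r_v = viscous_resistance(profile, fluid)
    dp = r_v * flow_m3_s
    for lesion in lesions:
        dp += expansion_loss(profile, lesion, params, fluid, flow_m3_s)
    return dp


def _pressure_curve(
    profile: AreaProfile,
    lesions: Sequence[LesionSpec],
    coeffs: Sequence[float],
    fluid: FluidProperties,
    inlet_pressure: float,
    q: float,
) -> np.ndarray:
    """Axial pressure: cumulative viscous drop plus expansion drops ramped over
    the downstream half of each lesion (min-area location to lesion end)."""
    x_m = profile.x_mm * MM
    d_eff_m = profile.d_eff_mm * MM
    dens = 128.0 * fluid.viscosity_Pa_s / np.pi / d_eff_m**4
    visc = np.concatenate(
        [[0.0], np.cumsum(np.diff(x_m) * 0.5 * (dens[1:] + dens[:-1]))]
    )
    p = inlet_pressure - q * visc
    for lesion, a in zip(lesions, coeffs):
        drop = a * q * abs(q)
        mask = (profile.x_mm >= lesion.start_mm) & (profile.x_mm <= lesion.end_mm)
        x_min = profile.x_mm[mask][int(np.argmin(profile.area_mm2[mask]))]
        ramp = np.clip(
            (profile.x_mm - x_min) / max(lesion.end_mm - x_min, 1e-9), 0.0, 1.0
        )
        p -= drop * ramp
    return p


def solve_flow(
    profile: AreaProfile,
    lesions: Sequence[LesionSpec],
    params: LossModelParams,
    fluid: FluidProperties,
    bc: BoundaryConditions,
) -> FlowSolution:
    """Find the unique flow satisfying Pa - dP_total(Q) = Pv + R_mv * Q.

    The left side strictly decreases and the right side strictly increases in
    Q, so the root is bracketed by ``[0, (Pa - Pv) / R_mv]``.
    """
    pa = bc.inlet_pressure_Pa
    pv = bc.venous_pressure_Pa
    r_mv = bc.outlet_mvr_Pa_s_m3
    r_v = viscous_resistance(profile, fluid)
    coeffs = [
        expansion_loss_coefficient(profile, lesion, params, fluid)
        for lesion in lesions
    ]
    a_sum = sum(coeffs)

    def balance(q: float) -> float:
        return pa - pv - (r_v + r_mv) * q - a_sum * q * abs(q)

    q_hi = (pa - pv) / r_mv
    try:
        # xtol far below any physiological flow (~1e-6 m^3/s) so the
        # pressure-balance residual reaches machine precision
        q = brentq(balance, 0.0, q_hi, xtol=1e-24, rtol=1e-15, maxiter=300)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - diagnostics
        raise SolverError(f"flow root-find failed: {exc}") from exc

    residual = abs(balance(q)) / pa
    converged = residual < RESIDUAL_RTOL
    if not converged:
        raise SolverError(
            f"flow solve residual {residual:.3e} exceeds {RESIDUAL_RTOL:.0e}",
            residual=residual,
        )

    pd = pv + r_mv * q
    # lesion-free reference flow through the same tube (Poiseuille resistance
    # of the healthy lumen), for the Q_stenosis / Q_normal identity
    length_m = profile.length_mm * MM
    d_ref_m = np.sqrt(4.0 * profile.reference_area_mm2 * MM**2 / np.pi)
    r_v_ref = 128.0 * fluid.viscosity_Pa_s * length_m / (np.pi * d_ref_m**4)
    q_normal = (pa - pv) / (r_mv + r_v_ref)

    return FlowSolution(
        flow_m3_s=q,
        pressure_curve_x_mm=profile.x_mm.copy(),
        pressure_curve_Pa=_pressure_curve(profile, lesions, coeffs, fluid, pa, q),
        outlet_pressure_Pa=pd,
        vffr=pd / pa,
        q_normal_m3_s=q_normal,
        converged=converged,
        residual=residual,
        viscous_resistance_Pa_s_m3=r_v,
        lesion_resistances_Pa_s_m3=tuple(
            (a * q * abs(q)) / q if q > 0 else 0.0 for a in coeffs
        ),
    )


def vffr_sensitivity_mvr(
    profile: AreaProfile,
    lesions: Sequence[LesionSpec],
    params: LossModelParams,
    fluid: FluidProperties,
    bc: BoundaryConditions,
    delta_mvr_Pa_s_m3: float = 2e9,
) -> tuple[float, float, float]:
    """vFFR at (R_mv - delta, R_mv, R_mv + delta); returned low <= std <= high."""
    r = bc.outlet_mvr_Pa_s_m3
    if r - delta_mvr_Pa_s_m3 <= 0:
        raise ValueError("delta_mvr would make the low MVR non-positive")
    out = []
    for r_i in (r - delta_mvr_Pa_s_m3, r, r + delta_mvr_Pa_s_m3):
        bc_i = BoundaryConditions(
            inlet_pressure_Pa=bc.inlet_pressure_Pa,
            venous_pressure_Pa=bc.venous_pressure_Pa,
            outlet_mvr_Pa_s_m3=r_i,
        )
        out.append(solve_flow(profile, lesions, params, fluid, bc_i).vffr)
    return tuple(out)  # type: ignore[return-value]
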
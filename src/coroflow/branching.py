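"""One-junction coronary bifurcation: diameter laws, outlet resistance
distribution and the coupled two-outlet flow solve.

Static pressure and mass are continuous at the junction; the branch angle is
recorded but carries no physics.  The reference microvascular resistance is
apportioned between the two outlets by a power law of outlet diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .geometry import AreaProfile, SegmentSpec, build_area_profile
from .hemodynamics import (
    RESIDUAL_RTOL,
    BoundaryConditions,
    FluidProperties,
    LossModelParams,
    SolverError,
    expansion_loss_coefficient,
    viscous_resistance,
)

__all__ = [
    "BifurcationLaw",
    "BifurcationSpec",
    "BranchSolution",
    "daughter_diameter",
    "distribute_mvr",
    "solve_branch_flow",
    "DEFAULT_MVR_EXPONENT",
]

#: default exponent of the diameter power law used to apportion MVR between
#: outlets; intermediate between the Huo-Kassab (7/3) and Murray (3) flow
#: scalings, shared across laws so that matched geometries remain comparable
DEFAULT_MVR_EXPONENT = 2.5


class BifurcationLaw(str, Enum):
    MURRAY = "murray"  # d_parent^3 = d1^3 + d2^3
    FINET = "finet"  # d_parent = 0.678 * (d1 + d2)
    HUO_KASSAB = "huo_kassab"  # d_parent^(7/3) = d1^(7/3) + d2^(7/3)


def daughter_diameter(
    law: BifurcationLaw | str, d_parent_mm: float, d_other_daughter_mm: float
) -> float:
    """Diameter [mm] of the second daughter implied by ``law``.

    Raises ``ValueError`` when the other daughter is too large for the law to
    yield a positive diameter.
    """
    law = BifurcationLaw(law)
    dp, dd = float(d_parent_mm), float(d_other_daughter_mm)
    if dp <= 0 or dd <= 0:
        raise ValueError("diameters must be positive")
    if law is BifurcationLaw.FINET:
        d_sb = dp / 0.678 - dd
    else:
        exp = 3.0 if law is BifurcationLaw.MURRAY else 7.0 / 3.0
        rhs = dp**exp - dd**exp
        if rhs <= 0.0:
            raise ValueError(
                f"{law.value}: daughter {dd} mm >= parent {dp} mm under the law"
            )
        d_sb = rhs ** (1.0 / exp)
    if d_sb <= 0.0:
        raise ValueError(
            f"{law.value}: no positive side-branch diameter for parent {dp} mm "
            f"and daughter {dd} mm"
        )
    return d_sb


def distribute_mvr(
    reference_mvr_Pa_s_m3: float,
    reference_diameter_mm: float,
    outlet_diameters_mm,
    exponent: float = DEFAULT_MVR_EXPONENT,
) -> np.ndarray:
    """Per-outlet microvascular resistance R_i = R_ref * (d_ref / d_i)^exponent."""
    d = np.asarray(outlet_diameters_mm, dtype=float)
    if np.any(d <= 0) or reference_diameter_mm <= 0:
        raise ValueError("diameters must be positive")
    return reference_mvr_Pa_s_m3 * (reference_diameter_mm / d) ** exponent


@dataclass(frozen=True)
class BifurcationSpec:
    """PMB/DMB/SB one-junction tree; SB diameter fixed by the selected law."""

    pmb: SegmentSpec
    dmb: SegmentSpec
    sb: SegmentSpec
    law: BifurcationLaw = BifurcationLaw.MURRAY
    angle_deg: float = 45.0  # recorded, not used in the physics

    def __post_init__(self) -> None:
        object.__setattr__(self, "law", BifurcationLaw(self.law))
        if self.dmb.diameter_mm >= self.pmb.diameter_mm:
            raise ValueError("DMB diameter must be smaller than PMB diameter")
        d_sb = daughter_diameter(self.law, self.pmb.diameter_mm, self.dmb.diameter_mm)
        if abs(d_sb - self.sb.diameter_mm) > 1e-6:
            raise ValueError(
                f"SB diameter {self.sb.diameter_mm} mm inconsistent with "
                f"{self.law.value} law (expected {d_sb:.6f} mm)"
            )

    @classmethod
    def from_law(
        cls,
        pmb: SegmentSpec,
        dmb: SegmentSpec,
        law: BifurcationLaw | str = BifurcationLaw.MURRAY,
        sb_length_mm: float | None = None,
        sb_lesions: tuple = (),
        angle_deg: float = 45.0,
    ) -> "BifurcationSpec":
        """Build the tree with the SB sized by ``law``."""
        d_sb = daughter_diameter(law, pmb.diameter_mm, dmb.diameter_mm)
        sb = SegmentSpec(
            diameter_mm=d_sb,
            length_mm=sb_length_mm if sb_length_mm is not None else dmb.length_mm,
            lesions=sb_lesions,
        )
        return cls(pmb=pmb, dmb=dmb, sb=sb, law=law, angle_deg=angle_deg)

    def to_dict(self) -> dict:
        return {
            "pmb": self.pmb.to_dict(),
            "dmb": self.dmb.to_dict(),
            "sb": self.sb.to_dict(),
            "law": self.law.value,
            "angle_deg": self.angle_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BifurcationSpec":
        return cls(
            pmb=SegmentSpec.from_dict(d["pmb"]),
            dmb=SegmentSpec.from_dict(d["dmb"]),
            sb=SegmentSpec.from_dict(d["sb"]),
            law=d.get("law", "murray"),
            angle_deg=d.get("angle_deg", 45.0),
        )


@dataclass(frozen=True)
class BranchSolution:
    """Converged state of the two-outlet network."""

    junction_pressure_Pa: float
    flow_pmb_m3_s: float
    outlet_flows_m3_s: Mapping[str, float]
    outlet_pressures_Pa: Mapping[str, float]
    outlet_mvr_Pa_s_m3: Mapping[str, float]
    vffr: Mapping[str, float]  # keyed "DMB", "SB"; each Pd / common inlet Pa
    converged: bool
    residual: float
    mass_residual: float


class _SegmentLoss:
    """Precomputed dP(Q) = R_v Q + sum a_i Q|Q| for one segment."""

    def __init__(
        self,
        segment: SegmentSpec,
        params: LossModelParams,
        fluid: FluidProperties,
        grid_step_mm: float,
    ):
        profile: AreaProfile = build_area_profile(segment, grid_step_mm)
        self.r_v = viscous_resistance(profile, fluid)
        self.a = sum(
            expansion_loss_coefficient(profile, lesion, params, fluid)
            for lesion in segment.lesions
        )

    def dp(self, q: float) -> float:
        return self.r_v * q + self.a * q * abs(q)

    def invert(self, drop: float) -> float:
        """Flow producing pressure drop ``drop`` (>= 0)."""
        if drop <= 0.0:
            return 0.0
        if self.a == 0.0:
            return drop / self.r_v
        # positive root of a q^2 + r_v q - drop = 0
        return (-self.r_v + np.sqrt(self.r_v**2 + 4.0 * self.a * drop)) / (2.0 * self.a)


def solve_branch_flow(
    spec: BifurcationSpec,
    params: LossModelParams,
    fluid: FluidProperties,
    bc: BoundaryConditions,
    mvr_exponent: float = DEFAULT_MVR_EXPONENT,
    grid_step_mm: float = 0.1,
) -> BranchSolution:
    """Solve the PMB -> (DMB, SB) network.

    The junction pressure is the single unknown: the PMB inflow decreases and
    the branch outflows increase with it, so the balance has a unique root in
    ``(Pv, Pa)``.  Mass conservation then holds by construction and pressure
    continuity is enforced to the solver tolerance.
    """
    pa = bc.inlet_pressure_Pa
    pv = bc.venous_pressure_Pa
    r_out = distribute_mvr(
        bc.outlet_mvr_Pa_s_m3,
        spec.pmb.diameter_mm,
        [spec.dmb.diameter_mm, spec.sb.diameter_mm],
        exponent=mvr_exponent,
    )
    r_mv = {"DMB": float(r_out[0]), "SB": float(r_out[1])}
    seg = {
        "PMB": _SegmentLoss(spec.pmb, params, fluid, grid_step_mm),
        "DMB": _SegmentLoss(spec.dmb, params, fluid, grid_step_mm),
        "SB": _SegmentLoss(spec.sb, params, fluid, grid_step_mm),
    }

    def q_branch(p_j: float, name: str) -> float:
        """Flow through branch ``name`` for junction pressure p_j."""
        if p_j <= pv:
            return 0.0
        s = seg[name]
        f = lambda q: p_j - pv - s.dp(q) - r_mv[name] * q
        return brentq(f, 0.0, (p_j - pv) / r_mv[name], xtol=1e-24, rtol=1e-15,
                      maxiter=300)

    def balance(p_j: float) -> float:
        q_in = seg["PMB"].invert(pa - p_j)
        return q_in - q_branch(p_j, "DMB") - q_branch(p_j, "SB")

    try:
        p_j = brentq(balance, pv, pa, rtol=1e-15, maxiter=200)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover
        raise SolverError(f"junction pressure root-find failed: {exc}") from exc

    q = {name: q_branch(p_j, name) for name in ("DMB", "SB")}
    q_pmb = q["DMB"] + q["SB"]  # mass conserved by construction
    # pressure-continuity residual of the PMB leg at the reconciled flow
    residual = abs(pa - seg["PMB"].dp(q_pmb) - p_j) / pa
    if residual > RESIDUAL_RTOL:
        raise SolverError(
            f"branch solve residual {residual:.3e} exceeds {RESIDUAL_RTOL:.0e}",
            residual=residual,
        )
    mass_residual = abs(seg["PMB"].invert(pa - p_j) - q_pmb) / max(q_pmb, 1e-300)
    p_out = {name: pv + r_mv[name] * q[name] for name in q}
    return BranchSolution(
        junction_pressure_Pa=p_j,
        flow_pmb_m3_s=q_pmb,
        outlet_flows_m3_s=q,
        outlet_pressures_Pa=p_out,
        outlet_mvr_Pa_s_m3=r_mv,
        vffr={name: p_out[name] / pa for name in p_out},
        converged=True,
        residual=residual,
        mass_residual=mass_residual,
    )
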
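"""Circulatory-equilibrium model.

Steady-state hemodynamics are described by the intersection of three
surfaces in (CO, P_LA, P_RA) space:

* a left-ventricular Frank-Starling curve   CO = S_L * (ln(P_LA - P0_L) + k_L)
* a right-ventricular Frank-Starling curve  CO = S_R * (ln(P_RA - P0_R) + k_R)
* a planar venous-return surface            CO = (V - G_L*P_LA - G_R*P_RA) / W

with mean arterial pressure closed by the systemic circulation,
AP = R * CO + P_RA.  The four subject-specific parameters are the pumping
slopes S_L and S_R, the systemic vascular resistance R and the stressed
blood volume V; the curve offsets/intercepts (P0, k) and the venous-return
coefficients (W, G_L, G_R) are population shape constants held in
:class:`ModelConstants`.

This module provides the forward map (parameters -> equilibrium state), the
inverse map (measured state -> parameters) and the target-determination step
that converts clinical targets (AP*, P_LA*) into parameter targets
(S_L*, V*) for the drug controllers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "ModelConstants",
    "HemodynamicState",
    "EquilibriumParameters",
    "ControlTargets",
    "DomainError",
    "InfeasibleEquilibriumError",
    "frank_starling_co",
    "venous_return_co",
    "estimate_parameters",
    "solve_equilibrium",
    "compute_targets",
    "AP_STAR_FLOOR",
    "P_LA_STAR_CEIL",
]

#: Safety clamps on the clinical targets: mean AP is never targeted below
#: 70 mmHg and mean P_LA never above 18 mmHg.
AP_STAR_FLOOR = 70.0
P_LA_STAR_CEIL = 18.0


class DomainError(ValueError):
    """Input outside the model's admissible domain (e.g. preload <= offset)."""


class InfeasibleEquilibriumError(RuntimeError):
    """No equilibrium point exists for the given parameters/constants."""


@dataclass(frozen=True)
class ModelConstants:
    """Shape constants of the Frank-Starling curves and venous-return plane.

    Defaults are the canine values of the published circulatory-equilibrium
    framework; every run configuration may override them.

    Attributes
    ----------
    P0_L, P0_R:
        Preload offsets of the left/right Frank-Starling curves (mmHg).
    k_L, k_R:
        Additive constants of the logarithmic preload term (dimensionless).
    W:
        Venous-return CO coefficient (min); 1/W is the slope of venous
        return with respect to stressed volume.
    G_L, G_R:
        Venous-return pressure coefficients (ml.kg-1.mmHg-1).
    co_max:
        Upper bracket for the equilibrium CO root search (ml.min-1.kg-1).
    """

    P0_L: float = 2.03
    k_L: float = 0.80
    P0_R: float = 2.13
    k_R: float = 1.90
    W: float = 0.129
    G_L: float = 0.424
    G_R: float = 1.31
    co_max: float = 1000.0

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError(f"W must be positive, got {self.W}")
        if self.G_L < 0 or self.G_R < 0:
            raise ValueError("G_L and G_R must be non-negative")
        if self.P0_L < 0 or self.P0_R < 0:
            raise ValueError("P0_L and P0_R must be non-negative")


@dataclass(frozen=True)
class HemodynamicState:
    """One time point of mean hemodynamics.

    AP, P_LA, P_RA in mmHg; CO in ml.min-1.kg-1; HR (informational) in
    beats.min-1; t in minutes.
    """

    t: float
    AP: float
    CO: float
    P_LA: float
    P_RA: float
    HR: float | None = None

    def validate(self, c: ModelConstants) -> None:
        """Check the invariants required for parameter estimation."""
        if not self.AP > self.P_RA >= 0:
            raise DomainError(
                f"require AP > P_RA >= 0, got AP={self.AP}, P_RA={self.P_RA}"
            )
        if self.CO <= 0:
            raise DomainError(f"CO must be positive, got {self.CO}")
        if self.P_LA <= c.P0_L:
            raise DomainError(f"P_LA={self.P_LA} <= P0_L={c.P0_L}")
        if self.P_RA <= c.P0_R:
            raise DomainError(f"P_RA={self.P_RA} <= P0_R={c.P0_R}")


@dataclass(frozen=True)
class EquilibriumParameters:
    """The four mechanistic parameters of the circulatory equilibrium.

    S_L, S_R: Frank-Starling slopes (ml.min-1.kg-1 per log-preload unit);
    R: systemic vascular resistance (mmHg.min.kg.ml-1);
    V: stressed blood volume (ml.kg-1).
    """

    S_L: float
    S_R: float
    R: float
    V: float

    def validate(self) -> None:
        for name in ("S_L", "S_R", "R", "V"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")


@dataclass(frozen=True)
class ControlTargets:
    """Clinical targets and the parameter targets derived from them."""

    AP_star: float
    P_LA_star: float
    S_L_star: float
    V_star: float
    CO_star: float
    P_RA_star: float
    #: True when the requested AP*/P_LA* had to be clamped to the safety bounds.
    clamped_AP: bool = False
    clamped_P_LA: bool = False


def frank_starling_co(S: float, P_atrium: float, P0: float, k: float) -> float:
    """Cardiac output of one ventricle as a function of its atrial preload.

    CO = S * (ln(P_atrium - P0) + k).  Strictly increasing in preload and
    linear in the pumping slope S.
    """
    if S <= 0:
        raise DomainError(f"slope S must be positive, got {S}")
    if P_atrium <= P0:
        raise DomainError(f"preload {P_atrium} below curve offset P0={P0}")
    return S * (math.log(P_atrium - P0) + k)


def _invert_frank_starling(S: float, CO: float, P0: float, k: float) -> float:
    """Atrial pressure on a Frank-Starling curve at a given CO (closed form).

    The exponent is capped at 700 so that root-bracketing over a wide CO
    range stays finite; the capped branch is far outside any physiologic
    solution and only ever signals infeasibility.
    """
    return P0 + math.exp(min(CO / S - k, 700.0))


def venous_return_co(
    V: float, P_LA: float, P_RA: float, c: ModelConstants
) -> float:
    """Venous return through the planar surface CO = (V - G_L*P_LA - G_R*P_RA)/W.

    Raises :class:`DomainError` when the stressed volume cannot sustain a
    non-negative venous return at the given atrial pressures.
    """
    co = (V - c.G_L * P_LA - c.G_R * P_RA) / c.W
    if co < 0:
        raise DomainError(
            f"negative venous return: V={V} < G_L*P_LA + G_R*P_RA ="
            f" {c.G_L * P_LA + c.G_R * P_RA}"
        )
    return co


def estimate_parameters(
    state: HemodynamicState, c: ModelConstants
) -> EquilibriumParameters:
    """Invert one measured state into the four equilibrium parameters.

    S_L = CO / (ln(P_LA - P0_L) + k_L)
    S_R = CO / (ln(P_RA - P0_R) + k_R)
    R   = (AP - P_RA) / CO
    V   = W*CO + G_L*P_LA + G_R*P_RA
    """
    state.validate(c)
    log_l = math.log(state.P_LA - c.P0_L) + c.k_L
    log_r = math.log(state.P_RA - c.P0_R) + c.k_R
    if log_l <= 0 or log_r <= 0:
        raise DomainError(
            "non-positive Frank-Starling log term "
            f"(left {log_l:.4g}, right {log_r:.4g}); state outside curve domain"
        )
    return EquilibriumParameters(
        S_L=state.CO / log_l,
        S_R=state.CO / log_r,
        R=(state.AP - state.P_RA) / state.CO,
        V=c.W * state.CO + c.G_L * state.P_LA + c.G_R * state.P_RA,
    )


def _volume_residual(co: float, p: EquilibriumParameters, c: ModelConstants) -> float:
    """Stressed volume implied by CO minus the actual V (increasing in CO)."""
    p_la = _invert_frank_starling(p.S_L, co, c.P0_L, c.k_L)
    p_ra = _invert_frank_starling(p.S_R, co, c.P0_R, c.k_R)
    return c.W * co + c.G_L * p_la + c.G_R * p_ra - p.V


def solve_equilibrium(
    p: EquilibriumParameters,
    c: ModelConstants,
    t: float = 0.0,
    HR: float | None = None,
) -> HemodynamicState:
    """Forward-solve the equilibrium (CO, P_LA, P_RA, AP) for given parameters.

    Both Frank-Starling curves invert in closed form, reducing the
    three-equation system to a single strictly increasing residual in CO,
    which is bracketed and solved with Brent's method to 1e-10.
    """
    p.validate()
    lo, hi = 1e-12, c.co_max
    f_lo = _volume_residual(lo, p, c)
    if f_lo >= 0:
        raise InfeasibleEquilibriumError(
            f"stressed volume V={p.V:.4g} ml/kg too low: no positive-CO "
            f"equilibrium (residual at CO~0 is {f_lo:.4g})"
        )
    f_hi = _volume_residual(hi, p, c)
    if f_hi <= 0:
        raise InfeasibleEquilibriumError(
            f"no equilibrium below CO={hi} ml/min/kg (residual {f_hi:.4g}); "
            "stressed volume implausibly high for the given slopes"
        )
    co = brentq(_volume_residual, lo, hi, args=(p, c), xtol=1e-10, rtol=1e-14)
    p_la = _invert_frank_starling(p.S_L, co, c.P0_L, c.k_L)
    p_ra = _invert_frank_starling(p.S_R, co, c.P0_R, c.k_R)
    return HemodynamicState(
        t=t, AP=p.R * co + p_ra, CO=co, P_LA=p_la, P_RA=p_ra, HR=HR
    )


def compute_targets(
    AP_star: float,
    P_LA_star: float,
    S_R: float,
    R: float,
    c: ModelConstants,
) -> ControlTargets:
    """Derive the parameter targets (S_L*, V*) from the clinical targets.

    AP* is clamped to >= 70 mmHg and P_LA* to <= 18 mmHg.  Holding S_R and R
    at their estimated values, the coupled pair

        CO*   = (AP* - P_RA*) / R
        P_RA* = P0_R + exp(CO*/S_R - k_R)

    is solved for CO* (single increasing residual, Brent to 1e-10), after
    which S_L* = CO*/(ln(P_LA*-P0_L)+k_L) and
    V* = W*CO* + G_L*P_LA* + G_R*P_RA*.
    """
    if S_R <= 0 or R <= 0:
        raise DomainError(f"S_R and R must be positive, got S_R={S_R}, R={R}")
    clamped_ap = AP_star < AP_STAR_FLOOR
    clamped_pla = P_LA_star > P_LA_STAR_CEIL
    ap = max(AP_star, AP_STAR_FLOOR)
    pla = min(P_LA_star, P_LA_STAR_CEIL)
    if pla <= c.P0_L:
        raise DomainError(f"P_LA*={pla} <= P0_L={c.P0_L}")

    def residual(co: float) -> float:
        return R * co + _invert_frank_starling(S_R, co, c.P0_R, c.k_R) - ap

    lo, hi = 1e-12, c.co_max
    if residual(lo) >= 0 or residual(hi) <= 0:
        raise InfeasibleEquilibriumError(
            f"no positive CO* reaches AP*={ap} mmHg with S_R={S_R:.4g}, R={R:.4g}"
        )
    co_star = brentq(residual, lo, hi, xtol=1e-10, rtol=1e-14)
    p_ra_star = _invert_frank_starling(S_R, co_star, c.P0_R, c.k_R)
    log_l = math.log(pla - c.P0_L) + c.k_L
    if log_l <= 0:
        raise DomainError(
            f"P_LA*={pla} gives non-positive log term; target below curve domain"
        )
    s_l_star = co_star / log_l
    v_star = c.W * co_star + c.G_L * pla + c.G_R * p_ra_star
    return ControlTargets(
        AP_star=ap,
        P_LA_star=pla,
        S_L_star=s_l_star,
        V_star=v_star,
        CO_star=co_star,
        P_RA_star=p_ra_star,
        clamped_AP=clamped_ap,
        clamped_P_LA=clamped_pla,
    )
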
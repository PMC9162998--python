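"""Drug feedback controllers.

Two laws close the loop on the two controllable parameters of the
circulatory equilibrium:

* landiolol (ultra-short-acting beta-blocker) lowers the left Frank-Starling
  slope S_L; a discrete proportional-integral (PI) controller with
  conditional-integration anti-windup maps the slope error
  dS_L = S_L - S_L* to an infusion rate;
* dextran raises and furosemide lowers the stressed blood volume V; a
  nonlinear controller with a dead band maps the volume error dV = V - V*
  to either a proportional dextran infusion (deficit) or a fixed furosemide
  bolus gated by a lockout interval (excess).  The two branches are mutually
  exclusive by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["PIController", "VolumeControllerConfig", "volume_update"]


@dataclass
class PIController:
    """Discrete PI controller with output clamping and conditional integration.

    ``update`` advances the integral by ``error*dt`` and returns
    ``clamp(Kp*error + Ki*integral, u_min, u_max)``.  On steps where the
    unclamped output saturates and the error would push further into
    saturation, the integral is left untouched (anti-windup), so the output
    leaves saturation as soon as the error reverses.

    Sign convention: a positive error (S_L above target, i.e. the heart
    working harder than desired) commands a positive landiolol rate.
    """

    Kp: float
    Ki: float
    u_max: float
    u_min: float = 0.0
    integral: float = field(default=0.0)

    def update(self, error: float, dt: float) -> float:
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        u_unsat = self.Kp * error + self.Ki * (self.integral + error * dt)
        if u_unsat > self.u_max and error > 0:
            return self.u_max
        if u_unsat < self.u_min and error < 0:
            return self.u_min
        self.integral += error * dt
        return min(max(u_unsat, self.u_min), self.u_max)

    def reset(self) -> None:
        self.integral = 0.0


@dataclass(frozen=True)
class VolumeControllerConfig:
    """Parameters of the nonlinear volume controller.

    dead_band: |dV| below which no drug is given (ml/kg).
    dextran_gain: infusion rate per ml/kg of deficit beyond the dead band
        ((ml.min-1.kg-1) / (ml.kg-1)).
    dextran_max: infusion-rate ceiling (ml.min-1.kg-1).
    furosemide_bolus: fixed intravenous dose per injection (mg).
    furosemide_lockout: minimum interval between boluses (min).
    """

    dead_band: float = 1.0
    dextran_gain: float = 1.0
    dextran_max: float = 1.0
    furosemide_bolus: float = 5.0
    furosemide_lockout: float = 10.0

    def __post_init__(self) -> None:
        if self.dead_band < 0:
            raise ValueError("dead_band must be >= 0")
        if min(self.dextran_gain, self.dextran_max, self.furosemide_bolus) < 0:
            raise ValueError("gains, maxima and bolus dose must be >= 0")


def volume_update(
    cfg: VolumeControllerConfig,
    delta_V: float,
    t: float,
    last_bolus_t: float = -math.inf,
) -> tuple[float, float]:
    """Volume-control law: returns ``(dextran_rate, furosemide_bolus_mg)``.

    Inside the dead band nothing is given.  A volume deficit
    (``delta_V < -dead_band``) commands dextran proportional to the deficit
    beyond the band, capped at ``dextran_max``.  A volume excess commands one
    fixed furosemide bolus, but only if at least ``furosemide_lockout``
    minutes have elapsed since the previous bolus.  At most one of the two
    outputs is nonzero.
    """
    if abs(delta_V) <= cfg.dead_band:
        return 0.0, 0.0
    if delta_V < 0:  # deficit -> volume expansion
        rate = min(cfg.dextran_gain * (-delta_V - cfg.dead_band), cfg.dextran_max)
        return rate, 0.0
    # excess -> diuresis, rate-limited by the lockout
    if t - last_bolus_t >= cfg.furosemide_lockout:
        return 0.0, cfg.furosemide_bolus
    return 0.0, 0.0
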
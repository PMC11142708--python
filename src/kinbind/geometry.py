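"""Assay geometry: microtubule, coverslip, optical trap.

The microtubule is a rigid cylinder of outer radius 12.5 nm whose axis runs
along x, resting on the coverslip plane z = 0 (axis at y = 0,
z = ``mt_radius``).  The trap holds the cargo directly above the
microtubule; its center is placed so that the mean gap between the bead
surface and the microtubule top equals the condition's nominal distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ExperimentCondition, PhysicalParams
from .states import CargoMotorState, MotorState

MT_RADIUS = 12.5
"""Microtubule outer radius, nm."""


@dataclass
class EnvironmentGeometry:
    """Microtubule cylinder plus trap placement.

    ``trap_center`` may be None until a condition is applied via
    :func:`trap_center_for`.
    """

    mt_radius: float = MT_RADIUS
    trap_center: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mt_radius <= 0:
            raise ValueError("mt_radius must be positive")
        if self.trap_center is not None:
            self.trap_center = np.asarray(self.trap_center, dtype=float)

    @property
    def mt_top(self) -> float:
        """Height of the top of the microtubule above the coverslip, nm."""
        return 2.0 * self.mt_radius

    def head_mt_distance(self, h: np.ndarray) -> float:
        """Distance from a head position to the microtubule surface, nm."""
        d = float(np.hypot(h[1], h[2] - self.mt_radius)) - self.mt_radius
        return max(d, 0.0)

    def nearest_mt_point(self, h: np.ndarray) -> np.ndarray:
        """Closest point on the microtubule surface to ``h``."""
        dy = h[1]
        dz = h[2] - self.mt_radius
        d = float(np.hypot(dy, dz))
        if d < 1e-12:
            dy, dz, d = 0.0, 1.0, 1.0  # degenerate: pick the top
        return np.array([h[0],
                         dy / d * self.mt_radius,
                         self.mt_radius + dz / d * self.mt_radius])


def trap_center_for(cond: ExperimentCondition, p: PhysicalParams,
                    geom: EnvironmentGeometry | None = None) -> np.ndarray:
    """Trap center realizing the condition's bead-surface-to-MT-top gap."""
    geom = geom or EnvironmentGeometry()
    return np.array([0.0, 0.0, geom.mt_top + cond.gap + p.R])


def init_state(cond: ExperimentCondition, p: PhysicalParams | None = None,
               geom: EnvironmentGeometry | None = None) -> CargoMotorState:
    """Initial configuration of a binding attempt.

    The cargo sits at the trap center, the anchor at the bottom pole of the
    bead, and the head hangs straight down from the anchor by the motor
    length — truncated at the microtubule top, reflecting the fast reset of
    the trap between attempts.  The motor starts ADP-bound and unattached.
    """
    p = (p or PhysicalParams()).with_length(cond.motor_length)
    if cond.bead_radius is not None:
        from dataclasses import replace
        p = replace(p, R=cond.bead_radius)
    geom = geom or EnvironmentGeometry()
    trap = trap_center_for(cond, p, geom)
    c = trap.copy()
    a = c + np.array([0.0, 0.0, -p.R])
    if a[2] < geom.mt_top - 1e-9:
        raise ValueError(
            f"gap {cond.gap} nm is geometrically impossible: anchor would "
            "sit inside the microtubule")
    h = a + np.array([0.0, 0.0, -p.L_m])
    # the head starts directly above the MT (y = 0): clamp at the MT top
    h[2] = max(h[2], geom.mt_top)
    return CargoMotorState(c=c, a=a, h=h, a_mt=None, t=0.0,
                           kstate=MotorState.ADP_FREE)
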
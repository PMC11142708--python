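"""Discrete motor states and the combined continuous/discrete system state."""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np


class MotorState(IntEnum):
    """Nucleotide/attachment state of the (coarse-grained) motor.

    The motor is tracked as a single unit: one ADP flag for the pair of
    heads, one attachment flag.  ``STRONG`` is absorbing and ends a
    binding event.
    """

    ADP_FREE = 0     # ADP-bound, unattached: diffusive search with ADP
    APO_FREE = 1     # ADP released, unattached
    WEAK = 2         # ADP-bound, weakly attached to the microtubule
    STRONG = 3       # strongly attached (absorbing)

    @property
    def is_unbound(self) -> bool:
        return self in (MotorState.ADP_FREE, MotorState.APO_FREE)


#: Ordered kinetic channels.  Index order is the deterministic tie-break
#: for (probability-zero) simultaneous minimal waiting times.
CH_ADP_RELEASE = 0   # ADP_FREE -> APO_FREE        rate k_off_adp
CH_WEAK_BIND = 1     # ADP_FREE -> WEAK (adp model) rate k_on_mt within d_mt
#                      ADP_FREE -> STRONG (diffusion model)
CH_ADP_BIND = 2      # APO_FREE -> ADP_FREE        rate k_on_adp
CH_STRONG_BIND = 3   # APO_FREE -> STRONG          rate k_on_mt within d_mt
CH_FAST_RELEASE = 4  # WEAK -> STRONG              rate k_off_adp_fast
CH_WEAK_UNBIND = 5   # WEAK -> ADP_FREE            rate k_off_mt*exp(Fw/Fd)

N_CHANNELS = 6

CHANNEL_NAMES = {
    CH_ADP_RELEASE: "adp_release",
    CH_WEAK_BIND: "weak_bind",
    CH_ADP_BIND: "adp_bind",
    CH_STRONG_BIND: "strong_bind",
    CH_FAST_RELEASE: "fast_adp_release",
    CH_WEAK_UNBIND: "weak_unbind",
}


@dataclass
class CargoMotorState:
    """Continuous coordinates plus discrete state and clock.

    ``c`` cargo center, ``a`` motor anchor on the cargo surface, ``h``
    motor head, ``a_mt`` weak-bond site on the microtubule surface
    (meaningful only while ``kstate`` is ``WEAK``); all nm.  ``t`` is the
    clock in seconds since the last (re)initialization.
    """

    c: np.ndarray
    a: np.ndarray
    h: np.ndarray
    a_mt: np.ndarray | None = None
    t: float = 0.0
    kstate: MotorState = MotorState.ADP_FREE

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float).copy()
        self.a = np.asarray(self.a, dtype=float).copy()
        self.h = np.asarray(self.h, dtype=float).copy()
        if self.a_mt is not None:
            self.a_mt = np.asarray(self.a_mt, dtype=float).copy()
        self.kstate = MotorState(self.kstate)

    def copy(self) -> "CargoMotorState":
        return CargoMotorState(
            c=self.c, a=self.a, h=self.h,
            a_mt=None if self.a_mt is None else self.a_mt,
            t=self.t, kstate=self.kstate)
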
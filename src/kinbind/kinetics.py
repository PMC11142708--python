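"""The four-state nucleotide/attachment state machine and its scheduling.

States (see :class:`~kinbind.states.MotorState`): the motor starts
ADP-bound and unattached (ADP_FREE), may release ADP in solution
(APO_FREE, reversible by ADP rebinding), may attach weakly to the
microtubule while ADP-bound (WEAK), and becomes strongly attached
(STRONG, absorbing) either by tubulin-stimulated ADP release from the
weak state or directly from the apo state on microtubule contact.

All transitions are Poisson channels whose rates depend on the head
position (Doi reactivity within reach ``d_mt``) and, for weak
detachment, on the instantaneous weak-bond force:

    ADP_FREE -> APO_FREE   k_off_adp
    ADP_FREE -> WEAK       k_on_mt        if head within d_mt
    APO_FREE -> ADP_FREE   k_on_adp
    APO_FREE -> STRONG     k_on_mt        if head within d_mt
    WEAK     -> STRONG     k_off_adp_fast
    WEAK     -> ADP_FREE   k_off_mt * exp(F_w / F_d)

The diffusion-only model variant keeps a single channel,
ADP_FREE -> STRONG at k_on_mt within reach.

Scheduling is Gillespie-style with a cap: per step, exponential waiting
times are drawn for every open channel at the current (frozen) rates; if
the minimum is below ``dt_max`` that event fires at that time, otherwise
the system advances by ``dt_max`` with no event.  Rates are re-evaluated
every step as positions move, so the cap bounds the first-order error of
freezing position-dependent rates.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from ._rng import next_exponential as _next_exponential
from .geometry import EnvironmentGeometry
from .params import MODEL_ADP, MODEL_DIFFUSION, RateParams
from .states import (CH_ADP_BIND, CH_ADP_RELEASE, CH_FAST_RELEASE,
                     CH_STRONG_BIND, CH_WEAK_BIND, CH_WEAK_UNBIND,
                     N_CHANNELS, CargoMotorState, MotorState)

__all__ = ["transition_rates", "sample_next_event", "apply_event",
           "CHANNEL_TARGETS"]

#: target state of each channel, per model flag (0 = adp, 1 = diffusion)
CHANNEL_TARGETS = {
    CH_ADP_RELEASE: MotorState.APO_FREE,
    CH_WEAK_BIND: MotorState.WEAK,       # STRONG under the diffusion model
    CH_ADP_BIND: MotorState.ADP_FREE,
    CH_STRONG_BIND: MotorState.STRONG,
    CH_FAST_RELEASE: MotorState.STRONG,
    CH_WEAK_UNBIND: MotorState.ADP_FREE,
}

_SOURCE_STATE = {
    CH_ADP_RELEASE: MotorState.ADP_FREE,
    CH_WEAK_BIND: MotorState.ADP_FREE,
    CH_ADP_BIND: MotorState.APO_FREE,
    CH_STRONG_BIND: MotorState.APO_FREE,
    CH_FAST_RELEASE: MotorState.WEAK,
    CH_WEAK_UNBIND: MotorState.WEAK,
}


@njit(cache=True, inline="always")
def _channel_rates(kstate, within, fw_mag, k_off_adp, k_fast, k_on_adp,
                   k_on_mt, k_off_mt, F_d, diffusion_model, out):
    """Fill the 6-channel rate vector for the current state.

    ``within`` is the Doi reach indicator (head within d_mt of the MT
    surface), evaluated by the caller.
    """
    for i in range(6):
        out[i] = 0.0
    if kstate == 0:  # ADP_FREE
        if not diffusion_model:
            out[0] = k_off_adp
        if within:
            out[1] = k_on_mt
    elif kstate == 1:  # APO_FREE
        out[2] = k_on_adp
        if within:
            out[3] = k_on_mt
    elif kstate == 2:  # WEAK
        out[4] = k_fast
        out[5] = k_off_mt * math.exp(fw_mag / F_d)


@njit(cache=True, inline="always")
def _draw_event(rates, dt_max, rng_state):
    """Per-channel exponential waits at frozen rates; min wins.

    Returns (channel or -1, dt).  Ties (probability zero) break toward
    the lowest channel index by strict comparison.
    """
    ev = -1
    dt = dt_max
    for i in range(6):
        if rates[i] > 0.0:
            w = _next_exponential(rng_state, 1.0 / rates[i])
            if w < dt:
                dt = w
                ev = i
    return ev, dt


def transition_rates(kstate, head_to_mt_distance: float, f_w_magnitude: float,
                     rp: RateParams, model: str = MODEL_ADP) -> dict:
    """Open kinetic channels and their rates (1/s) for the current state."""
    if head_to_mt_distance < 0 or f_w_magnitude < 0:
        raise ValueError("distance and weak-bond force must be non-negative")
    kstate = MotorState(kstate)
    if model not in (MODEL_ADP, MODEL_DIFFUSION):
        raise ValueError(f"unknown model flag {model!r}")
    out = np.empty(N_CHANNELS)
    _channel_rates(int(kstate), head_to_mt_distance <= rp.d_mt,
                   f_w_magnitude, rp.k_off_adp, rp.k_off_adp_fast,
                   rp.k_on_adp, rp.k_on_mt, rp.k_off_mt, rp.F_d,
                   model == MODEL_DIFFUSION, out)
    return {ch: float(out[ch]) for ch in range(N_CHANNELS) if out[ch] > 0.0}


def sample_next_event(rates: dict, dt_max: float, rng):
    """Sample the next kinetic event under frozen rates, capped at dt_max.

    Returns ``(channel, dt)`` with ``channel is None`` when no event fires
    before the cap.
    """
    if dt_max <= 0:
        raise ValueError("dt_max must be positive")
    ev = None
    dt = dt_max
    for ch in sorted(rates):
        lam = rates[ch]
        if lam < 0:
            raise ValueError("rates must be non-negative")
        if lam > 0.0:
            w = rng.exponential(1.0 / lam)
            if w < dt:
                dt = w
                ev = ch
    return ev, dt


def apply_event(state: CargoMotorState, event: int,
                geom: EnvironmentGeometry | None = None,
                model: str = MODEL_ADP) -> CargoMotorState:
    """Apply a kinetic event; returns the updated state (copy).

    On weak binding the attachment site ``a_mt`` is set to the nearest
    point on the microtubule surface to the head; on weak unbinding it is
    cleared.  Raises on transitions that are illegal from the current
    state (including any event from the absorbing strong state).
    """
    geom = geom or EnvironmentGeometry()
    new = state.copy()
    kstate = MotorState(state.kstate)
    if kstate == MotorState.STRONG:
        raise ValueError("strong state is absorbing; no further events")
    if event not in _SOURCE_STATE or _SOURCE_STATE[event] != kstate:
        raise ValueError(
            f"event {event} is illegal from state {kstate.name}")
    target = CHANNEL_TARGETS[event]
    if event == CH_WEAK_BIND:
        if model == MODEL_DIFFUSION:
            target = MotorState.STRONG
        else:
            new.a_mt = geom.nearest_mt_point(state.h)
    if event == CH_WEAK_UNBIND:
        new.a_mt = None
    new.kstate = target
    return new
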
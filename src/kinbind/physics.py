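"""Overdamped Brownian dynamics of the cargo-motor system.

The cargo bead, its surface anchor and the motor head evolve by
Euler-Maruyama steps of force-balance (Langevin) equations in the
overdamped limit:

    c_{n+1} = c_n + [F_cargo + kappa_t (x_trap - c_n)] dt / (6 pi eta R)
                  + sqrt(2 kBT dt / (6 pi eta R)) G
    dtheta  = tau dt / (8 pi eta R^3) + sqrt(2 kBT dt / (8 pi eta R^3)) G
    h_{n+1} = h_n + F_head D_m dt / kBT + sqrt(2 D_m dt) G

with G i.i.d. standard normal per axis.  The anchor is carried by the
rigid-body rotation dtheta about the cargo center (Rodrigues' formula) and
by the cargo translation, so |a - c| = R is preserved exactly up to
round-off.  Hard constraints (cargo above coverslip and outside the
microtubule; head outside cargo and microtubule and above the coverslip)
are enforced by projection onto the nearest admissible point.

Near-wall drag increases for the cargo use the classical perpendicular
corrections for a sphere approaching a plane wall,

    trans: (1 - (9/8)(R/z) + (1/8)(R/z)^3)^-1
    rot:   (1 - (5/16)(R/z)^3 + (15/256)(R/z)^6)^-1

applied as multipliers on the full isotropic drags (the parallel/
perpendicular anisotropy is deliberately neglected).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .geometry import EnvironmentGeometry
from .params import PhysicalParams
from .states import CargoMotorState, MotorState

__all__ = [
    "tether_force",
    "motor_torque",
    "update_cargo",
    "update_orientation_anchor",
    "update_head",
    "wall_correction_factors",
]


# ---------------------------------------------------------------------------
# numba kernels (composed by the event loop in simulate.py)

@njit(cache=True, inline="always")
def _brenner_factors(z, R):
    x = R / z
    ft = 1.0 / (1.0 - 1.125 * x + 0.125 * x ** 3)
    fr = 1.0 / (1.0 - 0.3125 * x ** 3 + 0.05859375 * x ** 6)
    return ft, fr


@njit(cache=True, inline="always")
def _tether_forces(a, h, a_mt, weakly_bound, kappa_m, L_m, kappa_w,
                   weak_taut_only, third_law, f_head, f_cargo):
    """Fill f_head/f_cargo in place; return |F_w| for the kinetics."""
    rx = h[0] - a[0]
    ry = h[1] - a[1]
    rz = h[2] - a[2]
    r2 = rx * rx + ry * ry + rz * rz
    taut = r2 > L_m * L_m
    hx = hy = hz = 0.0
    if taut:
        r = math.sqrt(r2)
        fmag = -kappa_m * (r - L_m) / r
        hx = fmag * rx
        hy = fmag * ry
        hz = fmag * rz
    fw_mag = 0.0
    wx = wy = wz = 0.0
    if weakly_bound and (taut or not weak_taut_only):
        wx = kappa_w * (a_mt[0] - h[0])
        wy = kappa_w * (a_mt[1] - h[1])
        wz = kappa_w * (a_mt[2] - h[2])
        fw_mag = math.sqrt(wx * wx + wy * wy + wz * wz)
    f_head[0] = hx + wx
    f_head[1] = hy + wy
    f_head[2] = hz + wz
    if third_law:
        f_cargo[0] = -hx
        f_cargo[1] = -hy
        f_cargo[2] = -hz
    else:
        f_cargo[0] = f_head[0]
        f_cargo[1] = f_head[1]
        f_cargo[2] = f_head[2]
    return fw_mag


@njit(cache=True, inline="always")
def _motor_torque(a, c, f_cargo, active, out):
    if active:
        rx = a[0] - c[0]
        ry = a[1] - c[1]
        rz = a[2] - c[2]
        out[0] = ry * f_cargo[2] - rz * f_cargo[1]
        out[1] = rz * f_cargo[0] - rx * f_cargo[2]
        out[2] = rx * f_cargo[1] - ry * f_cargo[0]
    else:
        out[0] = 0.0
        out[1] = 0.0
        out[2] = 0.0


@njit(cache=True, inline="always")
def _project_cargo(c, R, mt_radius):
    # outside the microtubule cylinder (axis along x at y=0, z=mt_radius)
    dy = c[1]
    dz = c[2] - mt_radius
    d2 = dy * dy + dz * dz
    dmin = R + mt_radius
    if d2 < dmin * dmin:
        d = math.sqrt(d2)
        if d < 1e-12:
            dy, dz, d = 0.0, 1.0, 1.0
        c[1] = dy / d * dmin
        c[2] = mt_radius + dz / d * dmin
    # above the coverslip
    if c[2] < R:
        c[2] = R


@njit(cache=True, inline="always")
def _project_head(h, c, R, mt_radius):
    # outside the microtubule
    dy = h[1]
    dz = h[2] - mt_radius
    d2 = dy * dy + dz * dz
    if d2 < mt_radius * mt_radius:
        d = math.sqrt(d2)
        if d < 1e-12:
            dy, dz, d = 0.0, 1.0, 1.0
        h[1] = dy / d * mt_radius
        h[2] = mt_radius + dz / d * mt_radius
    # outside the cargo sphere
    rx = h[0] - c[0]
    ry = h[1] - c[1]
    rz = h[2] - c[2]
    r2 = rx * rx + ry * ry + rz * rz
    if r2 < R * R:
        r = math.sqrt(r2)
        if r < 1e-12:
            rx, ry, rz, r = 0.0, 0.0, -1.0, 1.0
        s = R / r
        h[0] = c[0] + rx * s
        h[1] = c[1] + ry * s
        h[2] = c[2] + rz * s
    # above the coverslip
    if h[2] < 0.0:
        h[2] = 0.0


@njit(cache=True, inline="always")
def _update_cargo(c, f_cargo, trap, kt, eta, R, kBT, dt, wall_on,
                  mt_radius, g, amp):
    """One cargo EM step; ``amp`` < 0 recomputes the noise amplitude
    (needed off the cached-dt fast path and whenever wall corrections
    make the drag height-dependent)."""
    xi = 6.0 * math.pi * eta * R
    if wall_on:
        ft, _ = _brenner_factors(c[2], R)
        xi *= ft
    if amp < 0.0 or wall_on:
        amp = math.sqrt(2.0 * kBT * dt / xi)
    for i in range(3):
        F = f_cargo[i] + kt[i] * (trap[i] - c[i])
        c[i] += F * dt / xi + amp * g[i]
    _project_cargo(c, R, mt_radius)


@njit(cache=True, inline="always")
def _update_anchor(a, c_old, c_new, torque, eta, R, kBT, dt, wall_on, g,
                   amp):
    xi = 8.0 * math.pi * eta * R ** 3
    if wall_on:
        _, fr = _brenner_factors(c_old[2], R)
        xi *= fr
    if amp < 0.0 or wall_on:
        amp = math.sqrt(2.0 * kBT * dt / xi)
    tx = torque[0] * dt / xi + amp * g[0]
    ty = torque[1] * dt / xi + amp * g[1]
    tz = torque[2] * dt / xi + amp * g[2]
    ang2 = tx * tx + ty * ty + tz * tz
    rx = a[0] - c_old[0]
    ry = a[1] - c_old[1]
    rz = a[2] - c_old[2]
    if ang2 > 0.0:
        ang = math.sqrt(ang2)
        kx = tx / ang
        ky = ty / ang
        kz = tz / ang
        if ang < 1e-2:
            # rotation increments are ~1e-3 rad; 4th-order Taylor is
            # exact to ~1e-12 and spares the trig calls
            ca = 1.0 - 0.5 * ang2 + ang2 * ang2 / 24.0
            sa = ang * (1.0 - ang2 / 6.0)
        else:
            ca = math.cos(ang)
            sa = math.sin(ang)
        dot = kx * rx + ky * ry + kz * rz
        cx = ky * rz - kz * ry
        cy = kz * rx - kx * rz
        cz = kx * ry - ky * rx
        nx = rx * ca + cx * sa + kx * dot * (1.0 - ca)
        ny = ry * ca + cy * sa + ky * dot * (1.0 - ca)
        nz = rz * ca + cz * sa + kz * dot * (1.0 - ca)
        rx, ry, rz = nx, ny, nz
    a[0] = c_new[0] + rx
    a[1] = c_new[1] + ry
    a[2] = c_new[2] + rz


@njit(cache=True, inline="always")
def _update_head(h, c, f_head, D_m, kBT, dt, R, mt_radius, g, amp):
    if amp < 0.0:
        amp = math.sqrt(2.0 * D_m * dt)
    mob = D_m * dt / kBT
    for i in range(3):
        h[i] += f_head[i] * mob + amp * g[i]
    _project_head(h, c, R, mt_radius)


# ---------------------------------------------------------------------------
# Python-level operations (unit-testable surface; same kernels underneath)

def wall_correction_factors(z: float, R: float) -> tuple[float, float]:
    """Near-wall drag multipliers (translational, rotational) at height z.

    Both factors are >= 1 and decay to 1 as z -> infinity.  Raises for
    z <= R (sphere intersecting the wall).
    """
    if z <= R:
        raise ValueError("cargo center height z must exceed the radius R")
    return _brenner_factors(float(z), float(R))


def tether_force(a, h, kstate, a_mt, p: PhysicalParams,
                 kappa_w: float = 0.0):
    """Force on the motor head and on the cargo from tether and weak bond.

    The tether is a one-way (extension-only) spring of stiffness
    ``p.kappa_m`` and rest length ``p.L_m``; the weak bond pulls the head
    toward its attachment site ``a_mt`` with stiffness ``kappa_w`` while
    weakly bound.  Returns ``(f_head, f_cargo)`` in pN.
    """
    a = np.asarray(a, dtype=float)
    h = np.asarray(h, dtype=float)
    kstate = MotorState(kstate)
    weakly = kstate == MotorState.WEAK
    if weakly and a_mt is None:
        raise ValueError("a_mt is required while weakly bound")
    if kappa_w < 0:
        raise ValueError("kappa_w must be non-negative")
    if float(np.linalg.norm(h - a)) < 1e-12:
        raise ValueError("anchor and head coincide: degenerate geometry")
    amt = np.zeros(3) if a_mt is None else np.asarray(a_mt, dtype=float)
    f_head = np.empty(3)
    f_cargo = np.empty(3)
    _tether_forces(a, h, amt, weakly, p.kappa_m, p.L_m, kappa_w,
                   p.weak_force_taut_only, p.third_law_cargo_force,
                   f_head, f_cargo)
    return f_head, f_cargo


def motor_torque(a, h, c, kstate, f_cargo, *, torque_always: bool = False):
    """Torque on the cargo, (a - c) x F_cargo while the motor is weakly
    bound (or always, if ``torque_always``)."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    f_cargo = np.asarray(f_cargo, dtype=float)
    active = MotorState(kstate) == MotorState.WEAK or torque_always
    out = np.empty(3)
    _motor_torque(a, c, f_cargo, active, out)
    return out


def _normals(rng, n=3):
    if rng is None:
        return np.zeros(n)
    return rng.standard_normal(n)


def update_cargo(state: CargoMotorState, force, geom: EnvironmentGeometry,
                 p: PhysicalParams, dt: float, rng=None) -> np.ndarray:
    """One Euler-Maruyama step of the cargo center; returns the new center.

    ``rng=None`` disables thermal noise (deterministic drift step).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    c = state.c.astype(float).copy()
    trap = geom.trap_center
    if trap is None:
        raise ValueError("geometry has no trap center set")
    kt = np.asarray(p.kappa_t, dtype=float)
    _update_cargo(c, np.asarray(force, dtype=float), trap, kt, p.eta, p.R,
                  p.kBT, dt, p.wall_correction, geom.mt_radius,
                  _normals(rng), -1.0)
    return c


def update_orientation_anchor(state: CargoMotorState, torque,
                              p: PhysicalParams, dt: float, rng=None,
                              c_new=None) -> np.ndarray:
    """Rotate the anchor about the cargo center by the torque/noise
    increment and translate it with the cargo (to ``c_new`` if given)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = state.a.astype(float).copy()
    c_old = state.c.astype(float)
    c_new = c_old if c_new is None else np.asarray(c_new, dtype=float)
    _update_anchor(a, c_old, c_new, np.asarray(torque, dtype=float),
                   p.eta, p.R, p.kBT, dt, p.wall_correction, _normals(rng),
                   -1.0)
    return a


def update_head(state: CargoMotorState, force, geom: EnvironmentGeometry,
                p: PhysicalParams, dt: float, rng=None) -> np.ndarray:
    """One Euler-Maruyama step of the motor head; returns the new head."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    h = state.h.astype(float).copy()
    _update_head(h, state.c.astype(float), np.asarray(force, dtype=float),
                 p.D_m, p.kBT, dt, p.R, geom.mt_radius, _normals(rng),
                 -1.0)
    return h
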
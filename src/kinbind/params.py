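"""Parameter containers for the cargo-motor binding model.

Units are fixed globally: lengths in nm, time in s, force in pN, energy in
pN*nm.  Thermal energy at room temperature is kBT = 4.114 pN*nm.

Two groups of parameters exist.  :class:`PhysicalParams` holds the measured
or assumed physical constants of the optical-trap assay (viscosity, bead
radius, trap and motor stiffness, integration step).  :class:`ParameterVector`
holds the seven free parameters of the ADP-release binding model (four
kinetic rates, the head diffusivity, the weak-bond stiffness) together with
the model-variant flag; the diffusion-only variant pins five of the seven
to zero so that the first microtubule contact binds strongly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

KBT_ROOM = 4.114
"""Thermal energy at ~25 C, pN*nm."""

#: Default assay design: motor contour lengths (nm, incl. ~10 nm antibody
#: linker) crossed with mean bead-surface-to-microtubule-top gaps (nm).
DEFAULT_MOTOR_LENGTHS = (33.0, 45.0, 60.0)
DEFAULT_GAPS = (0.0, 20.0, 40.0, 60.0)


@dataclass
class PhysicalParams:
    """Physical constants of the trapped-bead assay.

    Parameters
    ----------
    kappa_m : float
        Motor (tether) stiffness, pN/nm.  Acts only in extension
        (one-way spring).
    L_m : float
        Motor rest length including the ~10 nm antibody linker, nm.
        Overridden per experimental condition.
    kappa_t : tuple of float
        Per-axis optical-trap stiffness (x, y, z), pN/nm.
    eta : float
        Fluid viscosity, pN*s/nm^2.
    R : float
        Cargo bead radius, nm.
    kBT : float
        Thermal energy, pN*nm.
    D_m : float
        Motor-head diffusion constant, nm^2/s (free parameter of the
        binding model; this copy is the default used by the physics layer
        when no :class:`ParameterVector` is supplied).
    dt_max : float
        Maximum integration step, s.
    wall_correction : bool
        Apply near-wall (coverslip) drag corrections to the cargo.
    third_law_cargo_force : bool
        If True (default) the cargo feels the reaction of the Hookean
        tether force only; if False it feels the same force vector as the
        head (the printed-equation convention).
    weak_force_taut_only : bool
        If True the weak-bond spring force acts on the head only while the
        tether is taut (printed-equation convention); default False applies
        it whenever weakly bound.
    torque_always : bool
        If True the motor torque acts on the cargo in every kinetic state;
        default False restricts it to the weakly bound state.
    """

    kappa_m: float = 0.32
    L_m: float = 45.0
    kappa_t: tuple = (0.045, 0.045, 0.03)
    eta: float = 1e-5
    R: float = 280.0
    kBT: float = KBT_ROOM
    D_m: float = 1994.0
    dt_max: float = 0.004
    wall_correction: bool = False
    third_law_cargo_force: bool = True
    weak_force_taut_only: bool = False
    torque_always: bool = False

    def __post_init__(self) -> None:
        kt = np.asarray(self.kappa_t, dtype=float)
        if kt.shape != (3,):
            raise ValueError("kappa_t must be a length-3 per-axis vector")
        if np.any(kt < 0):
            raise ValueError("kappa_t entries must be non-negative")
        self.kappa_t = tuple(float(v) for v in kt)
        for name in ("kappa_m", "L_m", "eta", "R", "kBT", "D_m", "dt_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    # drag coefficients are always derived, never stored
    @property
    def xi_trans(self) -> float:
        """Translational cargo drag 6*pi*eta*R, pN*s/nm."""
        return 6.0 * math.pi * self.eta * self.R

    @property
    def xi_rot(self) -> float:
        """Rotational cargo drag 8*pi*eta*R^3, pN*s*nm."""
        return 8.0 * math.pi * self.eta * self.R ** 3

    @property
    def xi_m(self) -> float:
        """Motor-head drag kBT/D_m, pN*s/nm."""
        return self.kBT / self.D_m

    @property
    def D_cargo(self) -> float:
        """Bulk translational diffusivity of the cargo, nm^2/s."""
        return self.kBT / self.xi_trans

    @property
    def D_rot(self) -> float:
        """Bulk rotational diffusivity of the cargo, rad^2/s."""
        return self.kBT / self.xi_rot

    def with_length(self, L_m: float) -> "PhysicalParams":
        return replace(self, L_m=float(L_m))


MODEL_ADP = "adp"
MODEL_DIFFUSION = "diffusion"


@dataclass
class ParameterVector:
    """The free parameters of the binding model.

    Rates are per second, ``D_m`` in nm^2/s, ``kappa_w`` in pN/nm.  The
    ``model`` flag selects the four-state ADP-release model (``"adp"``) or
    the diffusion-only restriction (``"diffusion"``), in which the first
    microtubule contact binds strongly and all ADP bookkeeping rates and
    the weak bond are fixed at zero.
    """

    k_off_adp: float = 0.008
    k_off_adp_fast: float = 2.12
    k_on_adp: float = 883.9
    k_on_mt: float = 70.65
    k_off_mt: float = 0.2
    D_m: float = 1994.0
    kappa_w: float = 0.0020
    model: str = MODEL_ADP

    FREE_NAMES = (
        "k_off_adp",
        "k_off_adp_fast",
        "k_on_adp",
        "k_on_mt",
        "k_off_mt",
        "D_m",
        "kappa_w",
    )

    def __post_init__(self) -> None:
        if self.model not in (MODEL_ADP, MODEL_DIFFUSION):
            raise ValueError(f"unknown model flag {self.model!r}")
        for name in self.FREE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.model == MODEL_DIFFUSION:
            # diffusion-only restriction: no ADP bookkeeping, no weak state
            for name in ("k_off_adp", "k_off_adp_fast", "k_on_adp",
                         "k_off_mt", "kappa_w"):
                object.__setattr__(self, name, 0.0)

    @classmethod
    def fitted_adp(cls) -> "ParameterVector":
        """Fitted parameters of the ADP-release model."""
        return cls()

    @classmethod
    def fitted_diffusion(cls) -> "ParameterVector":
        """Fitted parameters of the diffusion-only model."""
        return cls(k_off_adp=0.0, k_off_adp_fast=0.0, k_on_adp=0.0,
                   k_on_mt=80.6, k_off_mt=0.0, D_m=4459.8, kappa_w=0.0,
                   model=MODEL_DIFFUSION)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.FREE_NAMES])

    def replace_values(self, **kwargs) -> "ParameterVector":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {n: getattr(self, n) for n in self.FREE_NAMES} | {
            "model": self.model}


@dataclass
class RateParams:
    """Kinetic-rate inputs of the state machine, plus the reaction geometry.

    ``d_mt`` is the Doi binding reach of the head (nm), ``F_d`` the critical
    detachment force (pN) entering the force-dependent weak off-rate
    k_off_mt * exp(F_w / F_d).
    """

    k_off_adp: float = 0.008
    k_off_adp_fast: float = 2.12
    k_on_adp: float = 883.9
    k_on_mt: float = 70.65
    k_off_mt: float = 0.2
    d_mt: float = 5.0
    F_d: float = 4.0
    kappa_w: float = 0.0020

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.d_mt <= 0 or self.F_d <= 0:
            raise ValueError("d_mt and F_d must be strictly positive")

    @classmethod
    def from_vector(cls, pv: ParameterVector, d_mt: float = 5.0,
                    F_d: float = 4.0) -> "RateParams":
        return cls(k_off_adp=pv.k_off_adp, k_off_adp_fast=pv.k_off_adp_fast,
                   k_on_adp=pv.k_on_adp, k_on_mt=pv.k_on_mt,
                   k_off_mt=pv.k_off_mt, d_mt=d_mt, F_d=F_d,
                   kappa_w=pv.kappa_w)


@dataclass
class ExperimentCondition:
    """One cell of the assay design.

    ``motor_length`` in nm (includes the antibody linker); ``gap`` is the
    mean distance between the bead surface and the top of the microtubule,
    nm.  ``trap_stiffness`` and ``bead_radius`` override the physical
    defaults when set.
    """

    motor_length: float = 45.0
    gap: float = 20.0
    trap_stiffness: tuple | None = None
    bead_radius: float | None = None

    def __post_init__(self) -> None:
        if self.motor_length <= 0:
            raise ValueError("motor_length must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")

    def resolve(self, p: PhysicalParams) -> PhysicalParams:
        """Physical parameters with this condition's overrides applied."""
        out = replace(p, L_m=float(self.motor_length))
        if self.trap_stiffness is not None:
            out = replace(out, kappa_t=tuple(self.trap_stiffness))
        if self.bead_radius is not None:
            out = replace(out, R=float(self.bead_radius))
        return out

    @property
    def label(self) -> str:
        return f"L{self.motor_length:g}_g{self.gap:g}"


def default_design(lengths=DEFAULT_MOTOR_LENGTHS, gaps=DEFAULT_GAPS):
    """The full assay grid: every motor length at every gap."""
    return [ExperimentCondition(motor_length=L, gap=g)
            for L in lengths for g in gaps]
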
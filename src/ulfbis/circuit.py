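"""Closed-form impedance models of the tetrapolar validation circuit.

The virtual measurement object is a series loop

    generator -- node1 -- Zin -- node2 -- Zbody -- node3 -- Zout -- node4
              -- Rref -- ground

where Zin and Zout are parallel-RC contact (residual) impedances, Zbody is a
Debye relaxation branch (series R_inf plus a parallel (R0-R_inf) || C), and
Rref is a precision reference resistor used for voltage comparison.

Phasor convention: time dependence e^{+j*omega*t}, so a capacitor has
admittance j*omega*C and capacitive reactance carries a negative imaginary
part.  All interfaces take ordinary frequency in Hz; omega = 2*pi*f is formed
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extract import PhasorRecord

__all__ = [
    "ColeColeParams",
    "ParallelRC",
    "PhantomConfig",
    "PAPER_PHANTOM",
    "cole_cole_impedance",
    "parallel_rc_impedance",
    "phantom_impedances",
    "body_cole_params",
    "theoretical_tau",
    "solve_node_phasors",
]


def _check_freq(freq):
    f = np.asarray(freq, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise ValueError("frequency must be finite and non-negative (Hz)")
    return f


@dataclass(frozen=True)
class ColeColeParams:
    """Cole-Cole relaxation parameters: Z = Rinf + (R0-Rinf)/(1+(j w tau)^a).

    ``a = 1`` reduces to the Debye model.
    """

    r0: float
    rinf: float
    tau: float
    a: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r0 > self.rinf > 0):
            raise ValueError(f"require R0 > Rinf > 0, got R0={self.r0}, Rinf={self.rinf}")
        if not self.tau > 0:
            raise ValueError(f"time constant must be positive, got {self.tau}")
        if not 0 < self.a <= 1:
            raise ValueError(f"exponent a must lie in (0, 1], got {self.a}")


@dataclass(frozen=True)
class ParallelRC:
    """Resistor R in parallel with capacitor C (C = 0 means plain resistor)."""

    r: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"R must be positive, got {self.r}")
        if self.c < 0:
            raise ValueError(f"C must be non-negative, got {self.c}")


@dataclass(frozen=True)
class PhantomConfig:
    """Full validation-circuit description (SI units).

    ``body_dr`` is the R0 - Rinf resistor of the Debye branch; the branch
    capacitor ``body_c`` sets the relaxation time tau = body_dr * body_c.
    Component tolerances are stored but only applied when explicitly sampling
    a perturbed phantom (:func:`ulfbis.synth.perturb_phantom`).
    """

    contact_in: ParallelRC
    contact_out: ParallelRC
    body_rinf: float
    body_dr: float
    body_c: float
    rref: float
    r_tolerance: float = 0.01
    c_tolerance: float = 0.05

    def __post_init__(self) -> None:
        for name in ("body_rinf", "body_dr", "body_c", "rref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("r_tolerance", "c_tolerance"):
            tol = getattr(self, name)
            if not 0 <= tol <= 0.2:
                raise ValueError(f"{name} must lie in [0, 0.2], got {tol}")

    @property
    def body_r0(self) -> float:
        return self.body_rinf + self.body_dr


#: The validation phantom: 100 kOhm || 100 uF contacts, 1 kOhm + (10 kOhm ||
#: 10 uF) Debye body, 100 Ohm reference; 1 % resistors, 5 % capacitors.
PAPER_PHANTOM = PhantomConfig(
    contact_in=ParallelRC(r=100e3, c=100e-6),
    contact_out=ParallelRC(r=100e3, c=100e-6),
    body_rinf=1e3,
    body_dr=10e3,
    body_c=10e-6,
    rref=100.0,
)


def cole_cole_impedance(params: ColeColeParams, freq):
    """Complex Cole-Cole impedance at frequency ``freq`` (Hz, scalar or array).

    Uses the principal branch of (j w tau)^a, the standard Cole-Cole
    convention, continuous in ``a`` at the Debye limit a = 1.
    """
    f = _check_freq(freq)
    jwt = (1j * 2.0 * np.pi * f * params.tau) ** params.a
    z = params.rinf + (params.r0 - params.rinf) / (1.0 + jwt)
    return complex(z) if np.isscalar(freq) else z


def parallel_rc_impedance(rc: ParallelRC, freq):
    """Impedance 1 / (1/R + j w C) of a parallel RC block."""
    f = _check_freq(freq)
    z = 1.0 / (1.0 / rc.r + 1j * 2.0 * np.pi * f * rc.c)
    return complex(z) if np.isscalar(freq) else z


def body_cole_params(cfg: PhantomConfig) -> ColeColeParams:
    """Theoretical Cole-Cole parameters of the phantom body branch (a = 1)."""
    return ColeColeParams(
        r0=cfg.body_r0, rinf=cfg.body_rinf, tau=theoretical_tau(cfg), a=1.0
    )


def theoretical_tau(cfg: PhantomConfig) -> float:
    """Relaxation time tau = (R0 - Rinf) * C of the Debye body branch."""
    return cfg.body_dr * cfg.body_c


def phantom_impedances(cfg: PhantomConfig, freq):
    """Theoretical (Zin, Zbody, Zout, Z) of the phantom at ``freq`` Hz.

    Zbody is the Debye branch (Cole-Cole with a = 1); the total is the exact
    series sum Z = Zin + Zbody + Zout.
    """
    z_in = parallel_rc_impedance(cfg.contact_in, freq)
    z_out = parallel_rc_impedance(cfg.contact_out, freq)
    z_body = cole_cole_impedance(body_cole_params(cfg), freq)
    return z_in, z_body, z_out, z_in + z_body + z_out


def solve_node_phasors(cfg: PhantomConfig, freq: float, v_gen: float) -> PhasorRecord:
    """Exact phasor solution of the series measurement loop at one frequency.

    The generator drives node 1 with ``v_gen`` peak volts; the loop current is
    I = v_gen / (Zin + Zbody + Zout + Rref) and the node potentials follow by
    voltage division.  Substituting the returned phasors into the extraction
    ratios recovers the theoretical impedances exactly.
    """
    if not v_gen > 0:
        raise ValueError("generator amplitude must be positive")
    z_in, z_body, z_out, z_total = phantom_impedances(cfg, float(freq))
    z_loop = z_total + cfg.rref
    if z_loop == 0:
        raise ArithmeticError(f"zero total loop impedance at {freq} Hz")
    current = v_gen / z_loop
    u1 = complex(v_gen)
    u2 = u1 - current * z_in
    u4 = current * cfg.rref
    u3 = u4 + current * z_out
    return PhasorRecord(freq=float(freq), u1=u1, u2=u2, u3=u3, u4=u4)
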
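"""Sampled four-channel waveform synthesis: the virtual ADC front end.

Generates time-domain node voltages for a phantom under sinusoidal voltage
excitation, with configurable instrument imperfections:

* additive white noise per channel (independent input amplifiers),
* a 1/f-shaped ("pink") fraction of that noise,
* generator harmonic distortion, injected by re-solving the circuit at each
  harmonic frequency so the harmonics see the correct transfer,
* component-tolerance perturbation of the phantom.

The excitation starts at a rising zero crossing (generator phase 0 at the
first sample), matching how the instrument switches frequency mid-sweep.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .circuit import ParallelRC, PhantomConfig, solve_node_phasors

__all__ = [
    "NoiseModel",
    "QUIET",
    "DEFAULT_INSTRUMENT_NOISE",
    "WaveformBlock",
    "synthesize_waveforms",
    "perturb_phantom",
]


@dataclass(frozen=True)
class NoiseModel:
    """Channel noise and generator distortion description.

    ``white_rms`` is the total per-channel noise in volts RMS;
    ``pink_fraction`` of it is realized as 1/f-shaped noise and the remainder
    stays spectrally flat.  ``harmonic_levels`` lists generator harmonics as
    (order >= 2, level in dB relative to the carrier amplitude).  All
    randomness is drawn from ``seed``; a model with ``white_rms = 0`` is
    exactly deterministic.
    """

    white_rms: float = 0.0
    pink_fraction: float = 0.0
    harmonic_levels: tuple[tuple[int, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_rms < 0:
            raise ValueError("white_rms must be non-negative")
        if not 0 <= self.pink_fraction <= 1:
            raise ValueError("pink_fraction must lie in [0, 1]")
        object.__setattr__(
            self, "harmonic_levels", tuple((int(h), float(db)) for h, db in self.harmonic_levels)
        )
        for order, level_db in self.harmonic_levels:
            if order < 2:
                raise ValueError("harmonic orders must be >= 2")
            if level_db > 0:
                raise ValueError("harmonic levels must be <= 0 dB re carrier")


#: Ideal front end: no noise, no distortion.
QUIET = NoiseModel()

#: Default imperfection budget.  The white level puts the per-bin FFT
#: amplitude floor near -120 dB relative to a 0.5 V peak carrier for a
#: 2^17-sample rectangular-window spectrum; the harmonic pair gives a
#: generator THD near -100 dB.
DEFAULT_INSTRUMENT_NOISE = NoiseModel(
    white_rms=1.28e-4,
    pink_fraction=0.1,
    harmonic_levels=((2, -100.0), (3, -105.0)),
    seed=0,
)


@dataclass
class WaveformBlock:
    """Four sampled node-voltage series at one excitation frequency."""

    fs: float
    f_exc: float
    v_gen: float
    channels: np.ndarray  # shape (4, n), volts
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        if self.channels.ndim != 2 or self.channels.shape[0] != 4:
            raise ValueError("channels must have shape (4, n)")
        if self.channels.shape[1] < 1:
            raise ValueError("need at least one sample")
        if not self.fs > 2.0 * self.f_exc:
            raise ValueError(
                f"Nyquist violation: fs={self.fs} must exceed 2*f_exc={2 * self.f_exc}"
            )

    @property
    def n(self) -> int:
        return self.channels.shape[1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-shaped noise from a parallel bank of first-order low-pass sections.

    Three one-pole sections with staggered corner frequencies plus a direct
    path (Kellet's economy coefficients) approximate a -10 dB/decade slope
    over about four decades below Nyquist; output normalized to unit RMS.
    """
    white = rng.standard_normal(n)
    poles = (0.99765, 0.96300, 0.57000)
    gains = (0.0990460, 0.2965164, 1.0526913)
    shaped = 0.1848 * white
    for rho, g in zip(poles, gains):
        shaped = shaped + lfilter([g], [1.0, -rho], white)
    rms = float(np.sqrt(np.mean(shaped**2)))
    return shaped / rms if rms > 0 else shaped


def synthesize_waveforms(
    cfg: PhantomConfig,
    f_exc: float,
    v_gen: float,
    fs: float,
    n_periods: int,
    noise: NoiseModel = QUIET,
) -> WaveformBlock:
    """Sample the four node voltages for ``n_periods`` excitation periods.

    Each channel k is Re{u_k * exp(j*2*pi*f_exc*t)} with u_k from the exact
    circuit solution, sampled at ``fs`` for round(n_periods * fs / f_exc)
    samples, plus generator harmonics and channel noise per ``noise``.
    Bit-identical output for identical inputs and seed.
    """
    if not fs > 2.0 * f_exc:
        raise ValueError(f"Nyquist violation: fs={fs} must exceed 2*f_exc={2 * f_exc}")
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    n = int(round(n_periods * fs / f_exc))
    if n < 1:
        raise ValueError("requested block contains no samples")

    t = np.arange(n) / fs
    omega = 2.0 * np.pi * f_exc
    rec = solve_node_phasors(cfg, f_exc, v_gen)
    phasors = np.array([rec.u1, rec.u2, rec.u3, rec.u4])
    channels = np.real(phasors[:, None] * np.exp(1j * omega * t)[None, :])

    for order, level_db in noise.harmonic_levels:
        f_h = order * f_exc
        if f_h >= fs / 2.0:
            continue  # would alias; the instrument's anti-alias stage removes it
        rec_h = solve_node_phasors(cfg, f_h, v_gen * 10.0 ** (level_db / 20.0))
        ph_h = np.array([rec_h.u1, rec_h.u2, rec_h.u3, rec_h.u4])
        channels += np.real(ph_h[:, None] * np.exp(1j * order * omega * t)[None, :])

    if noise.white_rms > 0:
        rng = np.random.default_rng(noise.seed)
        sigma_flat = (1.0 - noise.pink_fraction) * noise.white_rms
        sigma_pink = noise.pink_fraction * noise.white_rms
        for k in range(4):  # fixed draw order keeps blocks reproducible
            if sigma_flat > 0:
                channels[k] += sigma_flat * rng.standard_normal(n)
            if sigma_pink > 0:
                channels[k] += sigma_pink * _pink_noise(rng, n)

    return WaveformBlock(
        fs=fs,
        f_exc=f_exc,
        v_gen=v_gen,
        channels=channels,
        meta={"n_periods": n_periods, "seed": noise.seed},
    )


def perturb_phantom(cfg: PhantomConfig, seed: int) -> PhantomConfig:
    """Draw one phantom realization within component tolerances.

    Every resistance is multiplied by (1 + d) with d uniform in
    +-r_tolerance and every capacitance by (1 + d') with d' uniform in
    +-c_tolerance; deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)

    def _r(x: float) -> float:
        return x * (1.0 + rng.uniform(-cfg.r_tolerance, cfg.r_tolerance))

    def _c(x: float) -> float:
        if x == 0:
            return 0.0
        return x * (1.0 + rng.uniform(-cfg.c_tolerance, cfg.c_tolerance))

    return dataclasses.replace(
        cfg,
        contact_in=ParallelRC(r=_r(cfg.contact_in.r), c=_c(cfg.contact_in.c)),
        contact_out=ParallelRC(r=_r(cfg.contact_out.r), c=_c(cfg.contact_out.c)),
        body_rinf=_r(cfg.body_rinf),
        body_dr=_r(cfg.body_dr),
        body_c=_c(cfg.body_c),
        rref=_r(cfg.rref),
    )
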
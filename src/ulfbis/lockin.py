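"""Digital lock-in amplifier: phase-sensitive demodulation and FFT mode.

The measured channel s(t) = Vs*cos(2*pi*f*t - phi_s) is multiplied by the
in-phase and quadrature references Vr*cos(2*pi*f*t - phi_r) and
Vr*sin(2*pi*f*t - phi_r).  Averaging the products over a whole number of
excitation periods leaves only the DC terms

    VX = 0.5 * Vs * Vr * cos(phi_r - phi_s)
    VY = 0.5 * Vs * Vr * sin(phi_r - phi_s)

from which Vs = (2/Vr)*sqrt(VX^2 + VY^2) and phi_s = phi_r - atan2(VY, VX).
An optional RC low-pass after the mixers reproduces the hardware signal
path; with whole-period integration it changes nothing, which is itself a
tested property of the implementation.

Phasor convention: the complex phasor is u = Vs * exp(-j*phi_s), so that
Re{u * exp(j*2*pi*f*t)} reproduces the signal.  Downstream impedance ratios
use this complex form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .synth import WaveformBlock

__all__ = [
    "Phasor",
    "ReferenceConfig",
    "FilterConfig",
    "demodulate",
    "apply_lowpass",
    "apply_bandpass",
    "fft_spectrum",
]


def _wrap_phase(phi: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    wrapped = math.remainder(phi, 2.0 * math.pi)
    if wrapped <= -math.pi:
        wrapped += 2.0 * math.pi
    return wrapped


@dataclass(frozen=True)
class Phasor:
    """Amplitude (peak volts) and phase phi_s (radians, in (-pi, pi])."""

    amplitude: float
    phase: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def to_complex(self) -> complex:
        """Complex phasor u with Re{u e^{j w t}} = signal, i.e. A*e^{-j*phi}."""
        return self.amplitude * complex(math.cos(-self.phase), math.sin(-self.phase))

    @classmethod
    def from_complex(cls, u: complex) -> "Phasor":
        return cls(amplitude=abs(u), phase=_wrap_phase(-math.atan2(u.imag, u.real)))


@dataclass(frozen=True)
class ReferenceConfig:
    """Lock-in reference Vr*cos(2*pi*fr*t - phi_r)."""

    fr: float
    vr: float = 1.0
    phi_r: float = 0.0

    def __post_init__(self) -> None:
        if not self.vr > 0:
            raise ValueError("reference amplitude must be positive")
        if not self.fr > 0:
            raise ValueError("reference frequency must be positive")


@dataclass(frozen=True)
class FilterConfig:
    """Optional post-mixer low-pass and pre-mixer band-pass stages.

    ``lowpass_order`` 0 disables the RC stage (the configuration used for
    all headline measurements); 1 or 2 selects one or two cascaded
    first-order sections with corner ``lowpass_cutoff`` Hz.
    """

    lowpass_order: int = 0
    lowpass_cutoff: float | None = None
    bandpass_enabled: bool = False

    def __post_init__(self) -> None:
        if self.lowpass_order not in (0, 1, 2):
            raise ValueError("lowpass_order must be 0, 1 or 2")
        if self.lowpass_order > 0 and not (
            self.lowpass_cutoff is not None and self.lowpass_cutoff > 0
        ):
            raise ValueError("lowpass_cutoff must be positive when the filter is on")


def apply_lowpass(
    series: np.ndarray,
    fs: float,
    order: int,
    cutoff: float,
    y0: float | None = None,
) -> np.ndarray:
    """Discrete first-order RC low-pass, y[k] = y[k-1] + a*(x[k] - y[k-1]).

    a = dt/(RC + dt) with RC = 1/(2*pi*cutoff); DC gain is exactly 1.
    ``order`` 2 cascades two identical sections.  The filter state starts at
    ``y0`` (default: the first sample), avoiding an artificial step from a
    zero initial condition.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if not 0 < cutoff < fs / 2.0:
        raise ValueError(f"cutoff must lie in (0, fs/2), got {cutoff} at fs={fs}")
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty input series")
    dt = 1.0 / fs
    rc = 1.0 / (2.0 * np.pi * cutoff)
    alpha = dt / (rc + dt)
    b, a = [alpha], [1.0, alpha - 1.0]
    start = float(x[0]) if y0 is None else float(y0)
    y = x
    for _ in range(order):
        y, _zf = lfilter(b, a, y, zi=[(1.0 - alpha) * start])
    return y


def apply_bandpass(series: np.ndarray, fs: float, center: float) -> np.ndarray:
    """First-order complementary band-pass around ``center`` Hz.

    Composition of a first-order high-pass (complement of the RC low-pass)
    at center/sqrt(10) with a first-order low-pass at center*sqrt(10) --
    a gentle half-decade skirt on each side used to pre-smooth raw ADC data.
    """
    if not 0 < center < fs / 2.0:
        raise ValueError("band center must lie in (0, fs/2)")
    x = np.asarray(series, dtype=float)
    lo = center / np.sqrt(10.0)
    hi = min(center * np.sqrt(10.0), 0.49 * fs)
    highpassed = x - apply_lowpass(x, fs, 1, lo)
    return apply_lowpass(highpassed, fs, 1, hi, y0=0.0)


def _whole_period_slice(block: WaveformBlock) -> int:
    """Number of leading samples spanning the largest whole period count.

    Periods are counted in time, so a fractional samples-per-period ratio is
    allowed; leftover samples beyond the last whole period are discarded.
    """
    periods = int(np.floor(block.n * block.f_exc / block.fs))
    if periods < 1:
        raise ValueError(
            f"block holds {block.n * block.f_exc / block.fs:.3g} periods; "
            "demodulation needs at least one whole period"
        )
    return min(block.n, int(round(periods * block.fs / block.f_exc)))


def demodulate(
    block: WaveformBlock,
    channel: int,
    ref: ReferenceConfig | None = None,
    filt: FilterConfig = FilterConfig(),
) -> Phasor:
    """Recover the amplitude and phase of one channel at the reference tone.

    The reference frequency must equal the block's excitation frequency
    (homodyne operation).  Averaging runs over the largest whole number of
    excitation periods that fit in the block.
    """
    if not 0 <= channel < 4:
        raise ValueError("channel index must be 0..3")
    if ref is None:
        ref = ReferenceConfig(fr=block.f_exc)
    if not np.isclose(ref.fr, block.f_exc, rtol=1e-12, atol=0.0):
        raise ValueError(
            f"reference frequency {ref.fr} Hz does not match excitation "
            f"{block.f_exc} Hz"
        )

    n_use = _whole_period_slice(block)
    x = block.channels[channel][:n_use]
    if filt.bandpass_enabled:
        x = apply_bandpass(x, block.fs, block.f_exc)
    t = np.arange(n_use) / block.fs
    arg = 2.0 * np.pi * block.f_exc * t - ref.phi_r
    va = x * (ref.vr * np.cos(arg))
    # Quadrature reference -sin so that the averaged products are
    # VX = 0.5*Vs*Vr*cos(phi_r - phi_s) and VY = +0.5*Vs*Vr*sin(phi_r - phi_s),
    # the orientation assumed by the phase formula below.
    vb = x * (-ref.vr * np.sin(arg))
    if filt.lowpass_order > 0:
        # Start the RC stage at the whole-period mean so its settling
        # transient does not bias the short simulated records.
        va = apply_lowpass(
            va, block.fs, filt.lowpass_order, filt.lowpass_cutoff, y0=float(va.mean())
        )
        vb = apply_lowpass(
            vb, block.fs, filt.lowpass_order, filt.lowpass_cutoff, y0=float(vb.mean())
        )
    vx = float(va.mean())
    vy = float(vb.mean())
    amplitude = (2.0 / ref.vr) * math.hypot(vx, vy)
    phase = _wrap_phase(ref.phi_r - math.atan2(vy, vx))
    return Phasor(amplitude=amplitude, phase=phase)


def fft_spectrum(
    block: WaveformBlock, channel: int, window: str = "none"
) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided amplitude spectrum in dB re 1 V peak.

    Normalized (with window coherent-gain correction) so a sinusoid at an
    exact bin center reads its peak amplitude: a 1 V peak tone gives 0 dB.
    """
    if block.n < 2:
        raise ValueError("need at least two samples for a spectrum")
    if window not in ("none", "hann"):
        raise ValueError("window must be 'none' or 'hann'")
    x = block.channels[channel]
    w = np.hanning(block.n) if window == "hann" else np.ones(block.n)
    spectrum = np.fft.rfft(x * w)
    amp = 2.0 * np.abs(spectrum) / np.sum(w)
    amp[0] /= 2.0
    if block.n % 2 == 0:
        amp[-1] /= 2.0
    freqs = np.fft.rfftfreq(block.n, d=1.0 / block.fs)
    mag_db = 20.0 * np.log10(np.maximum(amp, 1e-300))
    return freqs, mag_db
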
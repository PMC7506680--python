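"""Frequency-sweep planning and orchestration.

Sweep grids are log-equidistant: with N points per decade the frequencies
are f_min * 10^(k/N), k = 0 .. decades*N - 1, covering [f_min, f_max) so
that an 8-decade span at 5/10/33 points per decade yields exactly
40/80/264 points.

Two execution profiles are provided:

* ``"paper"`` -- the instrument's settings: fs = 375 kS/s above 10 kHz and
  37.5 kS/s below, with per-decade dwell times of 33 s (each decade in
  10 Hz-100 kHz), 40 s (1-10 Hz), 180 s (0.1-1 Hz), 1800 s (0.01-0.1 Hz)
  and 18000 s (1 mHz-0.01 Hz) at 33 points per decade, scaled inversely
  with point density and rounded to whole excitation periods.
* ``"fast"`` -- a simulation profile: the sample rate is capped at 2000
  samples per period (a fixed 37.5 kS/s at 1 mHz would need 37.5 M samples
  per period), floored at 16 samples per period, snapped to an integer
  samples-per-period count (coherent sampling), and integration runs a
  fixed, configurable 8 periods per point.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .circuit import PhantomConfig
from .extract import PhasorRecord
from .lockin import FilterConfig, ReferenceConfig, demodulate
from .synth import QUIET, NoiseModel, synthesize_waveforms

__all__ = [
    "SweepPlan",
    "plan_sweep",
    "select_sampling_rate",
    "integration_periods",
    "run_sweep",
]

_PAPER_FS_LOW = 37.5e3  # S/s, 1 mHz - 10 kHz
_PAPER_FS_HIGH = 375e3  # S/s, 10 - 100 kHz
_FAST_MAX_SPP = 2000  # samples per period cap (fast profile)
_FAST_MIN_SPP = 16

# Per-decade dwell time in seconds at 33 points/decade, keyed by the decade's
# lower-edge exponent (decade = [10^e, 10^(e+1))).  The single 132 s figure
# quoted for the four decades of 10 Hz-100 kHz is split equally among them.
_PAPER_DECADE_SECONDS = {
    -3: 18000.0,
    -2: 1800.0,
    -1: 180.0,
    0: 40.0,
    1: 33.0,
    2: 33.0,
    3: 33.0,
    4: 33.0,
}
_PAPER_REF_POINTS_PER_DECADE = 33


@dataclass(frozen=True)
class SweepPlan:
    f_min: float
    f_max: float
    points_per_decade: int
    profile: str
    freqs: np.ndarray
    fs_per_point: np.ndarray
    integration_periods_per_point: np.ndarray
    fast_periods: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "fs_per_point", np.asarray(self.fs_per_point, dtype=float))
        object.__setattr__(
            self,
            "integration_periods_per_point",
            np.asarray(self.integration_periods_per_point, dtype=int),
        )
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("sweep frequencies must be strictly increasing")
        if np.any(self.fs_per_point <= 2.0 * self.freqs):
            raise ValueError("every point must satisfy fs > 2f")

    @property
    def n_points(self) -> int:
        return self.freqs.size


def select_sampling_rate(f: float, profile: str = "paper") -> float:
    """ADC sample rate for excitation frequency ``f`` under a profile.

    Paper profile: 375 kS/s above 10 kHz, 37.5 kS/s otherwise.  Fast
    profile: the paper rate capped at 2000 samples per period and floored
    at 16 samples per period, then snapped to an integer samples-per-period
    count so whole-period averages are exact.
    """
    if not f > 0:
        raise ValueError("frequency must be positive")
    paper_fs = _PAPER_FS_HIGH if f > 10e3 else _PAPER_FS_LOW
    if profile == "paper":
        return paper_fs
    if profile != "fast":
        raise ValueError(f"unknown profile {profile!r}")
    spp = min(paper_fs / f, _FAST_MAX_SPP)
    spp_int = int(round(spp))
    spp_int = min(max(spp_int, _FAST_MIN_SPP), _FAST_MAX_SPP)
    return spp_int * f


def integration_periods(
    f: float,
    profile: str = "paper",
    points_per_decade: int = _PAPER_REF_POINTS_PER_DECADE,
    fast_periods: int = 8,
) -> int:
    """Whole excitation periods integrated at one sweep point.

    Paper profile: the decade's dwell time (quoted for 33 points/decade)
    divided across its points, scaled inversely with point density, rounded
    to whole periods with a minimum of one.  Fast profile: a fixed count.
    """
    if not f > 0:
        raise ValueError("frequency must be positive")
    if profile == "fast":
        if fast_periods < 1:
            raise ValueError("fast_periods must be >= 1")
        return fast_periods
    if profile != "paper":
        raise ValueError(f"unknown profile {profile!r}")
    exponent = int(np.floor(np.log10(f) + 1e-12))
    exponent = min(max(exponent, -3), 4)
    per_point_seconds = _PAPER_DECADE_SECONDS[exponent] / points_per_decade
    return max(1, int(round(per_point_seconds * f)))


def plan_sweep(
    f_min: float,
    f_max: float,
    points_per_decade: int,
    profile: str = "fast",
    fast_periods: int = 8,
) -> SweepPlan:
    """Build a log-equidistant sweep plan over [f_min, f_max).

    The end frequency is excluded by the powers-of-ten construction, so a
    full-decade span contributes exactly ``points_per_decade`` points.
    """
    if not 0 < f_min < f_max:
        raise ValueError("require 0 < f_min < f_max")
    if not 3 <= points_per_decade <= 100:
        raise ValueError("points_per_decade must lie in [3, 100]")
    decades = np.log10(f_max / f_min)
    total = int(round(decades * points_per_decade))
    if total < 1:
        raise ValueError("sweep range shorter than one grid step")
    k = np.arange(total)
    freqs = f_min * 10.0 ** (k / points_per_decade)
    fs = np.array([select_sampling_rate(f, profile) for f in freqs])
    periods = np.array(
        [integration_periods(f, profile, points_per_decade, fast_periods) for f in freqs]
    )
    return SweepPlan(
        f_min=f_min,
        f_max=f_max,
        points_per_decade=points_per_decade,
        profile=profile,
        freqs=freqs,
        fs_per_point=fs,
        integration_periods_per_point=periods,
        fast_periods=fast_periods,
    )


def run_sweep(
    cfg: PhantomConfig,
    plan: SweepPlan,
    v_gen: float = 0.5,
    noise: NoiseModel = QUIET,
) -> list[PhasorRecord]:
    """Synthesize and demodulate all four channels at every planned point.

    Point k draws its noise from sub-seed ``noise.seed + k``, so results are
    deterministic for a given master seed and independent of execution
    order.
    """
    records: list[PhasorRecord] = []
    filt = FilterConfig()  # headline configuration: filters off
    for k in range(plan.n_points):
        f = float(plan.freqs[k])
        try:
            block = synthesize_waveforms(
                cfg,
                f_exc=f,
                v_gen=v_gen,
                fs=float(plan.fs_per_point[k]),
                n_periods=int(plan.integration_periods_per_point[k]),
                noise=dataclasses.replace(noise, seed=noise.seed + k),
            )
            ref = ReferenceConfig(fr=f)
            phasors = [demodulate(block, ch, ref, filt).to_complex() for ch in range(4)]
        except Exception as exc:
            raise RuntimeError(f"sweep failed at point {k} ({f:.6g} Hz): {exc}") from exc
        records.append(
            PhasorRecord(freq=f, u1=phasors[0], u2=phasors[1], u3=phasors[2], u4=phasors[3])
        )
    return records
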
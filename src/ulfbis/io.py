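"""Configuration and file formats.

Configs are YAML with keys mirroring the dataclass field names (SI units).
Tabular outputs are comma-separated UTF-8 with a header row; complex values
are stored as paired re/im columns at full float precision (%.17g), so CSV
round trips are lossless.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .circuit import ParallelRC, PhantomConfig
from .extract import ImpedanceSpectrum, PhasorRecord
from .synth import DEFAULT_INSTRUMENT_NOISE, NoiseModel, WaveformBlock

__all__ = [
    "RunConfig",
    "load_phantom_config",
    "dump_phantom_config",
    "load_run_config",
    "dump_run_config",
    "spectrum_to_csv",
    "spectrum_from_csv",
    "phasors_to_csv",
    "phasors_from_csv",
    "waveform_to_csv",
    "waveform_from_csv",
]

_FLOAT_FMT = "%.17g"
_CHANNEL_NAMES = ("Zin", "Zbody", "Zout", "Z")


@dataclass(frozen=True)
class RunConfig:
    """Full acquisition-protocol description for one experiment.

    Defaults mirror the validation protocol: 1 V peak-to-peak excitation
    (0.5 V peak), 1 mHz-100 kHz, five repeated sweeps.
    """

    phantom: PhantomConfig
    noise: NoiseModel = DEFAULT_INSTRUMENT_NOISE
    f_min: float = 1e-3
    f_max: float = 1e5
    points_per_decade: int = 5
    profile: str = "fast"
    fast_periods: int = 8
    v_gen: float = 0.5
    repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.v_gen > 0:
            raise ValueError("v_gen must be positive")


# -- YAML configs -----------------------------------------------------------


def _phantom_from_dict(d: dict) -> PhantomConfig:
    return PhantomConfig(
        contact_in=ParallelRC(**d["contact_in"]),
        contact_out=ParallelRC(**d["contact_out"]),
        body_rinf=d["body_rinf"],
        body_dr=d["body_dr"],
        body_c=d["body_c"],
        rref=d["rref"],
        r_tolerance=d.get("r_tolerance", 0.01),
        c_tolerance=d.get("c_tolerance", 0.05),
    )


def load_phantom_config(path: str | Path) -> PhantomConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return _phantom_from_dict(yaml.safe_load(fh))


def dump_phantom_config(cfg: PhantomConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    noise_d = d.get("noise", {})
    noise = NoiseModel(
        white_rms=noise_d.get("white_rms", 0.0),
        pink_fraction=noise_d.get("pink_fraction", 0.0),
        harmonic_levels=tuple(
            (int(h), float(db)) for h, db in noise_d.get("harmonic_levels", [])
        ),
        seed=noise_d.get("seed", d.get("seed", 0)),
    )
    kwargs = {
        k: d[k]
        for k in (
            "f_min",
            "f_max",
            "points_per_decade",
            "profile",
            "fast_periods",
            "v_gen",
            "repeats",
            "seed",
        )
        if k in d
    }
    return RunConfig(phantom=_phantom_from_dict(d["phantom"]), noise=noise, **kwargs)


def dump_run_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["noise"]["harmonic_levels"] = [list(hl) for hl in cfg.noise.harmonic_levels]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


# -- CSV formats ------------------------------------------------------------


def spectrum_to_csv(spectrum: ImpedanceSpectrum, path: str | Path) -> None:
    """Long-format spectrum: freq_hz, channel, re_ohm, im_ohm."""
    rows = []
    for name, z in zip(
        _CHANNEL_NAMES,
        (spectrum.z_in, spectrum.z_body, spectrum.z_out, spectrum.z_total),
    ):
        for f, val in zip(spectrum.freqs, z):
            rows.append((f, name, val.real, val.imag))
    df = pd.DataFrame(rows, columns=["freq_hz", "channel", "re_ohm", "im_ohm"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def spectrum_from_csv(path: str | Path, rref: float) -> ImpedanceSpectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    per_channel = {}
    freqs = None
    for name in _CHANNEL_NAMES:
        sub = df[df["channel"] == name].sort_values("freq_hz")
        if sub.empty:
            raise ValueError(f"channel {name} missing from {path}")
        per_channel[name] = sub["re_ohm"].to_numpy() + 1j * sub["im_ohm"].to_numpy()
        f = sub["freq_hz"].to_numpy()
        if freqs is None:
            freqs = f
        elif not np.array_equal(freqs, f):
            raise ValueError("channels disagree on the frequency grid")
    return ImpedanceSpectrum(
        freqs=freqs,
        z_in=per_channel["Zin"],
        z_body=per_channel["Zbody"],
        z_out=per_channel["Zout"],
        z_total=per_channel["Z"],
        rref=rref,
        meta={"source": str(path)},
    )


def phasors_to_csv(records: Sequence[PhasorRecord], path: str | Path) -> None:
    """Lock-in output table: freq_hz, channel, amplitude_v, phase_rad.

    Phase follows the signal convention V*cos(2*pi*f*t - phi), i.e.
    phi = -arg(u) for the complex phasor u.
    """
    rows = []
    for rec in records:
        for idx, u in enumerate((rec.u1, rec.u2, rec.u3, rec.u4)):
            rows.append((rec.freq, f"u{idx + 1}", abs(u), -np.angle(u)))
    df = pd.DataFrame(rows, columns=["freq_hz", "channel", "amplitude_v", "phase_rad"])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def phasors_from_csv(path: str | Path) -> list[PhasorRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for f, group in df.groupby("freq_hz", sort=True):
        u = {}
        for _, row in group.iterrows():
            u[row["channel"]] = row["amplitude_v"] * np.exp(-1j * row["phase_rad"])
        try:
            records.append(
                PhasorRecord(freq=float(f), u1=u["u1"], u2=u["u2"], u3=u["u3"], u4=u["u4"])
            )
        except KeyError as exc:
            raise ValueError(f"missing channel {exc} at {f} Hz in {path}") from exc
    return records


def waveform_to_csv(block: WaveformBlock, path: str | Path) -> None:
    """Debug export of a sampled block: t, u1..u4."""
    df = pd.DataFrame(
        {
            "t": block.t,
            "u1": block.channels[0],
            "u2": block.channels[1],
            "u3": block.channels[2],
            "u4": block.channels[3],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def waveform_from_csv(path: str | Path, f_exc: float, v_gen: float) -> WaveformBlock:
    df = pd.read_csv(path, float_precision="round_trip")
    t = df["t"].to_numpy()
    if t.size < 2:
        raise ValueError("waveform CSV must hold at least two samples")
    fs = 1.0 / (t[1] - t[0])
    channels = np.vstack([df[f"u{k}"].to_numpy() for k in (1, 2, 3, 4)])
    return WaveformBlock(fs=fs, f_exc=f_exc, v_gen=v_gen, channels=channels)
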
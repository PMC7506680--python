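"""Four-electrode impedance extraction by voltage comparison.

The measurement loop is driven by a voltage generator and the four node
potentials u1..u4 are measured against the common ground.  Because every
extracted impedance is a *ratio* of phasor differences against the voltage
across the reference resistor, series residual (contact) impedances and any
common scale factor drop out:

    Zin'   = Rref * (u1 - u2) / u4
    Zbody' = Rref * (u2 - u3) / u4
    Zout'  = Rref * (u3 / u4 - 1)
    Z'     = Rref * (u1 / u4 - 1)

The additivity identity Z' = Zin' + Zbody' + Zout' holds exactly by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

__all__ = [
    "PhasorRecord",
    "ImpedanceSpectrum",
    "extract_impedances",
    "spectrum_from_records",
    "average_spectra",
]


@dataclass(frozen=True)
class PhasorRecord:
    """Complex node-voltage phasors u1..u4 (peak volts) at one frequency."""

    freq: float
    u1: complex
    u2: complex
    u3: complex
    u4: complex

    def __post_init__(self) -> None:
        # freq = 0 is admitted as the DC limit of the phasor solution.
        if not (self.freq >= 0 and np.isfinite(self.freq)):
            raise ValueError(f"freq must be non-negative and finite, got {self.freq}")


@dataclass
class ImpedanceSpectrum:
    """Per-frequency complex Zin', Zbody', Zout', Z' with provenance metadata."""

    freqs: np.ndarray
    z_in: np.ndarray
    z_body: np.ndarray
    z_out: np.ndarray
    z_total: np.ndarray
    rref: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        for name in ("z_in", "z_body", "z_out", "z_total"):
            arr = np.asarray(getattr(self, name), dtype=complex)
            if arr.shape != self.freqs.shape:
                raise ValueError(f"{name} length does not match frequency grid")
            setattr(self, name, arr)
        if self.freqs.ndim != 1:
            raise ValueError("frequency grid must be one-dimensional")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("frequencies must be strictly increasing")


def extract_impedances(
    rec: PhasorRecord, rref: float
) -> tuple[complex, complex, complex, complex]:
    """Extract (Zin', Zbody', Zout', Z') from one phasor record.

    Raises
    ------
    ValueError
        If the reference-resistor voltage u4 vanishes (degenerate
        measurement: no loop current).
    """
    if rref <= 0:
        raise ValueError("Rref must be positive")
    if rec.u4 == 0:
        raise ValueError(
            f"degenerate measurement at {rec.freq} Hz: u4 = 0 (no loop current)"
        )
    z_in = rref * (rec.u1 - rec.u2) / rec.u4
    z_body = rref * (rec.u2 - rec.u3) / rec.u4
    z_out = rref * (rec.u3 / rec.u4 - 1.0)
    # Z' computed as the sum so that the additivity identity is exact even in
    # floating point; algebraically identical to Rref*(u1/u4 - 1).
    z_total = z_in + z_body + z_out
    return z_in, z_body, z_out, z_total


def spectrum_from_records(
    records: Sequence[PhasorRecord],
    rref: float,
    meta: dict[str, Any] | None = None,
) -> ImpedanceSpectrum:
    """Apply :func:`extract_impedances` over a sweep's phasor records."""
    recs = sorted(records, key=lambda r: r.freq)
    if not recs:
        raise ValueError("no phasor records supplied")
    extracted = [extract_impedances(r, rref) for r in recs]
    z_in, z_body, z_out, z_total = (np.array(col) for col in zip(*extracted))
    return ImpedanceSpectrum(
        freqs=np.array([r.freq for r in recs]),
        z_in=z_in,
        z_body=z_body,
        z_out=z_out,
        z_total=z_total,
        rref=rref,
        meta=dict(meta or {}),
    )


def average_spectra(spectra: Sequence[ImpedanceSpectrum]) -> ImpedanceSpectrum:
    """Complex mean of repeated spectra recorded on the same frequency grid."""
    if not spectra:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if not np.array_equal(s.freqs, first.freqs):
            raise ValueError("cannot average spectra on different frequency grids")
        if s.rref != first.rref:
            raise ValueError("cannot average spectra with different Rref")
    return ImpedanceSpectrum(
        freqs=first.freqs.copy(),
        z_in=np.mean([s.z_in for s in spectra], axis=0),
        z_body=np.mean([s.z_body for s in spectra], axis=0),
        z_out=np.mean([s.z_out for s in spectra], axis=0),
        z_total=np.mean([s.z_total for s in spectra], axis=0),
        rref=first.rref,
        meta={"n_averaged": len(spectra)},
    )
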
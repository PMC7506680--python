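import numpy as np
import pytest

import ulfbis as u


@pytest.fixture(scope="session")
def phantom():
    return u.PAPER_PHANTOM


@pytest.fixture(scope="session")
def noiseless_sweep_spectrum(phantom):
    """Noiseless 40-point fast-profile sweep run once per session."""
    plan = u.plan_sweep(1e-3, 1e5, 5, profile="fast")
    records = u.run_sweep(phantom, plan, v_gen=0.5, noise=u.QUIET)
    return u.spectrum_from_records(records, phantom.rref, meta={"plan": "40pt"})


@pytest.fixture()
def pure_tone_block():
    """1 V peak cosine at 1 kHz, 37.5 kS/s, 100 whole periods, all channels."""

    def _make(phase_rad: float = 0.0, amplitude: float = 1.0):
        fs, f = 37500.0, 1000.0
        n = round(100 * fs / f)
        t = np.arange(n) / fs
        sig = amplitude * np.cos(2 * np.pi * f * t - phase_rad)
        return u.WaveformBlock(fs=fs, f_exc=f, v_gen=amplitude, channels=np.vstack([sig] * 4))

    return _make
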
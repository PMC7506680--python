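"""Validation mathematics: error spectra, Cole-Cole fitting, goodness of fit.

Relative errors compare a measured spectrum against the closed-form phantom
impedances, per channel and frequency:

    eps = 100 * |Z' - Z| / |Z|   (percent)

The Cole-Cole model Z = Rinf + (R0 - Rinf)/(1 + (j w tau)^a) is fitted by
Levenberg-Marquardt on residuals stacked over real and imaginary parts
(complex non-linear least squares); goodness of fit is

    R^2 = 1 - sum |Zhat_i - Z'_i|^2 / sum |Zbar' - Z'_i|^2

with Zbar' the complex mean of the data, which is exactly the stacked
real/imaginary reading of the residual and total sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

from .circuit import ColeColeParams, PhantomConfig, cole_cole_impedance, phantom_impedances
from .extract import ImpedanceSpectrum

__all__ = [
    "FitResult",
    "ErrorReport",
    "relative_errors",
    "fit_cole_cole",
    "parameter_errors",
    "goodness_of_fit",
    "summarize_parameters",
]

_A_MIN = 1e-3  # open lower bound for the CPE exponent


@dataclass(frozen=True)
class FitResult:
    """Outcome of a Cole-Cole fit; ``params`` is None when not converged."""

    params: ColeColeParams | None
    r_squared: float
    residual_norm: float
    n_points: int
    converged: bool


@dataclass
class ErrorReport:
    """Per-frequency relative errors (percent) for the four channels."""

    freqs: np.ndarray
    eps_in: np.ndarray
    eps_body: np.ndarray
    eps_out: np.ndarray
    eps_z: np.ndarray

    @property
    def max_in(self) -> float:
        return float(np.max(self.eps_in))

    @property
    def max_body(self) -> float:
        return float(np.max(self.eps_body))

    @property
    def max_out(self) -> float:
        return float(np.max(self.eps_out))

    @property
    def max_z(self) -> float:
        return float(np.max(self.eps_z))


def relative_errors(measured: ImpedanceSpectrum, cfg: PhantomConfig) -> ErrorReport:
    """Percent relative error of each measured channel vs the phantom theory."""
    z_in, z_body, z_out, z_total = phantom_impedances(cfg, measured.freqs)
    for name, z in (("Zin", z_in), ("Zbody", z_body), ("Zout", z_out), ("Z", z_total)):
        if np.any(np.abs(z) == 0):
            raise ValueError(f"theoretical {name} magnitude vanishes on the grid")
    return ErrorReport(
        freqs=measured.freqs.copy(),
        eps_in=100.0 * np.abs(measured.z_in - z_in) / np.abs(z_in),
        eps_body=100.0 * np.abs(measured.z_body - z_body) / np.abs(z_body),
        eps_out=100.0 * np.abs(measured.z_out - z_out) / np.abs(z_out),
        eps_z=100.0 * np.abs(measured.z_total - z_total) / np.abs(z_total),
    )


def goodness_of_fit(model_values, data_values) -> float:
    """R^2 over stacked real/imaginary components of complex spectra."""
    model = np.asarray(model_values, dtype=complex)
    data = np.asarray(data_values, dtype=complex)
    if model.shape != data.shape or data.size < 2:
        raise ValueError("model and data must have equal length >= 2")
    ss_res = float(np.sum(np.abs(model - data) ** 2))
    ss_tot = float(np.sum(np.abs(np.mean(data) - data) ** 2))
    if ss_tot == 0:
        raise ValueError("total sum of squares is zero (constant data)")
    return 1.0 - ss_res / ss_tot


def _default_init(freqs: np.ndarray, z: np.ndarray) -> ColeColeParams:
    """Data-driven starting point: plateau magnitudes, reactance-peak tau."""
    order = np.argsort(freqs)
    mag = np.abs(z[order])
    rinf0 = max(float(mag[-1]), 1e-9)
    r00 = max(float(mag[0]), rinf0 * (1.0 + 1e-6))
    im = np.abs(np.imag(z[order]))
    if np.max(im) > 0:
        f_star = float(freqs[order][int(np.argmax(im))])
    else:
        f_star = float(np.sqrt(freqs[order][0] * freqs[order][-1]))
    tau0 = 1.0 / (2.0 * np.pi * f_star) if f_star > 0 else 1.0
    return ColeColeParams(r0=r00, rinf=rinf0, tau=tau0, a=0.9)


def fit_cole_cole(
    freqs,
    z_body,
    init: ColeColeParams | None = None,
    magnitude_only: bool = False,
) -> FitResult:
    """Fit the Cole-Cole model to a complex body-impedance spectrum.

    Levenberg-Marquardt minimization of residuals stacked over real and
    imaginary parts (or magnitudes when ``magnitude_only`` is set, offered
    for sensitivity analysis).  The exponent is constrained to (0, 1] and
    R0 > Rinf > 0 by fitting Rinf and the positive increment R0 - Rinf.
    Non-convergence and degenerate (flat) spectra yield a flagged result,
    not an exception.
    """
    freqs = np.asarray(freqs, dtype=float)
    z = np.asarray(z_body, dtype=complex)
    if freqs.shape != z.shape or freqs.size < 4:
        raise ValueError("need matching freqs/impedances with at least 4 points")

    mag = np.abs(z)
    if np.ptp(mag) <= 1e-9 * np.mean(mag):  # flat spectrum: nothing to fit
        return FitResult(
            params=None,
            r_squared=0.0,
            residual_norm=float("nan"),
            n_points=freqs.size,
            converged=False,
        )

    start = init or _default_init(freqs, z)
    params = lmfit.Parameters()
    params.add("rinf", value=start.rinf, min=1e-12)
    params.add("dr", value=max(start.r0 - start.rinf, 1e-9), min=1e-12)
    params.add("tau", value=start.tau, min=1e-15)
    params.add("a", value=min(max(start.a, _A_MIN), 1.0), min=_A_MIN, max=1.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        model = _model_eval(p, freqs)
        if magnitude_only:
            return np.abs(model) - np.abs(z)
        diff = model - z
        return np.concatenate([diff.real, diff.imag])

    try:
        result = lmfit.minimize(
            residual, params, method="leastsq", xtol=1e-14, ftol=1e-14, max_nfev=20000
        )
    except Exception:
        return FitResult(
            params=None,
            r_squared=0.0,
            residual_norm=float("nan"),
            n_points=freqs.size,
            converged=False,
        )

    p = result.params
    fitted = ColeColeParams(
        r0=p["rinf"].value + p["dr"].value,
        rinf=p["rinf"].value,
        tau=p["tau"].value,
        a=min(p["a"].value, 1.0),
    )
    model = cole_cole_impedance(fitted, freqs)
    r2 = goodness_of_fit(model, z)
    res_norm = float(np.sqrt(np.sum(np.abs(model - z) ** 2)))
    return FitResult(
        params=fitted,
        r_squared=r2,
        residual_norm=res_norm,
        n_points=freqs.size,
        converged=bool(result.success),
    )


def _model_eval(p: lmfit.Parameters, freqs: np.ndarray) -> np.ndarray:
    jwt = (1j * 2.0 * np.pi * freqs * p["tau"].value) ** p["a"].value
    return p["rinf"].value + p["dr"].value / (1.0 + jwt)


def parameter_errors(
    fit: FitResult | ColeColeParams, truth: ColeColeParams
) -> tuple[float, float, float, float]:
    """Percent relative errors (eps_a, eps_tau, eps_R0, eps_Rinf) vs truth."""
    fitted = fit.params if isinstance(fit, FitResult) else fit
    if fitted is None:
        raise ValueError("fit did not converge; no parameters to compare")
    return (
        100.0 * abs(fitted.a - truth.a) / truth.a,
        100.0 * abs(fitted.tau - truth.tau) / truth.tau,
        100.0 * abs(fitted.r0 - truth.r0) / truth.r0,
        100.0 * abs(fitted.rinf - truth.rinf) / truth.rinf,
    )


def summarize_parameters(fits) -> ColeColeParams:
    """Arithmetic mean of each Cole-Cole parameter over converged fits."""
    converged = [f.params for f in fits if f.converged and f.params is not None]
    if not converged:
        raise ValueError("no converged fits to summarize")
    return ColeColeParams(
        r0=float(np.mean([p.r0 for p in converged])),
        rinf=float(np.mean([p.rinf for p in converged])),
        tau=float(np.mean([p.tau for p in converged])),
        a=float(np.mean([p.a for p in converged])),
    )
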
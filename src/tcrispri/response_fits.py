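"""Descriptive model fits: sigmoid dose-response, gamma expression noise,
exponential dilution decay.

The dose-response of an inducible promoter is summarised by a logistic

    f(x) = f_max / (1 + exp(-(x - x_half) / gamma_rate))

with x the inducer concentration (% w/v), f_max the maximal induction level,
x_half the half-max concentration and gamma_rate the induction rate constant.
This rising form is the default; a falling variant (exp with the opposite
sign) is available by flag for completeness, since the two differ only in
the sign convention of gamma_rate.

Per-cell fluorescence distributions are fitted by a two-parameter gamma
distribution (maximum likelihood, location fixed at zero); the predicted
coefficient of variation is 1/sqrt(shape).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class FitConvergenceError(RuntimeError):
    """Raised when a least-squares fit fails; carries the last iterate."""

    def __init__(self, message: str, last_params=None, residual=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual = residual


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted logistic dose-response parameters."""

    f_max: float
    x_half: float
    gamma_rate: float
    residual_norm: float
    falling: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sign = 1.0 if self.falling else -1.0
        return self.f_max / (1.0 + np.exp(sign * (x - self.x_half) / self.gamma_rate))


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit of a per-cell signal distribution."""

    shape: float
    scale: float

    @property
    def cv_predicted(self) -> float:
        """Coefficient of variation implied by the shape: 1/sqrt(shape)."""
        return 1.0 / np.sqrt(self.shape)


def _logistic(x, f_max, x_half, gamma_rate, sign):
    return f_max / (1.0 + np.exp(sign * (x - x_half) / gamma_rate))


def fit_sigmoid(x, y, falling: bool = False) -> DoseResponseFit:
    """Least-squares logistic fit of signal vs inducer concentration.

    Initialisation is taken from the data: f_max from the maximum signal,
    x_half from the concentration nearest half-max, gamma_rate from a tenth
    of the concentration span. Requires >= 4 points with non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 points, got {x.size}")
    if np.any(x < 0):
        raise ValueError("concentrations must be non-negative")
    if np.ptp(x) == 0:
        raise ValueError("concentrations are all equal")
    if np.allclose(y, 0):
        return DoseResponseFit(0.0, float(np.median(x)), float(np.ptp(x) / 10 or 1.0), 0.0, falling)

    sign = 1.0 if falling else -1.0
    f0 = float(np.max(y))
    half_idx = int(np.argmin(np.abs(y - f0 / 2)))
    x0 = float(x[half_idx]) or float(np.median(x))
    g0 = float(np.ptp(x)) / 10.0

    try:
        popt, _ = optimize.curve_fit(
            lambda xx, f, xh, g: _logistic(xx, f, xh, g, sign),
            x,
            y,
            p0=[f0, x0, g0],
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(
            f"sigmoid fit did not converge: {exc}", last_params=(f0, x0, g0)
        ) from exc
    f_max, x_half, gamma_rate = (float(v) for v in popt)
    # the two sign conventions are related by gamma_rate -> -gamma_rate;
    # normalise so gamma_rate > 0 in the declared convention
    if gamma_rate < 0:
        gamma_rate = -gamma_rate
        sign = -sign
    resid = y - _logistic(x, f_max, x_half, gamma_rate, 1.0 if falling else -1.0)
    return DoseResponseFit(
        f_max=f_max,
        x_half=x_half,
        gamma_rate=gamma_rate,
        residual_norm=float(np.linalg.norm(resid)),
        falling=falling,
    )


def fit_gamma(values) -> GammaFit:
    """Maximum-likelihood gamma fit (location fixed at 0) of positive values.

    Requires n >= 50 strictly positive values with non-zero variance.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 50:
        raise ValueError(f"need >= 50 values for a stable fit, got {values.size}")
    if np.any(values <= 0):
        raise ValueError("all values must be > 0 for a gamma fit")
    if np.ptp(values) == 0:
        raise ValueError("constant-value input: zero variance, gamma fit undefined")
    shape, _, scale = stats.gamma.fit(values, floc=0)
    return GammaFit(shape=float(shape), scale=float(scale))


def decay_halflife(t, y) -> tuple[float, float]:
    """Exponential decay rate and half-time from a log-linear fit.

    Fits log(y) = log(y0) - rate * t by least squares. Returns (rate,
    half_time = ln2/rate); a flat signal gives rate 0 and infinite
    half-time. All signals must be positive.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError(f"need >= 3 points, got {t.size}")
    if np.any(y <= 0):
        raise ValueError("signals must be > 0 for a log-linear fit")
    slope, _, _, _, _ = stats.linregress(t, np.log(y))
    rate = -float(slope)
    half_time = float(np.log(2) / rate) if rate != 0 else float("inf")
    return rate, half_time
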
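"""Quantum-catch log-curve structure-function model.

Fits ``y = y0 + a * log10(x)`` where ``x`` is foveal outer nuclear layer (ONL)
thickness in microns and ``y`` is either foveal sensitivity (FS, dB) or
decimal visual acuity (VA).  The model is linear after the log transform, so
ordinary least squares gives the exact optimum together with standard
coefficient inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .prediction import Prediction

Target = Literal["FS", "VA"]

#: Frozen clinical coefficients (y0, a) for FS in dB vs log10(ONL um).
FS_COEFFS: tuple[float, float] = (-12.01, 17.38)
#: Frozen clinical coefficients (y0, a) for decimal VA vs log10(ONL um).
VA_COEFFS: tuple[float, float] = (-1.07, 0.91)


@dataclass(frozen=True)
class CurveFitResult:
    """Least-squares fit of ``y = y0 + a * log10(onl)``.

    Attributes
    ----------
    target:
        ``"FS"`` (dB) or ``"VA"`` (decimal acuity).
    y0, a:
        Intercept and slope (per log10 micron).
    se_y0, se_a:
        Standard errors of the coefficients.
    p_y0, p_a:
        Two-sided p-values from the t distribution with ``n - 2`` df.
    rmse:
        Root-mean-square residual in target units.
    n:
        Number of fitted points.
    """

    target: Target
    y0: float
    a: float
    se_y0: float
    se_a: float
    p_y0: float
    p_a: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError(f"curve fit needs n >= 3, got n={self.n}")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")

    def predict(self, onl: float | np.ndarray) -> float | np.ndarray:
        """Evaluate the fitted curve at ONL thickness ``onl`` (um)."""
        onl = np.asarray(onl, dtype=float)
        if np.any(onl <= 0):
            raise ValueError("ONL thickness must be positive")
        out = self.y0 + self.a * np.log10(onl)
        return float(out) if out.ndim == 0 else out


def fit_log_model(onl: Sequence[float], y: Sequence[float], target: Target) -> CurveFitResult:
    """Fit ``y = y0 + a*log10(onl)`` by least squares.

    Parameters
    ----------
    onl:
        Foveal ONL thicknesses in microns, all positive, at least two distinct.
    y:
        Target values (FS in dB or VA in decimal), same length as ``onl``.
    target:
        Which functional quantity ``y`` is.

    Returns
    -------
    CurveFitResult
        Coefficients with standard errors, p-values and residual RMSE.
    """
    onl = np.asarray(onl, dtype=float)
    y = np.asarray(y, dtype=float)
    if onl.shape != y.shape or onl.ndim != 1:
        raise ValueError("onl and y must be 1-d of equal length")
    if onl.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(onl <= 0):
        raise ValueError("ONL thickness must be positive")
    if np.unique(onl).size < 2:
        raise ValueError("design is rank deficient: all ONL values identical")
    if target not in ("FS", "VA"):
        raise ValueError(f"unknown target {target!r}")

    X = sm.add_constant(np.log10(onl))
    res = sm.OLS(y, X).fit()
    rmse = float(np.sqrt(np.mean(res.resid**2)))
    return CurveFitResult(
        target=target,
        y0=float(res.params[0]),
        a=float(res.params[1]),
        se_y0=float(res.bse[0]),
        se_a=float(res.bse[1]),
        p_y0=float(res.pvalues[0]),
        p_a=float(res.pvalues[1]),
        rmse=rmse,
        n=int(onl.size),
    )


def predict_cf(fit: CurveFitResult, onl_per_scan: Sequence[float]) -> Prediction:
    """Predict a subject's foveal function from three per-scan foveal ONLs.

    The subject-level value is the mean of the three single-scan evaluations
    of the fitted curve; the half-width is ``1.96 * rmse`` of the fit.
    Negative predictions are reported as-is with a warning (below measurable
    range), never clipped.
    """
    onls = np.asarray(onl_per_scan, dtype=float)
    if onls.shape != (3,):
        raise ValueError(f"expected 3 per-scan foveal ONL values, got shape {onls.shape}")
    if np.any(onls <= 0):
        raise ValueError("ONL thickness must be positive")
    value = float(np.mean(fit.y0 + fit.a * np.log10(onls)))
    if value < 0:
        warnings.warn(
            f"curve-fit {fit.target} prediction {value:.3f} is negative "
            "(below measurable range); reported unclipped",
            stacklevel=2,
        )
    return Prediction(value=value, half_width=1.96 * fit.rmse)


def va_from_onl(onl: float) -> float:
    """Decimal VA predicted from foveal ONL thickness via the frozen clinical
    formula ``VA = -1.07 + 0.91 * log10(ONL)``."""
    if onl <= 0:
        raise ValueError("ONL thickness must be positive")
    y0, a = VA_COEFFS
    return y0 + a * np.log10(onl)


def fs_from_onl(onl: float) -> float:
    """Foveal sensitivity (dB) from foveal ONL thickness via the frozen
    clinical formula ``FS = -12.01 + 17.38 * log10(ONL)``."""
    if onl <= 0:
        raise ValueError("ONL thickness must be positive")
    y0, a = FS_COEFFS
    return y0 + a * np.log10(onl)
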
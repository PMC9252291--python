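"""Numerosity tuning-curve analysis.

Given output-layer responses to the 30 numerosities (1..30) over repeated
runs, this module computes:

* per-unit mean tuning curves and preferred numerosities (argmax of the mean
  curve; ties break to the smallest numerosity),
* the distribution of preferred numerosities (per-run histograms, averaged
  over runs),
* pooled, normalized tuning curves for units sharing a preference (used for
  the tuning-curve displays),
* Gaussian fits of tuning curves -- per unit, or of a pooled curve -- on a
  linear and three compressed abscissae (f(x) = x, sqrt(x), cbrt(x), log2(x))
  with goodness of fit measured as the regression sum of squares over the
  total sum of squares, and
* the ordinary-least-squares slope of best-fit tuning width against preferred
  numerosity (the quantitative size-effect measure: on a linear axis tuning
  broadens with preference; on a well-matched compressed axis the width is
  flat, the Weber-Fechner signature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

NUMEROSITIES = np.arange(1, 31)

#: preferences pooled for curve fitting and plotting: 1, 2, 4, 6, ..., 28, 30
PREFERENCE_GRID = (1,) + tuple(range(2, 31, 2))

SCALES = {
    "linear": lambda x: np.asarray(x, dtype=float),
    "sqrt": lambda x: np.sqrt(np.asarray(x, dtype=float)),
    "cuberoot": lambda x: np.cbrt(np.asarray(x, dtype=float)),
    "log2": lambda x: np.log2(np.asarray(x, dtype=float)),
}

#: linear first, then increasing abscissa compression
SCALE_ORDER = ("linear", "sqrt", "cuberoot", "log2")

#: map a fitted center back from transformed to raw numerosity units
INVERSE_SCALES = {
    "linear": lambda c: c,
    "sqrt": lambda c: c**2,
    "cuberoot": lambda c: c**3,
    "log2": lambda c: 2.0**c,
}


@dataclass
class UnitTuningCurve:
    """One output unit's mean response per numerosity, with its preference.

    ``mean_response`` is the raw average over repeats (it defines the
    preferred numerosity).  ``normalized_response`` averages the unit's
    per-repeat curves after each is normalized to its own peak — the
    "average response after normalization" used for display and Gaussian
    fitting; repeats in which the unit never responded are skipped.
    """

    unit: tuple
    mean_response: np.ndarray
    preferred_numerosity: int
    normalized_response: np.ndarray | None = None


@dataclass
class PooledCurve:
    """Average normalized curve of all units sharing one preference."""

    preferred_numerosity: int
    response: np.ndarray | None
    unit_count: int

    @property
    def absent(self) -> bool:
        return self.unit_count == 0


@dataclass
class GaussianFitResult:
    """Least-squares Gaussian fit of one pooled curve on one scale."""

    scale_id: str
    preferred_numerosity: int
    amplitude: float = np.nan
    center: float = np.nan
    sigma: float = np.nan
    r_square: float = np.nan
    converged: bool = False
    message: str = ""


def _as_response_array(responses: np.ndarray) -> np.ndarray:
    responses = np.asarray(responses, dtype=float)
    if responses.ndim == 2:
        responses = responses[None]
    if responses.ndim != 3 or responses.shape[-1] != len(NUMEROSITIES):
        raise ValueError(
            "responses must have shape (repeats, units, 30) covering "
            "numerosities 1..30"
        )
    return responses


def preferred_numerosities(curves: np.ndarray) -> np.ndarray:
    """Argmax numerosity per row; ties resolve to the smallest numerosity."""
    curves = np.asarray(curves)
    return NUMEROSITIES[np.argmax(curves, axis=-1)]


def normalized_mean_curves(responses: np.ndarray) -> np.ndarray:
    """Per-repeat peak-normalized curves averaged over repeats, per unit.

    Each unit's curve in each repeat is divided by its own maximum before
    averaging, so weakly- and strongly-responding repeats weigh equally;
    repeats in which a unit never responds are skipped (all-silent units
    yield an all-zero row).
    """
    responses = _as_response_array(responses)
    total = np.zeros(responses.shape[1:])
    count = np.zeros(responses.shape[1])
    for rep in responses:
        peak = rep.max(axis=1)
        ok = peak > 0
        total[ok] += rep[ok] / peak[ok, None]
        count[ok] += 1
    count[count == 0] = 1.0
    return total / count[:, None]


def mean_tuning_curves(
    responses: np.ndarray, output_shape: tuple = (20, 20)
) -> list:
    """Average each unit's responses over repeats and attach its preference.

    ``responses`` is (repeats, units, 30); units are flattened row-major over
    ``output_shape``.  The preferred numerosity is the argmax of the raw mean
    curve; the per-repeat-normalized average is attached alongside.
    """
    responses = _as_response_array(responses)
    mean = responses.mean(axis=0)
    normed = normalized_mean_curves(responses)
    prefs = preferred_numerosities(mean)
    curves = []
    for u in range(mean.shape[0]):
        unit = tuple(np.unravel_index(u, output_shape)) if (
            int(np.prod(output_shape)) == mean.shape[0]
        ) else (u,)
        curves.append(UnitTuningCurve(unit, mean[u], int(prefs[u]), normed[u]))
    return curves


def preference_distribution(responses: np.ndarray) -> np.ndarray:
    """Per-repeat preference histograms (fraction of units), averaged.

    Returns a length-30 vector of proportions that sums to 1.
    """
    responses = _as_response_array(responses)
    prefs = preferred_numerosities(responses)  # (repeats, units)
    n_units = prefs.shape[1]
    hists = np.stack(
        [np.bincount(p - 1, minlength=30) / n_units for p in prefs]
    )
    return hists.mean(axis=0)


def _normalize(curve: np.ndarray, normalization: str) -> np.ndarray:
    lo, hi = float(curve.min()), float(curve.max())
    if normalization == "minmax":
        if hi > lo:
            return (curve - lo) / (hi - lo)
        return np.zeros_like(curve)
    if normalization == "max":
        return curve / hi if hi > 0 else np.zeros_like(curve)
    raise ValueError(f"unknown normalization {normalization!r}")


def pool_curves(
    curves: list,
    preferred_numerosity: int,
    normalization: str = "minmax",
) -> PooledCurve:
    """Average the curves of all units preferring one numerosity.

    Pools the per-repeat-normalized average curves when present (raw means
    otherwise).  The pooled average is then normalized to [0, 1] (min-max by
    default; ``"max"`` divides by the peak instead).  A preference that
    attracted no units yields an absent result rather than an error.
    """
    pool = [c.normalized_response if c.normalized_response is not None
            else c.mean_response
            for c in curves
            if c.preferred_numerosity == preferred_numerosity]
    if not pool:
        return PooledCurve(preferred_numerosity, None, 0)
    avg = np.mean(pool, axis=0)
    return PooledCurve(preferred_numerosity, _normalize(avg, normalization),
                       len(pool))


def _gaussian(x, amplitude, center, sigma):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def r_square(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Regression SS over total SS, clipped to [0, 1]; 0 for a flat target."""
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        return 0.0
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_reg = float(np.sum((np.asarray(y_hat) - y.mean()) ** 2))
    return float(np.clip(ss_reg / ss_tot, 0.0, 1.0))


def fit_gaussian_on_scale(
    curve: PooledCurve | np.ndarray,
    scale_id: str,
    preferred_numerosity: int | None = None,
) -> GaussianFitResult:
    """Fit A*exp(-(f(n)-mu)^2 / (2 sigma^2)) to a pooled curve on scale f."""
    if isinstance(curve, PooledCurve):
        if curve.absent:
            return GaussianFitResult(scale_id, curve.preferred_numerosity,
                                     message="empty pool")
        y = curve.response
        pref = curve.preferred_numerosity
    else:
        y = np.asarray(curve, dtype=float)
        pref = int(preferred_numerosity if preferred_numerosity is not None
                   else NUMEROSITIES[int(np.argmax(y))])
    x = SCALES[scale_id](NUMEROSITIES)
    span = float(x[-1] - x[0])
    p0 = (max(float(y.max()), 1e-6), float(SCALES[scale_id]([pref])[0]), span / 4.0)
    bounds = (
        [0.0, x[0] - 2.0 * span, 1e-9],
        [10.0 * max(float(y.max()), 1.0), x[-1] + 2.0 * span, 10.0 * span],
    )
    try:
        popt, _ = curve_fit(
            _gaussian, x, y, p0=p0, bounds=bounds,
            xtol=1e-8, ftol=1e-8, maxfev=5000,
        )
    except (RuntimeError, ValueError) as err:
        return GaussianFitResult(scale_id, pref, message=str(err))
    amplitude, center, sigma = (float(v) for v in popt)
    return GaussianFitResult(
        scale_id, pref, amplitude, center, sigma,
        r_square(y, _gaussian(x, *popt)), converged=True,
    )


def fit_unit_curves(curves: list, scale_id: str) -> list:
    """Gaussian fits of every responsive unit's normalized average curve.

    Fits use the per-repeat-normalized average when available (falling back
    to the peak-normalized raw mean).  Units with constant curves (typically
    all-zero after rectification) carry no numerosity signal and are skipped.
    """
    fits = []
    for c in curves:
        y = c.normalized_response
        if y is None:
            y = np.asarray(c.mean_response, dtype=float)
            y = y / y.max() if y.max() > 0 else y
        if np.ptp(y) == 0:
            continue
        fits.append(
            fit_gaussian_on_scale(y, scale_id, c.preferred_numerosity)
        )
    return fits


def mean_r_square_by_preference(fits: list) -> float:
    """Mean r-square per preferred numerosity, then averaged over preferences.

    Grouping first keeps rarely-preferred numerosities from being swamped by
    preferences that attract many units.  NaN if no fit converged.
    """
    by_pref: dict = {}
    for f in fits:
        if f.converged:
            by_pref.setdefault(f.preferred_numerosity, []).append(f.r_square)
    if not by_pref:
        return float("nan")
    return float(np.mean([np.mean(v) for v in by_pref.values()]))


def sigma_slope(fits: list, abscissa: str = "center") -> float:
    """OLS slope of best-fit tuning width against preferred numerosity.

    The abscissa is always in raw numerosity units.  ``"center"`` (default)
    uses each fitted curve's own preferred numerosity — the Gaussian center
    mapped back through the scale's inverse — so width and position come from
    the same fit; ``"argmax"`` uses the discrete preference class of the
    underlying curve instead.
    """
    if abscissa == "center":
        pts = [(INVERSE_SCALES[f.scale_id](f.center), f.sigma)
               for f in fits if f.converged]
    elif abscissa == "argmax":
        pts = [(f.preferred_numerosity, f.sigma) for f in fits if f.converged]
    else:
        raise ValueError(f"unknown abscissa {abscissa!r}")
    if len(pts) < 2:
        raise ValueError("sigma_slope needs at least two converged fits")
    x, y = np.array(pts, dtype=float).T
    return float(np.polyfit(x, y, 1)[0])


def mean_r_square(fits: list) -> float:
    """Average goodness of fit over converged fits (NaN if none)."""
    vals = [f.r_square for f in fits if f.converged]
    return float(np.mean(vals)) if vals else float("nan")
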
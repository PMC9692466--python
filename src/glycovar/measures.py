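"""Derived biomarkers for the longitudinal diabetes/kidney analysis.

This module is a pure computational layer: CKD-EPI (2009 creatinine)
eGFR, the HbA1c variability score (HVS) and its 20%-wide categories,
time-weighted average HbA1c, NGSP->IFCC unit conversion, per-subject
least-squares eGFR slopes, and the rapid-decline classification.

All functions accept scalars or numpy arrays where that is natural; the
per-subject functions (``hvs``, ``twa_hba1c``, ``egfr_slope``) take one
subject's ordered series.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import MeasureError

__all__ = [
    "SlopeEstimate",
    "creatinine_to_mgdl",
    "egfr_ckdepi",
    "creatinine_from_egfr",
    "hvs",
    "hvs_category",
    "twa_hba1c",
    "hba1c_pct_to_mmolmol",
    "egfr_slope",
    "rapid_decline",
]

#: NGSP % change in HbA1c that counts as a qualifying visit-to-visit jump.
JUMP_THRESHOLD_PCT = 0.5

#: mean eGFR slope at or below this value flags a rapid decliner
RAPID_DECLINE_THRESHOLD = -5.0

#: micromol/L of creatinine per mg/dL
UMOL_PER_MGDL = 88.4

# CKD-EPI 2009 creatinine equation constants (race coefficient fixed at 1)
_KAPPA = {"F": 0.7, "M": 0.9}
_ALPHA = {"F": -0.329, "M": -0.411}
_BETA = -1.209
_AGE_BASE = 0.993
_FEMALE_FACTOR = 1.018
_SCALE = 141.0

# absolute guard against binary-float artefacts in threshold comparisons
_FLOAT_EPS = 1e-9

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class SlopeEstimate:
    """Per-subject least-squares slope of eGFR on time.

    ``window_years`` is the restriction applied to the series ("full" when
    all measurements were used).
    """

    slope: float
    intercept: float
    n_points: int
    window_years: Union[float, str] = "full"


def creatinine_to_mgdl(value: ArrayLike, unit: str) -> ArrayLike:
    """Normalise a serum creatinine value to mg/dL.

    Accepted units: ``mg/dL`` (returned unchanged) and ``umol/L`` /
    ``µmol/L`` (divided by 88.4).
    """
    u = unit.strip().lower().replace("µ", "u")
    if u in ("mg/dl", "mgdl"):
        return value
    if u in ("umol/l", "umoll"):
        return np.asarray(value) / UMOL_PER_MGDL if np.ndim(value) else value / UMOL_PER_MGDL
    raise MeasureError(f"unknown creatinine unit: {unit!r}")


def _female_mask(sex) -> np.ndarray:
    s = np.char.upper(np.asarray(sex, dtype=str))
    ok = np.isin(s, ("F", "M"))
    if not np.all(ok):
        bad = np.asarray(s)[~ok]
        raise MeasureError(f"sex must be 'F' or 'M', got {bad[:3]!r}")
    return s == "F"


def egfr_ckdepi(scr_mgdl: ArrayLike, age: ArrayLike, sex) -> ArrayLike:
    """CKD-EPI 2009 creatinine eGFR in mL/min/1.73 m^2.

    ``141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209 * 0.993^age``
    times 1.018 for females; k = 0.7 (F) / 0.9 (M), a = -0.329 (F) /
    -0.411 (M).  The race coefficient is fixed at 1.

    Parameters are broadcast; ``sex`` is 'F'/'M' (scalar or array).
    """
    scr = np.asarray(scr_mgdl, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise MeasureError("creatinine must be strictly positive")
    if np.any(age_a < 18):
        raise MeasureError("egfr_ckdepi is defined for adults (age >= 18)")
    female = _female_mask(sex)
    kappa = np.where(female, _KAPPA["F"], _KAPPA["M"])
    alpha = np.where(female, _ALPHA["F"], _ALPHA["M"])
    ratio = scr / kappa
    g = (
        _SCALE
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** _BETA
        * _AGE_BASE**age_a
        * np.where(female, _FEMALE_FACTOR, 1.0)
    )
    if np.ndim(scr_mgdl) == 0 and np.ndim(age) == 0 and np.ndim(sex) == 0:
        return float(g)
    return g


def creatinine_from_egfr(egfr: ArrayLike, age: ArrayLike, sex) -> ArrayLike:
    """Invert the CKD-EPI equation: serum creatinine (mg/dL) giving ``egfr``.

    The equation is piecewise power-law and strictly decreasing in
    creatinine, so the inverse is closed-form on each branch; the branch is
    selected by comparing ``egfr`` with its value at Scr = kappa.
    Round-trips with :func:`egfr_ckdepi` to machine precision.
    """
    g = np.asarray(egfr, dtype=float)
    age_a = np.asarray(age, dtype=float)
    if np.any(g <= 0):
        raise MeasureError("egfr must be strictly positive")
    female = _female_mask(sex)
    kappa = np.where(female, _KAPPA["F"], _KAPPA["M"])
    alpha = np.where(female, _ALPHA["F"], _ALPHA["M"])
    base = _SCALE * _AGE_BASE**age_a * np.where(female, _FEMALE_FACTOR, 1.0)
    r = g / base  # = (Scr/kappa)^alpha if Scr <= kappa else (Scr/kappa)^beta
    ratio = np.where(r >= 1.0, r ** (1.0 / alpha), r ** (1.0 / _BETA))
    scr = ratio * kappa
    if np.ndim(egfr) == 0 and np.ndim(age) == 0 and np.ndim(sex) == 0:
        return float(scr)
    return scr


def hvs(values: ArrayLike) -> float:
    """HbA1c variability score: percent of successive pairs with |change| >= 0.5%.

    ``values`` must be the chronologically ordered HbA1c series (NGSP %).
    The comparison is inclusive at 0.5 (with a 1e-9 float guard).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise MeasureError("HVS undefined: need at least 2 HbA1c measures")
    jumps = np.abs(np.diff(v)) >= JUMP_THRESHOLD_PCT - _FLOAT_EPS
    return 100.0 * float(np.mean(jumps))


def hvs_category(value: ArrayLike) -> ArrayLike:
    """Map an HVS percentage to its category 1-5.

    Bands: [0, 20], (20, 40], (40, 60], (60, 80], (80, 100] — the reference
    band is closed at 20 and each higher band is open on the left.
    """
    h = np.asarray(value, dtype=float)
    if np.any(h < -_FLOAT_EPS) or np.any(h > 100 + _FLOAT_EPS):
        raise MeasureError("hvs must lie in [0, 100]")
    edges = np.array([20.0, 40.0, 60.0, 80.0])
    cat = 1 + (h[..., None] > edges + _FLOAT_EPS).sum(axis=-1)
    if np.ndim(value) == 0:
        return int(cat)
    return cat.astype(int)


def twa_hba1c(times: ArrayLike, values: ArrayLike) -> float:
    """Time-weighted average HbA1c over the series span.

    Integral of the piecewise-linear interpolant divided by the spanned
    time (trapezoidal rule); a single measure, or several measures at one
    time point, reduce to the plain mean.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        raise MeasureError("twa_hba1c needs at least one measure")
    if t.size != v.size:
        raise MeasureError("times and values must have equal length")
    if np.any(np.diff(t) < 0):
        raise MeasureError("times must be non-decreasing")
    span = t[-1] - t[0]
    if span <= 0:
        return float(np.mean(v))
    return float(np.trapezoid(v, t) / span)


def hba1c_pct_to_mmolmol(pct: ArrayLike) -> ArrayLike:
    """Convert HbA1c NGSP % to IFCC mmol/mol: (pct - 2.15) * 10.929.

    Returns the exact (unrounded) value; display layers round to integer.
    """
    p = np.asarray(pct, dtype=float)
    if np.any(p <= 2.15):
        raise MeasureError("HbA1c % must exceed 2.15 for IFCC conversion")
    out = (p - 2.15) * 10.929
    return float(out) if np.ndim(pct) == 0 else out


def egfr_slope(
    times: ArrayLike,
    values: ArrayLike,
    window_years: Union[float, str, None] = "full",
    min_points: int = 2,
) -> SlopeEstimate:
    """Ordinary least-squares slope of eGFR on time (years).

    ``window_years`` restricts the fit to measurements with
    ``time <= window_years``; pass "full" (or None) to use every point.
    Raises :class:`MeasureError` if fewer than ``min_points`` in-window
    points remain (analysis inclusion uses ``min_points=3``).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise MeasureError("times and values must have equal length")
    if window_years not in ("full", None):
        w = float(window_years)
        keep = t <= w + _FLOAT_EPS
        t, y = t[keep], y[keep]
    else:
        window_years = "full"
    n = int(t.size)
    if n < max(min_points, 2):
        raise MeasureError(
            f"egfr_slope undefined: {n} in-window points (< {max(min_points, 2)})"
        )
    tbar = t.mean()
    ybar = y.mean()
    denom = float(np.sum((t - tbar) ** 2))
    if denom == 0.0:
        raise MeasureError("egfr_slope undefined: all measurements at one time")
    slope = float(np.sum((t - tbar) * (y - ybar)) / denom)
    intercept = float(ybar - slope * tbar)
    return SlopeEstimate(slope=slope, intercept=intercept, n_points=n, window_years=window_years)


def rapid_decline(slope: ArrayLike) -> ArrayLike:
    """True iff the mean eGFR slope is <= -5 mL/min/1.73 m^2/yr (inclusive)."""
    s = np.asarray(slope, dtype=float)
    out = s <= RAPID_DECLINE_THRESHOLD + _FLOAT_EPS
    return bool(out) if np.ndim(slope) == 0 else out
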
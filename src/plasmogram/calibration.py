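"""Concentration-response calibration and limit of detection.

The sensor is calibrated by flowing analyte at increasing concentrations
(cumulatively, lowest to highest) and recording the equilibrium shift at
each step.  The limit of detection follows the standard ICH-style
definition LOD = 3.3 * sigma / S, with sigma the standard deviation of
replicate responses at blank/lowest concentration and S the slope of the
calibration curve over its lower, linear range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "CalibrationCurve",
    "limit_of_detection",
    "fit_calibration",
    "invert_response",
    "fit_langmuir",
]

LOD_FACTOR = 3.3


def limit_of_detection(sigma: float, slope: float) -> float:
    """LOD = 3.3 * sigma / S for blank noise ``sigma`` and slope ``S`` > 0."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return LOD_FACTOR * sigma / slope


@dataclass
class CalibrationCurve:
    """Fitted calibration: low-range slope, blank noise and LOD.

    ``slope`` (S) is in shift units per pg/mL, ``sigma`` in shift units,
    LOD = 3.3 * sigma / slope in pg/mL.  ``low_range_idx`` records which
    concentrations defined the linear range; ``units`` labels the shift
    scale (nm or wavelength pixels) without changing any arithmetic.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    sigma: float
    lod: float
    low_range_idx: list[int] = field(default_factory=list)
    units: str = "px"

    @property
    def linear_range(self) -> tuple[float, float]:
        r = self.responses[self.low_range_idx]
        return float(r.min()), float(r.max())


def _low_range_indices(responses: np.ndarray, k_max: int = 4) -> list[int]:
    """Lower concentration range: the lowest k points, k = min(k_max, number
    of points strictly below half the saturation response), at least 2."""
    half_sat = responses.max() / 2.0
    below = int(np.sum(responses < half_sat))
    k = max(2, min(k_max, below if below >= 2 else k_max))
    return list(range(min(k, len(responses))))


def fit_calibration(
    concentrations: np.ndarray,
    responses: np.ndarray,
    replicate_responses: np.ndarray,
    k_max: int = 4,
    units: str = "px",
) -> CalibrationCurve:
    """Fit the low-range slope and compute LOD = 3.3 * sigma / S.

    ``replicate_responses`` are repeated measurements at blank or the lowest
    concentration, whose standard deviation gives sigma (ddof = 1).  The
    slope is an ordinary least-squares fit over the lower concentration
    range (default: the lowest 4 points, or fewer if saturation sets in
    earlier).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    reps = np.asarray(replicate_responses, dtype=float)
    if c.ndim != 1 or len(c) != len(r):
        raise ValueError("concentrations and responses must be equal-length 1-D")
    if len(c) < 3:
        raise ValueError("need at least 3 concentrations to fit")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if len(reps) < 3:
        raise ValueError("sigma undefined: need at least 3 replicate responses")

    idx = _low_range_indices(r, k_max=k_max)
    slope, intercept = np.polyfit(c[idx], r[idx], 1)
    if slope <= 0:
        raise ValueError("non-responsive sensor: calibration slope is not positive")
    sigma = float(np.std(reps, ddof=1))
    return CalibrationCurve(
        concentrations=c,
        responses=r,
        slope=float(slope),
        intercept=float(intercept),
        sigma=sigma,
        lod=limit_of_detection(sigma, float(slope)),
        low_range_idx=idx,
        units=units,
    )


def invert_response(curve: CalibrationCurve, response: float) -> tuple[float, str]:
    """Convert a measured shift to a concentration estimate via the low range.

    Returns (concentration in pg/mL, flag) where flag is "" for an in-range
    estimate, "below LOD" when the estimate is under the detection limit and
    "out of range" when the response exceeds the fitted linear range (no
    extrapolation is attempted).
    """
    lo, hi = curve.linear_range
    if response > hi:
        return float("nan"), "out of range"
    est = response / curve.slope
    if est < 0:
        est = 0.0
    flag = "below LOD" if est < curve.lod else ""
    return float(est), flag


def fit_langmuir(
    concentrations: np.ndarray, responses: np.ndarray
) -> tuple[float, float]:
    """Optional saturating (Langmuir isotherm) fit R = Rmax*C/(Kd + C).

    Useful for phantom-generated full curves; LOD always uses the linear
    low-range fit, never this one.  Returns (Rmax, Kd).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    rmax0 = r.max() if r.max() > 0 else 1.0
    kd0 = c[len(c) // 2] if c[len(c) // 2] > 0 else 1.0
    popt, _ = optimize.curve_fit(
        lambda x, rmax, kd: rmax * x / (kd + x), c, r, p0=(rmax0, kd0), maxfev=10000
    )
    return float(popt[0]), float(popt[1])


def load_calibration_table(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a calibration CSV: columns concentration, response, and either
    replicate columns (replicate_1, ...) or rows repeated at the lowest
    concentration."""
    df = pd.read_csv(path)
    rep_cols = [col for col in df.columns if col.startswith("replicate")]
    c = df["concentration"].to_numpy(dtype=float)
    r = df["response"].to_numpy(dtype=float)
    if rep_cols:
        reps = df.loc[0, rep_cols].to_numpy(dtype=float)
    else:
        reps = r[c == c.min()]
    return c, r, reps
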
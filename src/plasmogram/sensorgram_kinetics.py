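"""Sensorgram construction and secretion kinetics.

Turns reference-corrected centroid traces into the two standard views of a
binding experiment — the spatiotemporal sensorgram (shift over slit position
and time, zero-offset at T = 0) and the temporal sensorgram (ROI-averaged,
left/right-well-averaged shift trace) — and derives the downstream
quantities: secretion levels at named time points, the instantaneous
secretion rate (first derivative of the smoothed trace), and nonparametric
group comparisons between experimental conditions.

Traces are upsampled by a factor of 5 on both axes by piecewise-linear
interpolation (original samples preserved exactly) and smoothed with a
running median followed by Lowess, mirroring the acquisition pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .spectral_tracking import CentroidTrace

logger = logging.getLogger(__name__)

UPSAMPLE_FACTOR = 5

__all__ = [
    "SpatiotemporalSensorgram",
    "TemporalSensorgram",
    "SecretionKinetics",
    "ROI",
    "smooth_trace",
    "build_spatiotemporal",
    "extract_temporal",
    "secretion_level",
    "secretion_rate",
    "onset_time",
    "compare_groups",
]


@dataclass(frozen=True)
class ROI:
    """Region of interest along the slit, in native slit pixels."""

    start: int
    height: int = 20

    def __post_init__(self) -> None:
        if self.height < 1:
            raise ValueError("ROI height must be >= 1")


@dataclass
class SpatiotemporalSensorgram:
    """Centroid-shift field over (slit position, time), zero at T = 0.

    ``native_*`` hold the field on the acquisition grid; ``up_*`` the 5x
    linearly upsampled field (both axes, knots preserved, pre-smoothing) and
    ``smoothed`` its per-position time-smoothed version.
    """

    native_values: np.ndarray  # frames x positions
    native_times: np.ndarray  # min
    native_positions: np.ndarray  # slit pixels
    up_values: np.ndarray
    up_times: np.ndarray
    up_positions: np.ndarray
    smoothed: np.ndarray
    units: str = "px"
    well_id: str = ""
    excluded_positions: list[int] = field(default_factory=list)


@dataclass
class TemporalSensorgram:
    """ROI-averaged shift trace for one tumoroid (raw + smoothed)."""

    times_min: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray
    units: str = "px"
    tumoroid_id: str = ""
    contributing_wells: list[str] = field(default_factory=list)
    rois: dict[str, ROI] = field(default_factory=dict)
    provenance: str = ""

    @property
    def times_h(self) -> np.ndarray:
        return self.times_min / 60.0


@dataclass
class SecretionKinetics:
    """Secretion-rate curve and its summary statistics for one tumoroid."""

    times_min: np.ndarray
    rate_per_h: np.ndarray  # shift units per hour
    mean_rate: float
    rate_sd: float
    levels: dict[str, float] = field(default_factory=dict)
    units: str = "px"
    tumoroid_id: str = ""


def _upsample_grid(x: np.ndarray, factor: int = UPSAMPLE_FACTOR) -> np.ndarray:
    """n samples -> factor*(n-1)+1 samples; original knots preserved."""
    n = len(x)
    if n < 2:
        return np.asarray(x, dtype=float)
    idx = np.arange(factor * (n - 1) + 1) / factor
    return np.interp(idx, np.arange(n), x)


def smooth_trace(
    values: np.ndarray,
    median_window: int = 5 * UPSAMPLE_FACTOR,
    lowess_frac: float = 0.15,
    lowess_it: int = 1,
) -> np.ndarray:
    """Running-median then Lowess smoothing of a 1-D trace.

    ``median_window`` is in samples of the input grid; the default covers
    5 native frames on the 5x-upsampled grid.  The Lowess span is a fraction
    of the series length with one robustness iteration — wide enough to
    suppress single-frame spikes while preserving hour-scale kinetics.
    Constant traces are fixed points.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("smooth_trace expects a 1-D trace")
    if len(v) < 3:
        return v.copy()
    w = min(median_window, len(v))
    if w % 2 == 0:
        w -= 1
    med = ndimage.median_filter(v, size=w, mode="nearest") if w >= 3 else v
    x = np.arange(len(v), dtype=float)
    sm = sm_lowess(med, x, frac=lowess_frac, it=lowess_it, return_sorted=False)
    return np.asarray(sm, dtype=float)


def build_spatiotemporal(trace: CentroidTrace) -> SpatiotemporalSensorgram:
    """Build the spatiotemporal sensorgram from a detection-well trace.

    Per slit position: offset so the T = 0 value is exactly zero, fill
    flagged (NaN) samples by 1-D linear interpolation in time, then upsample
    5x on both axes and smooth along time.  Positions with more than 50%
    flagged frames are excluded and logged.
    """
    v = np.asarray(trace.values, dtype=float)
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("need at least 2 frames and 2 slit pixels")
    n_t, n_p = v.shape
    keep: list[int] = []
    excluded: list[int] = []
    for p in range(n_p):
        if np.isnan(v[:, p]).mean() > 0.5:
            excluded.append(p)
        else:
            keep.append(p)
    if excluded:
        logger.warning(
            "well %s: excluding %d slit positions with >50%% flagged frames",
            trace.well_id, len(excluded),
        )
    if len(keep) < 2:
        raise ValueError("fewer than 2 usable slit positions")

    filled = np.empty((n_t, len(keep)))
    tgrid = np.arange(n_t, dtype=float)
    for j, p in enumerate(keep):
        col = v[:, p]
        bad = np.isnan(col)
        if bad.any():
            col = col.copy()
            col[bad] = np.interp(tgrid[bad], tgrid[~bad], col[~bad])
        filled[:, j] = col
    filled = filled - filled[0]  # exact zero at T=0 per position

    positions = np.asarray(keep, dtype=float)
    up_times = _upsample_grid(trace.times)
    up_positions = _upsample_grid(positions)
    # separable bilinear upsampling: time axis then position axis
    half = np.empty((len(up_times), filled.shape[1]))
    for j in range(filled.shape[1]):
        half[:, j] = np.interp(up_times, trace.times, filled[:, j])
    up = np.empty((len(up_times), len(up_positions)))
    for i in range(len(up_times)):
        up[i] = np.interp(up_positions, positions, half[i])
    smoothed = np.empty_like(up)
    for j in range(up.shape[1]):
        smoothed[:, j] = smooth_trace(up[:, j])
    return SpatiotemporalSensorgram(
        native_values=filled,
        native_times=np.asarray(trace.times, dtype=float),
        native_positions=positions,
        up_values=up,
        up_times=up_times,
        up_positions=up_positions,
        smoothed=smoothed,
        units=trace.units,
        well_id=trace.well_id,
        excluded_positions=excluded,
    )


def _roi_average(sg: SpatiotemporalSensorgram, roi: ROI) -> np.ndarray:
    lo, hi = roi.start, roi.start + roi.height - 1
    sel = (sg.up_positions >= lo) & (sg.up_positions <= hi)
    if not sel.any():
        raise ValueError("ROI lies outside the sensorgram positions")
    return sg.up_values[:, sel].mean(axis=1)


def _centered_roi(sg: SpatiotemporalSensorgram, height: int = 20) -> ROI:
    n = len(sg.native_positions)
    h = min(height, n)
    start = int(sg.native_positions[0] + (n - h) // 2)
    return ROI(start=start, height=h)


def extract_temporal(
    sensorgram_left: SpatiotemporalSensorgram | None,
    sensorgram_right: SpatiotemporalSensorgram | None = None,
    roi_left: ROI | None = None,
    roi_right: ROI | None = None,
    tumoroid_id: str = "",
) -> TemporalSensorgram:
    """Average ROIs and the two flanking detection wells into one trace.

    Each detection well contributes the mean shift over a 20-native-pixel
    ROI (default: centered); the final raw trace is the mean of the left and
    right well traces, then smoothed.  When one well is missing the other is
    used alone and noted in the provenance.
    """
    wells = []
    traces = []
    rois: dict[str, ROI] = {}
    for sg, roi in ((sensorgram_left, roi_left), (sensorgram_right, roi_right)):
        if sg is None:
            continue
        r = roi if roi is not None else _centered_roi(sg)
        traces.append(_roi_average(sg, r))
        wells.append(sg.well_id)
        rois[sg.well_id] = r
    if not traces:
        raise ValueError("at least one detection-well sensorgram is required")
    ref = (sensorgram_left or sensorgram_right)
    for sg in (sensorgram_left, sensorgram_right):
        if sg is not None and len(sg.up_times) != len(ref.up_times):
            raise ValueError("left/right sensorgrams have different time axes")
    raw = np.mean(traces, axis=0)
    prov = "" if len(traces) == 2 else f"single well ({wells[0]})"
    return TemporalSensorgram(
        times_min=ref.up_times.copy(),
        raw=raw,
        smoothed=smooth_trace(raw),
        units=ref.units,
        tumoroid_id=tumoroid_id,
        contributing_wells=wells,
        rois=rois,
        provenance=prov,
    )


def secretion_level(
    trace: TemporalSensorgram, t_center_h: float, half_window_h: float = 1.0
) -> float:
    """Mean smoothed shift over a time window centered at ``t_center_h``.

    The window is clipped at the final time point so an end-of-run level
    (e.g. 20 h on a 20 h record) averages the trailing half-window.
    """
    t = trace.times_h
    lo = t_center_h - half_window_h
    hi = t_center_h + half_window_h
    if hi < t[0] or lo > t[-1]:
        raise ValueError("averaging window lies entirely outside the record")
    sel = (t >= lo) & (t <= min(hi, t[-1]))
    return float(trace.smoothed[sel].mean())


def secretion_rate(trace: TemporalSensorgram) -> SecretionKinetics:
    """First derivative of the smoothed trace: the real-time secretion rate.

    Central finite differences (one-sided at the endpoints) on the smoothed
    trace, expressed in shift units per hour; the mean and standard
    deviation of the rate curve summarize each tumoroid's kinetics.
    """
    if len(trace.times_min) < 3:
        raise ValueError("need at least 3 time samples for a rate curve")
    rate = np.gradient(trace.smoothed, trace.times_h)
    return SecretionKinetics(
        times_min=trace.times_min.copy(),
        rate_per_h=rate,
        mean_rate=float(rate.mean()),
        rate_sd=float(rate.std()),
        units=trace.units,
        tumoroid_id=trace.tumoroid_id,
    )


def onset_time(trace: TemporalSensorgram, fraction: float = 0.1) -> float:
    """Secretion onset: first crossing of ``fraction`` of the final level.

    Returns the crossing time in hours (linear interpolation between
    samples); NaN when the trace never reaches the threshold.
    """
    y = trace.smoothed
    thresh = fraction * y[-1]
    above = y >= thresh
    if y[-1] <= 0 or not above.any():
        return float("nan")
    i = int(np.argmax(above))
    t = trace.times_h
    if i == 0:
        return float(t[0])
    # linear interpolation between the bracketing samples
    y0, y1 = y[i - 1], y[i]
    f = (thresh - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def compare_groups(
    levels_a: np.ndarray, levels_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two groups of secretion levels.

    Returns (U statistic for group a, two-sided p).  Midranks handle ties;
    the p-value is exact for min(n) <= 8 without ties, otherwise the normal
    approximation with tie correction is used.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) < 3 or len(b) < 3:
        logger.warning("group sizes below 3; p-value has little power")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
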
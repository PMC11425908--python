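"""Resonance peak-centroid tracking of spectroscopic image stacks.

The sensor signal is the wavelength position of the EOT transmission peak at
each pixel along the spectrometer slit.  For each slit pixel a fixed
wavelength window is defined once, from the first frame, at 50% of the
peak-to-valley intensity; the intensity-weighted centroid inside that window
is then tracked over all frames.  Shifts relative to T = 0, corrected by the
mean shift of reference wells (which see only common-mode drift), are the
binding signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NoResonanceError",
    "SpectralImageStack",
    "CentroidWindow",
    "CentroidTrace",
    "define_window",
    "peak_centroid",
    "track_stack",
    "reference_correct",
    "traces_to_frame",
]


class NoResonanceError(ValueError):
    """Raised when a spectrum has no usable interior resonance peak."""


@dataclass
class SpectralImageStack:
    """Time series of spectroscopic images for one well.

    ``intensity`` is frames x slit-position x wavelength-pixel.
    ``wavelength_axis`` maps wavelength-pixel to nm; when ``None`` the
    centroid traces are reported in wavelength-pixel units.
    """

    intensity: np.ndarray
    times: np.ndarray
    wavelength_axis: np.ndarray | None = None
    well_id: str = ""
    role: str = "detection"  # "detection" | "reference"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be frames x slit x wavelength")
        if len(self.times) != self.intensity.shape[0]:
            raise ValueError("times length must match the number of frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.wavelength_axis is not None:
            self.wavelength_axis = np.asarray(self.wavelength_axis, dtype=float)
            d = np.diff(self.wavelength_axis)
            if len(self.wavelength_axis) != self.intensity.shape[2]:
                raise ValueError("wavelength_axis length must match spectra")
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("wavelength_axis must be strictly monotone")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_slit_pixels(self) -> int:
        return self.intensity.shape[1]


@dataclass(frozen=True)
class CentroidWindow:
    """Fixed wavelength-pixel window around a resonance peak.

    Bounds are inclusive pixel indices; ``threshold`` is the intensity at
    50% of peak-to-valley, used both to bound the window and as the baseline
    subtracted from the centroid weights.
    """

    lo: int
    hi: int
    threshold: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("window lo must be <= hi")


@dataclass
class CentroidTrace:
    """Per-slit-pixel resonance centroid positions over time.

    ``values`` is frames x slit-pixels; undefined centroids are NaN (flagged,
    never interpolated at this stage).  ``units`` is ``"nm"`` or ``"px"``.
    ``is_shift`` marks traces already expressed as shift-from-T0.
    """

    values: np.ndarray
    times: np.ndarray
    units: str = "px"
    well_id: str = ""
    role: str = "detection"
    is_shift: bool = False
    windows: list[CentroidWindow | None] = field(default_factory=list)

    @property
    def undefined_fraction(self) -> float:
        return float(np.isnan(self.values).mean())


def define_window(spectrum: np.ndarray) -> CentroidWindow:
    """Define the 50% peak-to-valley window around the resonance peak.

    The peak is the global maximum (required to be a strict interior
    maximum); the valley is the lower of the two minima flanking it; the
    threshold is the midpoint of peak and valley; the window is the maximal
    contiguous run of samples around the peak at or above the threshold.
    """
    s = np.asarray(spectrum, dtype=float)
    if s.ndim != 1 or len(s) < 8:
        raise NoResonanceError("spectrum must be 1-D with at least 8 samples")
    if not np.all(np.isfinite(s)):
        raise NoResonanceError("spectrum contains non-finite values")
    p = int(np.argmax(s))
    if p == 0 or p == len(s) - 1 or s[0] == s.max() or s[-1] == s.max():
        raise NoResonanceError("peak lies at the spectrum edge")
    valley = min(s[:p].min(), s[p + 1:].min())
    peak = s[p]
    if peak <= valley:
        raise NoResonanceError("flat spectrum: no interior resonance peak")
    threshold = valley + 0.5 * (peak - valley)
    lo = p
    while lo > 0 and s[lo - 1] >= threshold:
        lo -= 1
    hi = p
    while hi < len(s) - 1 and s[hi + 1] >= threshold:
        hi += 1
    return CentroidWindow(lo=lo, hi=hi, threshold=threshold)


def peak_centroid(
    spectrum: np.ndarray,
    window: CentroidWindow,
    wavelength_axis: np.ndarray | None = None,
) -> float:
    """Baseline-subtracted intensity centroid inside a fixed window.

    centroid = sum(pos_i * (I_i - threshold)+) / sum((I_i - threshold)+) over
    the window, with negative weights clipped to zero; positions come from
    ``wavelength_axis`` (nm) or default to pixel indices.  Returns NaN when
    every clipped weight is zero (undefined centroid).
    """
    s = np.asarray(spectrum, dtype=float)
    if window.hi >= len(s):
        raise ValueError("window exceeds the spectrum axis")
    seg = s[window.lo : window.hi + 1]
    w = np.clip(seg - window.threshold, 0.0, None)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        return float("nan")
    if wavelength_axis is None:
        pos = np.arange(window.lo, window.hi + 1, dtype=float)
    else:
        pos = np.asarray(wavelength_axis, dtype=float)[window.lo : window.hi + 1]
    return float((pos * w).sum() / total)


def track_stack(stack: SpectralImageStack) -> CentroidTrace:
    """Track the resonance centroid of every slit pixel across all frames.

    The centroid window is defined once per slit pixel from the T = 0 frame
    and reused for all frames (the window is fixed, per the detection
    scheme); slit pixels without a usable T = 0 resonance, and frames where
    the clipped weights vanish, are flagged NaN.  A warning is logged when a
    frame has more than 20% undefined centroids.
    """
    n_t, n_p, _ = stack.intensity.shape
    windows: list[CentroidWindow | None] = []
    for p in range(n_p):
        try:
            windows.append(define_window(stack.intensity[0, p]))
        except NoResonanceError:
            windows.append(None)
    values = np.full((n_t, n_p), np.nan)
    for p, win in enumerate(windows):
        if win is None:
            continue
        for t in range(n_t):
            values[t, p] = peak_centroid(
                stack.intensity[t, p], win, stack.wavelength_axis
            )
    frac = np.isnan(values).mean(axis=1)
    for t in np.nonzero(frac > 0.20)[0]:
        logger.warning(
            "well %s frame %d: %.0f%% undefined centroids",
            stack.well_id, t, 100 * frac[t],
        )
    return CentroidTrace(
        values=values,
        times=stack.times.copy(),
        units="nm" if stack.wavelength_axis is not None else "px",
        well_id=stack.well_id,
        role=stack.role,
        windows=windows,
    )


def reference_correct(
    trace: CentroidTrace, reference_traces: list[CentroidTrace]
) -> CentroidTrace:
    """Subtract the mean reference-well shift to reject common-mode drift.

    Both the trace and the references are first expressed as
    shift-from-T0 per slit pixel; at each frame the mean reference shift
    (across reference wells and their slit pixels, NaN centroids dropped) is
    subtracted.  The result is a shift trace, exactly zero at T = 0.
    """
    if not reference_traces:
        raise ValueError("at least one reference trace is required")
    for ref in reference_traces:
        if ref.units != trace.units:
            raise ValueError("trace and reference units differ")
        if len(ref.times) != len(trace.times) or np.any(ref.times != trace.times):
            raise ValueError("trace and reference time axes differ")

    shift = trace.values - trace.values[0]
    ref_shifts = np.concatenate(
        [ref.values - ref.values[0] for ref in reference_traces], axis=1
    )
    with np.errstate(invalid="ignore"):
        ref_mean = np.nanmean(ref_shifts, axis=1)
    corrected = shift - ref_mean[:, np.newaxis]
    return CentroidTrace(
        values=corrected,
        times=trace.times.copy(),
        units=trace.units,
        well_id=trace.well_id,
        role=trace.role,
        is_shift=True,
        windows=trace.windows,
    )


def traces_to_frame(traces: list[CentroidTrace]) -> pd.DataFrame:
    """Flatten centroid traces to a long table (one row per pixel, frame)."""
    rows = []
    for tr in traces:
        n_t, n_p = tr.values.shape
        tt, pp = np.meshgrid(tr.times, np.arange(n_p), indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "well_id": tr.well_id,
                    "role": tr.role,
                    "time_min": tt.ravel(),
                    "slit_pixel": pp.ravel(),
                    "centroid": tr.values.ravel(),
                    "units": tr.units,
                    "is_shift": tr.is_shift,
                    "undefined": np.isnan(tr.values).ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def traces_from_frame(df: pd.DataFrame) -> list[CentroidTrace]:
    """Inverse of :func:`traces_to_frame`."""
    out = []
    for well_id, g in df.groupby("well_id", sort=False):
        times = np.sort(g["time_min"].unique())
        pivot = g.pivot_table(
            index="time_min", columns="slit_pixel", values="centroid", dropna=False
        ).reindex(times)
        out.append(
            CentroidTrace(
                values=pivot.to_numpy(),
                times=times,
                units=str(g["units"].iloc[0]),
                well_id=str(well_id),
                role=str(g["role"].iloc[0]),
                is_shift=bool(g["is_shift"].iloc[0]),
            )
        )
    return out


def save_traces_csv(traces: list[CentroidTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def load_traces_csv(path: str | Path) -> list[CentroidTrace]:
    return traces_from_frame(pd.read_csv(path))
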
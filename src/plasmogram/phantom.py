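"""Synthetic optofluidic phantom with known ground truth.

Emulates the raw data of a nanohole-array (EOT) microwell biosensing run:
per-well spectroscopic image stacks whose transmission resonance (a peak near
860 nm) red-shifts as secreted analyte binds the functionalized surface, and
bright-field stacks showing a textured quasi-circular tumoroid that grows and
wanders inside its microwell.  Every stochastic element flows from a single
seed through spawned generators, so two runs with the same config are
bit-identical and each downstream stage can be tested against the recorded
ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile

from .spectral_tracking import SpectralImageStack

__all__ = [
    "ResonanceModel",
    "BindingKinetics",
    "SecretionProfile",
    "PhantomConfig",
    "GroundTruth",
    "simulate_binding_trace",
    "render_spectral_stack",
    "render_brightfield_stack",
    "write_phantom",
]


@dataclass(frozen=True)
class ResonanceModel:
    """Lorentzian transmission resonance of the sensor.

    Parameters
    ----------
    lambda0 : float
        Resonance center wavelength at t = 0, in nm.
    fwhm : float
        Full width at half maximum of the peak, nm.
    peak_amp, valley_amp : float
        Transmitted intensity at the peak and far off resonance (arb. units).
    band : (float, float)
        Wavelength range covered by the spectrometer window, nm.
    """

    lambda0: float = 860.0
    fwhm: float = 12.0
    peak_amp: float = 1.0
    valley_amp: float = 0.05
    band: tuple[float, float] = (800.0, 920.0)

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (self.peak_amp > self.valley_amp >= 0):
            raise ValueError("require peak_amp > valley_amp >= 0")
        if not (lo < self.lambda0 < hi):
            raise ValueError("lambda0 must lie strictly inside the band")
        if not (0 < self.fwhm < hi - lo):
            raise ValueError("fwhm must be positive and narrower than the band")

    def spectrum(self, wavelengths: np.ndarray, center: float) -> np.ndarray:
        """Transmission at ``wavelengths`` for a peak centered at ``center``."""
        half = self.fwhm / 2.0
        lorentz = 1.0 / (1.0 + ((wavelengths - center) / half) ** 2)
        return self.valley_amp + (self.peak_amp - self.valley_amp) * lorentz


@dataclass(frozen=True)
class BindingKinetics:
    """First-order Langmuir binding of analyte to the sensor surface.

    ``k_on`` is per (concentration * minute), ``k_off`` per minute,
    ``gamma_max`` the saturation coverage (arb. units) and
    ``shift_per_coverage`` the resonance red-shift in nm per unit coverage.
    """

    k_on: float = 2e-4
    k_off: float = 0.0
    gamma_max: float = 1.0
    shift_per_coverage: float = 0.3

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "gamma_max", "shift_per_coverage"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SecretionProfile:
    """Well-mixed analyte concentration in a well as a function of time.

    kind
        ``constant``: C(t) = plateau.
        ``delayed_onset``: zero until ``onset_min``, then a linear ramp of
        ``slope`` (concentration per minute) capped at ``plateau`` — the
        shape of a secretion signal that appears after a few hours.
        ``logistic``: plateau / (1 + exp(-slope * (t - onset_min))).
    """

    kind: str = "delayed_onset"
    onset_min: float = 240.0
    plateau: float = 10.0
    slope: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "delayed_onset", "logistic"):
            raise ValueError(f"unknown secretion profile kind {self.kind!r}")
        if self.plateau < 0:
            raise ValueError("plateau concentration must be >= 0")

    def concentration(self, t_min):
        """Concentration at time ``t_min`` (minutes); vectorized, always >= 0."""
        t = np.asarray(t_min, dtype=float)
        if self.kind == "constant":
            c = np.full_like(t, self.plateau)
        elif self.kind == "delayed_onset":
            c = np.clip(self.slope * (t - self.onset_min), 0.0, self.plateau)
        else:  # logistic
            c = self.plateau / (1.0 + np.exp(-self.slope * (t - self.onset_min)))
        return c


@dataclass(frozen=True)
class PhantomConfig:
    """All parameters of a simulated run.

    Defaults mirror a typical acquisition: 10-minute frame interval over 20 h
    (121 frames), an 860 nm resonance, a tumoroid whose effective diameter sits
    near the 150 µm working range at 0.73 µm/px.  ``roles`` assigns each well
    ``tumoroid`` (detection well fed by a secreting tumoroid), ``reference``
    (drift only) or ``empty``.
    """

    n_wells: int = 4
    roles: tuple[str, ...] = ("tumoroid", "tumoroid", "reference", "reference")
    resonance: ResonanceModel = field(default_factory=ResonanceModel)
    kinetics: BindingKinetics = field(default_factory=BindingKinetics)
    secretion: SecretionProfile = field(default_factory=SecretionProfile)
    drift_nm_per_h: float = 0.015
    noise_sd: float = 0.004
    duration_min: float = 1200.0
    frame_interval_min: float = 10.0
    slit_pixels_per_well: int = 20
    wavelength_pixels: int = 512
    bf_image_size: int = 256
    pixel_size_um: float = 0.73
    radius_start_px: float = 95.0
    radius_end_px: float = 105.0
    step_sd_px: float = 1.0
    bf_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_min <= 0:
            raise ValueError("frame interval must be > 0")
        if self.duration_min < self.frame_interval_min:
            raise ValueError("duration must cover at least one frame interval")
        if len(self.roles) != self.n_wells:
            raise ValueError("roles must list one role per well")
        bad = set(self.roles) - {"tumoroid", "reference", "empty"}
        if bad:
            raise ValueError(f"unknown well roles: {sorted(bad)}")

    @property
    def times_min(self) -> np.ndarray:
        n = int(round(self.duration_min / self.frame_interval_min)) + 1
        return np.arange(n) * self.frame_interval_min

    def well_ids(self) -> list[str]:
        return [f"well{i:02d}" for i in range(self.n_wells)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roles"] = list(self.roles)
        d["resonance"]["band"] = list(self.resonance.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        d["roles"] = tuple(d["roles"])
        res = dict(d["resonance"])
        res["band"] = tuple(res["band"])
        d["resonance"] = ResonanceModel(**res)
        d["kinetics"] = BindingKinetics(**d["kinetics"])
        d["secretion"] = SecretionProfile(**d["secretion"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True signals underlying a rendered phantom, for recovery tests."""

    times_min: np.ndarray
    shift_traces_nm: dict[str, np.ndarray] = field(default_factory=dict)
    drift_nm: np.ndarray | None = None
    masks: np.ndarray | None = None  # frames x H x W bool
    areas_um2: np.ndarray | None = None
    centroids_um: np.ndarray | None = None  # frames x 2, (x, y)
    centers_px: np.ndarray | None = None  # continuous disk centers, (x, y)
    radii_px: np.ndarray | None = None


def simulate_binding_trace(
    kinetics: BindingKinetics,
    secretion: SecretionProfile | Callable[[float], float],
    times: Sequence[float],
) -> np.ndarray:
    """Integrate surface binding and return the resonance shift trace in nm.

    Solves dG/dt = k_on * C(t) * (gamma_max - G) - k_off * G with G(0) = 0
    using classical fixed-step RK4 with ten sub-steps per frame interval, and
    returns ``shift_per_coverage * G`` sampled on ``times`` (minutes).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise ValueError("times must be a 1-D grid")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    conc = secretion.concentration if isinstance(secretion, SecretionProfile) else secretion

    def rhs(t: float, g: float) -> float:
        return kinetics.k_on * float(conc(t)) * (kinetics.gamma_max - g) - kinetics.k_off * g

    gamma = np.empty_like(times)
    g = 0.0  # coverage starts at zero at times[0]
    gamma[0] = 0.0
    for i in range(1, len(times)):
        t0, t1 = times[i - 1], times[i]
        h = (t1 - t0) / 10.0
        t = t0
        for _ in range(10):
            k1 = rhs(t, g)
            k2 = rhs(t + h / 2, g + h / 2 * k1)
            k3 = rhs(t + h / 2, g + h / 2 * k2)
            k4 = rhs(t + h, g + h * k3)
            g += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        gamma[i] = g
    return kinetics.shift_per_coverage * gamma


def _drift_trace(config: PhantomConfig, drift_fn: Callable | None) -> np.ndarray:
    t = config.times_min
    if drift_fn is not None:
        return np.asarray([float(drift_fn(ti)) for ti in t])
    return config.drift_nm_per_h * t / 60.0


def render_spectral_stack(
    config: PhantomConfig,
    drift_fn: Callable[[float], float] | None = None,
) -> tuple[dict[str, SpectralImageStack], GroundTruth]:
    """Render per-well spectroscopic image stacks plus ground truth.

    Each frame holds, for every slit pixel of a well, the Lorentzian resonance
    sampled on the wavelength axis and centered at ``lambda0 + shift(t) +
    drift(t)`` (reference/empty wells carry drift only), with seeded Gaussian
    detector noise added per pixel.  ``drift_fn`` (nm as a function of minutes)
    overrides the default linear drift, e.g. to inject sinusoidal drift.
    """
    times = config.times_min
    res = config.resonance
    drift = _drift_trace(config, drift_fn)
    shift = simulate_binding_trace(config.kinetics, config.secretion, times)

    lo, hi = res.band
    margin = res.fwhm
    centers_all = res.lambda0 + drift
    centers_sig = centers_all + shift
    worst_lo = min(centers_all.min(), centers_sig.min())
    worst_hi = max(centers_all.max(), centers_sig.max())
    if worst_lo - margin < lo or worst_hi + margin > hi:
        raise ValueError(
            "spectrometer band too narrow: shifted peak reaches "
            f"[{worst_lo:.1f}, {worst_hi:.1f}] nm but band is [{lo}, {hi}] nm "
            f"(need {margin:.1f} nm margin for the window)"
        )

    wavelengths = np.linspace(lo, hi, config.wavelength_pixels)
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_wells + 1)
    truth = GroundTruth(times_min=times, drift_nm=drift)
    stacks: dict[str, SpectralImageStack] = {}
    for w, (well_id, role) in enumerate(zip(config.well_ids(), config.roles)):
        rng = np.random.default_rng(seqs[w])
        centers = centers_sig if role == "tumoroid" else centers_all
        frames = np.empty(
            (len(times), config.slit_pixels_per_well, config.wavelength_pixels)
        )
        for i, c in enumerate(centers):
            frames[i] = res.spectrum(wavelengths, c)[np.newaxis, :]
        if config.noise_sd > 0:
            frames = frames + rng.normal(0.0, config.noise_sd, size=frames.shape)
        stacks[well_id] = SpectralImageStack(
            intensity=frames,
            times=times,
            wavelength_axis=wavelengths,
            well_id=well_id,
            role="reference" if role != "tumoroid" else "detection",
        )
        truth.shift_traces_nm[well_id] = (
            shift.copy() if role == "tumoroid" else np.zeros_like(shift)
        )
    return stacks, truth


def render_brightfield_stack(
    config: PhantomConfig,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a bright-field stack of one wandering, growing tumoroid.

    The tumoroid is a disk with multiplicative speckle inside and a darker
    3-px rim, on a brighter noisy background — separable by a pixel
    classifier without being photorealistic.  Returns the float image stack
    (frames x H x W, values in [0, 1]) and ground truth with the true masks,
    mask areas (µm²) and mask centroids (µm, x/y order).
    """
    times = config.times_min
    n = len(times)
    size = config.bf_image_size
    radii = np.linspace(config.radius_start_px, config.radius_end_px, n)
    max_r = radii.max()
    wall = 2.0  # px kept clear of the image border
    if max_r + wall >= size / 2:
        raise ValueError(
            f"tumoroid radius {max_r:.0f} px does not fit a {size}-px well"
        )

    seqs = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(seqs[1])

    # bounded random walk of the disk center (reflecting at the well wall)
    centers = np.empty((n, 2))
    pos = np.array([size / 2.0, size / 2.0])
    for i in range(n):
        if i > 0 and config.step_sd_px > 0:
            pos = pos + rng.normal(0.0, config.step_sd_px, size=2)
        lo_b = radii[i] + wall
        hi_b = size - 1 - radii[i] - wall
        for ax in range(2):
            if pos[ax] < lo_b:
                pos[ax] = 2 * lo_b - pos[ax]
            elif pos[ax] > hi_b:
                pos[ax] = 2 * hi_b - pos[ax]
        centers[i] = pos

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    frames = np.empty((n, size, size), dtype=np.float32)
    masks = np.empty((n, size, size), dtype=bool)
    areas = np.empty(n)
    cents = np.empty((n, 2))
    for i in range(n):
        cx, cy = centers[i]
        r = radii[i]
        dist = np.hypot(xx - cx, yy - cy)
        mask = dist <= r
        rim = mask & (dist > r - 3.0)
        img = np.full((size, size), 0.85)
        speckle = 1.0 + 0.15 * rng.standard_normal((size, size))
        img[mask] = 0.55 * speckle[mask]
        img[rim] = 0.25
        img += rng.normal(0.0, config.bf_noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0.0, 1.0)
        masks[i] = mask
        areas[i] = mask.sum() * config.pixel_size_um**2
        ys, xs = np.nonzero(mask)
        cents[i] = (xs.mean() * config.pixel_size_um, ys.mean() * config.pixel_size_um)

    truth = GroundTruth(
        times_min=times,
        masks=masks,
        areas_um2=areas,
        centroids_um=cents,
        centers_px=centers,
        radii_px=radii,
    )
    return frames, truth


def write_phantom(config: PhantomConfig, outdir: str | Path) -> Path:
    """Render a full phantom run and write it to ``outdir``.

    Layout: one multi-page TIFF per spectral well (``spectral_<well>.tif``),
    one bright-field TIFF per tumoroid well, ground-truth CSV tables, a
    layout JSON for downstream stages and the full config as JSON sidecar.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stacks, truth = render_spectral_stack(config)
    wells = []
    for well_id, stack in stacks.items():
        tifffile.imwrite(outdir / f"spectral_{well_id}.tif", stack.intensity.astype(np.float32))
        role = config.roles[config.well_ids().index(well_id)]
        wells.append(
            {
                "id": well_id,
                "role": role,
                "slit_pixels": config.slit_pixels_per_well,
                "condition": "phantom",
            }
        )
        np.savetxt(
            outdir / f"truth_shift_{well_id}.csv",
            np.column_stack([truth.times_min, truth.shift_traces_nm[well_id]]),
            delimiter=",",
            header="time_min,shift_nm",
            comments="",
        )
    bf_truth_rows = None
    for well_id, role in zip(config.well_ids(), config.roles):
        if role != "tumoroid":
            continue
        frames, bft = render_brightfield_stack(
            dataclasses.replace(config, seed=config.seed + 1000 + config.well_ids().index(well_id))
        )
        tifffile.imwrite(
            outdir / f"brightfield_{well_id}.tif",
            (frames * 65535).astype(np.uint16),
        )
        bf_truth_rows = np.column_stack(
            [bft.times_min, bft.areas_um2, bft.centroids_um]
        )
        np.savetxt(
            outdir / f"truth_morphology_{well_id}.csv",
            bf_truth_rows,
            delimiter=",",
            header="time_min,area_um2,centroid_x_um,centroid_y_um",
            comments="",
        )
    layout = {
        "wavelength_band_nm": list(config.resonance.band),
        "wavelength_pixels": config.wavelength_pixels,
        "pixel_size_um": config.pixel_size_um,
        "frame_interval_min": config.frame_interval_min,
        "wells": wells,
    }
    (outdir / "layout.json").write_text(json.dumps(layout, indent=2))
    (outdir / "phantom_config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return outdir
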
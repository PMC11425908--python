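"""End-to-end runs: configuration, layout handling, orchestration, report.

The layout JSON is the single source of geometry truth: which wells exist,
their roles (detection vs reference), slit-pixel extents, frame interval and
pixel sizes.  ``run_pipeline`` chains tracking -> drift correction ->
sensorgrams -> kinetics (-> optional segmentation/motility when a trained
classifier is supplied) into one output tree with a machine-readable
manifest, and ``render_report`` draws the standard figure panels from that
tree.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import morphology_motility as mm
from . import sensorgram_kinetics as sk
from . import spectral_tracking as st

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_layout",
    "load_spectral_stacks",
    "run_pipeline",
    "render_report",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Condition labels (e.g. normoxia / hypoxia / hypoxia+ActD) are carried as
    metadata per well for group comparisons; no biology is computed from
    them.
    """

    stacks_dir: str
    layout_path: str
    out_dir: str
    units: str = "nm"  # "nm" when a wavelength axis is available, else "px"
    roi_height: int = 20
    level_times_h: tuple[float, ...] = (12.0, 20.0)
    level_half_window_h: float = 1.0
    end_level_half_window_h: float = 2.0
    diameter_range_um: tuple[float, float] = (130.0, 170.0)
    pixel_size_um: float = 0.73
    classifier_path: str | None = None
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["level_times_h"] = list(self.level_times_h)
        d["diameter_range_um"] = list(self.diameter_range_um)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["level_times_h"] = tuple(d["level_times_h"])
        d["diameter_range_um"] = tuple(d["diameter_range_um"])
        return cls(**d)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d["level_times_h"] = list(self.level_times_h)
        d["diameter_range_um"] = list(self.diameter_range_um)
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of a run: config hash, per-file checksums, warnings."""

    version: str
    config_digest: str
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def load_layout(path: str | Path) -> dict:
    layout = json.loads(Path(path).read_text())
    if "wells" not in layout or not layout["wells"]:
        raise ValueError("layout must declare at least one well")
    return layout


def _wavelength_axis(layout: dict) -> np.ndarray | None:
    if "wavelength_band_nm" in layout and "wavelength_pixels" in layout:
        lo, hi = layout["wavelength_band_nm"]
        return np.linspace(lo, hi, int(layout["wavelength_pixels"]))
    return None


def load_spectral_stacks(
    stacks_dir: str | Path, layout: dict, units: str = "nm"
) -> dict[str, st.SpectralImageStack]:
    """Read per-well multi-page spectral TIFFs declared in the layout."""
    stacks_dir = Path(stacks_dir)
    interval = float(layout.get("frame_interval_min", 10.0))
    axis = _wavelength_axis(layout) if units == "nm" else None
    stacks = {}
    for well in layout["wells"]:
        path = stacks_dir / f"spectral_{well['id']}.tif"
        if not path.exists():
            raise FileNotFoundError(f"missing spectral stack for well {well['id']}: {path}")
        frames = tifffile.imread(path).astype(float)
        times = np.arange(frames.shape[0]) * interval
        stacks[well["id"]] = st.SpectralImageStack(
            intensity=frames,
            times=times,
            wavelength_axis=axis,
            well_id=well["id"],
            role="reference" if well["role"] in ("reference", "empty") else "detection",
        )
    return stacks


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute tracking -> correction -> sensorgrams -> kinetics (+motility).

    Writes, under ``config.out_dir``: per-well corrected trace CSV, one
    sensorgram CSV per tumoroid (raw + smoothed), a kinetics summary CSV
    (levels, mean rate, rate SD per tumoroid), a pairwise group-comparison
    CSV when several conditions exist, an optional motility table, and the
    JSON manifest.  Any stage failure aborts with the stage and well id.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = load_layout(config.layout_path)
    manifest = RunManifest(version="plasmogram-0.1.0", config_digest=config.digest())

    stacks = load_spectral_stacks(config.stacks_dir, layout, units=config.units)
    detection = [s for s in stacks.values() if s.role == "detection"]
    references = [s for s in stacks.values() if s.role == "reference"]
    if not references:
        raise ValueError("pipeline requires at least one reference well")
    if not detection:
        raise ValueError("pipeline requires at least one detection well")

    conditions = {w["id"]: w.get("condition", "default") for w in layout["wells"]}

    try:
        ref_traces = [st.track_stack(s) for s in references]
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"stage=track (reference wells): {exc}") from exc

    traces = []
    rows = []
    cmp_rows: dict[str, dict[str, list[float]]] = {}
    for stack in detection:
        try:
            raw = st.track_stack(stack)
            corrected = st.reference_correct(raw, ref_traces)
            traces.append(corrected)
            sg = sk.build_spatiotemporal(corrected)
            if sg.excluded_positions:
                manifest.warnings.append(
                    f"well {stack.well_id}: excluded positions {sg.excluded_positions}"
                )
            roi = sk.ROI(
                start=int(sg.native_positions[0]
                          + max(0, (len(sg.native_positions) - config.roi_height) // 2)),
                height=min(config.roi_height, len(sg.native_positions)),
            )
            trace = sk.extract_temporal(sg, roi_left=roi, tumoroid_id=stack.well_id)
            kin = sk.secretion_rate(trace)
            t_end = trace.times_h[-1]
            row = {
                "tumoroid_id": stack.well_id,
                "condition": conditions.get(stack.well_id, "default"),
                "mean_rate": kin.mean_rate,
                "rate_sd": kin.rate_sd,
                "units": trace.units,
            }
            for t_level in config.level_times_h:
                half = (
                    config.end_level_half_window_h
                    if t_level >= t_end
                    else config.level_half_window_h
                )
                level = sk.secretion_level(trace, t_level, half)
                row[f"level_{t_level:g}h"] = level
                cmp_rows.setdefault(f"{t_level:g}h", {}).setdefault(
                    row["condition"], []
                ).append(level)
            rows.append(row)
            pd.DataFrame(
                {
                    "time_min": trace.times_min,
                    "raw": trace.raw,
                    "smoothed": trace.smoothed,
                    "rate_per_h": kin.rate_per_h,
                }
            ).to_csv(out / f"sensorgram_{stack.well_id}.csv", index=False)
            # spatiotemporal field (upsampled) for the heat-map panel
            pd.DataFrame(
                sg.up_values, index=sg.up_times, columns=sg.up_positions
            ).to_csv(out / f"spatiotemporal_{stack.well_id}.csv")
        except Exception as exc:
            raise RuntimeError(f"stage=kinetics well={stack.well_id}: {exc}") from exc

    st.save_traces_csv(traces, out / "traces.csv")
    pd.DataFrame(rows).to_csv(out / "kinetics_summary.csv", index=False)

    cmp_table = []
    for when, by_cond in cmp_rows.items():
        for ca, cb in itertools.combinations(sorted(by_cond), 2):
            if len(by_cond[ca]) >= 1 and len(by_cond[cb]) >= 1:
                u, p = sk.compare_groups(by_cond[ca], by_cond[cb])
                cmp_table.append(
                    {"time_point": when, "group_a": ca, "group_b": cb, "U": u, "p": p}
                )
    if cmp_table:
        pd.DataFrame(cmp_table).to_csv(out / "group_comparisons.csv", index=False)

    if config.classifier_path:
        try:
            _run_morphology(config, layout, out)
        except Exception as exc:
            raise RuntimeError(f"stage=morphology: {exc}") from exc

    for f in sorted(out.glob("*.csv")):
        manifest.checksums[f.name] = _sha256(f)
    manifest.save(out / "manifest.json")
    return manifest


def _run_morphology(config: RunConfig, layout: dict, out: Path) -> None:
    clf = mm.PixelClassifier.load(config.classifier_path)
    px = float(layout.get("pixel_size_um", config.pixel_size_um))
    interval = float(layout.get("frame_interval_min", 10.0))
    track_rows = []
    for well in layout["wells"]:
        path = Path(config.stacks_dir) / f"brightfield_{well['id']}.tif"
        if not path.exists():
            continue
        frames = tifffile.imread(path).astype(float)
        if frames.dtype.kind != "f" or frames.max() > 1.5:
            frames = frames / frames.max()
        masks = np.stack(
            [mm.postprocess_mask(mm.segment(f, clf))[0] for f in frames]
        )
        track = mm.measure_track(
            masks, px, times_min=np.arange(len(frames)) * interval,
            track_id=well["id"], condition=well.get("condition", "default"),
        )
        pd.DataFrame(
            {
                "time_min": track.times_min,
                "area_um2": track.areas_um2,
                "centroid_x_um": track.centroids_um[:, 0],
                "centroid_y_um": track.centroids_um[:, 1],
                "valid": track.valid,
            }
        ).to_csv(out / f"track_{well['id']}.csv", index=False)
        track_rows.append(track)
    if track_rows:
        kept = mm.motility_filter(track_rows, *config.diameter_range_um)
        kept_ids = {t.track_id for t in kept}
        pd.DataFrame(
            [
                {
                    "track_id": t.track_id,
                    "condition": t.condition,
                    "median_effective_diameter_um": t.median_effective_diameter_um,
                    "total_displacement_um": t.total_displacement_um,
                    "in_size_window": t.track_id in kept_ids,
                }
                for t in track_rows
            ]
        ).to_csv(out / "motility_summary.csv", index=False)


def render_report(out_dir: str | Path, dpi: int = 110) -> list[Path]:
    """Draw the standard panels from a completed run's output tree.

    Per tumoroid: the spatiotemporal heat map and the raw/smoothed trace
    with its rate curve.  Cohort panels (mean +/- across-tumoroid 95%
    t-interval band per condition; rate SD vs mean rate scatter) are drawn
    only when at least two tumoroids per condition exist.  Purely
    presentational — no statistic beyond the t-based band is introduced.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    out = Path(out_dir)
    figures: list[Path] = []
    summary_path = out / "kinetics_summary.csv"
    if not summary_path.exists():
        logger.warning("no kinetics summary in %s; report skipped", out)
        return figures
    summary = pd.read_csv(summary_path)

    for sg_path in sorted(out.glob("spatiotemporal_*.csv")):
        well = sg_path.stem.split("_", 1)[1]
        field = pd.read_csv(sg_path, index_col=0)
        fig, ax = plt.subplots(figsize=(6, 3))
        im = ax.pcolormesh(
            field.index.to_numpy() / 60.0,
            field.columns.to_numpy(dtype=float),
            field.to_numpy().T,
            shading="auto",
        )
        ax.set(xlabel="time (h)", ylabel="slit position (px)", title=f"{well} shift")
        fig.colorbar(im, ax=ax, label="shift")
        p = out / f"fig_spatiotemporal_{well}.png"
        fig.savefig(p, dpi=dpi)
        plt.close(fig)
        figures.append(p)

    for tr_path in sorted(out.glob("sensorgram_*.csv")):
        well = tr_path.stem.split("_", 1)[1]
        df = pd.read_csv(tr_path)
        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 5), sharex=True)
        t = df["time_min"] / 60.0
        ax1.plot(t, df["raw"], color="0.7", lw=0.8, label="raw")
        ax1.plot(t, df["smoothed"], color="tab:green", lw=1.5, label="smoothed")
        ax1.set_ylabel("shift")
        ax1.legend(frameon=False)
        ax2.plot(t, df["rate_per_h"], color="tab:blue", lw=1.2)
        ax2.set(xlabel="time (h)", ylabel="rate (shift/h)")
        fig.suptitle(f"{well} sensorgram")
        p = out / f"fig_sensorgram_{well}.png"
        fig.savefig(p, dpi=dpi)
        plt.close(fig)
        figures.append(p)

    by_cond = summary.groupby("condition")
    if any(len(g) >= 2 for _, g in by_cond):
        traces = {}
        for tr_path in sorted(out.glob("sensorgram_*.csv")):
            well = tr_path.stem.split("_", 1)[1]
            traces[well] = pd.read_csv(tr_path)
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for cond, g in by_cond:
            ids = [i for i in g["tumoroid_id"] if i in traces]
            if len(ids) < 2:
                continue
            mat = np.stack([traces[i]["smoothed"].to_numpy() for i in ids])
            t = traces[ids[0]]["time_min"].to_numpy() / 60.0
            mean = mat.mean(axis=0)
            sem = mat.std(axis=0, ddof=1) / np.sqrt(len(ids))
            tcrit = sps.t.ppf(0.975, df=len(ids) - 1)
            ax.plot(t, mean, label=cond)
            ax.fill_between(t, mean - tcrit * sem, mean + tcrit * sem, alpha=0.3)
        ax.set(xlabel="time (h)", ylabel="shift", title="cohort mean ± 95% CI")
        ax.legend(frameon=False)
        p = out / "fig_cohort_mean.png"
        fig.savefig(p, dpi=dpi)
        plt.close(fig)
        figures.append(p)

        fig, ax = plt.subplots(figsize=(4.2, 4))
        for cond, g in by_cond:
            ax.scatter(g["mean_rate"], g["rate_sd"], label=cond, s=24)
        ax.set(xlabel="mean secretion rate (shift/h)", ylabel="rate SD (shift/h)")
        ax.legend(frameon=False)
        p = out / "fig_rate_scatter.png"
        fig.savefig(p, dpi=dpi)
        plt.close(fig)
        figures.append(p)
    else:
        logger.warning("fewer than 2 tumoroids per condition; cohort panels skipped")

    motility = out / "motility_summary.csv"
    if motility.exists():
        df = pd.read_csv(motility)
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        for cond, g in df.groupby("condition"):
            ax.scatter(
                g["median_effective_diameter_um"], g["total_displacement_um"],
                label=cond, s=24,
            )
        ax.axvspan(130, 170, color="0.9", zorder=0)
        ax.set(xlabel="median effective diameter (µm)", ylabel="total displacement (µm)")
        ax.legend(frameon=False)
        p = out / "fig_motility.png"
        fig.savefig(p, dpi=dpi)
        plt.close(fig)
        figures.append(p)
    return figures
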
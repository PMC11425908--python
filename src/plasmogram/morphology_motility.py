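"""Bright-field tumoroid segmentation, size and motility analysis.

A multiscale per-pixel feature bank (Gaussian smoothing, Laplacian of
Gaussian, Gaussian gradient magnitude, difference of Gaussians, structure
tensor and Hessian eigenvalue summaries — 37 values per pixel at the default
radii) feeds a 100-tree random-forest pixel classifier that separates
tumoroid from background.  Masks are post-processed to a single filled
component; per-frame area and centroid give the growth curve and, summed
over frame-to-frame centroid moves, the total displacement used as the
motility measure.  Size-window filtering (effective diameter 150 +/- 20 µm
by default) removes the confound of well geometry on motility.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import measure as skmeasure
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "FeatureBankConfig",
    "PixelClassifier",
    "TumoroidTrack",
    "compute_features",
    "train_classifier",
    "segment",
    "postprocess_mask",
    "measure_track",
    "motility_filter",
    "effective_diameter",
]

TUMOROID_LABEL = 1
BACKGROUND_LABEL = 2


@dataclass(frozen=True)
class FeatureBankConfig:
    """Multiscale feature bank: which filters at which kernel radii.

    Radii act as Gaussian sigmas in pixels.  Eigenvalue-based features
    (structure tensor, Hessian) contribute one scalar per radius under the
    default ``eigen_summary="largest"`` so the default bank is exactly
    37-dimensional (7 Gaussian radii + 5 further feature kinds x 6 radii);
    ``"both"`` keeps both eigenvalues (49 features).
    """

    gaussian_radii: tuple[float, ...] = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0)
    other_radii: tuple[float, ...] = (0.7, 1.0, 1.6, 3.5, 5.0, 10.0)
    eigen_summary: str = "largest"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.gaussian_radii + self.other_radii):
            raise ValueError("kernel radii must be positive")
        if self.eigen_summary not in ("largest", "both"):
            raise ValueError("eigen_summary must be 'largest' or 'both'")

    @property
    def n_features(self) -> int:
        per_eigen = 1 if self.eigen_summary == "largest" else 2
        n_scalar_kinds = 3  # LoG, gradient magnitude, DoG
        n_eigen_kinds = 2  # structure tensor, Hessian
        return len(self.gaussian_radii) + len(self.other_radii) * (
            n_scalar_kinds + n_eigen_kinds * per_eigen
        )

    def digest(self) -> str:
        payload = json.dumps(
            [list(self.gaussian_radii), list(self.other_radii), self.eigen_summary]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def compute_features(image: np.ndarray, config: FeatureBankConfig | None = None) -> np.ndarray:
    """Per-pixel feature vectors for a single-channel image.

    Returns an (H, W, n_features) float32 array.  Feature order: Gaussian
    smoothing at each Gaussian radius, then per non-Gaussian kind (LoG,
    gradient magnitude, DoG, structure-tensor eigenvalues, Hessian
    eigenvalues) at each of the other radii.
    """
    if config is None:
        config = FeatureBankConfig()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("compute_features expects a single-channel 2-D image")
    if max(config.gaussian_radii + config.other_radii) >= min(img.shape) / 4:
        raise ValueError("kernel radii must be smaller than image size / 4")

    planes: list[np.ndarray] = []
    for r in config.gaussian_radii:
        planes.append(ndimage.gaussian_filter(img, r))
    for r in config.other_radii:
        # discrete Laplacian of the smoothed image: zero-sum stencil, so
        # constant regions map to exactly zero (sampled-Gaussian LoG kernels
        # carry a small truncation offset)
        planes.append(ndimage.laplace(ndimage.gaussian_filter(img, r)))
    for r in config.other_radii:
        planes.append(ndimage.gaussian_gradient_magnitude(img, r))
    for r in config.other_radii:
        planes.append(ndimage.gaussian_filter(img, r) - ndimage.gaussian_filter(img, 1.6 * r))
    for r in config.other_radii:
        tensor = skfeature.structure_tensor(img, sigma=r, order="rc")
        eig = skfeature.structure_tensor_eigenvalues(tensor)  # descending
        planes.append(eig[0])
        if config.eigen_summary == "both":
            planes.append(eig[1])
    for r in config.other_radii:
        hess = skfeature.hessian_matrix(
            img, sigma=r, order="rc", use_gaussian_derivatives=True
        )
        eig = skfeature.hessian_matrix_eigvals(hess)  # descending
        planes.append(eig[0])
        if config.eigen_summary == "both":
            planes.append(eig[1])

    out = np.stack(planes, axis=-1).astype(np.float32)
    assert out.shape[-1] == config.n_features
    return out


@dataclass
class PixelClassifier:
    """Trained two-class random-forest pixel classifier with provenance."""

    model: RandomForestClassifier
    config: FeatureBankConfig
    config_digest: str
    n_tumoroid_px: int
    n_background_px: int
    seed: int

    def metadata(self) -> dict:
        return {
            "n_trees": self.model.n_estimators,
            "feature_config_digest": self.config_digest,
            "n_features": self.config.n_features,
            "n_tumoroid_px": self.n_tumoroid_px,
            "n_background_px": self.n_background_px,
            "seed": self.seed,
            "max_depth": self.model.max_depth,
            "max_features": self.model.max_features,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump({"model": self.model, "config": self.config, "meta": self.metadata()}, path)
        path.with_suffix(".json").write_text(json.dumps(self.metadata(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        blob = joblib.load(path)
        meta = blob["meta"]
        return cls(
            model=blob["model"],
            config=blob["config"],
            config_digest=meta["feature_config_digest"],
            n_tumoroid_px=meta["n_tumoroid_px"],
            n_background_px=meta["n_background_px"],
            seed=meta["seed"],
        )


def train_classifier(
    images: np.ndarray,
    label_masks: np.ndarray,
    config: FeatureBankConfig | None = None,
    seed: int = 0,
    max_samples_per_class: int | None = 20000,
) -> PixelClassifier:
    """Train the 100-tree random forest on labeled pixels.

    ``label_masks`` use 0 = unlabeled (ignored), 1 = tumoroid,
    2 = background.  Labeled pixels beyond ``max_samples_per_class`` are
    subsampled with the given seed; training is fully reproducible.
    """
    if config is None:
        config = FeatureBankConfig()
    images = np.asarray(images, dtype=float)
    labels = np.asarray(label_masks)
    if images.ndim == 2:
        images = images[np.newaxis]
        labels = labels[np.newaxis]
    if images.shape != labels.shape:
        raise ValueError("images and label masks must share shape")

    feats = []
    labs = []
    for img, lab in zip(images, labels):
        sel = lab > 0
        if sel.any():
            f = compute_features(img, config)
            feats.append(f[sel])
            labs.append(lab[sel])
    if not feats:
        raise ValueError("no labeled pixels")
    x = np.concatenate(feats)
    y = np.concatenate(labs)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels must contain both tumoroid and background pixels")

    rng = np.random.default_rng(seed)
    if max_samples_per_class is not None:
        keep = []
        for cl in classes:
            idx = np.nonzero(y == cl)[0]
            if len(idx) > max_samples_per_class:
                idx = rng.choice(idx, size=max_samples_per_class, replace=False)
            keep.append(idx)
        keep = np.sort(np.concatenate(keep))
        x, y = x[keep], y[keep]

    model = RandomForestClassifier(
        n_estimators=100, random_state=int(seed), n_jobs=1
    )
    model.fit(x, y)
    return PixelClassifier(
        model=model,
        config=config,
        config_digest=config.digest(),
        n_tumoroid_px=int(np.sum(y == TUMOROID_LABEL)),
        n_background_px=int(np.sum(y == BACKGROUND_LABEL)),
        seed=int(seed),
    )


def segment(
    image: np.ndarray,
    classifier: PixelClassifier,
    config: FeatureBankConfig | None = None,
) -> np.ndarray:
    """Classify every pixel; returns a boolean tumoroid mask.

    The feature configuration must match the one used at training time
    (checked by digest); inverted-contrast images relative to training are
    unsupported and will simply segment poorly — there is no silent
    auto-correction.
    """
    cfg = config if config is not None else classifier.config
    if cfg.digest() != classifier.config_digest:
        raise ValueError("feature configuration differs from training")
    f = compute_features(image, cfg)
    pred = classifier.model.predict(f.reshape(-1, f.shape[-1]))
    return pred.reshape(image.shape) == TUMOROID_LABEL


def postprocess_mask(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Largest 8-connected component with its holes filled.

    Ties on component size go to the component whose first pixel comes
    earliest in row-major order.  Returns (mask, valid); an empty input
    yields an empty mask flagged invalid rather than an error.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m), False
    lab = skmeasure.label(m, connectivity=2)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    best = counts.max()
    candidates = np.nonzero(counts == best)[0]
    if len(candidates) == 1:
        chosen = candidates[0]
    else:
        flat = lab.ravel()
        first = {int(c): int(np.argmax(flat == c)) for c in candidates}
        chosen = min(first, key=first.get)
    comp = lab == chosen
    return ndimage.binary_fill_holes(comp), True


def effective_diameter(area: float) -> float:
    """Diameter of the circle with the same area: 2 * sqrt(area / pi)."""
    return 2.0 * np.sqrt(area / np.pi)


@dataclass
class TumoroidTrack:
    """Per-frame size and position of one tumoroid, plus motility summary.

    Areas are in µm², centroids in µm ((x, y) = (column, row) scaled by the
    pixel size).  ``step_displacements_um[i]`` is the move from frame i-1 to
    frame i (NaN when either frame is invalid — invalid frames break the
    chain); their sum is the total displacement.
    """

    times_min: np.ndarray
    areas_um2: np.ndarray
    centroids_um: np.ndarray  # frames x 2
    valid: np.ndarray
    pixel_size_um: float
    track_id: str = ""
    condition: str = ""
    step_displacements_um: np.ndarray = field(default=None)  # type: ignore[assignment]
    total_displacement_um: float = 0.0

    @property
    def effective_diameters_um(self) -> np.ndarray:
        return effective_diameter(self.areas_um2)

    @property
    def median_effective_diameter_um(self) -> float:
        d = self.effective_diameters_um[self.valid]
        return float(np.median(d)) if len(d) else float("nan")


def measure_track(
    mask_stack: np.ndarray,
    pixel_size_um: float,
    times_min: np.ndarray | None = None,
    track_id: str = "",
    condition: str = "",
) -> TumoroidTrack:
    """Measure area, centroid and displacement from post-processed masks.

    Area is the pixel count scaled by pixel_size²; the centroid is the
    unweighted mean of mask pixel coordinates scaled by the pixel size.
    Steps are Euclidean distances between centroids of *consecutive* valid
    frames only; an invalid frame contributes no step on either side.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    masks = np.asarray(mask_stack, dtype=bool)
    if masks.ndim == 2:
        masks = masks[np.newaxis]
    n = masks.shape[0]
    times = np.asarray(times_min, dtype=float) if times_min is not None else np.arange(n, dtype=float)

    areas = np.full(n, np.nan)
    cents = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        npx = masks[i].sum()
        if npx == 0:
            continue
        valid[i] = True
        areas[i] = npx * pixel_size_um**2
        ys, xs = np.nonzero(masks[i])
        cents[i] = (xs.mean() * pixel_size_um, ys.mean() * pixel_size_um)
    if not valid.any():
        raise ValueError("empty track: all frames invalid")

    steps = np.full(n, np.nan)
    for i in range(1, n):
        if valid[i] and valid[i - 1]:
            steps[i] = float(np.hypot(*(cents[i] - cents[i - 1])))
    total = float(np.nansum(steps))
    return TumoroidTrack(
        times_min=times,
        areas_um2=areas,
        centroids_um=cents,
        valid=valid,
        pixel_size_um=pixel_size_um,
        track_id=track_id,
        condition=condition,
        step_displacements_um=steps,
        total_displacement_um=total,
    )


def motility_filter(
    tracks: list[TumoroidTrack], d_min: float = 130.0, d_max: float = 170.0
) -> list[TumoroidTrack]:
    """Keep tracks whose median effective diameter lies in [d_min, d_max].

    Bounds are inclusive; the default window is the 150 +/- 20 µm size range
    that decouples motility from how much room a tumoroid has in its well.
    """
    if d_min > d_max:
        raise ValueError("d_min must be <= d_max")
    return [
        t for t in tracks if d_min <= t.median_effective_diameter_um <= d_max
    ]
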
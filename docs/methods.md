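# Methods

## Detection model and signal chain

The sensor signal is the wavelength position of an extraordinary-optical-
transmission (EOT) resonance. The analysis chain is:

1. **Window definition** (per slit pixel, from the T = 0 frame only): the
   resonance peak is the global maximum of the spectrum; the valley is the
   lower of the two minima flanking it; the threshold θ sits at 50% of
   peak-to-valley; the window is the maximal contiguous run of samples ≥ θ
   around the peak. The window is *fixed* for the whole run — re-fitting
   per frame would trade a small attenuation bias for window-jitter noise,
   and a shift large enough to leave the window is flagged rather than
   silently biased.
2. **Centroid**: `c = Σ λᵢ·(Iᵢ − θ)₊ / Σ (Iᵢ − θ)₊` over the window, with
   negative weights clipped. On a symmetric peak this is exact; under a
   shift s it responds as ≈ s − α·s² with α ∝ 1/FWHM (the window truncates
   the shifted half-maximum region on one side). With shifts of a few
   tenths of a nm against a 12 nm linewidth the quadratic term stays below
   0.01 nm, which is the regime the phantom emulates.
3. **Reference correction**: shift-from-T0 minus the mean shift-from-T0 of
   all reference-well slit pixels (NaN centroids dropped per frame). The
   result is exactly zero at T = 0. Because of the quadratic tracker
   response, a drift d common to all wells leaves a residual cross-term
   ≈ 2·α·b·d on a binding signal b; at the default scales this sits below
   the tracker noise and is budgeted under drift rejection, not noise.
4. **Sensorgrams**: per-position zero-offset at T = 0, NaNs filled by
   linear interpolation in time (positions over 50% flagged are excluded),
   then 5× piecewise-linear upsampling on both axes with original samples
   preserved exactly (n → 5(n−1)+1). The temporal trace averages a
   20-native-pixel ROI per detection well and then the two wells flanking
   the tumoroid.
5. **Smoothing**: running median (5 native frames, i.e. 25 upsampled
   samples) to kill single-frame spikes, then Lowess (span 0.15 of the
   series, one robustness iteration) for broadband noise. Constant traces
   are exact fixed points; both parameters are exposed in
   `smooth_trace`.
6. **Kinetics**: levels are means of the smoothed trace over configurable
   windows (default ±1 h; end-of-run levels use the trailing 2 h, the
   window clipping at the last sample). The secretion rate is the central
   finite difference of the smoothed trace per hour; no separate
   derivative filter is applied — noise control lives entirely in the
   smoothing. Onset is the first crossing of 10% of the final level, with
   sub-sample linear interpolation. Group comparisons use the two-sided
   Mann–Whitney U with midranks (exact p for min(n) ≤ 8 without ties,
   normal approximation with tie correction otherwise).

## Calibration

LOD = 3.3·σ/S with σ the SD (ddof = 1) of ≥ 3 replicate responses at
blank/lowest concentration and S the least-squares slope over the lower
concentration range — by default the lowest four points, shrunk to the
points below half-saturation when the curve bends earlier. Response
inversion divides by S within the fitted range only, flagging estimates
below the LOD; no extrapolation. A Langmuir fit is available for full
synthetic curves but never feeds the LOD.

## Morphometry

The per-pixel feature bank follows the ilastik convention: Gaussian
smoothing at radii (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0) px and, at the six
radii ≥ 0.7 px, Laplacian of Gaussian, Gaussian gradient magnitude,
difference of Gaussians (σ vs 1.6σ), and the largest eigenvalue of the
structure tensor and of the Hessian — 37 values per pixel. Keeping one
eigenvalue per tensor feature is deliberate: emitting both would give 49
features; a `both` mode exists but 37 is the default. The LoG is computed
as a discrete Laplacian of the Gaussian-smoothed image so that its kernel
sums to exactly zero (sampled-Gaussian LoG kernels carry a small
truncation offset on constant regions).

Segmentation is a 100-tree random forest (scikit-learn defaults
otherwise: unlimited depth, √d features per split, recorded in the
classifier metadata), trained on labeled pixels only (0 = unlabeled,
1 = tumoroid, 2 = background) with seeded subsampling. Masks keep the
largest 8-connected component (ties broken by first pixel in row-major
order) and fill its enclosed holes; empty masks are flagged invalid, not
raised. Area is pixel count × pixel-size², centroid the unweighted mean
of mask coordinates; the default pixel size 0.73 µm/px is the 7.3 µm
camera pixel behind a 10× objective and is overridable. Steps are
Euclidean distances between centroids of consecutive valid frames —
invalid frames break the chain — and their sum is the total displacement.
The motility size filter keeps tracks whose *median* effective diameter
over valid frames lies in the inclusive 130–170 µm window (the per-track
median is robust to single bad frames; the choice per-track vs per-frame
was open and is configurable only through re-measurement).

## The phantom

The synthetic generator produces what the instrument would: per-well
spectroscopic stacks (frames × slit pixels × wavelength pixels) and
bright-field stacks, plus the ground truth behind them.

- **Resonance**: symmetric Lorentzian transmission peak (λ₀ = 860 nm,
  FWHM 12 nm, peak 1.0, baseline 0.05) on an 800–920 nm band sampled at
  512 pixels (≈ 0.23 nm/px). A Lorentzian is the simplest peaked shape
  with an analytic half-maximum width for window tests; real EOT lines are
  Fano-asymmetric, which the tracker does not require.
- **Binding**: first-order Langmuir kinetics
  dΓ/dt = k_on·C(t)·(Γ_max − Γ) − k_off·Γ, integrated with classical RK4
  at one tenth of the frame interval (a fixed explicit step; fine enough
  that the constant-C closed form is matched to 1e−6 relative). The shift
  is 0.3 nm per unit saturation coverage — about two spectrometer pixels,
  the scale of real single-tumoroid signals. Concentration profiles:
  constant, delayed-onset (default: ramp starting at 4 h, the onset the
  biology shows), or logistic.
- **Drift and noise**: common-mode drift, default 0.015 nm/h (≈ 0.3 nm
  over 20 h, comparable to the signal — the regime where reference
  correction earns its keep; arbitrary drift shapes can be injected), and
  i.i.d. Gaussian detector noise, default SD 0.004 of the unit peak
  (SNR ≈ 250, a deep-cooled CCD at reasonable well depth).
- **Timing**: 10-minute frames over 20 h → 121 frames, matching the
  acquisition cadence of the real experiment.
- **Bright-field**: a disk with multiplicative speckle interior (mean
  0.55, 15% speckle), a darker 3 px rim (0.25) on a bright background
  (0.85, 3% noise), radius following a configured trajectory and centroid
  following a seeded random walk reflected at the well wall. The texture
  is designed to be separable by a pixel classifier, not photorealistic.
- **Determinism**: one seed feeds a splittable `SeedSequence`; identical
  configs render bit-identical stacks, and the ground-truth binding trace
  is independent of noise and drift settings by construction.

What the phantom does *not* emulate — and what passing recovery tests
therefore do not certify for real data: Fano line-shape asymmetry and
spatial inhomogeneity of the resonance along the slit; correlated
(non-white) detector noise and drift that is not perfectly common-mode;
diffusion gradients within a well (concentration is well-mixed by
assumption); tumoroids that are non-convex, multiple, or touching the
well wall; and illumination changes between training and inference for
the classifier (inverted contrast is explicitly unsupported).

## Problem sizes and numerical choices

Recovery benchmarks run at the full 121-frame, 4-well geometry with 20
slit pixels per well. Segmentation benchmarks use 30 frames of 128 px
phantoms (20 training, 10 held-out, ≤ 8000 labeled pixels per class) —
small enough to iterate quickly, large enough that held-out accuracy is
meaningful at the default contrast. Centroids are NaN-flagged when all
clipped weights vanish and are never interpolated before the sensorgram
stage; ties in the window run and in connected-component size break
deterministically (first in scan order). Statistical tolerances in the
test suite mirror the analytic expectations stated above, not tuned
margins.

## Known limitations

- The fixed-window centroid attenuates large shifts quadratically; shifts
  approaching half the linewidth need a wider window or re-centering,
  which the pipeline deliberately does not do (it flags instead).
- Shift units convert to concentration only through a user-supplied
  calibration; the slit monitors part of the well, so absolute secreted
  mass is out of reach by design.
- The Mann–Whitney exact path is limited to min(n) ≤ 8 without ties;
  beyond that the tie-corrected normal approximation is used.
- One tumoroid per well is assumed throughout tracking and morphometry.
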
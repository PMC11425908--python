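# plasmogram

Label-free analysis of protein secretion from single tumoroids on
nanohole-array (EOT) plasmonic microwell biosensors, plus machine-learning
bright-field morphometry — implemented as a tested, reusable Python
pipeline with a synthetic optofluidic phantom so every stage can be
validated without instrument data.

## The problem

A gold nanohole array transmits light anomalously (extraordinary optical
transmission) at a resonance wavelength λ near 860 nm that depends on the
refractive index at its surface. When proteins secreted by a tumoroid bind
antibodies functionalized on the sensor, the resonance red-shifts; the
shift Δλ(t) tracked over time is a *sensorgram* of secretion. In a
microwell chip, detection wells flank each tumoroid well and empty wells
serve as references for common-mode drift. In parallel, bright-field
frames of each well record tumoroid growth and movement.

The quantities the pipeline computes:

- **Δλ(t)** per slit pixel: the baseline-clipped intensity centroid
  `c = Σ λᵢ (Iᵢ − θ)₊ / Σ (Iᵢ − θ)₊` inside a fixed wavelength window at
  50% of peak-to-valley intensity (θ), defined once at T = 0, minus the
  mean reference-well shift.
- **Temporal sensorgram**: ROI-averaged (20 slit pixels), left/right-well
  averaged, 5× upsampled, median+Lowess smoothed Δλ(t).
- **Secretion kinetics**: levels at named time points (e.g. 12 h, 20 h),
  the secretion rate dΔλ/dt (first derivative of the smoothed trace), its
  mean and SD, and Mann–Whitney U comparisons between conditions.
- **Calibration**: low-range slope S, blank noise σ, and the limit of
  detection LOD = 3.3 σ / S.
- **Morphometry**: a 37-feature multiscale filter bank + 100-tree random
  forest segments the tumoroid; area (µm²), effective diameter
  2·√(area/π), and total centroid displacement quantify growth and
  motility, with a 150 ± 20 µm size window decoupling motility from well
  geometry.

## Worked example

Generate a default phantom (four wells: two detection wells flanking a
secreting tumoroid with a 4 h delayed onset, two references; 121 frames at
10-minute intervals over 20 h) and run the spectral chain:

```python
from plasmogram import phantom, spectral_tracking as st, sensorgram_kinetics as sk

cfg = phantom.PhantomConfig(seed=1)
stacks, truth = phantom.render_spectral_stack(cfg)
refs = [st.track_stack(s) for s in stacks.values() if s.role == "reference"]
sgs = [sk.build_spatiotemporal(st.reference_correct(st.track_stack(stacks[w]), refs))
       for w in ("well00", "well01")]
tem = sk.extract_temporal(sgs[0], sgs[1], tumoroid_id="tumoroid-0")
kin = sk.secretion_rate(tem)
print(f"secretion level @12 h : {sk.secretion_level(tem, 12, 1):.3f} nm")
print(f"secretion level @20 h : {sk.secretion_level(tem, 20, 2):.3f} nm")
print(f"mean secretion rate   : {kin.mean_rate:.4f} nm/h (SD {kin.rate_sd:.4f})")
print(f"secretion onset       : {sk.onset_time(tem):.2f} h")
```

prints

```
secretion level @12 h : 0.154 nm
secretion level @20 h : 0.227 nm
mean secretion rate   : 0.0115 nm/h (SD 0.0082)
secretion onset       : 5.98 h
```

i.e. the tracked, drift-corrected, smoothed sensorgram recovers the
injected binding trace (true final shift 0.246 nm) to within a few
percent, and the onset detector places the 10%-of-final-level crossing
about 2 h after secretion begins at 4 h (the surface coverage needs that
long to reach 10% of its final value — compare against the same detector
applied to the ground-truth trace, not against the raw 4 h switch-on).

The same flow is available from the shell:

```bash
plasmogram simulate --out run1 --seed 1
plasmogram track --stacks run1 --layout run1/layout.json --units nm --out run1/traces.csv
plasmogram kinetics --traces run1/traces.csv --layout run1/layout.json --levels 12,20 --out run1/kinetics
plasmogram report --out-dir run1/kinetics
```

plus `calibrate`, `segment-train`, `segment`, `motility`, and `run` (full
pipeline from a YAML config).

## Layout

```
src/plasmogram/
  phantom.py              synthetic spectral + bright-field stacks with ground truth
  spectral_tracking.py    window definition, peak centroid, drift correction
  sensorgram_kinetics.py  sensorgrams, smoothing, levels, rates, group tests
  calibration.py          concentration-response fit, LOD = 3.3σ/S
  morphology_motility.py  feature bank, random-forest segmentation, tracks
  workflow_io.py          run orchestration, layout/manifest, figure report
  validation.py           phantom-based recovery benchmarks
  cli.py                  click command-line interface
```

See `docs/methods.md` for the models, parameter choices and limitations.
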
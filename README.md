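# spikecal

Calibration analysis for paired cell-attached electrophysiology and
two-photon GCaMP6 calcium imaging: how reliably can action potentials (APs)
be detected in fluorescence, and how does that reliability degrade under
population-imaging conditions?

`spikecal` is aimed at labs that characterize the AP-to-fluorescence
transfer function of genetically encoded calcium indicators with
simultaneous ground-truth recordings. It implements the full analysis
chain as a tested Python library:

- **synthetic_data** — a generator of paired recordings (40 kHz voltage
  trace + ~158 fps movie) with Poisson AP trains, difference-of-exponential
  calcium transients, r-scaled neuropil contamination, Poisson photon shot
  noise, and injectable artifacts (drift, photobleaching, waveform change,
  AP loss). Hidden ground truths ride along for recovery tests.
- **ephys** — AP detection (250–5000 Hz band-pass + 5×std, or 10× the
  Quiroga threshold median(|V|)/0.6745) and a 35-metric quality-control
  battery with a reference-range gate.
- **imaging** — ROI traces, neuropil subtraction
  F_true(t) = F_meas(t) − r·F_np(t) with the 0.8→0.7→0.6→0.5 fallback,
  isolated-event bookkeeping (≤5 APs within 250 ms, indicator-specific
  isolation margins), ΔF/F = (F − F0_local)/F0_global, transient fits
  A·(e^(−t/τ_d) − e^(−t/τ_r)), photon-transfer (variance-vs-mean) gain
  calibration, and trial-to-trial variability.
- **detection** — ground-truth-optimized event detection: zero-mean unit
  template projection, noise-percentile threshold sweep (so the sweep
  position *is* the false-positive probability), ROC area, and selection of
  the neuropil r that maximizes it.
- **downsample** — 4× spatial / 5× temporal block downsampling with all 20
  phase variants and 400 tiled ROIs, DBSCAN + KS trace QC, AP-train-guided
  cluster-combination selection against a Poisson-train null, and a robust
  (median-based) noise estimate.
- **inference_eval** — native non-negative deconvolution (NND)
  min_s ‖F − K∗s‖² with s ≥ 0, solved to KKT optimality, optional fine-grid
  (upsampled) solving, and an evaluation harness (binned Pearson, Matthews
  correlation, per-AP-class ROC at fixed false-positive probability) that
  accepts any algorithm's non-negative per-frame output.

## Worked example

```python
import numpy as np
from spikecal import SimConfig, simulate_ap_train, render_movie
from spikecal.imaging import extract_traces
from spikecal.detection import optimize_r, detection_probability

cfg = SimConfig(seed=3, duration_s=180.0, fov_px=(44, 44), soma_radius_px=6,
                indicator="6f", firing_rate=2.0, neuropil_amp=0.5,
                neuropil_rate=10.0, r_true=0.8, baseline_photons=0.45,
                neuropil_ring_px=(2, 12), pedestal=0.0)
aps = simulate_ap_train(cfg)                   # 354 APs in 180 s
rec = render_movie(aps, cfg)
f_cell, f_np = extract_traces(rec.movie, rec.soma_mask, rec.neuropil_mask,
                              cfg.frame_rate)
res = optimize_r(f_cell, f_np, aps, indicator="6f")
print(res.r_opt)                               # 0.85
print(round(detection_probability(res.roc_opt, fp=0.01), 2))   # 0.87
```

The recording was contaminated with neuropil scaled by r_true = 0.8; the
ROC-area optimization lands one grid step away at `r_opt = 0.85` (the grid
is 0–1.2 in steps of 0.05), and at that r 87% of isolated single-AP events
are detected at a 1% false-positive probability.

A thin CLI mirrors the library (`spikecal simulate/qc/events/detect/
downsample/infer/evaluate`); run `spikecal --help`.

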
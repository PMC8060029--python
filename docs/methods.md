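# Methods

## The generative model

A paired recording consists of a cell-attached voltage trace and a
two-photon movie sharing one clock (t = 0 aligned exactly; an optional
uniform sub-frame offset models acquisition jitter).

**AP train.** A renewal process with inter-AP intervals
refractory + Exp(λ), giving an effective rate λ/(1 + λ·refractory).
Defaults: λ = 2 Hz, refractory 3 ms — typical of L2/3 pyramidal neurons
under light anesthesia. A sinusoidal rate modulation (`rate_mod_frac`,
implemented by thinning) emulates slow anesthesia-driven firing-rate
fluctuation; linear trends in AP amplitude and noise amplitude emulate
slow seal/electrode changes. These nonstationarities exist so that a
reference set of "good" recordings spans realistic heterogeneity — a
range-based QC gate is only as tolerant as the spread of its reference.

**Voltage.** Resting potential −45 mV plus Gaussian noise (default
sd 0.02 mV), optional linear drift, and one stereotyped biphasic waveform
per AP: a positive Gaussian lobe (amplitude 1 mV, FWHM 1 ms by default)
followed by a 20%-deep, 2.5×-wider after-hyperpolarizing lobe. Cell-attached
recordings do not constrain the waveform shape beyond its scale; the gentle
negative lobe was chosen so that zero-phase band-pass
filtering does not ring above detection thresholds.

**Calcium transients.** The single-AP kernel is the difference of
exponentials k(t) ∝ e^(−t/τ_d) − e^(−t/τ_r), peak-normalized so event
amplitudes read in ΔF/F units. Indicator defaults are order-of-magnitude
literature values, not fitted constants: GCaMP6s τ_r = 50 ms, τ_d = 600 ms,
0.25 ΔF/F per AP; GCaMP6f τ_r = 15 ms, τ_d = 200 ms, 0.15 ΔF/F per AP.
APs are grouped into 250 ms events; an n-AP event contributes
per_ap_gain[n]·n·amp·k(t − t_first). The default gain vector is linear
(all ones), matching the approximately linear growth of peak ΔF/F with AP
count in this regime.

**Movie.** Background pixels rest at `baseline_photons` × a static
lognormal brightness texture (sd 0.25 — expression variation and
vignetting; without spread in pixel means the variance-vs-mean photon
calibration would be ill-posed). Soma pixels are `soma_brightness` (2×)
brighter and additionally receive the point-spread-function leak of the
surrounding neuropil — baseline *and* transients — scaled by r_true:

    rate = B·tex·[ sb·(1 + soma ΔF/F) + r_true·(1 + neuropil ΔF/F) ]

so subtracting r_true × the neuropil-ring trace recovers the pure somatic
fluorescence. Getting this bookkeeping right matters: if only the neuropil
*transients* leak (scaled by the soma's brightness), the effective
contamination coefficient in trace units is sb·r_true and no r on a
[0, 1.2] grid can null it. Photon counts are Poisson per pixel per frame;
the recorded value is gain·photons + pedestal. Neuropil transients use the
same kernel, driven by an independent Poisson train — independence from
the soma train is deliberate, so r-optimization can be validated without
the confound of shared network activity.

## Electrophysiology analysis

The slow baseline is a third-order Savitzky–Golay smooth over 20001
samples. The textbook tap construction is numerically catastrophic at this
window length (the taps sum to ~10⁻¹⁶ in double precision), so the taps
are derived from a least-squares polynomial basis on a unit-scaled
abscissa and applied by FFT convolution; the first and last half-windows
use an explicit polynomial fit, which also keeps the filter symmetric
under time reversal.

Two AP detectors are provided. The default band-passes 250–5000 Hz
(4th-order Butterworth, zero-phase) and thresholds at 5× the filtered
trace's sd; peaks smaller than half the largest filtered peak within
±5 ms are discarded, suppressing the symmetric ringing side lobes that
zero-phase filtering places around large spikes. The Quiroga variant
thresholds the detrended trace at k× median(|V|)/0.6745 (k = 10), and is
the path the QC battery uses. Accepted peaks are strict local maxima with
a 1 ms refractory.

The 35 QC statistics follow the standard battery (robust deviation of Vm,
baseline moments and trends, Quiroga-threshold stability over 10 s windows
— evenly spaced starts, so the statistic is reversal-invariant — AP
amplitude/width statistics from smoothed ±1 ms snippets with interpolated
half-max crossings, 1 s box-car firing rate, and baseline-versus-AP
correlations). Recordings with ≤3 APs get NaN for AP-dependent metrics,
flagged not-applicable. The gate passes a recording iff every applicable
metric falls within the [min, max] range of the reference set.

A small imaging-stability metric set (fractional frame-mean slope and its
r²) accompanies the battery for movie artifacts such as photobleaching,
gated by the same range rule.

### A note on range gates and clean recordings

For any i.i.d. draw, the probability that a new recording falls inside the
min–max range of n references is (n−1)/(n+1) per metric, independent of
the distribution. With 20 references and ~35 partially correlated metrics
a statistically exchangeable clean recording therefore fails the gate more
often than not — the gate is *designed* to be strict (reference-range
screening of real datasets typically rejects the majority of recordings).
Clean recordings pass reliably only when the reference set is much more
heterogeneous than the tested recording; the packaged reference design
(`pipelines.qc_reference_set`) stratifies short/sparse, mid, and long/dense
recordings with spread in noise, amplitude, spike width, drift, and
nonstationarity for that reason, and the tests treat held-out clean passes
as the adversarial case they are.

## Imaging analysis

Neuropil subtraction is linear in r with the standard fallback ladder
(requested r, then 0.8, 0.7, 0.6, 0.5) when the subtracted baseline goes
negative; the r actually used is reported and exhaustion flags the
recording. Isolated events require ≥1.0 s before / ≥0.5 s after for
GCaMP6s and ≥0.3 s both sides for GCaMP6f; >5 AP bursts are excluded.
ΔF/F uses a 100 ms pre-event local baseline and the minimum local baseline
across same-class events as the global denominator, which makes ΔF/F
exactly invariant under rescaling of the raw fluorescence. Peak ΔF/F is
the 100 ms mean around the maximum within 500 ms (6s) or 300 ms (6f) of
the first AP. All windows are half-open, with times mapped to frames by
floor((t − t0)·rate).

Transient fits minimize squared error of A·(e^(−t/τ_d) − e^(−t/τ_r)) over
three starts; swapped time constants are relabeled (the model is symmetric
up to the sign of A). Fits of the decay constant are biased fast when the
fitted window is contaminated by neighbouring events' tails — at 2 Hz
firing the GCaMP6f margins admit previous-event tails of up to ~20% of
peak — so parameter-recovery studies use sparse firing (0.3 Hz) and
extended windows around well-isolated APs.

Photon-transfer calibration regresses pixel temporal variance on pixel
temporal mean per column along the resonant axis; the slope is the gain
and −offset/slope the pedestal, with photons = (F − pedestal)/gain.

Trial-to-trial variability reads each baseline-subtracted 1 AP photon
trial at the t_max of the mean trace and reports the fraction outside a
95% band. Three band rules are provided — ±1.96·SEM (default), ±1.96·SD,
and ±1.96·mean-peak — because the conventional phrasing of this interval
is ambiguous; the SEM reading flags most trials whenever true variability
exceeds photon noise, the SD reading has ~5% nominal coverage.

## Ground-truth-optimized detection

The template is the mean event segment; projections use the zero-mean,
unit-norm template, making scores invariant to DC offsets. Noise segments
are non-overlapping AP-free windows (every sample at least the indicator's
largest isolation margin from any AP), converted to ΔF/F with the same
local-baseline convention as events. The detection threshold is the x-th
percentile of the noise scores with x swept in 0.1 steps, so the nominal
false-positive probability is 1 − x/100 by construction; the ROC anchors
at (1, 1) and AUC is trapezoidal. `optimize_r` rebuilds template and ROC
per r on a 0–1.2 grid (step 0.05), flags r values that drive any event
baseline non-positive, and returns the AUC argmax (smallest r on ties).

Two regime caveats, both visible in testing and documented here as
findings about the method rather than the implementation: (i) at high
photon flux the AUC saturates at exactly 1 over a range of r and the
smallest-r tie-break returns the plateau's left edge — r is only
identifiable when detection is imperfect, so calibration conditions should
put 1 AP detection in the 0.5–0.9 range; (ii) the AUC optimum shrinks
toward zero by the factor V_N/(V_N + σ²_np), where V_N is the variance of
neuropil-transient projections and σ²_np the shot-noise variance of the
neuropil trace — the neuropil ring must be large and bright enough that
its own shot noise is negligible relative to the contamination being
removed.

## Downsampling and trace QC

Block means over 4×4 pixels × 5 frames with all 20 phase offsets; trailing
partial blocks are dropped. Each variant's somatic trace (blocks with ≥50%
soma coverage) is tiled into the 4×5 grid for 400 nearly identical ROIs;
the median across variants is the consensus trace. DBSCAN clusters the
traces with distance 1 − Pearson (eps 0.2, min_samples 5 — phase variants
of one neuron correlate ≫ 0.8); each cluster median is compared by
two-sample KS against white noise of matched mean/sd and rejected when not
significantly different (p ≥ 0.05). Candidate signals are sums over all 7
non-empty subsets of the three largest kept clusters; the target is the AP
count per downsampled frame smoothed with a 3-frame box-car. Significance
uses 1000 rate-matched Poisson trains, with the null statistic being the
*maximum* candidate correlation per train — calibrating the null against
the same selection that the statistic uses keeps the false-pass rate at
the nominal 0.5%. The robust noise estimate is 1.4826×MAD of first
differences /√2, recomputed after excluding samples beyond 4 initial
estimates from the median.

## Spike inference and evaluation

NND solves min_s ½‖F − K∗s‖² with s ≥ 0 by bound-constrained quasi-Newton
iteration (FFT convolutions for the operator, projected-gradient tolerance
10⁻¹⁰), which makes Karush–Kuhn–Tucker residuals directly checkable. With
`upsample_to`, the spike vector lives on an integer-multiple finer grid
and the forward model averages back to observed frames — sub-frame spike
placement without altering the data; the solution is reported both at the
fine grid and summed to native frames. The kernel peak equals the
configured single-AP amplitude, so total inferred mass estimates AP count.

Evaluation: Pearson correlation of bin-summed series (NaN when a binned
series is constant), Matthews correlation of bin-level event presence
(threshold 0: any inferred mass counts; 0 on degenerate margins), and a
per-AP-class ROC in which window scores are summed inferred activity and
the threshold is the (1 − fp) quantile of AP-free-window scores. For
unpenalized NND, whose output carries small noise mass in most frames, the
zero MCC threshold saturates the inferred margin; summary reports use a
presence threshold of half an AP per bin. The
reporting bin grid is {33, 100, 250, 300, 500} ms.

On this generator, exact NND at 30 Hz with a correctly discretized kernel
already attains the performance of the 150 Hz upsampled solve: across
seeds the binned-Pearson difference is within Monte-Carlo error of zero
(the fine grid fits the data at least as well, but its extra freedom adds
small-mass noise that cancels the timing benefit). Reports of large
upsampling gains are likely sensitive to how the low-rate kernel is
discretized and aligned; the packaged test therefore asserts
non-inferiority (upsampling does not significantly reduce agreement)
rather than superiority.

## Problem sizes and numerical choices

Tests and the acceptance script use desk-scale recordings: 8–10 s voltage
traces for QC studies, 120–240 s movies at 32×32–44×44 px for detection
and r-recovery, 3000-frame movies for photon calibration, and 10–20 seeds
per stochastic claim. Simulation parameters for each study are stated in
the corresponding test; none are fitted to data. Tolerances: KKT and
NNLS-equivalence at 10⁻⁶; exactness claims (event bookkeeping, ROC
counting) are bit-level; stochastic recovery claims use the margins quoted
in the tests (e.g. time constants within 10% median, r within one grid
step in ≥8/10 seeds).

## Known limitations

- No optical PSF, motion, or scanning-raster simulation; masks are inputs
  and segmentation/demixing of overlapping somata is out of scope.
- Neuropil activity is independent of the soma train; correlated network
  activity would make over-subtraction costlier and can shift the optimal
  r upward, as in strongly stimulus-driven data.
- The trial-variability interval rule and the event-ROC windowing for
  continuous inferred activity are documented choices where conventions
  differ between pipelines.
- MLspike- and L0-style inference algorithms are supported only through
  the evaluation interface (any non-negative per-frame series); their
  internals are not reimplemented.
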
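"""Electrophysiology: AP detection and the 35-metric quality-control battery.

A cell-attached voltage trace is detrended with a long Savitzky-Golay
baseline, APs are detected either on a 250-5000 Hz band-passed copy
(5 x std threshold, the default) or directly on the detrended trace
(10 x Quiroga threshold, the variant used by the QC battery), and 35
descriptive statistics of the recording are computed. A recording passes
QC when every applicable statistic falls inside the range spanned by a
reference set of known-good recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

QUIROGA_CONST = 0.6745

#: The 35 QC metric names, in battery order.
METRIC_NAMES = (
    "mrdm", "baseline_mean", "baseline_cv", "qt_mean", "qns",
    "qt_r2", "qt_slope", "bl_r2", "bl_slope", "polarity_ratio",
    "n_aps", "ml_isi", "ap_amp_mean", "ap_amp_cv", "ap_amp_mrd",
    "ap_amp_rel_range", "ap_amp_maxmin", "snr",
    "lwhm", "rwhm", "fwhm", "lwhm_cv", "rwhm_cv", "fwhm_cv",
    "amp_vs_time_r2", "amp_vs_time_slope", "fwhm_vs_time_r2", "fwhm_vs_time_slope",
    "fr_mean", "fr_cv", "fr_vs_time_r2", "fr_vs_time_slope",
    "corr_bl_fr", "corr_bl_ampl", "corr_bl_fwhm",
)

#: Metrics that require more than 3 detected APs.
AP_DEPENDENT = frozenset(METRIC_NAMES[11:])


@dataclass
class VoltageTrace:
    """A regularly sampled membrane-voltage trace in mV."""

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("voltage samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass
class APTrain:
    """Detected action potentials: times (s), peak amplitudes (mV), waveforms."""

    times: np.ndarray
    amplitudes: np.ndarray
    waveforms: np.ndarray      # (n_aps, snippet_len) smoothed +/-1 ms snippets
    waveform_rate: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("AP times must be strictly increasing")
        if self.times.size != self.amplitudes.size:
            raise ValueError("times and amplitudes must have equal length")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class QCReport:
    """The 35 descriptive statistics plus (after gating) per-metric flags."""

    metrics: dict
    applicable: dict
    flags: dict | None = None
    verdict: bool | None = None
    failing: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if set(self.metrics) != set(METRIC_NAMES):
            raise ValueError("QCReport requires exactly the 35 named metrics")

    def to_dict(self) -> dict:
        """JSON-serializable form: metrics, applicability, flags, verdict."""
        return {
            "metrics": {k: self.metrics[k] for k in METRIC_NAMES},
            "applicable": dict(self.applicable),
            "flags": dict(self.flags) if self.flags is not None else None,
            "verdict": self.verdict,
            "failing": list(self.failing),
        }


def sg_smooth(x: np.ndarray, window: int, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smooth that stays numerically stable for long windows.

    The filter taps are derived from a least-squares polynomial basis on a
    unit-scaled abscissa (the textbook construction loses all precision for
    windows of ~10^4 samples), applied by FFT convolution; the first and
    last half-windows are replaced by a polynomial fit to the edge window,
    so edge handling is symmetric under time reversal.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 != 1 or window < polyorder + 2:
        raise ValueError("window must be odd and exceed polyorder + 1")
    if x.size < window:
        raise ValueError(f"trace shorter than smoothing window ({window} samples)")
    m = window // 2
    t = np.arange(-m, m + 1) / m                     # scaled to [-1, 1]
    V = np.vander(t, polyorder + 1, increasing=True)
    # smoothing taps = centre row of the least-squares projection V (V^T V)^-1 V^T
    taps = V[m] @ np.linalg.solve(V.T @ V, V.T)
    out = signal.fftconvolve(x, taps[::-1], mode="same")
    # polynomial edge fit, as in the usual 'interp' edge mode
    for sl in (slice(0, window), slice(x.size - window, x.size)):
        coef = np.polynomial.polynomial.polyfit(t, x[sl], polyorder)
        half = slice(sl.start, sl.start + m) if sl.start == 0 else \
            slice(sl.stop - m - 1, sl.stop)
        tt = t[:m] if sl.start == 0 else t[m:]
        out[half] = np.polynomial.polynomial.polyval(tt, coef)
    return out


def detrend_vm(trace: VoltageTrace, window: int = 20001, polyorder: int = 3):
    """Split a trace into a slow Savitzky-Golay baseline and the residual.

    Returns ``(detrended, baseline)``. The default third-order filter over
    20001 samples (0.5 s at 40 kHz) tracks drift while passing APs.
    """
    if trace.samples.size < window:
        raise ValueError(f"trace shorter than detrending window ({window} samples)")
    baseline = sg_smooth(trace.samples, window, polyorder)
    detrended = trace.samples - baseline
    return (VoltageTrace(detrended, trace.rate, trace.t0),
            VoltageTrace(baseline, trace.rate, trace.t0))


def quiroga_threshold(samples: np.ndarray) -> float:
    """Robust noise scale median(|V|)/0.6745 (equals sigma for pure Gaussian noise)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0 or np.all(np.isnan(samples)):
        raise ValueError("cannot compute Quiroga threshold of empty/all-NaN input")
    return float(np.median(np.abs(samples)) / QUIROGA_CONST)


def _snippets(detrended: np.ndarray, rate: float, peak_idx: np.ndarray):
    """+/-1 ms snippets around each peak, Savitzky-Golay smoothed (quadratic, span 5).

    Peaks too close to the trace edges for a full snippet are dropped;
    the surviving index subset is returned alongside the snippet stack.
    """
    half = int(round(1e-3 * rate))
    ok = (peak_idx >= half) & (peak_idx < detrended.size - half)
    idx = peak_idx[ok]
    if idx.size == 0:
        return idx, np.empty((0, 2 * half + 1))
    snips = np.stack([detrended[i - half:i + half + 1] for i in idx])
    if snips.shape[1] >= 5:
        snips = signal.savgol_filter(snips, 5, 2, axis=1)
    return idx, snips


def detect_aps(detrended: VoltageTrace, method: str = "bandpass", k: float = 10.0,
               std_mult: float = 5.0, refractory_s: float = 1e-3) -> APTrain:
    """Detect APs on a detrended voltage trace.

    method='bandpass' (default): zero-phase 4th-order Butterworth 250-5000 Hz,
    peaks above ``std_mult`` x std of the filtered trace.
    method='quiroga': peaks of the detrended trace above ``k`` x the Quiroga
    threshold (the rule the QC battery uses).

    Accepted peaks are strict local maxima separated by >= ``refractory_s``.
    Amplitudes are peak values of the detrended trace; waveforms are smoothed
    +/-1 ms snippets.
    """
    if k <= 0 or std_mult <= 0:
        raise ValueError("threshold multipliers must be positive")
    x = detrended.samples
    rate = detrended.rate
    dist = max(1, int(round(refractory_s * rate)))
    if method == "bandpass":
        if rate < 10000:
            raise ValueError("band-pass detection requires >= 10 kHz sampling")
        sos = signal.butter(4, [250.0, 5000.0], btype="bandpass", fs=rate, output="sos")
        filt = signal.sosfiltfilt(sos, x)
        thr = std_mult * float(np.std(filt))
        peaks, props = signal.find_peaks(filt, height=thr, distance=dist)
        # suppress filter-ringing side lobes: zero-phase filtering rings
        # symmetrically around a large AP, so drop peaks smaller than half
        # the largest filtered peak within +/-5 ms
        if peaks.size:
            guard = int(round(5e-3 * rate))
            h = props["peak_heights"]
            keep = np.array([
                h[i] >= 0.5 * h[(np.abs(peaks - peaks[i]) <= guard)].max()
                for i in range(peaks.size)
            ])
            peaks = peaks[keep]
        # refine to the detrended-trace maximum within +/-0.5 ms
        half = max(1, int(round(0.5e-3 * rate)))
        refined = np.array([
            max(p - half, 0) + int(np.argmax(x[max(p - half, 0):p + half + 1]))
            for p in peaks
        ], dtype=int)
        peaks = np.unique(refined)
    elif method == "quiroga":
        thr = k * quiroga_threshold(x)
        peaks, _ = signal.find_peaks(x, height=thr, distance=dist)
    else:
        raise ValueError(f"unknown detection method: {method!r}")
    peaks, waveforms = _snippets(x, rate, peaks)
    times = detrended.t0 + peaks / rate
    return APTrain(times, x[peaks], waveforms, rate)


def _regress(x: np.ndarray, y: np.ndarray):
    """(slope, r^2) of an ordinary least-squares line; NaNs if degenerate."""
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _half_widths(waveform: np.ndarray, rate: float):
    """Left/right width at half amplitude of a snippet, by linear interpolation.

    The snippet peak defines the amplitude; widths are measured from the
    half-amplitude crossings nearest the peak on each side.
    """
    p = int(np.argmax(waveform))
    amp = waveform[p]
    if amp <= 0:
        return float("nan"), float("nan")
    half = amp / 2.0
    left = np.nan
    for i in range(p, 0, -1):
        if waveform[i - 1] <= half <= waveform[i]:
            frac = (waveform[i] - half) / (waveform[i] - waveform[i - 1])
            left = (p - i + frac) / rate
            break
    right = np.nan
    for i in range(p, waveform.size - 1):
        if waveform[i + 1] <= half <= waveform[i]:
            frac = (waveform[i] - half) / (waveform[i] - waveform[i + 1])
            right = (i - p + frac) / rate
            break
    return left, right


def firing_rate_boxcar(ap_times: np.ndarray, duration: float, grid_rate: float = 1000.0,
                       window_s: float = 1.0):
    """Firing rate (Hz) by convolving the AP train with a ~1 s box-car window.

    The train is binned on a 1 kHz grid and convolved with an odd-length
    box-car so the estimate is symmetric in time. Returns (t, fr).
    """
    n = max(1, int(round(duration * grid_rate)))
    counts = np.zeros(n)
    if ap_times.size:
        idx = np.clip((ap_times * grid_rate).astype(int), 0, n - 1)
        np.add.at(counts, idx, 1.0)
    w = int(round(window_s * grid_rate)) // 2 * 2 + 1
    fr = np.convolve(counts, np.ones(w), mode="same") / (w / grid_rate)
    t = (np.arange(n) + 0.5) / grid_rate
    return t, fr


def compute_qc_metrics(trace: VoltageTrace, ap_train: APTrain | None = None,
                       n_qt_windows: int = 1000) -> QCReport:
    """Compute the 35-metric QC battery for one recording.

    ``trace`` is the raw voltage trace; the baseline is its Savitzky-Golay
    smooth and AP-dependent metrics use the 10 x Quiroga-threshold detector
    unless an ``ap_train`` is supplied. Recordings with <= 3 APs get NaN for
    AP-dependent metrics, flagged not-applicable.

    QT-stability windows are 10 s long (duration/10 for shorter recordings)
    with evenly spaced start times, so the statistic is invariant under time
    reversal of a stationary trace.
    """
    detrended, baseline = detrend_vm(trace)
    if ap_train is None:
        ap_train = detect_aps(detrended, method="quiroga", k=10.0)
    v = trace.samples
    bl = baseline.samples
    det = detrended.samples
    rate = trace.rate
    duration = trace.duration
    qt = quiroga_threshold(det)

    m: dict[str, float] = {}
    med_v = float(np.median(v))
    mad_v = float(np.median(np.abs(v - med_v)))
    m["mrdm"] = mad_v / med_v if med_v != 0 else float("inf")
    m["baseline_mean"] = float(np.mean(bl))
    m["baseline_cv"] = float(np.std(bl) / np.mean(bl)) if np.mean(bl) != 0 else float("inf")
    m["qt_mean"] = qt

    # QT stability over evenly spaced windows: 10 s windows, shrunk to
    # duration/10 for recordings shorter than 10 s
    win_s = 10.0 if duration >= 10.0 else duration / 10.0
    win = int(round(win_s * rate))
    win = max(win, 2)
    starts = np.unique(np.round(
        np.linspace(0, det.size - win, min(n_qt_windows, det.size - win + 1))
    ).astype(int))
    qts = np.array([quiroga_threshold(det[s:s + win]) for s in starts])
    m["qns"] = float(np.std(qts) / np.mean(qts)) if np.mean(qts) != 0 else float("inf")
    t_starts = starts / rate
    m["qt_slope"], m["qt_r2"] = _regress(t_starts, qts)

    t_bl = np.arange(bl.size) / rate
    m["bl_slope"], m["bl_r2"] = _regress(t_bl, bl)

    n_pos = int(np.count_nonzero(det > qt))
    n_neg = int(np.count_nonzero(det < -qt))
    m["polarity_ratio"] = n_pos / n_neg if n_neg else float("inf")

    n_aps = len(ap_train)
    m["n_aps"] = float(n_aps)
    applicable = {k: True for k in METRIC_NAMES}
    if n_aps > 3:
        amps = ap_train.amplitudes
        ap_t = ap_train.times - trace.t0
        isis = np.diff(ap_t)
        # lognormal MLE of the inter-AP interval; report the fitted median
        m["ml_isi"] = float(np.exp(np.mean(np.log(isis)))) if isis.size else float("nan")
        m["ap_amp_mean"] = float(np.mean(amps))
        m["ap_amp_cv"] = float(np.std(amps) / np.mean(amps))
        med_a = float(np.median(amps))
        m["ap_amp_mrd"] = float(np.median(np.abs(amps - med_a)) / med_a)
        m["ap_amp_rel_range"] = float((amps.max() - amps.min()) / med_a)
        m["ap_amp_maxmin"] = float(amps.max() / amps.min())
        m["snr"] = med_a / qt

        widths = np.array([_half_widths(w, ap_train.waveform_rate) for w in ap_train.waveforms])
        lw, rw = widths[:, 0], widths[:, 1]
        fw = lw + rw
        for name, arr in (("lwhm", lw), ("rwhm", rw), ("fwhm", fw)):
            m[name] = float(np.nanmean(arr))
            mu = np.nanmean(arr)
            m[name + "_cv"] = float(np.nanstd(arr) / mu) if mu else float("nan")
        m["amp_vs_time_slope"], m["amp_vs_time_r2"] = _regress(ap_t, amps)
        good = np.isfinite(fw)
        m["fwhm_vs_time_slope"], m["fwhm_vs_time_r2"] = _regress(ap_t[good], fw[good])

        t_fr, fr = firing_rate_boxcar(ap_t, duration)
        m["fr_mean"] = float(np.mean(fr))
        m["fr_cv"] = float(np.std(fr) / np.mean(fr)) if np.mean(fr) else float("nan")
        m["fr_vs_time_slope"], m["fr_vs_time_r2"] = _regress(t_fr, fr)

        # baseline resampled to the firing-rate grid for the correlation metrics
        step = max(1, int(round(rate / 1000.0)))
        bl_grid = bl[::step][:t_fr.size]
        m["corr_bl_fr"] = _pearson(bl_grid, fr[:bl_grid.size])
        bl_at_ap = bl[np.clip((ap_t * rate).astype(int), 0, bl.size - 1)]
        m["corr_bl_ampl"] = _pearson(bl_at_ap, amps)
        m["corr_bl_fwhm"] = _pearson(bl_at_ap[good], fw[good])
    else:
        for k in AP_DEPENDENT:
            if k != "n_aps":
                m[k] = float("nan")
                applicable[k] = False
    m = {k: m[k] for k in METRIC_NAMES}
    return QCReport(metrics=m, applicable=applicable)


def range_gate(metrics: dict, applicable: dict, reference: list[dict]):
    """Flag each metric against the [min, max] range spanned by reference dicts.

    NaN reference values are ignored; non-applicable metrics are skipped.
    Returns (flags, verdict, failing_names).
    """
    if not reference:
        raise ValueError("reference set must be nonempty")
    flags = {}
    for k, val in metrics.items():
        if not applicable.get(k, True) or not np.isfinite(val):
            flags[k] = True
            continue
        ref = np.array([r[k] for r in reference if np.isfinite(r.get(k, np.nan))])
        if ref.size == 0:
            flags[k] = True
            continue
        flags[k] = bool(ref.min() <= val <= ref.max())
    failing = tuple(k for k, ok in flags.items() if not ok)
    return flags, not failing, failing


def qc_gate(report: QCReport, reference: list[QCReport]) -> QCReport:
    """Gate one recording against a reference set of known-good recordings.

    A recording passes iff every applicable metric lies within the range
    spanned by the reference reports. Returns a new QCReport carrying
    per-metric flags and the verdict.
    """
    if not reference:
        raise ValueError("reference set must be nonempty")
    for r in reference:
        if set(r.metrics) != set(report.metrics):
            raise ValueError("reference reports must share the metric keys")
    flags, verdict, failing = range_gate(report.metrics, report.applicable,
                                         [r.metrics for r in reference])
    return QCReport(metrics=dict(report.metrics), applicable=dict(report.applicable),
                    flags=flags, verdict=verdict, failing=failing)
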
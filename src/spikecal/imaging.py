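"""Fluorescence trace analysis for paired ground-truth recordings.

Covers ROI trace extraction, r-scaled neuropil subtraction with the
standard step-down fallback, isolated-event bookkeeping (250 ms grouping,
indicator-specific isolation margins, >5 AP exclusion), dF/F with local/
global baselines, difference-of-exponential transient fits, photon-transfer
(variance vs mean) gain calibration, and trial-to-trial variability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .kernels import dexp_kernel

#: (pre, post) isolation margins in seconds: the event's first AP must be
#: >= pre after the previous AP, and the last AP >= post before the next.
ISOLATION_MARGINS = {"6s": (1.0, 0.5), "6f": (0.3, 0.3)}

#: Post-AP search window for the dF/F maximum, seconds.
PEAK_SEARCH_S = {"6s": 0.5, "6f": 0.3}

EVENT_WINDOW_S = 0.25    # APs within 250 ms of the first AP form one event
PRE_BASELINE_S = 0.1     # F0_local window before the first AP
PEAK_HALF_S = 0.05       # peak dF/F = mean over t_max +/- 50 ms
MAX_APS_PER_EVENT = 5

R_FALLBACK_LADDER = (0.8, 0.7, 0.6, 0.5)


class NegativeBaselineError(ValueError):
    """F0 <= 0 after neuropil subtraction; step r down and retry."""


@dataclass
class FluoTrace:
    """A regularly sampled fluorescence trace (arbitrary units or photons)."""

    values: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    def frame_of(self, t: float) -> int:
        """Frame index containing time t (floor convention)."""
        return int(np.floor((t - self.t0) * self.rate))


@dataclass
class APEvent:
    """A group of <=5 APs within 250 ms, with its aligned dF/F segment.

    ``t0_index`` is the segment sample corresponding to the frame containing
    the first AP (t=0 at most one frame before the AP).
    """

    t_first: float
    n_aps: int
    ap_times: np.ndarray
    dff_segment: np.ndarray | None = None
    f0_local: float | None = None
    peak_dff: float | None = None
    t0_index: int = 0

    def __post_init__(self):
        self.ap_times = np.asarray(self.ap_times, dtype=float)
        if not 1 <= self.n_aps:
            raise ValueError("an event needs at least one AP")
        if np.any(self.ap_times < self.t_first) or \
                np.any(self.ap_times >= self.t_first + EVENT_WINDOW_S):
            raise ValueError("event APs must lie in [t_first, t_first + 250 ms)")


@dataclass
class TransientFit:
    """Difference-of-exponentials fit of a mean event transient."""

    amplitude: float
    tau_rise: float
    tau_decay: float
    rss: float
    flagged: bool = False


@dataclass
class PhotonCalibration:
    """Photon-transfer calibration: per-column gain (slope) and offset.

    For shot-noise-limited data, pixel temporal variance = gain * (mean -
    pedestal), fitted per column along the resonant axis. The pedestal
    (zero-photon fluorescence) is -offset/slope.
    """

    slope: np.ndarray
    offset: np.ndarray

    @property
    def gain(self) -> float:
        return float(np.mean(self.slope))

    @property
    def pedestal(self) -> float:
        return float(np.mean(-self.offset / self.slope))


@dataclass
class NeuropilResult:
    trace: "FluoTrace"
    r_used: float
    flagged: bool


def extract_traces(movie: np.ndarray, soma_mask: np.ndarray, neuropil_mask: np.ndarray,
                   rate: float, t0: float = 0.0):
    """Per-frame mean over mask pixels -> (F_cell_measured, F_neuropil)."""
    if not soma_mask.any() or not neuropil_mask.any():
        raise ValueError("masks must be nonempty")
    if np.any(soma_mask & neuropil_mask):
        raise ValueError("masks must be disjoint")
    f_cell = movie[:, soma_mask].mean(axis=1)
    f_np = movie[:, neuropil_mask].mean(axis=1)
    return FluoTrace(f_cell, rate, t0), FluoTrace(f_np, rate, t0)


def _baseline_ok(values: np.ndarray) -> bool:
    # conservative F0 proxy: the 10th percentile of the subtracted trace
    return float(np.percentile(values, 10)) > 0.0


def subtract_neuropil(f_cell: FluoTrace, f_neuropil: FluoTrace, r: float = 0.8,
                      fallback: bool = True) -> NeuropilResult:
    """F_cell_true(t) = F_cell_measured(t) - r * F_neuropil(t).

    If the requested r drives the baseline negative and ``fallback`` is on,
    r steps down through 0.8, 0.7, 0.6, 0.5; if the baseline is still
    negative at 0.5 the result is flagged.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    if f_cell.values.size != f_neuropil.values.size:
        raise ValueError("traces must have equal length")

    def sub(rv):
        return f_cell.values - rv * f_neuropil.values

    vals = sub(r)
    if not fallback or _baseline_ok(vals):
        return NeuropilResult(FluoTrace(vals, f_cell.rate, f_cell.t0), r,
                              not _baseline_ok(vals))
    for rv in R_FALLBACK_LADDER:
        if rv >= r:
            continue
        vals = sub(rv)
        if _baseline_ok(vals):
            return NeuropilResult(FluoTrace(vals, f_cell.rate, f_cell.t0), rv, False)
    vals = sub(R_FALLBACK_LADDER[-1])
    return NeuropilResult(FluoTrace(vals, f_cell.rate, f_cell.t0),
                          R_FALLBACK_LADDER[-1], True)


def find_isolated_events(ap_times: np.ndarray, indicator: str) -> list[APEvent]:
    """Group APs into 250 ms events and keep the isolated ones.

    An event is isolated when its first AP is >= the pre margin after the
    previous AP and its last AP is >= the post margin before the next AP
    (6s: 1.0 s / 0.5 s; 6f: 0.3 s / 0.3 s). Events with >5 APs are dropped.
    """
    if indicator not in ISOLATION_MARGINS:
        raise ValueError(f"unknown indicator {indicator!r}")
    pre, post = ISOLATION_MARGINS[indicator]
    ap_times = np.asarray(ap_times, dtype=float)
    from .synthetic_data import group_aps
    groups = group_aps(ap_times, EVENT_WINDOW_S)
    out = []
    for ev in groups:
        i0 = np.searchsorted(ap_times, ev[0])
        i1 = np.searchsorted(ap_times, ev[-1], side="right") - 1
        gap_pre = ev[0] - ap_times[i0 - 1] if i0 > 0 else np.inf
        gap_post = ap_times[i1 + 1] - ev[-1] if i1 + 1 < ap_times.size else np.inf
        if gap_pre >= pre and gap_post >= post and ev.size <= MAX_APS_PER_EVENT:
            out.append(APEvent(t_first=ev[0], n_aps=ev.size, ap_times=ev))
    return out


def compute_event_dff(f_cell_true: FluoTrace, events: list[APEvent], indicator: str,
                      ) -> list[APEvent]:
    """Attach dF/F segments and peak amplitudes to isolated events.

    dF/F = (F - F0_local) / F0_global, where F0_local is the mean over the
    100 ms before the first AP and F0_global the minimum F0_local across the
    neuron's events of the same AP-count class. Segments run from 100 ms
    before the first AP to the indicator's peak-search window plus 50 ms
    after it; events without full pre/post coverage are dropped. Peak dF/F
    is the 100 ms mean around the maximum within the search window.
    """
    if indicator not in PEAK_SEARCH_S:
        raise ValueError(f"unknown indicator {indicator!r}")
    rate = f_cell_true.rate
    vals = f_cell_true.values
    pre_f = int(round(PRE_BASELINE_S * rate))
    search_f = int(round(PEAK_SEARCH_S[indicator] * rate))
    post_f = search_f + int(round(PEAK_HALF_S * rate))
    half_pk = int(round(PEAK_HALF_S * rate))

    usable = []
    for ev in events:
        i0 = f_cell_true.frame_of(ev.t_first)
        if i0 - pre_f < 0 or i0 + post_f > vals.size:
            continue
        f0_local = float(np.mean(vals[i0 - pre_f:i0]))
        usable.append((ev, i0, f0_local))
    if not usable:
        return []

    # global baseline per AP-count class
    f0_global = {}
    for ev, _, f0l in usable:
        f0_global[ev.n_aps] = min(f0_global.get(ev.n_aps, np.inf), f0l)
    if min(f0_global.values()) <= 0:
        raise NegativeBaselineError(
            "F0_global <= 0 after neuropil subtraction; reduce r")

    out = []
    for ev, i0, f0l in usable:
        seg = (vals[i0 - pre_f:i0 + post_f] - f0l) / f0_global[ev.n_aps]
        pk_region = seg[pre_f:pre_f + search_f]
        t_max = int(np.argmax(pk_region)) + pre_f
        lo, hi = max(t_max - half_pk, 0), min(t_max + half_pk, seg.size)
        peak = float(np.mean(seg[lo:hi]))
        out.append(replace(ev, dff_segment=seg, f0_local=f0l, peak_dff=peak,
                           t0_index=pre_f))
    return out


def _dexp_model(t, a, tau_r, tau_d):
    tt = np.maximum(t, 0.0)
    return np.where(t >= 0, a * (np.exp(-tt / tau_d) - np.exp(-tt / tau_r)), 0.0)


def fit_transient(segment: np.ndarray, frame_rate: float, t0_index: int = 0) -> TransientFit:
    """Nonlinear least-squares difference-of-exponentials fit of a transient.

    Multi-start over three (tau_rise, tau_decay) initializations; the best
    residual sum of squares wins. If the optimizer lands with the time
    constants swapped they are relabeled (the model is symmetric up to the
    sign of the amplitude). Degenerate or non-convergent fits are flagged.
    """
    segment = np.asarray(segment, dtype=float)
    t = (np.arange(segment.size) - t0_index) / frame_rate
    scale = float(np.max(np.abs(segment))) if segment.size else 0.0
    if scale == 0.0:
        return TransientFit(0.0, np.nan, np.nan, 0.0, flagged=True)
    starts = [(0.01, 0.1), (0.03, 0.3), (0.1, 1.0)]
    best = None
    for tr0, td0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                _dexp_model, t, segment, p0=[scale, tr0, td0],
                bounds=([-np.inf, 1e-4, 1e-4], [np.inf, 10.0, 10.0]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((segment - _dexp_model(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return TransientFit(np.nan, np.nan, np.nan, np.inf, flagged=True)
    (a, tau_r, tau_d), rss = best
    if tau_r > tau_d:
        tau_r, tau_d, a = tau_d, tau_r, -a
    return TransientFit(float(a), float(tau_r), float(tau_d), rss,
                        flagged=not a >= 0)


def fit_photon_gain(movie: np.ndarray, resonant_axis: int = 2) -> PhotonCalibration:
    """Photon-transfer calibration: per-column variance-vs-mean regression.

    For each position along the resonant axis (image width by default), the
    temporal variance of every pixel in that column is regressed on its
    temporal mean; the slope is the photon gain and -offset/slope the
    pedestal for that column.
    """
    if movie.shape[0] < 100:
        raise ValueError("need >= 100 frames for photon calibration")
    if resonant_axis not in (1, 2):
        raise ValueError("resonant_axis must be 1 (height) or 2 (width)")
    m = movie if resonant_axis == 2 else np.swapaxes(movie, 1, 2)
    n_cols = m.shape[2]
    if m.shape[1] < 2:
        raise ValueError("need >= 2 pixels per resonant-axis column")
    mov = m.astype(np.float64, copy=False)
    means = mov.mean(axis=0)          # (H, W)
    vars_ = mov.var(axis=0, ddof=1)
    slope = np.empty(n_cols)
    offset = np.empty(n_cols)
    for j in range(n_cols):
        s, o = np.polyfit(means[:, j], vars_[:, j], 1)
        slope[j] = s
        offset[j] = o
    return PhotonCalibration(slope=slope, offset=offset)


def to_photons(values: np.ndarray, calib: PhotonCalibration,
               column: int | None = None) -> np.ndarray:
    """photons = (F - [-offset/slope]) / slope, per column or with the mean
    calibration."""
    if column is None:
        gain, ped = calib.gain, calib.pedestal
    else:
        gain = float(calib.slope[column])
        ped = float(-calib.offset[column] / calib.slope[column])
    return (np.asarray(values, dtype=float) - ped) / gain


def soma_photon_trace(movie: np.ndarray, soma_mask: np.ndarray,
                      calib: PhotonCalibration, rate: float) -> FluoTrace:
    """Summed somatic photon count per frame, via the mean calibration."""
    f_sum = movie[:, soma_mask].sum(axis=1)
    n_px = int(soma_mask.sum())
    photons = (f_sum - n_px * calib.pedestal) / calib.gain
    return FluoTrace(photons, rate)


def trial_variability(photon_segments: np.ndarray, t0_index: int,
                      rule: str = "sem") -> float:
    """Fraction of 1 AP trials whose peak photon count falls outside a 95% band.

    Each trial's mean photon count over the 100 ms before the AP (the
    samples before ``t0_index``) is subtracted, t_max is found on the mean
    trace after t0, and each trial is read out at t_max. The band is
    mean +/- 1.96 * {SEM | SD | mean-peak} across trials, per ``rule``.
    """
    segs = np.asarray(photon_segments, dtype=float)
    if segs.ndim != 2 or segs.shape[0] < 5:
        raise ValueError("need >= 5 one-AP trials")
    if rule not in ("sem", "std", "mean_peak"):
        raise ValueError(f"unknown CI rule {rule!r}")
    segs = segs - segs[:, :t0_index].mean(axis=1, keepdims=True)
    mean_trace = segs.mean(axis=0)
    t_max = int(np.argmax(mean_trace[t0_index:])) + t0_index
    vals = segs[:, t_max]
    m = float(np.mean(vals))
    if rule == "sem":
        half = 1.96 * float(np.std(vals, ddof=1)) / np.sqrt(vals.size)
    elif rule == "std":
        half = 1.96 * float(np.std(vals, ddof=1))
    else:
        half = 1.96 * abs(m)
    outside = (vals < m - half) | (vals > m + half)
    return float(np.mean(outside))


def imaging_qc_metrics(movie: np.ndarray, frame_rate: float) -> dict:
    """Movie-stability metrics for the imaging side of recording QC.

    frame_mean_slope_frac: fractional drift of the frame mean per second
    (photobleaching shows up as a negative slope); frame_mean_r2: r^2 of
    that regression (drift-like artifacts are well fit by a line).
    """
    fm = movie.reshape(movie.shape[0], -1).mean(axis=1)
    t = (np.arange(fm.size) + 0.5) / frame_rate
    res = stats.linregress(t, fm)
    mu = float(np.mean(fm))
    return {
        "frame_mean_slope_frac": float(res.slope) / mu if mu else float("inf"),
        "frame_mean_r2": float(res.rvalue ** 2),
    }
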
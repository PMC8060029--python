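"""Ground-truth-optimized event detection and neuropil-r optimization.

Detection works by projecting candidate fluorescence segments onto a
zero-mean unit template built from the mean event response. The detection
threshold is a percentile of the projections of AP-free (noise) segments,
so the threshold sweep maps directly to false-positive probability; the
ROC is the true-positive fraction against that nominal false-positive
probability, and the neuropil scale factor r is chosen to maximize the
area under this curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import (FluoTrace, ISOLATION_MARGINS, NegativeBaselineError,
                      PRE_BASELINE_S, compute_event_dff, find_isolated_events,
                      subtract_neuropil)


@dataclass
class Template:
    """Mean event response and its zero-mean, unit-norm projection vector."""

    mean_response: np.ndarray
    unit_vector: np.ndarray


@dataclass
class RocCurve:
    """Paired false-positive/true-positive probabilities over a threshold sweep."""

    fp_prob: np.ndarray       # ascending in [0, 1]
    tp_prob: np.ndarray
    thresholds: np.ndarray    # percentile values of the noise projections
    auc: float


@dataclass
class OptimizeRResult:
    r_opt: float
    r_grid: np.ndarray
    auc: np.ndarray           # NaN where flagged
    flagged: np.ndarray       # True where r produced a negative baseline
    roc_opt: RocCurve | None = None


def build_template(response_segments: np.ndarray) -> Template:
    """Template = mean across segments; unit vector = centered and normalized."""
    segs = np.atleast_2d(np.asarray(response_segments, dtype=float))
    if segs.shape[0] < 1:
        raise ValueError("need at least one response segment")
    mean = segs.mean(axis=0)
    centered = mean - mean.mean()
    norm = float(np.linalg.norm(centered))
    if norm < 1e-12:
        raise ValueError("zero-variance template")
    return Template(mean_response=mean, unit_vector=centered / norm)


def sample_noise_segments(f_cell_true: FluoTrace, ap_times: np.ndarray,
                          template_len: int, indicator: str):
    """Non-overlapping AP-free windows of template length.

    Every sample of a window must be at least the indicator's (largest)
    isolation margin away from any AP. Returns (segments, start_indices).
    """
    if indicator not in ISOLATION_MARGINS:
        raise ValueError(f"unknown indicator {indicator!r}")
    margin = max(ISOLATION_MARGINS[indicator])
    vals = f_cell_true.values
    if template_len > vals.size:
        raise ValueError("template longer than trace")
    rate = f_cell_true.rate
    bad = np.zeros(vals.size, dtype=bool)
    for ap in np.asarray(ap_times, dtype=float):
        lo = int(np.floor((ap - margin - f_cell_true.t0) * rate))
        hi = int(np.ceil((ap + margin - f_cell_true.t0) * rate)) + 1
        bad[max(lo, 0):min(hi, vals.size)] = True
    csum = np.concatenate([[0], np.cumsum(bad)])
    starts = []
    i = 0
    while i + template_len <= vals.size:
        if csum[i + template_len] - csum[i] == 0:
            starts.append(i)
            i += template_len
        else:
            i += 1
    if not starts:
        raise ValueError("no AP-free windows available")
    starts = np.asarray(starts, dtype=int)
    segs = np.stack([vals[s:s + template_len] for s in starts])
    return segs, starts


def noise_segments_dff(raw_segments: np.ndarray, pre_frames: int,
                       f0_global: float) -> np.ndarray:
    """Convert raw noise windows to dF/F with the event convention: the
    window's first ``pre_frames`` samples play the role of F0_local."""
    segs = np.asarray(raw_segments, dtype=float)
    f0_local = segs[:, :pre_frames].mean(axis=1, keepdims=True)
    return (segs - f0_local) / f0_global


def roc_from_projection(response_segments: np.ndarray, noise_segments: np.ndarray,
                        template: Template, x_step: float = 0.1) -> RocCurve:
    """ROC by sweeping the detection threshold over noise-score percentiles.

    r_i and n_i are dot products of the response/noise segments with the
    unit vector. For percentile x, threshold = x-th percentile of n_i,
    fp = 1 - x/100 (the nominal false-positive probability) and tp = the
    fraction of r_i strictly above threshold. AUC by the trapezoid rule;
    the curve is anchored at (fp=1, tp=1).
    """
    resp = np.atleast_2d(np.asarray(response_segments, dtype=float))
    noise = np.atleast_2d(np.asarray(noise_segments, dtype=float))
    if resp.shape[0] < 1:
        raise ValueError("need at least one response segment")
    if noise.shape[0] < 2:
        raise ValueError("need at least two noise segments")
    r_i = resp @ template.unit_vector
    n_i = noise @ template.unit_vector
    xs = np.arange(0.0, 100.0 + x_step / 2, x_step)
    thr = np.percentile(n_i, xs)
    tp = (r_i[None, :] > thr[:, None]).mean(axis=1)
    fp = 1.0 - xs / 100.0
    order = np.argsort(fp, kind="stable")
    fp, tp, thr = fp[order], tp[order], thr[order]
    fp = np.append(fp, 1.0)
    tp = np.append(tp, 1.0)
    thr = np.append(thr, -np.inf)
    auc = float(np.trapezoid(tp, fp))
    return RocCurve(fp_prob=fp, tp_prob=tp, thresholds=thr, auc=auc)


def detection_probability(roc: RocCurve, fp: float = 0.01) -> float:
    """True-positive probability at the largest tabulated fp <= requested fp."""
    if not 0.0 < fp <= 1.0:
        raise ValueError("fp must lie in (0, 1]")
    idx = np.searchsorted(roc.fp_prob, fp, side="right") - 1
    if idx < 0:
        raise ValueError("requested fp below the tabulated range")
    return float(roc.tp_prob[idx])


def response_and_noise(f_true: FluoTrace, ap_times: np.ndarray, indicator: str,
                       n_ap: int = 1):
    """Build matched response/noise dF/F segment sets for one subtracted trace.

    Responses are the dF/F segments of isolated ``n_ap``-AP events; noise
    windows share the segments' length and dF/F convention. Raises
    NegativeBaselineError when the baseline is negative at this r.
    """
    events = find_isolated_events(ap_times, indicator)
    events = [e for e in events if e.n_aps == n_ap]
    events = compute_event_dff(f_true, events, indicator)
    if not events:
        raise ValueError(f"no isolated {n_ap} AP events with full coverage")
    if any(e.f0_local <= 0 for e in events):
        raise NegativeBaselineError("an event has non-positive F0_local")
    resp = np.stack([e.dff_segment for e in events])
    pre_frames = events[0].t0_index
    f0_global = min(e.f0_local for e in events)
    raw_noise, starts = sample_noise_segments(f_true, ap_times, resp.shape[1], indicator)
    noise = noise_segments_dff(raw_noise, pre_frames, f0_global)
    return resp, noise, starts


def optimize_r(f_cell_measured: FluoTrace, f_neuropil: FluoTrace,
               ap_times: np.ndarray, r_grid: np.ndarray | None = None,
               indicator: str = "6f", n_ap: int = 1) -> OptimizeRResult:
    """Choose the neuropil scale factor r that maximizes ROC area.

    For each r on the grid the trace is re-subtracted, the 1 AP template is
    rebuilt, and the ROC recomputed. Values of r that drive any event
    baseline non-positive are flagged and excluded from the argmax; ties go
    to the smallest r.
    """
    if r_grid is None:
        r_grid = np.round(np.arange(0.0, 1.2001, 0.05), 10)
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size == 0 or np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be nonempty and ascending")
    aucs = np.full(r_grid.size, np.nan)
    flagged = np.zeros(r_grid.size, dtype=bool)
    best_roc = {}
    for i, r in enumerate(r_grid):
        f_true = subtract_neuropil(f_cell_measured, f_neuropil, r, fallback=False).trace
        try:
            resp, noise, _ = response_and_noise(f_true, ap_times, indicator, n_ap)
        except NegativeBaselineError:
            flagged[i] = True
            continue
        template = build_template(resp)
        roc = roc_from_projection(resp, noise, template)
        aucs[i] = roc.auc
        best_roc[i] = roc
    if flagged.all():
        raise ValueError("every r on the grid produced a negative baseline")
    valid = np.where(~flagged)[0]
    i_opt = valid[int(np.argmax(aucs[valid]))]
    return OptimizeRResult(r_opt=float(r_grid[i_opt]), r_grid=r_grid, auc=aucs,
                           flagged=flagged, roc_opt=best_roc.get(i_opt))
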
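"""End-to-end workflows combining the analysis stages.

These are the compositions a calibration study runs repeatedly: extract and
subtract traces, build the ground-truth-optimized detector, repeat on the
downsampled movie, and score blind inference on the same recording. They
exist so scripts and tests exercise one code path.
"""

from __future__ import annotations

import numpy as np

from .detection import (build_template, detection_probability, response_and_noise,
                        roc_from_projection, sample_noise_segments)
from .downsample import downsample_movie, extract_tiled_traces
from .imaging import (FluoTrace, compute_event_dff, find_isolated_events,
                      subtract_neuropil)
from .inference_eval import (Kernel, binned_mcc, binned_pearson,
                             inference_event_roc, nnd_deconvolve)
from .synthetic_data import GroundTruthRecording


def qc_recording(seed: int, duration=8.0, firing=3.0, noise=0.022, amp=1.0,
                 fwhm=1.0, drift=0.02, mod=0.4, amp_tr=0.006, noise_tr=0.005,
                 fwhm_tr=0.006) -> GroundTruthRecording:
    """A small paired recording for quality-control studies.

    Defaults sit strictly inside the reference design of
    ``qc_reference_set`` on every axis — including the magnitudes of the
    slow trends — so that a clean recording's metrics fall within the
    reference envelope rather than at its boundary.
    """
    from .synthetic_data import SimConfig, simulate_recording

    cfg = SimConfig(seed=seed, duration_s=duration, fov_px=(16, 16),
                    soma_radius_px=3, neuropil_ring_px=(1, 4), firing_rate=firing,
                    ap_amp_mv=amp, vm_noise_mv=noise, ap_fwhm_ms=fwhm,
                    drift_mv_per_s=drift, rate_mod_frac=mod, rate_mod_period_s=10.0,
                    ap_amp_trend_frac_per_s=amp_tr, noise_trend_frac_per_s=noise_tr,
                    ap_fwhm_trend_frac_per_s=fwhm_tr)
    return simulate_recording(cfg)


def qc_reference_set(base_seed: int = 100, n: int = 20) -> list:
    """A heterogeneous reference set of known-good recordings for the QC gate.

    Real reference datasets span short sparse recordings (wide metric
    distributions), mid-length ones, and long dense ones (pinning the low
    end of the positive noise statistics), with natural variation in noise,
    amplitude, spike width, drift, and slow nonstationarities. The gate's
    acceptable ranges are only as wide as this heterogeneity.
    """
    refs = []
    for i in range(n):
        if i < 8:
            dur, fir = 4.5 + 0.2 * i, 1.3 + 0.07 * i
        elif i < 14:
            dur, fir = 7.0 + 0.4 * (i - 8), 2.3 + 0.25 * (i - 8)
        else:
            dur, fir = 9.0 + 0.15 * (i - 14), 6.0 + 0.5 * (i - 14)
        refs.append(qc_recording(
            base_seed + i, duration=dur, firing=fir,
            noise=[0.012, 0.02, 0.028, 0.04][i % 4],
            amp=[0.6, 1.0, 1.5][i % 3],
            fwhm=[0.7, 0.9, 1.1, 1.4][(i // 3) % 4],
            drift=[-0.04, -0.015, 0.015, 0.04][(i // 4) % 4],
            mod=[0.0, 0.3, 0.6, 0.85][i % 4],
            amp_tr=[-0.012, -0.004, 0.004, 0.012][(i // 2) % 4],
            noise_tr=[-0.01, -0.003, 0.003, 0.01][(i // 5) % 4],
            fwhm_tr=[-0.012, -0.004, 0.004, 0.012][(i + 1) % 4]))
    return refs


def subtracted_trace(rec: GroundTruthRecording, r: float | None = None,
                     fallback: bool = False) -> FluoTrace:
    """Extract soma/neuropil traces and apply r-scaled neuropil subtraction.

    Defaults to the recording's true contamination factor.
    """
    from .imaging import extract_traces

    f_cell, f_np = extract_traces(rec.movie, rec.soma_mask, rec.neuropil_mask,
                                  rec.frame_rate)
    r = rec.config.r_true if r is None else r
    return subtract_neuropil(f_cell, f_np, r, fallback=fallback).trace


def ground_truth_detection(f_true: FluoTrace, ap_times: np.ndarray,
                           indicator: str, n_ap: int = 1, fp: float = 0.01) -> float:
    """Detection probability of the template-projection detector at fixed fp."""
    resp, noise, _ = response_and_noise(f_true, ap_times, indicator, n_ap=n_ap)
    template = build_template(resp)
    roc = roc_from_projection(resp, noise, template)
    return detection_probability(roc, fp)


def downsampled_trace(rec: GroundTruthRecording, r: float | None = None
                      ) -> FluoTrace:
    """Consensus somatic trace of the 4x/5x downsampled movie, subtracted."""
    ds = downsample_movie(rec.movie, frame_rate=rec.frame_rate)
    tiled_soma = extract_tiled_traces(ds, rec.soma_mask)
    tiled_np = extract_tiled_traces(ds, rec.neuropil_mask)
    r = rec.config.r_true if r is None else r
    return subtract_neuropil(FluoTrace(tiled_soma.consensus, ds.frame_rate),
                             FluoTrace(tiled_np.consensus, ds.frame_rate),
                             r, fallback=False).trace


def dff_trace(f_true: FluoTrace, baseline_percentile: float = 20.0) -> FluoTrace:
    """Whole-trace dF/F against a low-percentile baseline (for inference)."""
    f0 = float(np.percentile(f_true.values, baseline_percentile))
    if f0 <= 0:
        raise ValueError("non-positive baseline; reduce the neuropil r")
    return FluoTrace((f_true.values - f0) / f0, f_true.rate, f_true.t0)


def nnd_event_detection(rec: GroundTruthRecording, f_true: FluoTrace,
                        indicator: str, fp: float = 0.01,
                        upsample_to: float | None = None) -> dict:
    """Blind NND on the recording's dF/F, scored per event class at fixed fp."""
    cfg = rec.config
    dff = dff_trace(f_true)
    work_rate = upsample_to if upsample_to else f_true.rate
    kernel = Kernel.from_time_constants(cfg.tau_rise, cfg.tau_decay, work_rate,
                                        amp_1ap=cfg.kernel_amp_1ap)
    inferred = nnd_deconvolve(dff, kernel, upsample_to=upsample_to)
    events = find_isolated_events(rec.ap_times, indicator)
    events = compute_event_dff(f_true, events, indicator)
    if not events:
        raise ValueError("no isolated events with full coverage")
    window = events[0].dff_segment.size
    _, starts = sample_noise_segments(f_true, rec.ap_times, window, indicator)
    return inference_event_roc(inferred, events, starts, window_frames=window, fp=fp)


def inference_metrics(inferred, true_counts: np.ndarray,
                      bins_ms=(33, 100, 250, 300, 500)) -> dict:
    """Binned Pearson and Matthews correlation over the standard bin grid."""
    out = {}
    for b in bins_ms:
        out[f"pearson@{b}ms"] = binned_pearson(inferred, true_counts, b / 1e3)
        out[f"mcc@{b}ms"] = binned_mcc(inferred, true_counts, b / 1e3)
    return out
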
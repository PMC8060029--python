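"""Population-imaging simulation by block downsampling, with trace QC.

High-resolution single-soma movies are block-averaged 4x in space and 5x
in time (158 -> ~30 Hz, ~0.2 -> 0.8 um pixels) to mimic large field-of-view
population imaging. All 20 phase variants (4 spatial x 5 temporal start
offsets) are produced in parallel; their somatic traces are tiled into 400
nearly identical ROIs. Downstream QC clusters the traces (DBSCAN on
1 - Pearson distance), rejects clusters whose median is indistinguishable
from white noise (KS test), and picks the cluster-median combination most
correlated with the electrophysiological AP train, calibrated against a
Poisson-train null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import DBSCAN

SPATIAL_FACTOR = 4
TEMPORAL_FACTOR = 5


@dataclass
class DownsampleSet:
    """The 20 phase variants of one downsampled movie."""

    variants: list                  # 20 arrays (frames, H', W'), phase order
    phases: list                    # (spatial, temporal) offsets
    sf: int
    tf: int
    frame_rate: float               # output rate = input rate / tf
    n_frames: int                   # common (minimum) variant frame count
    pixel_size_um: float = float("nan")   # output pixel size = input * sf


@dataclass
class TiledTraces:
    traces: np.ndarray              # (400, T) tiled ROI traces
    variant_traces: np.ndarray      # (20, T) one somatic trace per variant
    consensus: np.ndarray           # median across the 20 variants


@dataclass
class ClusterQC:
    labels: np.ndarray
    cluster_medians: list
    cluster_sizes: list
    ks_p: list
    kept: list                      # indices into cluster_medians with p < alpha
    selected_trace: np.ndarray | None = None
    null_percentile_passed: bool | None = None


@dataclass
class SelectResult:
    trace: np.ndarray
    passed: bool
    best_corr: float
    null_threshold: float
    best_combo: tuple


def downsample_movie(movie: np.ndarray, sf: int = SPATIAL_FACTOR,
                     tf: int = TEMPORAL_FACTOR, frame_rate: float | None = None,
                     pixel_size_um: float | None = None) -> DownsampleSet:
    """Block-mean downsampling with all sf x tf phase offsets.

    Variant (p, q) starts at pixel p (both axes) and frame q; trailing
    partial blocks are dropped.
    """
    t, h, w = movie.shape
    if h < sf or w < sf or t < tf:
        raise ValueError("movie smaller than one downsampling block")
    variants, phases = [], []
    for p in range(sf):
        for q in range(tf):
            sub = movie[q:, p:, p:]
            tt = sub.shape[0] // tf * tf
            hh = sub.shape[1] // sf * sf
            ww = sub.shape[2] // sf * sf
            sub = sub[:tt, :hh, :ww].astype(np.float64)
            v = sub.reshape(tt // tf, tf, hh // sf, sf, ww // sf, sf).mean(axis=(1, 3, 5))
            variants.append(v)
            phases.append((p, q))
    n_frames = min(v.shape[0] for v in variants)
    rate = (frame_rate / tf) if frame_rate else float("nan")
    px = (pixel_size_um * sf) if pixel_size_um else float("nan")
    return DownsampleSet(variants=variants, phases=phases, sf=sf, tf=tf,
                         frame_rate=rate, n_frames=n_frames, pixel_size_um=px)


def _downsample_mask(mask: np.ndarray, sf: int, phase: int) -> np.ndarray:
    sub = mask[phase:, phase:].astype(float)
    hh = sub.shape[0] // sf * sf
    ww = sub.shape[1] // sf * sf
    frac = sub[:hh, :ww].reshape(hh // sf, sf, ww // sf, sf).mean(axis=(1, 3))
    ds = frac >= 0.5
    if not ds.any():
        ds = frac > 0
    return ds


def extract_tiled_traces(ds: DownsampleSet, soma_mask: np.ndarray) -> TiledTraces:
    """Somatic ROI trace per variant, tiled to the 400 nearly identical ROIs.

    The soma mask is block-downsampled per spatial phase (blocks with >= 50%
    soma coverage); traces are trimmed to the common frame count and each
    variant's trace is replicated into the 4 x 5 tiling.
    """
    if len(ds.variants) != ds.sf * ds.tf:
        raise ValueError(f"need all {ds.sf * ds.tf} phase variants")
    traces = []
    for v, (p, _) in zip(ds.variants, ds.phases):
        m = _downsample_mask(soma_mask, ds.sf, p)
        if not m.any():
            raise ValueError("soma mask vanished after downsampling")
        traces.append(v[:ds.n_frames, m].mean(axis=1))
    variant_traces = np.stack(traces)
    tiled = np.repeat(variant_traces, ds.sf * ds.tf, axis=0)
    consensus = np.median(variant_traces, axis=0)
    return TiledTraces(traces=tiled, variant_traces=variant_traces,
                       consensus=consensus)


def cluster_and_test(traces: np.ndarray, eps: float = 0.2, min_samples: int = 5,
                     alpha: float = 0.05, seed: int = 0) -> ClusterQC:
    """DBSCAN the traces (1 - Pearson distance) and KS-test cluster medians.

    Each cluster median is compared against white noise of the same mean
    and standard deviation (two-sample KS); clusters whose median is NOT
    significantly different from noise (p >= alpha) are rejected as
    artifact. An empty kept set signals a failed recording downstream.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need at least two traces")
    sd = traces.std(axis=1)
    z = (traces - traces.mean(axis=1, keepdims=True))
    z[sd > 0] /= np.linalg.norm(z[sd > 0], axis=1, keepdims=True)
    corr = z @ z.T
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(dist).labels_
    rng = np.random.default_rng(seed)
    medians, sizes, ks_p, kept = [], [], [], []
    for ci, c in enumerate(sorted(set(labels) - {-1})):
        med = np.median(traces[labels == c], axis=0)
        medians.append(med)
        sizes.append(int(np.sum(labels == c)))
        mstd = med.std()
        if mstd == 0:
            p = 1.0
        else:
            white = rng.normal(med.mean(), mstd, size=med.size)
            p = float(stats.ks_2samp(med, white).pvalue)
        ks_p.append(p)
        if p < alpha:
            kept.append(ci)
    return ClusterQC(labels=labels, cluster_medians=medians, cluster_sizes=sizes,
                     ks_p=ks_p, kept=kept)


def _binned_train(ap_times: np.ndarray, n_frames: int, frame_rate: float,
                  smooth_frames: int) -> np.ndarray:
    counts = np.zeros(n_frames)
    if len(ap_times):
        idx = np.clip((np.asarray(ap_times) * frame_rate).astype(int), 0, n_frames - 1)
        np.add.at(counts, idx, 1.0)
    if smooth_frames > 1:
        counts = np.convolve(counts, np.ones(smooth_frames), mode="same")
    return counts


def select_trace(cluster_medians: list, cluster_sizes: list, ap_times: np.ndarray,
                 frame_rate: float, n_null: int = 1000, seed: int = 0,
                 smooth_frames: int = 3) -> SelectResult:
    """Pick the cluster-median combination best correlated with the AP train.

    Candidates are sums over every non-empty subset of the (up to) three
    largest kept clusters. The target is the AP count per downsampled frame,
    box-car smoothed over ``smooth_frames``. Significance is calibrated
    against ``n_null`` rate-matched Poisson trains: the null statistic is
    the maximum candidate correlation per random train (so candidate
    selection does not bias the calibration), and the recording passes only
    if the best real correlation exceeds the null's 99.5th percentile.
    """
    if not cluster_medians:
        raise ValueError("no kept clusters: recording failed")
    order = np.argsort(cluster_sizes)[::-1][:3]
    top = [np.asarray(cluster_medians[i], dtype=float) for i in order]
    n_frames = top[0].size
    combos = []
    for mask in range(1, 2 ** len(top)):
        members = tuple(i for i in range(len(top)) if mask >> i & 1)
        combos.append((members, np.sum([top[i] for i in members], axis=0)))

    target = _binned_train(ap_times, n_frames, frame_rate, smooth_frames)

    def standardize(a):
        a = a - a.mean(axis=-1, keepdims=True)
        n = np.linalg.norm(a, axis=-1, keepdims=True)
        n[n == 0] = 1.0
        return a / n

    cand = standardize(np.stack([c for _, c in combos]))
    corr = cand @ standardize(target[None, :])[0]
    best_i = int(np.argmax(corr))
    best_corr = float(corr[best_i])

    rng = np.random.default_rng(seed)
    duration = n_frames / frame_rate
    rate = len(ap_times) / duration if duration > 0 else 0.0
    null_counts = rng.poisson(rate / frame_rate, size=(n_null, n_frames)).astype(float)
    if smooth_frames > 1:
        kern = np.ones(smooth_frames)
        null_counts = np.apply_along_axis(
            lambda x: np.convolve(x, kern, mode="same"), 1, null_counts)
    null_corr = (cand @ standardize(null_counts).T).max(axis=0)
    thr = float(np.percentile(null_corr, 99.5))
    passed = best_corr > thr
    return SelectResult(trace=combos[best_i][1], passed=bool(passed),
                        best_corr=best_corr, null_threshold=thr,
                        best_combo=combos[best_i][0])


def robust_std(trace: np.ndarray, clip: float = 4.0) -> float:
    """Median-based noise estimate of a trace, insensitive to transients.

    Works on first differences scaled by 1/sqrt(2) (removing slow signal),
    takes 1.4826 x MAD, excludes samples further than ``clip`` x that
    initial estimate from the median, and recomputes the scaled MAD on the
    survivors. Returns 0 for a constant trace.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 10:
        raise ValueError("need >= 10 samples")
    d = np.diff(trace) / np.sqrt(2.0)
    med = np.median(d)
    r0 = 1.4826 * np.median(np.abs(d - med))
    if r0 == 0:
        return 0.0
    keep = np.abs(d - med) <= clip * r0
    dk = d[keep]
    return float(1.4826 * np.median(np.abs(dk - np.median(dk))))
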
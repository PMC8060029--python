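"""Blind spike inference (non-negative deconvolution) and its evaluation.

``nnd_deconvolve`` inverts the calcium kernel under a non-negativity
constraint on the per-frame AP estimate (unconstrained in the sense of
carrying no sparseness penalty). The evaluation harness — binned Pearson
correlation, Matthews correlation coefficient, and an event-class ROC at
fixed false-positive probability — accepts any algorithm's non-negative
per-frame output, so externally computed inference traces can be scored
alongside the native solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .imaging import APEvent, FluoTrace
from .kernels import kernel_samples


@dataclass
class Kernel:
    """Sampled single-AP calcium kernel at a working rate.

    The peak equals the configured single-AP amplitude, so a unit of
    inferred activity corresponds to one AP and total inferred mass is
    comparable to AP counts.
    """

    samples: np.ndarray
    rate: float

    @classmethod
    def from_time_constants(cls, tau_rise: float, tau_decay: float, rate: float,
                            amp_1ap: float = 1.0, support_tau: float = 6.0) -> "Kernel":
        return cls(kernel_samples(tau_rise, tau_decay, rate, amplitude=amp_1ap,
                                  support_tau=support_tau), rate)


@dataclass
class InferredActivity:
    """Per-frame non-negative AP-count estimate.

    When the solve ran on an upsampled grid, ``working_values`` /
    ``working_rate`` hold the fine-grid solution (native ``values`` are its
    frame sums).
    """

    values: np.ndarray
    rate: float
    algorithm: str = "nnd"
    working_values: np.ndarray | None = None
    working_rate: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("inferred activity must be non-negative")

    def at_working_rate(self) -> "InferredActivity":
        """The solution on the (possibly upsampled) solver grid."""
        if self.working_values is None:
            return self
        return InferredActivity(self.working_values, self.working_rate,
                                self.algorithm)


def _conv(s: np.ndarray, k: np.ndarray, n: int) -> np.ndarray:
    return signal.fftconvolve(s, k)[:n]


def _conv_T(r: np.ndarray, k: np.ndarray, n: int) -> np.ndarray:
    return signal.fftconvolve(r[::-1], k)[:n][::-1]


def kkt_residual(s: np.ndarray, y: np.ndarray, kernel: Kernel) -> float:
    """Max violation of the non-negative least-squares optimality conditions.

    At the optimum the gradient g of 0.5||K s - y||^2 satisfies g >= 0 where
    s = 0 and g = 0 where s > 0; the residual is the largest violation.
    """
    n = y.size
    g = _conv_T(_conv(s, kernel.samples, n) - y, kernel.samples, n)
    active = s > 1e-12
    res = 0.0
    if active.any():
        res = float(np.max(np.abs(g[active])))
    if (~active).any():
        res = max(res, float(np.max(-g[~active], initial=0.0)))
    return res


def nnd_deconvolve(dff: FluoTrace, kernel: Kernel, upsample_to: float | None = None,
                   gtol: float = 1e-10, maxiter: int = 50000) -> InferredActivity:
    """Non-negative deconvolution: min_s ||F - K*s||^2 subject to s >= 0.

    If ``upsample_to`` is given, the spike vector lives on a finer time grid
    (an integer multiple of the native frame rate): the forward model
    convolves the fine-grid spikes with the fine-rate kernel and averages
    back to the observed frames, giving sub-frame spike placement without
    touching the data. The fine model class essentially contains the coarse
    one, which is why upsampling helps low-frame-rate traces. The solution
    is aggregated to native frames by summing. Solved with bound-constrained
    quasi-Newton iterations to a projected-gradient tolerance of ``gtol``.
    """
    y = np.asarray(dff.values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite fluorescence input")
    rate = dff.rate
    factor = 1
    if upsample_to is not None:
        factor = int(round(upsample_to / rate))
        if factor < 1:
            raise ValueError("upsample_to must exceed the native rate")
        work_rate = rate * factor
    else:
        work_rate = rate
    if not np.isclose(kernel.rate, work_rate, rtol=1e-6):
        raise ValueError("kernel rate must match the working rate")
    k = np.asarray(kernel.samples, dtype=float)
    n_obs = y.size
    n = n_obs * factor

    def fg(s):
        model = _conv(s, k, n)
        if factor > 1:
            model = model.reshape(-1, factor).mean(axis=1)
        r = model - y
        f = 0.5 * float(r @ r)
        if factor > 1:
            r_fine = np.repeat(r, factor) / factor
        else:
            r_fine = r
        return f, _conv_T(r_fine, k, n)

    res = optimize.minimize(fg, np.zeros(n), jac=True, method="L-BFGS-B",
                            bounds=[(0.0, None)] * n,
                            options=dict(maxiter=maxiter, maxfun=4 * maxiter,
                                         ftol=1e-16, gtol=gtol))
    s = np.maximum(res.x, 0.0)
    if factor > 1:
        return InferredActivity(values=s.reshape(-1, factor).sum(axis=1), rate=rate,
                                working_values=s, working_rate=work_rate)
    return InferredActivity(values=s, rate=rate)


def _bin_series(x: np.ndarray, bin_frames: int) -> np.ndarray:
    n = x.size // bin_frames * bin_frames
    return x[:n].reshape(-1, bin_frames).sum(axis=1)


def binned_pearson(inferred: InferredActivity, true_counts: np.ndarray,
                   bin_s: float) -> float:
    """Pearson correlation of the two series after summing into time bins.

    Returns NaN when either binned series is constant (correlation
    undefined).
    """
    true_counts = np.asarray(true_counts, dtype=float)
    if true_counts.size != inferred.values.size:
        raise ValueError("inferred and true series must share a time base")
    bin_frames = max(1, int(round(bin_s * inferred.rate)))
    a = _bin_series(inferred.values, bin_frames)
    b = _bin_series(true_counts, bin_frames)
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def binned_mcc(inferred: InferredActivity, true_counts: np.ndarray, bin_s: float,
               threshold: float = 0.0) -> float:
    """Matthews correlation of event presence/absence per time bin.

    Bins are marked active when summed inferred activity exceeds
    ``threshold`` (truth: >= 1 AP). Returns 0 when any confusion-table
    margin is zero.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    true_counts = np.asarray(true_counts, dtype=float)
    if true_counts.size != inferred.values.size:
        raise ValueError("inferred and true series must share a time base")
    bin_frames = max(1, int(round(bin_s * inferred.rate)))
    a = _bin_series(inferred.values, bin_frames) > threshold
    b = _bin_series(true_counts, bin_frames) >= 1.0
    tp = np.sum(a & b)
    fp = np.sum(a & ~b)
    fn = np.sum(~a & b)
    tn = np.sum(~a & ~b)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def inference_event_roc(inferred: InferredActivity, events: list[APEvent],
                        noise_starts: np.ndarray, window_frames: int,
                        fp: float = 0.01) -> dict:
    """Detection probability per AP-count class from windowed inference mass.

    The score of an event (or noise window) is the summed inferred activity
    over ``window_frames`` frames starting at the frame of the first AP (or
    at the noise start). The threshold is the (1 - fp) quantile of the
    noise scores; detection probability per class n = fraction of n AP
    events scoring above it.
    """
    if not 0.0 < fp <= 1.0:
        raise ValueError("fp must lie in (0, 1]")
    noise_starts = np.asarray(noise_starts, dtype=int)
    if noise_starts.size < 2:
        raise ValueError("need >= 2 noise windows")
    vals = inferred.values

    def score(i0):
        return float(np.sum(vals[i0:i0 + window_frames]))

    noise_scores = np.array([score(i) for i in noise_starts
                             if i + window_frames <= vals.size])
    if noise_scores.size < 2:
        raise ValueError("need >= 2 noise windows inside the trace")
    thr = float(np.quantile(noise_scores, 1.0 - fp))
    out: dict[int, float] = {}
    for n in sorted({e.n_aps for e in events}):
        evs = [e for e in events if e.n_aps == n]
        scores = np.array([score(int(np.floor(e.t_first * inferred.rate)))
                           for e in evs])
        out[n] = float(np.mean(scores > thr))
    return out
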
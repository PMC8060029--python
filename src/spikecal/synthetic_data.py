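"""Synthetic paired recordings: cell-attached voltage + two-photon movie.

Generates ground-truth data with the statistical structure the calibration
pipeline assumes: a Poisson AP train with dead time, a stereotyped biphasic
AP waveform on a noisy (optionally drifting) baseline, difference-of-
exponential calcium transients per indicator (GCaMP6s slow/large, GCaMP6f
fast/small), additive r-scaled neuropil contamination, and Poisson photon
shot noise per pixel. Hidden truths (kernel, r_true, photon gain, per-frame
AP counts) ride along for recovery tests.

Controlled artifacts (drift, bleaching, waveform change, AP loss) can be
injected to exercise the quality-control gates.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict, field, replace

import numpy as np

from .ephys import VoltageTrace
from .kernels import dexp_kernel, kernel_samples

#: Order-of-magnitude single-AP transient parameters per indicator.
#: GCaMP6s: slow and large; GCaMP6f: fast and small.
INDICATOR_DEFAULTS = {
    "6s": dict(kernel_amp_1ap=0.25, tau_rise=0.05, tau_decay=0.6),
    "6f": dict(kernel_amp_1ap=0.15, tau_rise=0.015, tau_decay=0.2),
}


class InfeasibleRateError(ValueError):
    """firing_rate x refractory_s >= 1: the requested train cannot exist."""


@dataclass
class SimConfig:
    """Parameters of one simulated paired recording.

    Rates in Hz, times in seconds, voltages in mV, fluorescence amplitudes
    in dF/F units. ``photon_gain``/``pedestal`` convert photon counts to
    recorded fluorescence units: F = gain * photons + pedestal.
    """

    seed: int = 0
    duration_s: float = 60.0
    ephys_rate: float = 40000.0
    frame_rate: float = 158.0
    fov_px: tuple = (64, 64)
    soma_radius_px: int = 10
    indicator: str = "6f"
    kernel_amp_1ap: float | None = None
    tau_rise: float | None = None
    tau_decay: float | None = None
    per_ap_gain: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)   # supralinearity multipliers, 1-5 APs
    firing_rate: float = 2.0
    refractory_s: float = 0.003
    neuropil_amp: float = 0.05
    neuropil_rate: float = 5.0
    r_true: float = 0.8
    baseline_photons: float = 50.0
    photon_gain: float = 2.0
    pedestal: float = 100.0
    ap_amp_mv: float = 1.0
    ap_fwhm_ms: float = 1.0
    vm_noise_mv: float = 0.02
    drift_mv_per_s: float = 0.0
    baseline_mv: float = -45.0
    neuropil_ring_px: tuple = (2, 10)   # neuropil annulus: soma radius + (inner, outer)
    # slow physiological/instrumental nonstationarities (fractional amplitudes)
    rate_mod_frac: float = 0.0          # sinusoidal firing-rate modulation depth
    rate_mod_period_s: float = 30.0
    ap_amp_trend_frac_per_s: float = 0.0   # linear drift of AP amplitude
    ap_fwhm_trend_frac_per_s: float = 0.0  # linear drift of AP width
    noise_trend_frac_per_s: float = 0.0    # linear drift of Vm noise amplitude
    soma_brightness: float = 2.0      # soma vs background resting brightness
    pixel_texture_sd: float = 0.25    # lognormal sd of the static per-pixel gain map
    frame_jitter: float = 0.0         # uniform imaging-clock offset, fraction of a frame

    def __post_init__(self):
        self.fov_px = tuple(self.fov_px)
        self.per_ap_gain = tuple(self.per_ap_gain)
        self.neuropil_ring_px = tuple(self.neuropil_ring_px)
        if self.indicator not in INDICATOR_DEFAULTS:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        for name, default in INDICATOR_DEFAULTS[self.indicator].items():
            if getattr(self, name) is None:
                setattr(self, name, default)
        if not self.tau_rise < self.tau_decay:
            raise ValueError("tau_rise must be < tau_decay")
        if min(self.ephys_rate, self.frame_rate, self.baseline_photons,
               self.photon_gain) <= 0:
            raise ValueError("rates, gain and baseline_photons must be positive")
        if self.refractory_s < 0:
            raise ValueError("refractory_s must be >= 0")
        if len(self.per_ap_gain) > 5:
            raise ValueError("per_ap_gain supports at most 5 AP classes")
        if not 0.0 <= self.r_true <= 1.5:
            raise ValueError("r_true must lie in [0, 1.5]")

    _TUPLE_FIELDS = ("fov_px", "per_ap_gain", "neuropil_ring_px")

    def to_json(self) -> str:
        d = asdict(self)
        for k in self._TUPLE_FIELDS:
            d[k] = list(d[k])
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "SimConfig":
        d = json.loads(s)
        for k in cls._TUPLE_FIELDS:
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class GroundTruthRecording:
    """A paired recording plus the hidden truths needed for recovery tests."""

    ap_times: np.ndarray
    vm: VoltageTrace
    movie: np.ndarray             # (frames, H, W) recorded fluorescence units
    frame_rate: float
    soma_mask: np.ndarray         # bool (H, W)
    neuropil_mask: np.ndarray     # bool (H, W), disjoint from soma_mask
    truth: dict
    config: SimConfig
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.soma_mask & self.neuropil_mask):
            raise ValueError("soma and neuropil masks must be disjoint")
        if self.ap_times.size and np.any(np.diff(self.ap_times) <= 0):
            raise ValueError("ap_times must be strictly increasing")


def _rngs(config: SimConfig, n: int):
    """Independent child generators derived from the config seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def simulate_ap_train(config: SimConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Poisson AP train with dead time ``refractory_s`` over ``duration_s``.

    Inter-AP intervals are refractory_s + Exp(firing_rate), giving an
    effective rate of firing_rate / (1 + firing_rate * refractory_s).
    """
    if config.duration_s <= 0:
        raise ValueError("duration_s must be positive")
    lam = config.firing_rate
    if lam == 0:
        return np.array([])
    if lam * config.refractory_s >= 1:
        raise InfeasibleRateError("firing_rate * refractory_s >= 1 is infeasible")
    if rng is None:
        rng = _rngs(config, 4)[0]
    times = []
    t = 0.0
    m = config.rate_mod_frac
    if not 0.0 <= m < 1.0:
        raise ValueError("rate_mod_frac must lie in [0, 1)")
    lam_max = lam * (1.0 + m)
    if lam_max * config.refractory_s >= 1:
        raise InfeasibleRateError("peak firing rate times refractory_s >= 1")
    phase = rng.uniform(0.0, 2 * np.pi) if m > 0.0 else 0.0
    while True:
        # thinning against the (possibly sinusoidally modulated) peak rate
        t += config.refractory_s + rng.exponential(1.0 / lam_max)
        if t >= config.duration_s:
            break
        if m > 0.0:
            accept = (1.0 + m * np.sin(2 * np.pi * t / config.rate_mod_period_s
                                       + phase)) / (1.0 + m)
            if rng.random() >= accept:
                continue
        times.append(t)
    return np.array(times)


def ap_waveform(config: SimConfig, rate: float | None = None, fwhm_ms: float | None = None):
    """Stereotyped biphasic AP: positive Gaussian lobe then a smaller negative lobe.

    Returns (offsets_in_samples, waveform). The positive lobe peaks at
    ``ap_amp_mv`` with the configured FWHM; the negative (after-hyperpolarizing)
    lobe is 20% as deep and 2.5x wider, delayed by ~1.5 FWHM.
    """
    if config.ap_amp_mv <= 0:
        raise ValueError("ap_amp_mv must be positive")
    rate = rate or config.ephys_rate
    fwhm = (fwhm_ms if fwhm_ms is not None else config.ap_fwhm_ms) * 1e-3
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(10 * sigma * rate))
    off = np.arange(-half, 3 * half + 1)
    t = off / rate
    w = (config.ap_amp_mv * np.exp(-t**2 / (2 * sigma**2))
         - 0.2 * config.ap_amp_mv * np.exp(-(t - 3.5 * sigma)**2 / (2 * (2.5 * sigma)**2)))
    return off, w


def render_vm(ap_times: np.ndarray, config: SimConfig,
              rng: np.random.Generator | None = None,
              fwhm_ms: float | None = None) -> VoltageTrace:
    """Render a voltage trace: baseline + noise + drift + one waveform per AP."""
    if config.ephys_rate < 10000:
        raise ValueError("ephys_rate must be >= 10 kHz")
    if rng is None:
        rng = _rngs(config, 4)[1]
    n = int(round(config.duration_s * config.ephys_rate))
    t = np.arange(n) / config.ephys_rate
    v = config.baseline_mv + config.drift_mv_per_s * t
    if config.vm_noise_mv > 0:
        scale = np.clip(1.0 + config.noise_trend_frac_per_s * t, 0.1, None)
        v = v + config.vm_noise_mv * scale * rng.normal(0.0, 1.0, size=n)
    base_fwhm = fwhm_ms if fwhm_ms is not None else config.ap_fwhm_ms
    off, w = ap_waveform(config, fwhm_ms=base_fwhm)
    for ap in np.asarray(ap_times):
        i = int(round(ap * config.ephys_rate))
        gain = max(1.0 + config.ap_amp_trend_frac_per_s * ap, 0.1)
        if config.ap_fwhm_trend_frac_per_s != 0.0:
            widen = max(1.0 + config.ap_fwhm_trend_frac_per_s * ap, 0.1)
            off, w = ap_waveform(config, fwhm_ms=base_fwhm * widen)
        idx = i + off
        ok = (idx >= 0) & (idx < n)
        v[idx[ok]] += gain * w[ok]
    return VoltageTrace(v, config.ephys_rate)


def group_aps(ap_times: np.ndarray, window_s: float = 0.25):
    """Greedy grouping of APs into events: all APs within ``window_s`` of the
    event's first AP, extending from the earliest unassigned AP. Returns a
    list of arrays of AP times."""
    ap_times = np.asarray(ap_times, dtype=float)
    events = []
    i = 0
    while i < ap_times.size:
        j = i
        while j + 1 < ap_times.size and ap_times[j + 1] - ap_times[i] < window_s:
            j += 1
        events.append(ap_times[i:j + 1])
        i = j + 1
    return events


def event_dff_trace(ap_times: np.ndarray, config: SimConfig, t_frames: np.ndarray) -> np.ndarray:
    """Noiseless somatic dF/F at the frame times: per-event scaled kernels.

    Each 250 ms event of n APs contributes per_ap_gain[n]*n*kernel_amp_1ap
    times the peak-normalized kernel, anchored at the event's first AP.
    """
    dff = np.zeros_like(t_frames)
    gains = np.asarray(config.per_ap_gain, dtype=float)
    for ev in group_aps(ap_times):
        n = ev.size
        g = gains[min(n, gains.size) - 1]
        amp = g * n * config.kernel_amp_1ap
        dff += amp * dexp_kernel(t_frames - ev[0], config.tau_rise, config.tau_decay)
    return dff


def neuropil_dff_trace(config: SimConfig, t_frames: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Neuropil dF/F: an independent Poisson train of the same kernel shape."""
    dff = np.zeros_like(t_frames)
    if config.neuropil_amp <= 0 or config.neuropil_rate <= 0:
        return dff
    n_exp = config.neuropil_rate * config.duration_s
    n = rng.poisson(n_exp)
    times = np.sort(rng.uniform(0.0, config.duration_s, size=n))
    for t0 in times:
        dff += config.neuropil_amp * dexp_kernel(t_frames - t0, config.tau_rise,
                                                 config.tau_decay)
    return dff


def make_masks(config: SimConfig):
    """Soma disk at the field centre; neuropil annulus a little further out."""
    h, w = config.fov_px
    r = config.soma_radius_px
    inner, outer = config.neuropil_ring_px
    yy, xx = np.mgrid[0:h, 0:w]
    d = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    soma = d <= r
    neuropil = (d >= r + inner) & (d <= r + outer)
    if not soma.any() or not neuropil.any():
        raise ValueError("field of view too small for soma disk plus neuropil ring")
    return soma, neuropil


def render_movie(ap_times: np.ndarray, config: SimConfig,
                 vm: VoltageTrace | None = None) -> GroundTruthRecording:
    """Render the movie and assemble a full GroundTruthRecording.

    Non-soma pixels carry the neuropil signal: photon rate
    B * tex * (1 + np_dff), with B = ``baseline_photons`` and ``tex`` a
    static lognormal per-pixel brightness texture. Soma pixels additionally
    receive the point-spread-function leak of the surrounding neuropil —
    baseline and transients alike — scaled by r_true:

        rate = B * tex * [soma_brightness * (1 + soma_dff) + r_true * (1 + np_dff)]

    so subtracting r_true times the neuropil trace from the somatic trace
    recovers the pure somatic fluorescence. Recorded movie value =
    photon_gain * photons + pedestal.
    """
    rng_np, rng_vm, rng_mov, rng_tex = _rngs(config, 4)
    ap_times = np.asarray(ap_times, dtype=float)
    n_frames = int(round(config.duration_s * config.frame_rate))
    offset = 0.0
    if config.frame_jitter:
        offset = rng_mov.uniform(0.0, config.frame_jitter) / config.frame_rate
    t_frames = (np.arange(n_frames) + 0.5) / config.frame_rate + offset

    soma_dff = event_dff_trace(ap_times, config, t_frames)
    np_dff = neuropil_dff_trace(config, t_frames, rng_np)
    if np.any(1.0 + soma_dff < 0) or np.any(1.0 + np_dff < 0):
        raise ValueError("negative intensity: 1 + dF/F < 0")

    soma_mask, neuropil_mask = make_masks(config)
    h, w = config.fov_px
    texture = rng_tex.lognormal(mean=0.0, sigma=config.pixel_texture_sd, size=(h, w))
    base_map = config.baseline_photons * texture
    soma_rate = (config.soma_brightness * (1.0 + soma_dff)
                 + config.r_true * (1.0 + np_dff))

    lam = np.empty((n_frames, h, w), dtype=np.float32)
    lam[:] = (1.0 + np_dff)[:, None, None].astype(np.float32)
    lam[:, soma_mask] = soma_rate[:, None].astype(np.float32)
    lam *= base_map[None, :, :].astype(np.float32)
    photons = rng_mov.poisson(lam).astype(np.float32)
    movie = config.photon_gain * photons + config.pedestal

    frame_idx = np.clip((ap_times * config.frame_rate).astype(int), 0, n_frames - 1)
    true_counts = np.bincount(frame_idx, minlength=n_frames).astype(float) if ap_times.size \
        else np.zeros(n_frames)
    truth = dict(
        kernel=kernel_samples(config.tau_rise, config.tau_decay, config.frame_rate,
                              amplitude=config.kernel_amp_1ap),
        r_true=config.r_true,
        photon_gain=config.photon_gain,
        pedestal=config.pedestal,
        true_counts=true_counts,
        soma_dff=soma_dff,
        neuropil_dff=np_dff,
        frame_times=t_frames,
        baseline_map=np.where(
            soma_mask,
            base_map * (config.soma_brightness + config.r_true),
            base_map),
    )
    if vm is None:
        vm = render_vm(ap_times, config, rng=rng_vm)
    return GroundTruthRecording(ap_times=ap_times, vm=vm, movie=movie,
                                frame_rate=config.frame_rate, soma_mask=soma_mask,
                                neuropil_mask=neuropil_mask, truth=truth, config=config)


def simulate_recording(config: SimConfig) -> GroundTruthRecording:
    """Convenience: AP train -> voltage trace -> movie, all from config.seed."""
    rngs = _rngs(config, 4)
    ap_times = simulate_ap_train(config, rng=rngs[0])
    vm = render_vm(ap_times, config, rng=rngs[1])
    return render_movie(ap_times, config, vm=vm)


ARTIFACT_KINDS = ("drift", "bleach", "waveform_change", "ap_loss")


def inject_artifact(rec: GroundTruthRecording, kind: str, **params) -> GroundTruthRecording:
    """Return a modified copy of ``rec`` carrying one controlled artifact.

    drift: add a linear voltage ramp (mv_per_s, default 0.5).
    bleach: exponential photobleaching of the fluorescence above pedestal
        (tau_s, default duration/3).
    waveform_change: re-render the voltage with 2x wider APs in the second
        half of the recording (widen, default 2.0).
    ap_loss: re-render the voltage with APs after the midpoint removed.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    out = copy.deepcopy(rec)
    cfg = rec.config
    if kind == "drift":
        slope = params.get("mv_per_s", 0.5)
        t = out.vm.times()
        out.vm = VoltageTrace(out.vm.samples + slope * (t - t[0]), out.vm.rate, out.vm.t0)
        params = {"mv_per_s": slope}
    elif kind == "bleach":
        tau = params.get("tau_s", cfg.duration_s / 3.0)
        t = (np.arange(out.movie.shape[0]) + 0.5) / out.frame_rate
        decay = np.exp(-t / tau).astype(np.float32)
        out.movie = cfg.pedestal + (out.movie - cfg.pedestal) * decay[:, None, None]
        params = {"tau_s": tau}
    elif kind == "waveform_change":
        widen = params.get("widen", 2.0)
        rng_seed = np.random.SeedSequence(cfg.seed).spawn(4)[1]
        v1 = render_vm(rec.ap_times, cfg, rng=np.random.default_rng(rng_seed))
        rng_seed = np.random.SeedSequence(cfg.seed).spawn(4)[1]
        v2 = render_vm(rec.ap_times, cfg, rng=np.random.default_rng(rng_seed),
                       fwhm_ms=cfg.ap_fwhm_ms * widen)
        half = v1.samples.size // 2
        merged = np.concatenate([v1.samples[:half], v2.samples[half:]])
        out.vm = VoltageTrace(merged, v1.rate, v1.t0)
        params = {"widen": widen}
    elif kind == "ap_loss":
        mid = cfg.duration_s / 2.0
        kept = rec.ap_times[rec.ap_times < mid]
        rng_seed = np.random.SeedSequence(cfg.seed).spawn(4)[1]
        out.vm = render_vm(kept, cfg, rng=np.random.default_rng(rng_seed))
        params = {"midpoint_s": mid}
    out.provenance = list(rec.provenance) + [{"artifact": kind, **params}]
    return out
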
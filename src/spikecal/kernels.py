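"""Difference-of-exponentials calcium transient kernel.

The single-AP fluorescence response of a GECI is modelled as

    k(t) = A * (exp(-t / tau_decay) - exp(-t / tau_rise)),  t >= 0

with tau_rise < tau_decay. ``A`` is chosen so the kernel peaks at a
configured amplitude (default 1), which makes event amplitudes read
directly in dF/F units per AP.
"""

from __future__ import annotations

import numpy as np


def dexp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the kernel maximum, (tr*td/(td-tr)) * log(td/tr)."""
    if not tau_rise < tau_decay:
        raise ValueError("tau_rise must be < tau_decay")
    return tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)


def dexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float,
                amplitude: float = 1.0) -> np.ndarray:
    """Evaluate the peak-normalized difference-of-exponentials kernel.

    Zero for t < 0; maximum equals ``amplitude``.
    """
    if not tau_rise < tau_decay:
        raise ValueError("tau_rise must be < tau_decay")
    t = np.asarray(t, dtype=float)
    tp = dexp_peak_time(tau_rise, tau_decay)
    peak = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    out = np.where(
        t >= 0.0,
        np.exp(-np.maximum(t, 0.0) / tau_decay) - np.exp(-np.maximum(t, 0.0) / tau_rise),
        0.0,
    )
    return amplitude * out / peak


def kernel_samples(tau_rise: float, tau_decay: float, rate: float,
                   amplitude: float = 1.0, support_tau: float = 6.0) -> np.ndarray:
    """Sample the kernel on a regular grid with support >= support_tau * tau_decay."""
    n = int(np.ceil(support_tau * tau_decay * rate)) + 1
    t = np.arange(n) / rate
    return dexp_kernel(t, tau_rise, tau_decay, amplitude)
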
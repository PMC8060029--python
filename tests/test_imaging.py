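"""Imaging tests: traces, neuropil subtraction, events, dF/F, fits, photons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecal.imaging import (FluoTrace, NegativeBaselineError, compute_event_dff,
                              extract_traces, find_isolated_events, fit_photon_gain,
                              fit_transient, soma_photon_trace, subtract_neuropil,
                              to_photons, trial_variability)
from spikecal.kernels import dexp_kernel, dexp_peak_time


class TestExtractTraces:
    def test_constant_movie(self):
        movie = np.full((10, 8, 8), 7.0)
        soma = np.zeros((8, 8), bool); soma[2:4, 2:4] = True
        npil = np.zeros((8, 8), bool); npil[6:, 6:] = True
        fc, fn = extract_traces(movie, soma, npil, rate=30.0)
        assert np.allclose(fc.values, 7.0) and np.allclose(fn.values, 7.0)

    def test_single_pixel_mask(self):
        rng = np.random.default_rng(0)
        movie = rng.normal(size=(20, 4, 4))
        soma = np.zeros((4, 4), bool); soma[1, 1] = True
        npil = np.zeros((4, 4), bool); npil[3, 3] = True
        fc, _ = extract_traces(movie, soma, npil, rate=30.0)
        assert np.array_equal(fc.values, movie[:, 1, 1])

    def test_empty_mask_raises(self):
        movie = np.zeros((5, 4, 4))
        with pytest.raises(ValueError):
            extract_traces(movie, np.zeros((4, 4), bool), np.ones((4, 4), bool), 30.0)


class TestSubtractNeuropil:
    def test_r_zero_is_identity(self):
        fc = FluoTrace(np.array([10.0, 12.0]), 30.0)
        fn = FluoTrace(np.array([5.0, 5.0]), 30.0)
        out = subtract_neuropil(fc, fn, 0.0)
        assert np.array_equal(out.trace.values, fc.values) and out.r_used == 0.0

    def test_arithmetic(self):
        fc = FluoTrace(np.array([10.0, 12.0]), 30.0)
        fn = FluoTrace(np.array([5.0, 5.0]), 30.0)
        out = subtract_neuropil(fc, fn, 0.8)
        assert np.allclose(out.trace.values, [6.0, 8.0])

    def test_fallback_ladder_and_flag(self):
        fc = FluoTrace(np.full(100, 10.0), 30.0)
        fn = FluoTrace(np.full(100, 13.0), 30.0)
        # 0.8*13 > 10 -> negative; steps down; 0.7*13=9.1 < 10 -> ok
        out = subtract_neuropil(fc, fn, 0.8)
        assert out.r_used == 0.7 and not out.flagged
        fn2 = FluoTrace(np.full(100, 25.0), 30.0)
        out2 = subtract_neuropil(fc, fn2, 0.8)
        assert out2.r_used == 0.5 and out2.flagged

    def test_negative_r_raises(self):
        fc = FluoTrace(np.ones(3), 30.0)
        with pytest.raises(ValueError):
            subtract_neuropil(fc, fc, -0.1)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.0, 1.2), st.floats(0.0, 1.2))
    def test_linearity_in_r(self, r1, r2):
        rng = np.random.default_rng(3)
        fc = FluoTrace(rng.uniform(50, 100, 64), 30.0)
        fn = FluoTrace(rng.uniform(10, 20, 64), 30.0)
        a = subtract_neuropil(fc, fn, r1, fallback=False).trace.values
        b = subtract_neuropil(fc, fn, r2, fallback=False).trace.values
        assert np.allclose(a - b, (r2 - r1) * fn.values, atol=1e-10)


class TestIsolatedEvents:
    def test_6f_example(self):
        evs = find_isolated_events(np.array([1.00, 1.10, 1.20, 2.00]), "6f")
        assert [(e.t_first, e.n_aps) for e in evs] == [(1.00, 3), (2.00, 1)]

    def test_6s_example(self):
        evs = find_isolated_events(np.array([1.0, 1.6]), "6s")
        assert [(e.t_first, e.n_aps) for e in evs] == [(1.0, 1)]

    def test_burst_of_more_than_5_excluded(self):
        aps = np.array([1.0, 1.03, 1.06, 1.09, 1.12, 1.15, 1.18, 5.0])
        evs = find_isolated_events(aps, "6f")
        assert [(e.t_first, e.n_aps) for e in evs] == [(5.0, 1)]

    def test_ap_between_window_and_margin_disqualifies(self):
        # second AP at 260 ms: outside the 250 ms window, inside the 300 ms margin
        evs = find_isolated_events(np.array([1.0, 1.26]), "6f")
        assert all(e.t_first != 1.0 for e in evs)

    def test_every_ap_in_at_most_one_event(self):
        rng = np.random.default_rng(8)
        aps = np.sort(rng.uniform(0, 60, 120))
        aps = aps[np.concatenate([[True], np.diff(aps) > 1e-3])]
        evs = find_isolated_events(aps, "6f")
        used = np.concatenate([e.ap_times for e in evs]) if evs else np.array([])
        assert len(np.unique(used)) == len(used)
        assert set(used).issubset(set(aps))

    def test_unknown_indicator_raises(self):
        with pytest.raises(ValueError):
            find_isolated_events(np.array([1.0]), "7x")


class TestEventDff:
    def _trace_with_kernel(self, aps, amp=0.3, f_base=100.0, rate=158.0, dur=20.0):
        t = (np.arange(int(dur * rate)) + 0.5) / rate
        f = np.full(t.size, f_base)
        for a in aps:
            f += amp * f_base * dexp_kernel(t - a, 0.015, 0.2)
        return FluoTrace(f, rate)

    def test_constant_trace_zero_dff(self):
        tr = FluoTrace(np.full(3000, 50.0), 158.0)
        evs = find_isolated_events(np.array([5.0]), "6f")
        out = compute_event_dff(tr, evs, "6f")
        assert np.allclose(out[0].dff_segment, 0.0) and out[0].peak_dff == 0.0

    def test_peak_matches_analytic_kernel(self):
        aps = np.array([5.0, 10.0])
        tr = self._trace_with_kernel(aps, amp=0.3)
        evs = find_isolated_events(aps, "6f")
        out = compute_event_dff(tr, evs, "6f")
        tp = dexp_peak_time(0.015, 0.2)
        # analytic 100 ms window means, allowing the window centre to land
        # anywhere within one frame of the true peak
        frame = 1.0 / tr.rate
        cands = []
        for shift in np.linspace(-frame, frame, 21):
            tt = np.linspace(tp + shift - 0.05, tp + shift + 0.05, 2001)
            cands.append(0.3 * np.mean(dexp_kernel(tt, 0.015, 0.2)))
        for e in out:
            assert min(cands) * 0.99 <= e.peak_dff <= max(cands) * 1.01

    def test_global_f0_is_min_rule(self):
        rate = 158.0
        f = np.full(int(20 * rate), 100.0)
        f[:int(7 * rate)] = 120.0   # first event sits on a higher local baseline
        tr = FluoTrace(f, rate)
        evs = find_isolated_events(np.array([5.0, 15.0]), "6f")
        out = compute_event_dff(tr, evs, "6f")
        assert out[0].f0_local == pytest.approx(120.0)
        assert out[1].f0_local == pytest.approx(100.0)
        # both events share F0_global = 100 as denominator
        assert np.allclose(out[0].dff_segment[:out[0].t0_index], 0.0)

    def test_scale_invariance(self):
        aps = np.array([5.0, 10.0])
        tr = self._trace_with_kernel(aps)
        evs = find_isolated_events(aps, "6f")
        out1 = compute_event_dff(tr, evs, "6f")
        out2 = compute_event_dff(FluoTrace(3.7 * tr.values, tr.rate), evs, "6f")
        for a, b in zip(out1, out2):
            assert np.allclose(a.dff_segment, b.dff_segment, atol=1e-12)

    def test_negative_global_baseline_raises(self):
        tr = FluoTrace(np.full(3000, -5.0), 158.0)
        evs = find_isolated_events(np.array([5.0]), "6f")
        with pytest.raises(NegativeBaselineError):
            compute_event_dff(tr, evs, "6f")


class TestFitTransient:
    def test_recovers_noiseless_parameters(self):
        rate = 158.0
        t0_index = 15
        t = (np.arange(int(3.0 * rate)) - t0_index) / rate
        seg = 0.3 * (np.exp(-np.maximum(t, 0) / 0.6) - np.exp(-np.maximum(t, 0) / 0.05))
        seg[t < 0] = 0.0
        fit = fit_transient(seg, rate, t0_index=t0_index)
        assert fit.tau_rise == pytest.approx(0.05, rel=0.01)
        assert fit.tau_decay == pytest.approx(0.6, rel=0.01)
        assert fit.amplitude == pytest.approx(0.3, rel=0.01)
        assert not fit.flagged

    def test_all_zero_segment_flagged(self):
        fit = fit_transient(np.zeros(300), 158.0)
        assert fit.amplitude == 0.0 and fit.flagged

    def test_swapped_time_constants_relabeled(self):
        assert fit_transient(np.zeros(10), 30.0).flagged  # degenerate guard
        rate = 100.0
        t = np.arange(300) / rate
        seg = 0.2 * (np.exp(-t / 0.5) - np.exp(-t / 0.04))
        fit = fit_transient(seg, rate)
        assert fit.tau_rise < fit.tau_decay and fit.amplitude > 0


class TestPhotonCalibration:
    def test_formula_arithmetic(self):
        from spikecal.imaging import PhotonCalibration

        calib = PhotonCalibration(slope=np.array([2.0]), offset=np.array([-4.0]))
        assert to_photons(np.array([10.0]), calib)[0] == pytest.approx(4.0)

    def test_simulated_gain_recovered(self, quiet_movie):
        rec = quiet_movie
        calib = fit_photon_gain(rec.movie)
        assert calib.gain == pytest.approx(2.0, rel=0.05)
        assert calib.pedestal == pytest.approx(100.0, abs=5.0)
        photons = to_photons(rec.movie, calib)
        # recovered photon means match the Poisson intensity map
        rel = np.abs(photons.mean(axis=0) - rec.truth["baseline_map"]) \
            / rec.truth["baseline_map"]
        assert rel.mean() < 0.05

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            fit_photon_gain(np.zeros((50, 8, 8)))


class TestTrialVariability:
    def test_identical_trials_fraction_zero(self):
        seg = np.tile(np.concatenate([np.zeros(16), np.ones(30)]), (8, 1))
        assert trial_variability(seg, t0_index=16) == 0.0

    def test_sem_rule_excludes_most_normal_trials(self):
        rng = np.random.default_rng(0)
        n = 400
        seg = np.zeros((n, 46))
        seg[:, 20] = 5.0 + rng.normal(0, 1.0, n)   # peak at a fixed sample
        frac = trial_variability(seg, t0_index=16, rule="sem")
        # the +/-1.96 SEM band shrinks as 1/sqrt(n); nearly all trials fall outside
        assert frac > 0.8

    def test_std_rule_has_nominal_coverage(self):
        rng = np.random.default_rng(1)
        n = 2000
        seg = np.zeros((n, 46))
        seg[:, 20] = 50.0 + rng.normal(0, 3.0, n)
        frac = trial_variability(seg, t0_index=16, rule="std")
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            trial_variability(np.zeros((3, 40)), t0_index=10)
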
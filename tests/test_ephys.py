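"""Ephys tests: detrending, Quiroga threshold, AP detection, QC battery, gate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecal.ephys import (METRIC_NAMES, VoltageTrace, compute_qc_metrics,
                            detect_aps, detrend_vm, qc_gate, quiroga_threshold,
                            sg_smooth)
from spikecal.synthetic_data import SimConfig, render_vm, simulate_ap_train


class TestDetrend:
    def test_constant_trace(self):
        tr = VoltageTrace(np.full(30000, 3.5), 40000.0)
        det, bl = detrend_vm(tr)
        assert np.allclose(det.samples, 0.0, atol=1e-10)
        assert np.allclose(bl.samples, 3.5)

    def test_linear_ramp_removed_in_interior(self):
        rate = 40000.0
        t = np.arange(400000) / rate
        ramp = -45.0 + 0.1 * t
        det, _ = detrend_vm(VoltageTrace(ramp, rate))
        interior = det.samples[20001:-20001]
        assert np.sqrt(np.mean(interior ** 2)) < 1e-9 * np.ptp(ramp)

    def test_baseline_tracks_ramp_under_spike(self):
        cfg = SimConfig(seed=4, duration_s=30.0, drift_mv_per_s=0.2,
                        vm_noise_mv=0.0, ap_amp_mv=1.0)
        vm = render_vm(np.array([15.0]), cfg)
        _, bl = detrend_vm(vm)
        t = vm.times()
        ideal = cfg.baseline_mv + 0.2 * t
        interior = slice(20001, -20001)
        assert np.max(np.abs(bl.samples[interior] - ideal[interior])) < 0.01 * cfg.ap_amp_mv

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            detrend_vm(VoltageTrace(np.zeros(1000), 40000.0))

    def test_sg_reproduces_cubic(self):
        t = np.arange(100000) / 4e4
        x = 1 + 2 * t + 0.5 * t ** 2 - 0.1 * t ** 3
        sm = sg_smooth(x, 20001)
        assert np.max(np.abs((x - sm)[20001:-20001])) < 1e-10


class TestQuiroga:
    def test_gaussian_sd_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0.0, 1.7, size=10 ** 6)
        assert abs(quiroga_threshold(x) - 1.7) / 1.7 < 0.01

    def test_all_zeros(self):
        assert quiroga_threshold(np.zeros(100)) == 0.0

    def test_alternating_unit_samples(self):
        qt = quiroga_threshold(np.array([-1.0, 1.0, -1.0, 1.0]))
        assert qt == pytest.approx(1.0 / 0.6745)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            quiroga_threshold(np.array([]))

    @settings(deadline=None, max_examples=25)
    @given(st.floats(min_value=-50.0, max_value=50.0).filter(lambda c: abs(c) > 1e-6))
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        assert quiroga_threshold(c * x) == pytest.approx(abs(c) * quiroga_threshold(x))


class TestDetectAps:
    def _rendered(self, seed=1, n_aps=3, amp=1.0, noise=0.02):
        cfg = SimConfig(seed=seed, duration_s=10.0, ap_amp_mv=amp, vm_noise_mv=noise)
        aps = np.linspace(2.0, 8.0, n_aps)
        vm = render_vm(aps, cfg)
        det, _ = detrend_vm(vm)
        return aps, det

    @pytest.mark.parametrize("method", ["bandpass", "quiroga"])
    def test_three_injected_aps_found(self, method):
        aps, det = self._rendered()
        train = detect_aps(det, method=method)
        assert len(train) == 3
        assert np.all(np.abs(train.times - aps) < 5e-4)

    def test_pure_noise_no_detections(self):
        rng = np.random.default_rng(2)
        det = VoltageTrace(rng.normal(0, 0.02, size=400000), 40000.0)
        train = detect_aps(det, method="quiroga", k=10.0)
        assert len(train) == 0

    def test_empty_result_is_not_an_error(self):
        det = VoltageTrace(np.random.default_rng(0).normal(0, 1, 40000), 40000.0)
        train = detect_aps(det, method="quiroga", k=50.0)
        assert len(train) == 0 and train.waveforms.shape[0] == 0

    def test_invalid_k_raises(self):
        _, det = self._rendered()
        with pytest.raises(ValueError):
            detect_aps(det, method="quiroga", k=-1.0)

    def test_count_non_increasing_in_k(self):
        _, det = self._rendered(n_aps=5, amp=0.5, noise=0.03)
        counts = [len(detect_aps(det, method="quiroga", k=k))
                  for k in (3.0, 5.0, 8.0, 12.0, 20.0)]
        assert counts == sorted(counts, reverse=True)


@pytest.fixture(scope="module")
def clean_report():
    cfg = SimConfig(seed=31, duration_s=8.0, firing_rate=3.0, ap_amp_mv=1.0)
    vm = render_vm(simulate_ap_train(cfg), cfg)
    return vm, compute_qc_metrics(vm)


class TestQcMetrics:
    def test_all_35_metrics_present(self, clean_report):
        _, rep = clean_report
        assert tuple(rep.metrics) == METRIC_NAMES

    def test_n_aps_matches_detection(self, clean_report):
        vm, rep = clean_report
        det, _ = detrend_vm(vm)
        train = detect_aps(det, method="quiroga", k=10.0)
        assert rep.metrics["n_aps"] == len(train)

    def test_snr_is_median_amp_over_qt(self, clean_report):
        vm, rep = clean_report
        det, _ = detrend_vm(vm)
        train = detect_aps(det, method="quiroga", k=10.0)
        qt = quiroga_threshold(det.samples)
        assert rep.metrics["snr"] == pytest.approx(np.median(train.amplitudes) / qt)

    def test_few_aps_flagged_not_applicable(self):
        cfg = SimConfig(seed=32, duration_s=10.0, firing_rate=0.0)
        vm = render_vm(np.array([5.0]), cfg)
        rep = compute_qc_metrics(vm)
        assert rep.metrics["n_aps"] <= 3
        assert not rep.applicable["snr"]
        assert np.isnan(rep.metrics["ap_amp_mean"])

    def test_stationary_recording_has_no_trend(self):
        # slopes indistinguishable from zero on a drift-free recording
        slopes = {"bl_slope": [], "fr_vs_time_slope": []}
        for seed in range(5):
            cfg = SimConfig(seed=40 + seed, duration_s=8.0, firing_rate=3.0)
            vm = render_vm(simulate_ap_train(cfg), cfg)
            rep = compute_qc_metrics(vm)
            for k in slopes:
                slopes[k].append(rep.metrics[k])
        assert abs(np.mean(slopes["bl_slope"])) < 1e-3          # mV/s
        assert abs(np.mean(slopes["fr_vs_time_slope"])) < 0.15  # Hz/s

    def test_time_reversal_leaves_stationary_metrics(self):
        # symmetric AP waveforms so mirrored snippets are identical
        rate = 40000.0
        rng = np.random.default_rng(5)
        n = int(8 * rate)
        x = -45.0 + rng.normal(0, 0.02, n)
        sigma = int(0.0005 * rate)
        for t_ap in np.arange(1.0, 7.0, 0.37):
            i = int(t_ap * rate)
            w = np.exp(-0.5 * ((np.arange(-4 * sigma, 4 * sigma + 1)) / sigma) ** 2)
            x[i - 4 * sigma:i + 4 * sigma + 1] += w
        fwd = compute_qc_metrics(VoltageTrace(x, rate))
        rev = compute_qc_metrics(VoltageTrace(x[::-1].copy(), rate))
        stationary = ("mrdm", "baseline_mean", "baseline_cv", "qt_mean", "qns",
                      "n_aps", "ml_isi", "ap_amp_mean", "ap_amp_cv", "ap_amp_mrd",
                      "ap_amp_rel_range", "ap_amp_maxmin", "snr", "lwhm", "rwhm",
                      "fwhm", "lwhm_cv", "rwhm_cv", "fwhm_cv", "fr_mean", "fr_cv")
        # time reversal mirrors each waveform, swapping left/right widths
        swapped = {"lwhm": "rwhm", "rwhm": "lwhm",
                   "lwhm_cv": "rwhm_cv", "rwhm_cv": "lwhm_cv"}
        for k in stationary:
            assert fwd.metrics[k] == pytest.approx(
                rev.metrics[swapped.get(k, k)], rel=1e-9), k


@pytest.fixture(scope="module")
def gate_reports():
    reps = []
    for seed in range(8):
        cfg = SimConfig(seed=100 + seed, duration_s=8.0, firing_rate=3.0)
        vm = render_vm(simulate_ap_train(cfg), cfg)
        reps.append(compute_qc_metrics(vm))
    return reps


class TestQcGate:
    def test_member_of_reference_passes(self, gate_reports):
        gated = qc_gate(gate_reports[0], gate_reports[:5])
        assert gated.verdict

    def test_empty_reference_raises(self, gate_reports):
        with pytest.raises(ValueError):
            qc_gate(gate_reports[0], [])

    def test_gate_monotone_in_reference(self, gate_reports):
        probe = gate_reports[-1]
        small = qc_gate(probe, gate_reports[:3])
        large = qc_gate(probe, gate_reports[:7])
        # enlarging the reference can only flip fail -> pass
        for k in METRIC_NAMES:
            if small.flags[k]:
                assert large.flags[k]

    def test_drift_fails_on_baseline_slope(self, gate_reports):
        from spikecal.synthetic_data import inject_artifact, simulate_recording

        cfg = SimConfig(seed=200, duration_s=8.0, firing_rate=3.0,
                        fov_px=(16, 16), soma_radius_px=3, neuropil_ring_px=(1, 4))
        rec = simulate_recording(cfg)
        drifted = inject_artifact(rec, "drift", mv_per_s=1.0)
        gated = qc_gate(compute_qc_metrics(drifted.vm), gate_reports)
        assert not gated.verdict
        assert "bl_slope" in gated.failing or "bl_r2" in gated.failing
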
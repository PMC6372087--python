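"""Train amplitude extraction, Rs correction and RRP back-extrapolation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from synaptiq.core_io import Sweep, TrainRecording
from synaptiq.minis import BiexpKernel
from synaptiq.synthdata import DepletionModelParams, gen_train
from synaptiq.trains import (EPSCTrain, SigmoidParams, backextrapolate_rrp,
                             eval_sigmoid, fit_ca_dose_response, initial_pr,
                             measure_train_amplitudes, normalize_train,
                             rs_offline_correct)


def _train_recording(amps_pa, freq=300.0, dt=2e-5, kernel=None):
    """Synthesize a sweep of overlapping EPSCs with known amplitudes."""
    kernel = kernel or BiexpKernel(0.2, 1.0)
    times = 0.005 + np.arange(len(amps_pa)) / freq
    n = int((times[-1] + 0.02) / dt)
    trace = np.zeros(n)
    w = kernel.sample(dt)
    for t, a in zip(times, amps_pa):
        i0 = int(round(t / dt))
        i1 = min(i0 + w.size, n)
        trace[i0:i1] += a * w[:i1 - i0]
    sw = Sweep(dt=dt, samples=trace)
    return TrainRecording(sw, times, freq)


class TestMeasureTrainAmplitudes:
    def test_identical_events_on_zero_baseline(self):
        rec = _train_recording([2000.0] * 30)
        train = measure_train_amplitudes(rec)
        assert train.amplitudes == pytest.approx(np.full(30, 2000.0), rel=0.02)

    def test_overlapping_residual_current_recovered(self):
        rng = np.random.default_rng(3)
        true = rng.uniform(500.0, 2000.0, 30)
        # physiological decay (~1.5 ms): each response rides on the
        # previous one's tail at the 3.33 ms inter-stimulus interval
        rec = _train_recording(true, kernel=BiexpKernel(0.2, 1.5))
        train = measure_train_amplitudes(rec)
        assert train.amplitudes == pytest.approx(true, rel=0.02)

    def test_empty_stimulus_list(self):
        sw = Sweep(dt=1e-4, samples=np.zeros(100))
        rec = TrainRecording(sw, np.empty(0), 300.0)
        assert measure_train_amplitudes(rec).n_stimuli == 0

    def test_peak_window_beyond_isi_rejected(self):
        rec = _train_recording([1000.0] * 10)
        with pytest.raises(ValueError, match="peak window"):
            measure_train_amplitudes(rec, peak_window_ms=5.0)


class TestRsCorrection:
    def test_zero_rs_is_identity(self):
        t = EPSCTrain([1000.0, 800.0], 300.0, rs_remaining=0.0)
        assert rs_offline_correct(t).amplitudes == pytest.approx(t.amplitudes)

    def test_fixed_point_oracle(self):
        # 4 nA, 2 MOhm, 60 mV driving force: solve I = I_meas*df/(df - I*Rs)
        t = EPSCTrain([4000.0], 300.0, rs_remaining=2.0,
                      reversal=0.0, holding=-60.0)
        corrected = rs_offline_correct(t).amplitudes[0]
        x = 4000.0
        for _ in range(500):
            x = 4000.0 * 60.0 / (60.0 - x * 2.0e-3)
        assert corrected == pytest.approx(x, rel=1e-6)
        # the corrected value satisfies the implicit relation exactly
        assert corrected * (60.0 - corrected * 2.0e-3) == \
            pytest.approx(4000.0 * 60.0, rel=1e-12)

    def test_critical_voltage_error_solved(self):
        # 5 nA, 3 MOhm, 60 mV: voltage error at the corrected amplitude is
        # exactly half the driving force (double root I = dV / 2Rs)
        t = EPSCTrain([5000.0], 300.0, rs_remaining=3.0,
                      reversal=0.0, holding=-60.0)
        assert rs_offline_correct(t).amplitudes[0] == \
            pytest.approx(60.0 / (2 * 3.0e-3), rel=1e-9)

    def test_tiny_current_correction_near_unity(self):
        t = EPSCTrain([1.0], 300.0, rs_remaining=3.0, holding=-60.0)
        assert rs_offline_correct(t).amplitudes[0] == pytest.approx(1.0, rel=1e-4)

    def test_monotone_in_rs(self):
        base = None
        for rs in (0.0, 1.0, 2.0, 3.0):
            t = EPSCTrain([4000.0], 300.0, rs_remaining=rs, holding=-70.0)
            amp = rs_offline_correct(t).amplitudes[0]
            if base is not None:
                assert amp >= base
            base = amp

    def test_pathological_voltage_error_rejected(self):
        t = EPSCTrain([25000.0], 300.0, rs_remaining=3.0, holding=-60.0)
        with pytest.raises(ValueError):
            rs_offline_correct(t)


class TestBackextrapolateRRP:
    def test_noiseless_pure_depletion_closed_form(self):
        train, _ = gen_train(DepletionModelParams(
            n0=100.0, p=0.2, r=0.0, q=1.0, noise_cv=0.0, n_stimuli=30))
        est = backextrapolate_rrp(train)
        total = 100.0 * (1.0 - 0.8 ** 30)
        assert est.rrp == pytest.approx(total, rel=0.02)
        assert est.pr_initial == pytest.approx(0.2, rel=0.02)

    def test_constant_train_pool_equals_single_release(self):
        # with p = 1, r = 1 every stimulus releases the full pool, so the
        # time-zero intercept equals the per-stimulus amplitude
        train = EPSCTrain(np.full(30, 500.0), 300.0)
        est = backextrapolate_rrp(train)
        assert est.rrp == pytest.approx(500.0, rel=1e-9)
        assert est.pr_initial == pytest.approx(1.0)

    def test_facilitating_train_flagged_invalid(self):
        train = EPSCTrain(np.linspace(100.0, 3000.0, 30) ** 1.2, 300.0)
        with pytest.warns(UserWarning, match="invalid"):
            est = backextrapolate_rrp(train)
        assert not est.valid

    def test_noisy_replenishment_recovery(self):
        errs = []
        for seed in range(100):
            train, truth = gen_train(DepletionModelParams(
                n0=100.0, p=0.2, r=0.016, q=30.0, noise_cv=0.1, seed=seed))
            est = backextrapolate_rrp(train)
            errs.append(abs(est.pr_initial - truth["p"]))
        assert np.median(errs) < 0.03

    def test_fit_range_validation(self):
        train = EPSCTrain(np.linspace(300, 100, 30), 300.0)
        with pytest.raises(ValueError, match="fit_range"):
            backextrapolate_rrp(train, (25, 40))

    def test_cumulative_invariants(self):
        train, _ = gen_train(DepletionModelParams(
            n0=100.0, p=0.2, r=0.02, q=30.0, noise_cv=0.05, seed=1))
        est = backextrapolate_rrp(train)
        cum = np.cumsum(train.amplitudes)
        assert np.all(np.diff(cum) >= 0)
        assert est.rrp <= cum[-1]


class TestInitialPr:
    def test_endpoints(self):
        assert initial_pr(0.0, 50.0) == (0.0, False)
        assert initial_pr(50.0, 50.0) == (1.0, False)

    def test_clipping_flag(self):
        with pytest.warns(UserWarning):
            pr, clipped = initial_pr(60.0, 50.0)
        assert pr == 1.0 and clipped

    def test_simulated_pr_distribution_centered_on_truth(self):
        prs = []
        for seed in range(60):
            train, _ = gen_train(DepletionModelParams(
                n0=100.0, p=0.12, r=0.0, q=30.0, noise_cv=0.05,
                n_stimuli=40, seed=seed))
            prs.append(backextrapolate_rrp(train).pr_initial)
        assert np.mean(prs) == pytest.approx(0.12, abs=0.015)

    def test_invalid_rrp_rejected(self):
        with pytest.raises(ValueError):
            initial_pr(10.0, 0.0)


class TestNormalizeTrain:
    def test_depressing_and_facilitating(self):
        assert normalize_train(EPSCTrain([4.0, 2.0, 1.0], 300.0)) == \
            pytest.approx([1.0, 0.5, 0.25])
        assert normalize_train(EPSCTrain([2.0, 3.0], 300.0)) == \
            pytest.approx([1.0, 1.5])

    def test_zero_first_amplitude_rejected(self):
        with pytest.raises(ValueError):
            normalize_train(EPSCTrain([0.0, 1.0], 300.0))

    @given(st.lists(st.floats(1.0, 1e4), min_size=2, max_size=30))
    def test_idempotent(self, amps):
        once = normalize_train(EPSCTrain(amps, 300.0))
        twice = normalize_train(EPSCTrain(once, 300.0))
        assert np.allclose(once, twice)


class TestCaDoseResponse:
    TRUE = SigmoidParams(max=10.0, x_half=1.0, rate=0.3)

    def test_midpoint_identity(self):
        assert eval_sigmoid(self.TRUE, 1.0) == pytest.approx(5.0)

    def test_recovery_at_protocol_concentrations(self):
        x = np.array([0.2, 0.5, 0.75, 1.0, 1.5])
        fit, _ = fit_ca_dose_response(np.column_stack([x, eval_sigmoid(self.TRUE, x)]))
        assert fit.max == pytest.approx(10.0, rel=1e-3)
        assert fit.x_half == pytest.approx(1.0, rel=1e-3)
        assert fit.rate == pytest.approx(0.3, rel=1e-3)

    def test_saturation_limit(self):
        assert eval_sigmoid(self.TRUE, 100.0) == pytest.approx(10.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_ca_dose_response([[0.2, 1.0], [0.5, 2.0], [1.0, 5.0]])
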
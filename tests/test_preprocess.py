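"""Drift correction, epoching, lag search, artifact rejection, trimming."""

import numpy as np
import pytest

from rapidffr.io import ContinuousRecording
from rapidffr.preprocess import (epoch_conventional, epoch_rapid,
                                 find_response_lag, reject_artifacts,
                                 resample_to_nominal, trim_to_elapsed_time)
from rapidffr.simulator import SimulationConfig, simulate_recording_pair
from rapidffr.spectral import average_erp, derive_efr_tfs, harmonic_spectrum

F0, FS = 128.0, 16384.0
L = 128


def _periodic_recording(n_cycles=50, pad=200, amp=1.0):
    n = pad + n_cycles * L + pad
    t = np.arange(n)
    eeg = amp * np.sin(2 * np.pi * t / L)
    return ContinuousRecording(eeg, FS, [10], "positive")


class TestResample:
    def test_zero_drift_is_identity(self):
        cfg = SimulationConfig(n_cycles=300, noise_rms=0.0, seed=0)
        rec, _ = simulate_recording_pair(cfg)
        out = resample_to_nominal(rec, rec.meta["expected_span_s"])
        assert out.meta["drift_ratio"] == pytest.approx(1.0)
        np.testing.assert_array_equal(out.eeg, rec.eeg)

    def test_simulated_drift_recovered(self):
        cfg = SimulationConfig(n_cycles=2000, noise_rms=0.0, drift=1.0005, seed=1)
        rec, _ = simulate_recording_pair(cfg)
        out = resample_to_nominal(rec, rec.meta["expected_span_s"])
        assert out.meta["drift_ratio"] == pytest.approx(1.0005, abs=1e-5)

    def test_drift_correction_restores_harmonics(self):
        cfg = SimulationConfig(n_cycles=2000, noise_rms=0.0, drift=1.0005, seed=1)
        rp, rn = simulate_recording_pair(cfg)
        truth = {**cfg.env_rms, **cfg.tfs_rms}
        erps = []
        for rec in (rp, rn):
            rec = resample_to_nominal(rec, rec.meta["expected_span_s"])
            erps.append(average_erp(epoch_rapid(rec, F0, 2000)))
        spec = harmonic_spectrum(derive_efr_tfs(*erps), F0, FS)
        for k, a in truth.items():
            assert spec.rms[k] == pytest.approx(a, rel=0.02)
        # uncorrected epoching smears the response across bins
        smeared = average_erp(epoch_rapid(rp, F0, 2000)).waveform
        from rapidffr.spectral import harmonic_rms
        assert harmonic_rms(smeared, F0, FS)[1] < 0.1 * truth[1]

    def test_implausible_drift_rejected(self):
        rec = ContinuousRecording(np.zeros(20000), FS, [0, 16384], "positive")
        with pytest.raises(ValueError, match="drift"):
            resample_to_nominal(rec, 0.9)

    def test_single_trigger_rejected(self):
        rec = _periodic_recording()
        with pytest.raises(ValueError, match="two reference triggers"):
            resample_to_nominal(rec, 1.0)


class TestEpochRapid:
    def test_periodic_input_gives_identical_epochs(self):
        rec = _periodic_recording(n_cycles=40)
        ep = epoch_rapid(rec, F0, 30)
        assert ep.trials.shape == (30, L)
        assert np.allclose(ep.trials, ep.trials[0][None], atol=1e-12)

    def test_epochs_tile_the_continuous_segment(self):
        rng = np.random.default_rng(0)
        rec = ContinuousRecording(rng.standard_normal(8000), FS, [5], "positive")
        ep = epoch_rapid(rec, F0, 40)
        start = ep.origin_starts[0]
        np.testing.assert_array_equal(
            ep.trials.reshape(-1), rec.eeg[start:start + 40 * L])
        assert (np.diff(ep.origin_starts) == L).all()

    def test_onset_skip_is_rounded_10ms(self):
        rec = _periodic_recording(n_cycles=40)
        ep = epoch_rapid(rec, F0, 10)
        assert ep.meta["onset_skip_samples"] == 164  # round(0.010 * 16384)

    def test_shortfall_error_names_cycles(self):
        rec = _periodic_recording(n_cycles=10)
        with pytest.raises(ValueError, match="cycles short"):
            epoch_rapid(rec, F0, 100)


class TestLagSearch:
    def test_recovers_constructed_delay(self):
        delay = int(round(0.008 * FS))  # 8 ms
        t = np.arange(2000)
        avg = np.zeros(2000)
        avg[delay:] = np.sin(2 * np.pi * (t[delay:] - delay) / L)
        lag = find_response_lag(avg, F0, FS)
        assert abs(lag - delay) <= 1

    def test_out_of_window_delay_aliases_by_one_cycle(self):
        # a periodic response identifies its lag only modulo one cycle, so
        # a 4 ms delay (below the window) is found one cycle later
        delay = int(round(0.004 * FS))  # 4 ms
        t = np.arange(2000)
        avg = np.zeros(2000)
        avg[delay:] = np.sin(2 * np.pi * (t[delay:] - delay) / L)
        lag = find_response_lag(avg, F0, FS)
        assert int(round(0.005 * FS)) <= lag <= int(round(0.015 * FS))
        assert (lag - delay) % L == 0

    def test_boundary_maximum_warns(self):
        # decaying-amplitude response phase-aligned at the lower edge puts
        # the correlation maximum on the search boundary
        lag_lo = int(round(0.005 * FS))
        t = np.arange(3000)
        avg = np.exp(-t / 500) * np.sin(2 * np.pi * (t - lag_lo) / L)
        with pytest.warns(UserWarning, match="boundary"):
            lag = find_response_lag(avg, F0, FS)
        assert lag == lag_lo

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError, match="no response"):
            find_response_lag(np.zeros(2000), F0, FS)


class TestEpochConventional:
    def test_one_epoch_per_trigger_with_baseline_zeroing(self):
        # constant offset vanishes after pre-trigger baseline subtraction
        eeg = np.full(20000, 3.7)
        triggers = np.arange(300, 19000, 1633)
        rec = ContinuousRecording(eeg, FS, triggers, "positive")
        ep = epoch_conventional(rec, lag=164, trial_len=896)
        assert ep.n_trials == len(triggers)
        assert np.allclose(ep.trials, 0.0)
        assert ep.soa_s == pytest.approx(1633 / FS)

    def test_early_trigger_dropped_with_warning(self):
        eeg = np.zeros(20000)
        eeg[0] = 1.0  # make it non-trivial
        rec = ContinuousRecording(eeg, FS, [50, 5000, 10000], "positive")
        with pytest.warns(UserWarning, match="dropped"):
            ep = epoch_conventional(rec, lag=164, trial_len=896)
        assert ep.n_trials == 2  # first trigger has no 7 ms baseline room


class TestRejectArtifacts:
    def _epochs(self, trials):
        from rapidffr.preprocess import EpochSet
        n = len(trials)
        return EpochSet(np.asarray(trials, float), "positive",
                        np.ones(n, bool), np.arange(n) * L, L / FS)

    def test_strict_threshold(self):
        base = np.zeros(L)
        over = base.copy(); over[3] = 36.0
        att = base.copy(); att[5] = 35.0   # exactly at threshold: retained
        neg = base.copy(); neg[7] = -40.0
        ep = reject_artifacts(self._epochs([base, over, att, neg]))
        assert list(ep.retained) == [True, False, True, False]
        assert ep.meta["n_rejected"] == 2

    def test_idempotent(self):
        trials = np.random.default_rng(0).normal(0, 8, (50, L))
        once = reject_artifacts(self._epochs(trials))
        twice = reject_artifacts(once)
        np.testing.assert_array_equal(once.retained, twice.retained)

    def test_all_rejected_is_an_error(self):
        with pytest.raises(ValueError, match="all"):
            reject_artifacts(self._epochs([np.full(L, 100.0)]))


class TestTrimToElapsedTime:
    def _rapid_epochs(self, n):
        from rapidffr.preprocess import EpochSet
        return EpochSet(np.zeros((n, L)), "positive", np.ones(n, bool),
                        np.arange(n) * L, L / FS)

    def _conv_epochs(self, n, soa_s):
        from rapidffr.preprocess import EpochSet
        return EpochSet(np.zeros((n, 896)), "positive", np.ones(n, bool),
                        np.arange(n) * 1633, soa_s)

    def test_conventional_count_from_realized_soa(self):
        # 54.6875 ms burst + 45 ms nominal ISI = 99.6875 ms SOA
        ep = trim_to_elapsed_time(self._conv_epochs(1500, 0.0996875), 60.0)
        assert ep.n_trials == 601

    def test_small_case(self):
        ep = trim_to_elapsed_time(self._conv_epochs(1500, 0.0996875), 0.2)
        assert ep.n_trials == 2

    def test_full_length_identity(self):
        # 7503 cycles last 58.6171875 s; a budget at least that long keeps all
        ep = trim_to_elapsed_time(self._rapid_epochs(7503), 58.62)
        assert ep.n_trials == 7503

    def test_too_short_budget_rejected(self):
        with pytest.raises(ValueError, match="shorter than one trial"):
            trim_to_elapsed_time(self._rapid_epochs(10), 0.001)
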
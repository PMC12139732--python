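"""Averaging, EFR/TFS algebra, and exact-bin harmonic amplitudes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rapidffr.preprocess import EpochSet
from rapidffr.spectral import (average_erp, derive_efr_tfs, harmonic_rms,
                               harmonic_spectrum, DerivedResponses)

F0, FS = 128.0, 16384.0
L = 128


def _epochs(trials, retained=None):
    n = len(trials)
    return EpochSet(np.asarray(trials, float), "positive",
                    np.ones(n, bool) if retained is None else np.asarray(retained),
                    np.arange(n) * L, L / FS)


class TestAverageErp:
    def test_mean_of_identical_epochs(self, rng):
        trial = rng.standard_normal(L)
        erp = average_erp(_epochs([trial] * 5))
        np.testing.assert_allclose(erp.waveform, trial)
        assert erp.n_averaged == 5

    def test_masked_trials_do_not_contribute(self, rng):
        good = rng.standard_normal((4, L))
        bad = np.full((1, L), 1e6)
        erp = average_erp(_epochs(np.vstack([good, bad]),
                                  [True] * 4 + [False]))
        np.testing.assert_allclose(erp.waveform, good.mean(axis=0))

    def test_residual_shrinks_as_inverse_sqrt_n(self, rng):
        signal = np.sin(2 * np.pi * np.arange(L) / L)
        resid = []
        for n in (100, 1600):
            trials = signal + rng.standard_normal((n, L))
            erp = average_erp(_epochs(trials))
            resid.append(np.sqrt(np.mean((erp.waveform - signal) ** 2)))
        # 16x more trials -> ~4x smaller residual
        assert resid[0] / resid[1] == pytest.approx(4.0, rel=0.35)

    def test_no_retained_trials_is_an_error(self):
        with pytest.raises(ValueError, match="retained"):
            average_erp(_epochs(np.zeros((3, L)), [False] * 3))


class TestDeriveEfrTfs:
    def test_algebraic_identity(self, rng):
        env = rng.standard_normal(L)
        fine = rng.standard_normal(L)
        d = derive_efr_tfs(env + fine, env - fine)
        np.testing.assert_allclose(d.efr, env)
        np.testing.assert_allclose(d.tfs, fine)

    def test_equal_polarities_have_zero_tfs(self, rng):
        x = rng.standard_normal(L)
        assert np.allclose(derive_efr_tfs(x, x).tfs, 0.0)

    def test_polarity_inverting_artifact_cancels_in_efr(self, rng):
        env = rng.standard_normal(L)
        artifact = 10 * rng.standard_normal(L)  # e.g. cochlear microphonic
        d = derive_efr_tfs(env + artifact, env - artifact)
        np.testing.assert_allclose(d.efr, env)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            derive_efr_tfs(np.zeros(L), np.zeros(L + 1))


class TestHarmonicRms:
    def test_single_sinusoid_rms(self):
        t = np.arange(L)
        wave = 3.0 * np.sin(2 * np.pi * t / L)
        rms = harmonic_rms(wave, F0, FS)
        assert rms[1] == pytest.approx(3.0 / np.sqrt(2), rel=1e-12)
        assert all(rms[k] < 1e-12 for k in range(2, 8))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.01, 5.0), min_size=7, max_size=7),
           st.lists(st.floats(0, 2 * np.pi), min_size=7, max_size=7))
    def test_round_trip_recovers_known_amplitudes(self, amps, phases):
        t = np.arange(L) / FS
        wave = sum(a * np.sqrt(2) * np.sin(2 * np.pi * k * F0 * t + p)
                   for k, (a, p) in enumerate(zip(amps, phases), start=1))
        rms = harmonic_rms(wave, F0, FS)
        for k, a in enumerate(amps, start=1):
            assert rms[k] == pytest.approx(a, rel=1e-9)

    def test_linearity(self, rng):
        wave = rng.standard_normal(L)
        r1 = harmonic_rms(wave, F0, FS)
        r2 = harmonic_rms(2.5 * wave, F0, FS)
        for k in r1:
            assert r2[k] == pytest.approx(2.5 * r1[k], rel=1e-12)

    def test_seven_cycle_epoch_uses_bins_at_multiples_of_seven(self):
        n = 7 * L
        t = np.arange(n) / FS
        wave = np.sqrt(2) * np.sin(2 * np.pi * 2 * F0 * t)  # harmonic 2
        spec = np.abs(np.fft.rfft(wave))
        assert np.argmax(spec) == 14  # bin index 7*k
        assert harmonic_rms(wave, F0, FS)[2] == pytest.approx(1.0, rel=1e-9)

    def test_misaligned_length_rejected(self):
        with pytest.raises(ValueError, match="bin"):
            harmonic_rms(np.zeros(100), F0, FS)


class TestHarmonicSpectrum:
    def test_source_assignment(self):
        t = np.arange(L) / FS
        efr = np.sqrt(2) * np.sin(2 * np.pi * F0 * t)
        tfs = np.sqrt(2) * np.sin(2 * np.pi * 4 * F0 * t)
        spec = harmonic_spectrum(DerivedResponses(efr=efr, tfs=tfs), F0, FS)
        assert spec.source == {1: "EFR", 2: "EFR", 3: "EFR",
                               4: "TFS", 5: "TFS", 6: "TFS", 7: "TFS"}
        assert spec.bin_hz[4] == 512.0
        assert spec.rms[1] == pytest.approx(1.0)
        assert spec.rms[4] == pytest.approx(1.0)
        # envelope energy does not leak into TFS-sourced bins and vice versa
        assert spec.rms[2] < 1e-12 and spec.rms[5] < 1e-12

    def test_frame_output(self):
        d = DerivedResponses(efr=np.zeros(L), tfs=np.zeros(L))
        df = harmonic_spectrum(d, F0, FS).to_frame()
        assert list(df.columns) == ["harmonic", "bin_hz", "source", "rms_uv"]
        assert len(df) == 7
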
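"""End-to-end analyses: rapid arm, conventional arm, and chunked series.

``analyze_rapid`` implements continuous-stimulation single-cycle analysis:
optional drift correction, 10 ms-skip single-cycle epoching, 35 uV artifact
rejection, polarity-wise averaging, EFR/TFS derivation, exact-bin harmonic
RMS, bootstrap noise floor, and per-harmonic SNR.

``analyze_conventional`` implements the burst protocol: drift correction,
lag search (5-15 ms cross-correlation of the provisional EFR with an F0
sine), per-burst epoching with 7 ms pre-trigger baseline correction,
rejection, averaging, spectra, and a noise bootstrap whose window length is
one full conventional epoch drawn from the concatenated retained epochs.

``chunk_series`` splits a long continuous recording into sequential chunks
of equal cycle count and runs the rapid analysis independently on each —
the design used to probe neural adaptation over extended stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess as pp
from . import spectral as sp
from .io import ContinuousRecording
from .noise_snr import NoiseEstimate, SnrResult, compute_snr, noise_floor
from .spectral import DerivedResponses, HarmonicSpectrum

__all__ = ["AnalysisResult", "ChunkResult", "analyze_rapid",
           "analyze_conventional", "chunk_series", "result_table"]


@dataclass
class AnalysisResult:
    """Spectra, noise floor and SNR of one recording pair."""

    spectrum: HarmonicSpectrum
    noise: NoiseEstimate
    snr: SnrResult
    responses: DerivedResponses
    erp_pos: sp.Erp
    erp_neg: sp.Erp
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = self.spectrum.to_frame()
        df["noise_rms_uv"] = [self.noise.noise_rms[k] for k in self.spectrum.rms]
        df["snr_db"] = [self.snr.snr_db[k] for k in self.spectrum.rms]
        df["n_trials_retained_pos"] = self.provenance.get("n_retained_pos")
        df["n_trials_retained_neg"] = self.provenance.get("n_retained_neg")
        df["n_boot"] = self.noise.n_boot
        df["seed"] = self.noise.seed
        return df


@dataclass
class ChunkResult:
    index: int
    n_cycles: int
    result: AnalysisResult
    short: bool = False


def _maybe_resample(rec: ContinuousRecording,
                    expected_span_s: float | None) -> ContinuousRecording:
    if expected_span_s is None:
        expected_span_s = rec.meta.get("expected_span_s")
    if expected_span_s is None:
        return rec
    return pp.resample_to_nominal(rec, float(expected_span_s))


def _analyze_epoch_pair(ep_pos: pp.EpochSet, ep_neg: pp.EpochSet, f0: float,
                        fs: float, n_boot: int, seed: int | None,
                        provenance: dict) -> AnalysisResult:
    erp_pos = sp.average_erp(ep_pos)
    erp_neg = sp.average_erp(ep_neg)
    responses = sp.derive_efr_tfs(erp_pos, erp_neg)
    spectrum = sp.harmonic_spectrum(responses, f0, fs)
    noise = noise_floor(
        ep_pos.concatenate_retained(), ep_neg.concatenate_retained(),
        (ep_pos.n_retained, ep_neg.n_retained), ep_pos.trial_len,
        f0, fs, n_boot=n_boot, seed=seed,
    )
    snr = compute_snr(spectrum, noise)
    provenance = dict(provenance)
    provenance.update(
        n_retained_pos=ep_pos.n_retained,
        n_retained_neg=ep_neg.n_retained,
        n_rejected_pos=ep_pos.meta.get("n_rejected", 0),
        n_rejected_neg=ep_neg.meta.get("n_rejected", 0),
        n_boot=n_boot, seed=seed,
    )
    return AnalysisResult(spectrum, noise, snr, responses, erp_pos, erp_neg,
                          provenance)


def analyze_rapid(rec_pos: ContinuousRecording, rec_neg: ContinuousRecording,
                  *, f0: float = 128.0, n_cycles: int | None = None,
                  skip_ms: float = 10.0, reject_uv: float = 35.0,
                  n_boot: int = 10000, seed: int | None = 0,
                  expected_span_s: float | None = None,
                  elapsed_s: float | None = None) -> AnalysisResult:
    """Full rapid-arm analysis of one polarity pair.

    ``n_cycles`` defaults to the largest cycle count available after the
    onset skip; ``elapsed_s`` optionally trims each polarity to an
    elapsed-time-matched prefix before artifact rejection.
    """
    fs = rec_pos.fs_nominal
    L = int(round(fs / f0))
    epochs = []
    for rec in (rec_pos, rec_neg):
        rec = _maybe_resample(rec, expected_span_s)
        if n_cycles is None:
            start = int(rec.triggers[0]) + int(round(skip_ms * fs / 1000.0))
            n_cycles = (len(rec.eeg) - start) // L
        ep = pp.epoch_rapid(rec, f0, n_cycles, onset_skip_ms=skip_ms)
        if elapsed_s is not None:
            ep = pp.trim_to_elapsed_time(ep, elapsed_s)
        epochs.append(pp.reject_artifacts(ep, reject_uv))
    prov = {"mode": "rapid", "f0": f0, "n_cycles": n_cycles,
            "skip_ms": skip_ms, "reject_uv": reject_uv,
            "drift_ratio_pos": epochs[0].meta.get("drift_ratio"),
            "elapsed_s": elapsed_s}
    return _analyze_epoch_pair(epochs[0], epochs[1], f0, fs, n_boot, seed, prov)


def analyze_conventional(rec_pos: ContinuousRecording,
                         rec_neg: ContinuousRecording, *, f0: float = 128.0,
                         trial_cycles: int = 7, skip_search_ms=(5.0, 15.0),
                         baseline_ms: float = 7.0, reject_uv: float = 35.0,
                         n_boot: int = 10000, seed: int | None = 0,
                         expected_span_s: float | None = None,
                         elapsed_s: float | None = None) -> AnalysisResult:
    """Full conventional-arm analysis of one polarity pair."""
    fs = rec_pos.fs_nominal
    L = int(round(fs / f0))
    trial_len = trial_cycles * L
    lag_hi = int(round(skip_search_ms[1] * fs / 1000.0))

    recs = [_maybe_resample(rec_pos, expected_span_s),
            _maybe_resample(rec_neg, expected_span_s)]

    # provisional onset-aligned averages for the lag search
    prov_avgs = []
    for rec in recs:
        ep = pp.epoch_conventional(rec, lag=0, trial_len=trial_len + lag_hi + L,
                                   baseline_ms=baseline_ms)
        prov_avgs.append(sp.average_erp(ep).waveform)
    prov_efr = (prov_avgs[0] + prov_avgs[1]) / 2.0
    lag = pp.find_response_lag(prov_efr, f0, fs, search_ms=skip_search_ms)

    epochs = []
    for rec in recs:
        ep = pp.epoch_conventional(rec, lag=lag, trial_len=trial_len,
                                   baseline_ms=baseline_ms)
        if elapsed_s is not None:
            ep = pp.trim_to_elapsed_time(ep, elapsed_s)
        epochs.append(pp.reject_artifacts(ep, reject_uv))
    prov = {"mode": "conventional", "f0": f0, "trial_cycles": trial_cycles,
            "lag_samples": lag, "lag_ms": lag / fs * 1000.0,
            "baseline_ms": baseline_ms, "reject_uv": reject_uv,
            "drift_ratio_pos": recs[0].meta.get("drift_ratio"),
            "elapsed_s": elapsed_s}
    return _analyze_epoch_pair(epochs[0], epochs[1], f0, fs, n_boot, seed, prov)


def chunk_series(rec_pos: ContinuousRecording, rec_neg: ContinuousRecording,
                 *, f0: float = 128.0, n_cycles: int | None = None,
                 n_chunks: int = 6, skip_ms: float = 10.0,
                 reject_uv: float = 35.0, n_boot: int = 10000,
                 seed: int = 0,
                 expected_span_s: float | None = None) -> list[ChunkResult]:
    """Split the cycle stream into sequential chunks; analyse each alone.

    Chunk boundaries fall on cycle multiples. If the cycle count is not
    divisible by ``n_chunks`` the last chunk is short and flagged. Each
    chunk gets an independent bootstrap seed spawned from ``seed``.
    """
    if n_chunks < 1:
        raise ValueError("n_chunks must be >= 1")
    fs = rec_pos.fs_nominal
    L = int(round(fs / f0))
    eps = []
    for rec in (rec_pos, rec_neg):
        rec = _maybe_resample(rec, expected_span_s)
        if n_cycles is None:
            start = int(rec.triggers[0]) + int(round(skip_ms * fs / 1000.0))
            n_cycles = (len(rec.eeg) - start) // L
        eps.append(pp.epoch_rapid(rec, f0, n_cycles, onset_skip_ms=skip_ms))

    per = n_cycles // n_chunks
    if per < 1:
        raise ValueError("fewer cycles than chunks")
    remainder = n_cycles - per * n_chunks
    if remainder:
        warnings.warn(
            f"{n_cycles} cycles not divisible by {n_chunks} chunks; the last "
            f"chunk has {per + remainder} cycles",
            stacklevel=2,
        )
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(n_chunks)]

    out = []
    for i in range(n_chunks):
        lo = i * per
        hi = (i + 1) * per if i < n_chunks - 1 else n_cycles
        chunk_eps = []
        for ep in eps:
            sub = pp.EpochSet(
                trials=ep.trials[lo:hi], polarity=ep.polarity,
                retained=ep.retained[lo:hi].copy(),
                origin_starts=ep.origin_starts[lo:hi], soa_s=ep.soa_s,
                meta=dict(ep.meta),
            )
            chunk_eps.append(pp.reject_artifacts(sub, reject_uv))
        prov = {"mode": "rapid-chunk", "chunk": i, "f0": f0,
                "cycles": hi - lo, "skip_ms": skip_ms, "reject_uv": reject_uv}
        res = _analyze_epoch_pair(chunk_eps[0], chunk_eps[1], f0, fs,
                                  n_boot, seeds[i], prov)
        out.append(ChunkResult(index=i, n_cycles=hi - lo, result=res,
                               short=(hi - lo) != per))
    return out


def result_table(results: list[ChunkResult]) -> pd.DataFrame:
    """Tidy per-chunk, per-harmonic table (ready for trend models)."""
    rows = []
    for cr in results:
        for k, rms in cr.result.spectrum.rms.items():
            rows.append({
                "chunk": cr.index,
                "n_cycles": cr.n_cycles,
                "harmonic": k,
                "source": cr.result.spectrum.source[k],
                "rms_uv": rms,
                "noise_rms_uv": cr.result.noise.noise_rms[k],
                "snr_db": cr.result.snr.snr_db[k],
            })
    return pd.DataFrame(rows)
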
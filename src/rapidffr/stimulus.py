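"""Band-limited sawtooth stimulus synthesis and presentation schedules.

The stimulus is a harmonic complex built by additive synthesis: harmonic
``k`` receives amplitude ``1/k`` with sine phase, the classic band-limited
sawtooth. The fundamental frequency must divide the sampling rate so that
one period is an integer number of samples — this is what later allows
response cycles to be excised from a continuous recording with
single-sample precision.

Two presentation schedules are supported:

* *rapid*: one uninterrupted block of ``n_cycles`` identical cycles,
  amplitude-tapered over the first and last cycle, with a single onset
  trigger;
* *conventional*: ``n_trials`` short tone bursts (default seven cycles,
  54.6875 ms at 128 Hz / 16384 Hz), each tapered on and off over one cycle,
  separated by a silent interstimulus interval (default 45 ms, realised on
  the sample grid), with one trigger per burst onset.

Playback level (e.g. 80 dB SPL) is hardware calibration and is carried as
metadata only; waveforms are peak-normalised to 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "StimulusSpec",
    "StimulusWaveform",
    "synthesize_sawtooth_cycle",
    "build_rapid_stimulus",
    "build_conventional_stimulus",
    "build_stimulus",
    "write_wav",
]


def _cycle_samples(f0: float, fs: float) -> int:
    ratio = fs / f0
    n = int(round(ratio))
    if abs(ratio - n) > 1e-9 or n < 1:
        raise ValueError(
            f"f0={f0} Hz must divide fs={fs} Hz exactly so one cycle is an "
            f"integer number of samples (fs/f0={ratio})"
        )
    return n


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a stimulus waveform and its presentation schedule."""

    f0: float = 128.0
    fs: float = 16384.0
    n_harmonics: int = 30
    polarity: Literal["positive", "negative"] = "positive"
    mode: Literal["rapid", "conventional"] = "rapid"
    n_cycles: int = 7503            # rapid mode
    n_trials: int = 1500            # conventional mode
    cycles_per_trial: int = 7       # conventional mode
    isi_ms: float = 45.0            # conventional mode
    taper_cycles: int = 1
    taper_shape: Literal["linear", "cosine"] = "linear"
    level_db_spl: float | None = 80.0  # metadata only; not applied to samples

    def __post_init__(self) -> None:
        _cycle_samples(self.f0, self.fs)
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.n_harmonics * self.f0 >= self.fs / 2:
            raise ValueError(
                f"highest harmonic {self.n_harmonics * self.f0} Hz violates "
                f"the Nyquist limit {self.fs / 2} Hz"
            )
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.mode not in ("rapid", "conventional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.taper_cycles < 0:
            raise ValueError("taper_cycles must be >= 0")
        if self.mode == "rapid" and self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.mode == "conventional" and self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def cycle_len(self) -> int:
        """Samples per F0 cycle (exact)."""
        return _cycle_samples(self.f0, self.fs)


@dataclass
class StimulusWaveform:
    """A realised stimulus: samples, trigger schedule and cycle geometry."""

    samples: np.ndarray
    fs: float
    onsets: np.ndarray          # sample index of each stimulus (block/burst) onset
    cycle_len: int
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


def synthesize_sawtooth_cycle(f0: float, fs: float, n_harmonics: int) -> np.ndarray:
    """One period of the band-limited sawtooth, peak-normalised to 1.

    The cycle is ``sum_{k=1..n_harmonics} (1/k) sin(2 pi k f0 t)`` sampled on
    ``fs/f0`` points.
    """
    n = _cycle_samples(f0, fs)
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    if n_harmonics * f0 >= fs / 2:
        raise ValueError(
            f"highest harmonic {n_harmonics * f0} Hz violates the Nyquist "
            f"limit {fs / 2} Hz"
        )
    t = np.arange(n) / fs
    k = np.arange(1, n_harmonics + 1)[:, None]
    cycle = ((1.0 / k) * np.sin(2 * np.pi * k * f0 * t)).sum(axis=0)
    return cycle / np.max(np.abs(cycle))


def _taper_envelope(n_samples: int, taper_len: int, shape: str) -> np.ndarray:
    """Unit envelope ramping 0->1 over the first and 1->0 over the last
    ``taper_len`` samples."""
    env = np.ones(n_samples)
    if taper_len == 0:
        return env
    if 2 * taper_len > n_samples:
        raise ValueError(
            f"stimulus of {n_samples} samples is too short for onset+offset "
            f"tapers of {taper_len} samples each"
        )
    ramp = np.arange(taper_len) / taper_len
    if shape == "cosine":
        ramp = 0.5 * (1 - np.cos(np.pi * ramp))
    elif shape != "linear":
        raise ValueError(f"unknown taper shape {shape!r}")
    env[:taper_len] = ramp
    env[n_samples - taper_len:] = ramp[::-1]
    return env


def build_rapid_stimulus(spec: StimulusSpec) -> StimulusWaveform:
    """Continuous block of ``n_cycles`` cycles, tapered at the block edges."""
    if spec.mode != "rapid":
        raise ValueError("spec.mode must be 'rapid'")
    L = spec.cycle_len
    if spec.n_cycles < 2 * spec.taper_cycles:
        raise ValueError(
            f"n_cycles={spec.n_cycles} is shorter than onset+offset tapers "
            f"({2 * spec.taper_cycles} cycles)"
        )
    cycle = synthesize_sawtooth_cycle(spec.f0, spec.fs, spec.n_harmonics)
    samples = np.tile(cycle, spec.n_cycles)
    samples *= _taper_envelope(len(samples), spec.taper_cycles * L, spec.taper_shape)
    if spec.polarity == "negative":
        samples = -samples
    return StimulusWaveform(
        samples=samples,
        fs=spec.fs,
        onsets=np.array([0], dtype=np.int64),
        cycle_len=L,
        meta={"spec": spec, "block_duration_s": len(samples) / spec.fs},
    )


def build_conventional_stimulus(spec: StimulusSpec) -> StimulusWaveform:
    """``n_trials`` tapered bursts separated by the (sample-grid) ISI.

    The requested ISI is rounded to the nearest sample; the realised value
    is recorded in ``meta['isi_samples']`` / ``meta['isi_realized_ms']``.
    """
    if spec.mode != "conventional":
        raise ValueError("spec.mode must be 'conventional'")
    if spec.isi_ms < 0:
        raise ValueError("isi_ms must be >= 0")
    L = spec.cycle_len
    if spec.cycles_per_trial < 2 * spec.taper_cycles:
        raise ValueError(
            f"cycles_per_trial={spec.cycles_per_trial} is shorter than "
            f"onset+offset tapers ({2 * spec.taper_cycles} cycles)"
        )
    cycle = synthesize_sawtooth_cycle(spec.f0, spec.fs, spec.n_harmonics)
    burst = np.tile(cycle, spec.cycles_per_trial)
    burst *= _taper_envelope(len(burst), spec.taper_cycles * L, spec.taper_shape)
    isi_samples = int(round(spec.isi_ms * spec.fs / 1000.0))
    soa = len(burst) + isi_samples
    samples = np.zeros(spec.n_trials * soa - isi_samples)
    onsets = np.arange(spec.n_trials, dtype=np.int64) * soa
    for o in onsets:
        samples[o:o + len(burst)] = burst
    if spec.polarity == "negative":
        samples = -samples
    return StimulusWaveform(
        samples=samples,
        fs=spec.fs,
        onsets=onsets,
        cycle_len=L,
        meta={
            "spec": spec,
            "burst_samples": len(burst),
            "burst_duration_ms": len(burst) / spec.fs * 1000.0,
            "isi_samples": isi_samples,
            "isi_realized_ms": isi_samples / spec.fs * 1000.0,
            "soa_samples": soa,
            "soa_s": soa / spec.fs,
        },
    )


def build_stimulus(spec: StimulusSpec) -> StimulusWaveform:
    """Dispatch on ``spec.mode``."""
    if spec.mode == "rapid":
        return build_rapid_stimulus(spec)
    return build_conventional_stimulus(spec)


def write_wav(wave: StimulusWaveform, path: str) -> None:
    """Float32 WAV plus a JSON sidecar with the spec and realised onsets."""
    from scipy.io import wavfile

    wavfile.write(path, int(wave.fs), wave.samples.astype(np.float32))
    spec = wave.meta.get("spec")
    sidecar = {
        "fs": wave.fs,
        "cycle_len": wave.cycle_len,
        "onsets": wave.onsets.tolist(),
        "onset_times_s": (wave.onsets / wave.fs).tolist(),
    }
    if spec is not None:
        sidecar["spec"] = {
            key: getattr(spec, key)
            for key in (
                "f0", "fs", "n_harmonics", "polarity", "mode", "n_cycles",
                "n_trials", "cycles_per_trial", "isi_ms", "taper_cycles",
                "taper_shape", "level_db_spl",
            )
        }
    for key in ("isi_realized_ms", "soa_s", "burst_duration_ms", "block_duration_s"):
        if key in wave.meta:
            sidecar[key] = wave.meta[key]
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
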
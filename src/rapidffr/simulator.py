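"""Synthetic two-polarity FFR recordings with known ground truth.

No raw EEG accompanies the method, so every pipeline stage is validated
against simulated recordings whose harmonic content is known exactly. The
simulated response is a sum of sinusoids at harmonics of F0: envelope
components (harmonics 1-3 by default) keep their sign in both stimulus
polarities, fine-structure components (harmonics 4-7) invert with
polarity — so after polarity averaging the envelope components appear only
in the EFR and the fine-structure components only in the TFS. The response
is delayed by a fixed neural transmission delay (default 10 ms), onset/
offset-ramped over one cycle to mirror the stimulus taper, and embedded in
independent broadband noise per polarity (white by default, optionally
mixed with 1/f). Occasional large-amplitude artifacts (Poisson-timed,
Hann-windowed deflections) and a clock-drift factor between the stimulus
and acquisition clocks complete the emulation.

Amplitudes are RMS values in uV: a component with ``env_rms[k] = A`` is a
sinusoid of peak ``A*sqrt(2)`` at ``k*f0``. Drift is modelled by sampling
the analytic response at ``t_n = n / (fs * drift)``: the acquisition clock
runs ``drift`` times fast, so the nominal-rate recording must be resampled
by ``1/drift`` before single-cycle epoching is exact.

Continuous (rapid) blocks carry two triggers, block onset and offset, which
is what drift estimation needs; burst schedules carry one trigger per burst
onset. The stimulated block is two ramp cycles plus two margin cycles
longer than ``n_cycles`` so that exactly ``n_cycles`` steady-state cycles
are available to the 10 ms-skip epoching.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .io import ContinuousRecording

__all__ = ["SimulationConfig", "simulate_recording_pair", "write_ground_truth"]


def _default_env() -> dict[int, float]:
    return {1: 0.12, 2: 0.08, 3: 0.05}


def _default_tfs() -> dict[int, float]:
    return {4: 0.05, 5: 0.04, 6: 0.03, 7: 0.025}


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a simulated recording pair.

    Defaults emulate a clean adult scalp recording: harmonic amplitudes of
    0.025-0.12 uV (RMS), broadband noise of 2.5 uV RMS, a 10 ms brainstem
    delay, and no clock drift or movement artifacts unless requested.
    """

    f0: float = 128.0
    fs: float = 16384.0
    n_cycles: int = 7503
    env_rms: dict[int, float] = field(default_factory=_default_env)
    tfs_rms: dict[int, float] = field(default_factory=_default_tfs)
    phases: dict[int, float] | None = None
    noise_rms: float = 2.5
    pink_fraction: float = 0.0
    drift: float = 1.0
    delay_ms: float = 10.0
    ramp_cycles: int = 1
    artifact_rate_hz: float = 0.0
    artifact_uv: float = 80.0
    artifact_width_ms: float = 20.0
    schedule: str = "continuous"      # "continuous" | "burst"
    n_trials: int = 1500              # burst schedule
    cycles_per_trial: int = 7         # burst schedule
    isi_ms: float = 45.0              # burst schedule
    pad_s: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        ratio = self.fs / self.f0
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("f0 must divide fs exactly")
        for name, d in (("env_rms", self.env_rms), ("tfs_rms", self.tfs_rms)):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"{name}[{k}] must be >= 0")
                if k * self.f0 >= self.fs / 2:
                    raise ValueError(f"{name}[{k}] violates the Nyquist limit")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be >= 0")
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ValueError("pink_fraction must be in [0, 1]")
        if not 0.99 <= self.drift <= 1.01:
            raise ValueError("drift must be within [0.99, 1.01]")
        if self.artifact_rate_hz < 0:
            raise ValueError("artifact_rate_hz must be >= 0")
        if self.artifact_rate_hz > 0 and self.artifact_uv <= 35:
            raise ValueError(
                "artifact_uv must exceed the 35 uV rejection threshold for "
                "artifacts to be meaningful"
            )
        if self.schedule not in ("continuous", "burst"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.ramp_cycles < 0:
            raise ValueError("ramp_cycles must be >= 0")

    @property
    def cycle_s(self) -> float:
        return 1.0 / self.f0

    def harmonic_phase(self, k: int) -> float:
        if self.phases is None:
            return 0.0
        return float(self.phases.get(k, 0.0))


def _pink_unit(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f-shaped Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x ** 2))


def _response_on(t: np.ndarray, t0: float, t1: float, ramp_s: float) -> np.ndarray:
    """Envelope 0 outside [t0, t1), linear ramps of ``ramp_s`` inside."""
    if ramp_s <= 0:
        return ((t >= t0) & (t < t1)).astype(np.float64)
    up = np.clip((t - t0) / ramp_s, 0.0, 1.0)
    down = np.clip((t1 - t) / ramp_s, 0.0, 1.0)
    return up * down


def simulate_recording_pair(
    config: SimulationConfig,
) -> tuple[ContinuousRecording, ContinuousRecording]:
    """Simulate the positive- and negative-polarity recordings of one run.

    Returns recordings whose ``meta`` carries the ground truth (config) and
    the ``expected_span_s`` between the reference triggers that drift
    correction needs.
    """
    cfg = config
    T = cfg.cycle_s
    delay = cfg.delay_ms / 1000.0
    ramp_s = cfg.ramp_cycles * T
    # snap the pre-stimulus pad to the sample grid so triggers are exact
    pad_s = round(cfg.pad_s * cfg.fs) / cfg.fs

    if cfg.schedule == "continuous":
        # two ramp + two margin cycles around the analysable steady cycles
        stim_dur = (cfg.n_cycles + 2 * cfg.ramp_cycles + 2) * T
        onset_times = np.array([pad_s])
        total_s = pad_s + stim_dur + delay + pad_s
        trig_times = np.array([pad_s, pad_s + stim_dur])
        expected_span_s = stim_dur
        burst_dur = stim_dur
    else:
        burst_dur = cfg.cycles_per_trial * T
        isi_samples = int(round(cfg.isi_ms * cfg.fs / 1000.0))
        soa_s = burst_dur + isi_samples / cfg.fs
        onset_times = pad_s + np.arange(cfg.n_trials) * soa_s
        total_s = onset_times[-1] + soa_s + delay + pad_s
        trig_times = onset_times
        expected_span_s = (cfg.n_trials - 1) * soa_s

    n_samples = int(round(total_s * cfg.fs * cfg.drift))
    t = np.arange(n_samples) / (cfg.fs * cfg.drift)  # stimulus-clock time

    # response phase-locks to each stimulus onset (bursts generally start
    # at a non-integer number of cycles apart, so a global sinusoid would
    # de-phase across trials)
    env_sum = np.zeros(n_samples)
    tfs_sum = np.zeros(n_samples)
    fs_eff = cfg.fs * cfg.drift
    for onset in onset_times:
        r0 = onset + delay
        i0 = max(int(np.floor(r0 * fs_eff)), 0)
        i1 = min(int(np.ceil((r0 + burst_dur) * fs_eff)) + 1, n_samples)
        tt = t[i0:i1]
        local_env = _response_on(tt, r0, r0 + burst_dur, ramp_s)
        tau = tt - r0
        for k, a in cfg.env_rms.items():
            env_sum[i0:i1] += local_env * a * np.sqrt(2.0) * np.sin(
                2 * np.pi * k * cfg.f0 * tau + cfg.harmonic_phase(k))
        for k, a in cfg.tfs_rms.items():
            tfs_sum[i0:i1] += local_env * a * np.sqrt(2.0) * np.sin(
                2 * np.pi * k * cfg.f0 * tau + cfg.harmonic_phase(k))

    ss = np.random.SeedSequence(cfg.seed)
    rng_np, rng_nn, rng_ap, rng_an = (np.random.default_rng(c) for c in ss.spawn(4))

    recs = []
    for polarity, sign, rng_noise, rng_art in (
        ("positive", +1.0, rng_np, rng_ap),
        ("negative", -1.0, rng_nn, rng_an),
    ):
        eeg = env_sum + sign * tfs_sum
        if cfg.noise_rms > 0:
            white = rng_noise.standard_normal(n_samples)
            if cfg.pink_fraction > 0:
                pink = _pink_unit(n_samples, rng_noise)
                p = cfg.pink_fraction
                mix = (1 - p) * white + p * pink
                mix /= np.sqrt((1 - p) ** 2 + p ** 2)
            else:
                mix = white
            eeg = eeg + cfg.noise_rms * mix
        if cfg.artifact_rate_hz > 0:
            n_events = rng_art.poisson(cfg.artifact_rate_hz * total_s)
            width = max(int(round(cfg.artifact_width_ms * cfg.fs / 1000.0)), 3)
            pulse = cfg.artifact_uv * np.hanning(width)
            for _ in range(n_events):
                pos0 = rng_art.integers(0, max(n_samples - width, 1))
                eeg[pos0:pos0 + width] += rng_art.choice([-1.0, 1.0]) * pulse
        triggers = np.round(trig_times * cfg.fs * cfg.drift).astype(np.int64)
        recs.append(
            ContinuousRecording(
                eeg=eeg,
                fs_nominal=cfg.fs,
                triggers=triggers,
                polarity=polarity,
                meta={
                    "simulated": True,
                    "seed": cfg.seed,
                    "expected_span_s": expected_span_s,
                    "config": dataclasses.asdict(cfg),
                },
            )
        )
    return recs[0], recs[1]


def write_ground_truth(config: SimulationConfig, path: str) -> None:
    """JSON dump of the simulation ground truth."""
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
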
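"""From continuous EEG to artifact-cleaned, polarity-labelled epoch sets.

The rapid arm treats every F0 period of the continuous recording as one
trial: after a 10 ms onset skip (accounting for the brainstem transmission
delay) the stream is cut into consecutive, non-overlapping single-cycle
epochs of exactly ``fs/f0`` samples. The conventional arm epochs one trial
per burst trigger, at a response lag found by cross-correlating the
provisional averaged response with an F0 sine in a 5-15 ms window, and
baseline-corrects each trial against the 7 ms pre-trigger interval.

Before epoching, the recording is resampled to correct the small clock
drift between the presentation and acquisition devices, estimated from the
span between reference triggers versus the stimulus-defined duration.

Conventions: 0-based indices, half-open intervals; rapid epoch ``i`` covers
``[start + i*L, start + (i+1)*L)``. Artifact rejection is strict
(``|x| > threshold`` rejects), so a sample at exactly 35.0 uV is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .io import ContinuousRecording

__all__ = [
    "EpochSet",
    "resample_to_nominal",
    "epoch_rapid",
    "find_response_lag",
    "epoch_conventional",
    "reject_artifacts",
    "trim_to_elapsed_time",
]

MAX_PLAUSIBLE_DRIFT = 0.01  # |r - 1| beyond this indicates a trigger fault


@dataclass
class EpochSet:
    """Fixed-length trial matrix with a retained-trial mask.

    ``soa_s`` is the stimulus-onset asynchrony of the schedule that produced
    the epochs (cycle duration for rapid, burst+ISI for conventional); it is
    what elapsed-time trimming accounts against.
    """

    trials: np.ndarray           # (n_trials, trial_len), uV
    polarity: str
    retained: np.ndarray         # bool, (n_trials,)
    origin_starts: np.ndarray    # start index of each trial in the source vector
    soa_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=np.float64))
        self.retained = np.asarray(self.retained, dtype=bool)
        if len(self.retained) != len(self.trials):
            raise ValueError("retained mask length must equal trial count")
        if len(self.origin_starts) != len(self.trials):
            raise ValueError("origin_starts length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def trial_len(self) -> int:
        return self.trials.shape[1]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    def retained_trials(self) -> np.ndarray:
        return self.trials[self.retained]

    def concatenate_retained(self) -> np.ndarray:
        """Retained epochs re-joined into one vector (noise-bootstrap source)."""
        return self.retained_trials().reshape(-1)


def _cycle_samples(f0: float, fs: float) -> int:
    n = int(round(fs / f0))
    if abs(fs / f0 - n) > 1e-9:
        raise ValueError(f"f0={f0} must divide fs={fs} exactly")
    return n


def resample_to_nominal(rec: ContinuousRecording,
                        expected_span_s: float) -> ContinuousRecording:
    """Correct clock drift so one F0 cycle is exactly ``fs/f0`` samples.

    The drift ratio ``r = observed_span / expected_span`` is estimated from
    the first-to-last trigger interval against the stimulus-defined duration
    between those reference events. The EEG is then resampled by ``1/r``
    (polyphase, rational approximation of the ratio) and trigger indices are
    rescaled. ``r`` is recorded in ``meta['drift_ratio']``.
    """
    if expected_span_s <= 0:
        raise ValueError("expected_span_s must be positive")
    if len(rec.triggers) < 2:
        raise ValueError(
            "drift estimation needs at least two reference triggers "
            "(block onset/offset or first/last burst onset)"
        )
    observed_span_s = (rec.triggers[-1] - rec.triggers[0]) / rec.fs_nominal
    r = observed_span_s / expected_span_s
    if abs(r - 1.0) > MAX_PLAUSIBLE_DRIFT:
        raise ValueError(
            f"implausible drift ratio {r:.6f} (>1% off); check triggers and "
            f"expected_span_s"
        )
    meta = dict(rec.meta)
    meta["drift_ratio"] = float(r)
    if r == 1.0:
        return ContinuousRecording(rec.eeg.copy(), rec.fs_nominal,
                                   rec.triggers.copy(), rec.polarity, meta)
    frac = Fraction(1.0 / r).limit_denominator(100_000)
    eeg = sps.resample_poly(rec.eeg, frac.numerator, frac.denominator)
    triggers = np.round(rec.triggers * (frac.numerator / frac.denominator)).astype(np.int64)
    triggers = np.clip(triggers, 0, len(eeg) - 1)
    meta["resample_up_down"] = (frac.numerator, frac.denominator)
    return ContinuousRecording(eeg, rec.fs_nominal, triggers, rec.polarity, meta)


def epoch_rapid(rec: ContinuousRecording, f0: float, n_cycles: int,
                onset_skip_ms: float = 10.0) -> EpochSet:
    """Cut ``n_cycles`` consecutive single-cycle epochs from the stream.

    Epochs start ``onset_skip_ms`` (rounded to the nearest sample) after the
    first trigger; a constant integer shift only rotates response phase.
    """
    fs = rec.fs_nominal
    L = _cycle_samples(f0, fs)
    if len(rec.triggers) < 1:
        raise ValueError("recording has no triggers")
    start = int(rec.triggers[0]) + int(round(onset_skip_ms * fs / 1000.0))
    stop = start + n_cycles * L
    if stop > len(rec.eeg):
        short = -(-(stop - len(rec.eeg)) // L)  # ceil division
        raise ValueError(
            f"recording is {short} cycles short of the requested "
            f"{n_cycles} cycles after the onset skip"
        )
    trials = rec.eeg[start:stop].reshape(n_cycles, L).copy()
    return EpochSet(
        trials=trials,
        polarity=rec.polarity,
        retained=np.ones(n_cycles, dtype=bool),
        origin_starts=start + np.arange(n_cycles, dtype=np.int64) * L,
        soa_s=L / fs,
        meta={"onset_skip_samples": start - int(rec.triggers[0]), "f0": f0, "fs": fs},
    )


def find_response_lag(avg: np.ndarray, f0: float, fs: float,
                      search_ms: tuple[float, float] = (5.0, 15.0),
                      use_abs: bool = False) -> int:
    """Integer-sample response lag maximising cross-correlation with an F0 sine.

    ``avg`` is a provisional onset-aligned averaged response. The search grid
    is one sample over ``search_ms``; if the optimum sits on a boundary a
    warning is raised (the true delay may lie outside the window). By default
    the signed maximum is used; ``use_abs=True`` switches to the absolute
    maximum (the sine phase of the underlying response is not knowable a
    priori).
    """
    avg = np.asarray(avg, dtype=np.float64)
    if not np.any(avg):
        raise ValueError("all-zero input: no response to align")
    L = _cycle_samples(f0, fs)
    lag_lo = int(round(search_ms[0] * fs / 1000.0))
    lag_hi = int(round(search_ms[1] * fs / 1000.0))
    if lag_hi <= lag_lo:
        raise ValueError("empty lag search window")
    n_fit = ((len(avg) - lag_hi) // L) * L
    if n_fit < L:
        raise ValueError(
            "averaged response too short for the lag search: need at least "
            "one full cycle beyond the largest lag"
        )
    sine = np.sin(2 * np.pi * f0 * np.arange(n_fit) / fs)
    lags = np.arange(lag_lo, lag_hi + 1)
    corr = np.array([avg[lag:lag + n_fit] @ sine for lag in lags])
    score = np.abs(corr) if use_abs else corr
    lag = int(lags[np.argmax(score)])
    if lag in (lag_lo, lag_hi):
        warnings.warn(
            f"response lag {lag / fs * 1000:.2f} ms sits on the search "
            f"boundary; the true delay may lie outside "
            f"[{search_ms[0]}, {search_ms[1]}] ms",
            stacklevel=2,
        )
    return lag


def epoch_conventional(rec: ContinuousRecording, lag: int, trial_len: int,
                       baseline_ms: float = 7.0) -> EpochSet:
    """One baseline-corrected epoch per burst trigger, starting at trigger+lag.

    The mean of the ``baseline_ms`` pre-trigger window is subtracted from
    each epoch. Triggers whose baseline window precedes the recording start,
    or whose epoch overruns the recording end, are dropped with a warning.
    """
    fs = rec.fs_nominal
    if len(rec.triggers) < 1:
        raise ValueError("recording has no triggers")
    b = int(round(baseline_ms * fs / 1000.0))
    trials, starts, dropped = [], [], 0
    for trig in rec.triggers:
        s = int(trig) + int(lag)
        if trig - b < 0 or s + trial_len > len(rec.eeg):
            dropped += 1
            continue
        baseline = rec.eeg[trig - b:trig].mean() if b > 0 else 0.0
        trials.append(rec.eeg[s:s + trial_len] - baseline)
        starts.append(s)
    if dropped:
        warnings.warn(f"dropped {dropped} trial(s) with out-of-range "
                      f"baseline or epoch windows", stacklevel=2)
    if not trials:
        raise ValueError("no usable trials: all epochs out of range")
    if len(rec.triggers) > 1:
        soa_s = float(np.median(np.diff(rec.triggers))) / fs
    else:
        soa_s = trial_len / fs
    return EpochSet(
        trials=np.asarray(trials),
        polarity=rec.polarity,
        retained=np.ones(len(trials), dtype=bool),
        origin_starts=np.asarray(starts, dtype=np.int64),
        soa_s=soa_s,
        meta={"lag_samples": int(lag), "baseline_samples": b,
              "dropped_out_of_range": dropped, "fs": fs},
    )


def reject_artifacts(epochs: EpochSet, threshold_uv: float = 35.0) -> EpochSet:
    """Reject every trial whose absolute maximum strictly exceeds the threshold.

    The rule is idempotent and order-independent; rejection counts are
    recorded in ``meta['n_rejected']``.
    """
    if epochs.n_trials == 0:
        raise ValueError("epoch set is empty")
    within = np.max(np.abs(epochs.trials), axis=1) <= threshold_uv
    retained = epochs.retained & within
    if not retained.any():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed the {threshold_uv} uV "
            f"rejection threshold"
        )
    meta = dict(epochs.meta)
    meta["reject_threshold_uv"] = threshold_uv
    meta["n_rejected"] = int((~within & epochs.retained).sum())
    return replace(epochs, retained=retained, meta=meta)


def trim_to_elapsed_time(epochs: EpochSet, elapsed_s: float) -> EpochSet:
    """Keep the maximal prefix of trials fitting in ``elapsed_s`` of wall time.

    Trial ``i`` is charged its full SOA (including the ISI for conventional
    schedules), so the prefix length is ``floor(elapsed_s / soa_s)``, capped
    at the available trial count.
    """
    if elapsed_s < epochs.soa_s:
        raise ValueError(
            f"elapsed_s={elapsed_s} is shorter than one trial "
            f"({epochs.soa_s:.6f} s)"
        )
    n_keep = min(int(np.floor(elapsed_s / epochs.soa_s + 1e-12)), epochs.n_trials)
    meta = dict(epochs.meta)
    meta["trimmed_to_s"] = elapsed_s
    return replace(
        epochs,
        trials=epochs.trials[:n_keep],
        retained=epochs.retained[:n_keep],
        origin_starts=epochs.origin_starts[:n_keep],
        meta=meta,
    )
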
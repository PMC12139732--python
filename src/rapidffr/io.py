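"""Continuous-recording container and file readers/writers.

The canonical in-memory object is :class:`ContinuousRecording`: one EEG
channel in microvolts, its nominal sampling rate, and the sample indices of
stimulus triggers. On disk three representations are supported:

* ``.npz`` — native container (eeg, triggers, fs, polarity, meta JSON);
* ``.csv`` — plain two-column fallback (``eeg`` in uV, ``trigger`` 0/1);
* ``.edf`` / ``.bdf`` — read through MNE when it is installed (one EEG
  channel and one stim channel; MNE returns volts, converted to uV here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ContinuousRecording", "read_recording", "write_recording"]

_POLARITIES = ("positive", "negative")


@dataclass
class ContinuousRecording:
    """One channel of continuous EEG (uV) with a stimulus trigger schedule."""

    eeg: np.ndarray
    fs_nominal: float
    triggers: np.ndarray
    polarity: str = "positive"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.triggers = np.asarray(self.triggers, dtype=np.int64)
        if self.fs_nominal <= 0:
            raise ValueError("fs_nominal must be positive")
        if self.eeg.ndim != 1:
            raise ValueError("eeg must be a 1-D sample vector")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")
        if len(self.triggers):
            if np.any(np.diff(self.triggers) <= 0):
                raise ValueError("triggers must be strictly increasing")
            if self.triggers[0] < 0 or self.triggers[-1] >= len(self.eeg):
                raise ValueError("triggers must lie within the sample range")

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def duration_s(self) -> float:
        return len(self.eeg) / self.fs_nominal


def write_recording(rec: ContinuousRecording, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            eeg=rec.eeg,
            triggers=rec.triggers,
            fs_nominal=rec.fs_nominal,
            polarity=rec.polarity,
            meta=json.dumps(rec.meta, default=str),
        )
    elif path.suffix == ".csv":
        trig = np.zeros(len(rec.eeg), dtype=np.int8)
        trig[rec.triggers] = 1
        pd.DataFrame({"eeg": rec.eeg, "trigger": trig}).to_csv(path, index=False)
        sidecar = {"fs_nominal": rec.fs_nominal, "polarity": rec.polarity,
                   "meta": rec.meta}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, default=str))
    else:
        raise ValueError(f"unsupported output format {path.suffix!r}")


def _read_csv(path: Path, fs_nominal: float | None, polarity: str) -> ContinuousRecording:
    df = pd.read_csv(path)
    if not {"eeg", "trigger"}.issubset(df.columns):
        raise ValueError("CSV recording needs 'eeg' and 'trigger' columns")
    meta: dict = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        fs_nominal = fs_nominal or info.get("fs_nominal")
        polarity = info.get("polarity", polarity)
        meta = info.get("meta", {})
    if fs_nominal is None:
        raise ValueError("fs_nominal required (no sidecar found)")
    triggers = np.flatnonzero(df["trigger"].to_numpy() > 0)
    return ContinuousRecording(df["eeg"].to_numpy(float), fs_nominal,
                               triggers, polarity, meta)


def _read_npz(path: Path) -> ContinuousRecording:
    with np.load(path, allow_pickle=False) as data:
        return ContinuousRecording(
            eeg=data["eeg"],
            fs_nominal=float(data["fs_nominal"]),
            triggers=data["triggers"],
            polarity=str(data["polarity"]),
            meta=json.loads(str(data["meta"])) if "meta" in data else {},
        )


def _read_edf(path: Path, polarity: str, eeg_channel: str | int = 0,
              stim_channel: str | int = 1) -> ContinuousRecording:
    import mne  # optional dependency

    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(str(path), preload=True, verbose="error")
    names = raw.ch_names
    eeg_name = names[eeg_channel] if isinstance(eeg_channel, int) else eeg_channel
    stim_name = names[stim_channel] if isinstance(stim_channel, int) else stim_channel
    eeg = raw.get_data(picks=[eeg_name])[0] * 1e6  # V -> uV
    stim = raw.get_data(picks=[stim_name])[0]
    onsets = np.flatnonzero(np.diff((stim > stim.max() / 2).astype(int)) > 0) + 1
    return ContinuousRecording(eeg, raw.info["sfreq"], onsets, polarity,
                               meta={"source": str(path)})


def read_recording(path: str | Path, polarity: str = "positive",
                   fs_nominal: float | None = None, **kwargs) -> ContinuousRecording:
    """Read a recording; the format is dispatched on the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npz":
        return _read_npz(path)
    if suffix == ".csv":
        return _read_csv(path, fs_nominal, polarity)
    if suffix in (".edf", ".bdf"):
        return _read_edf(path, polarity, **kwargs)
    raise ValueError(f"unsupported recording format {suffix!r}")
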
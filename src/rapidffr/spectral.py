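"""Epoch averaging, EFR/TFS polarity decomposition, exact-bin harmonic RMS.

Averaging retained trials gives one event-related potential (ERP) per
polarity. The mean of the two polarity ERPs is the envelope-following
response (EFR) — polarity-inverting components such as the cochlear
microphonic and any linear stimulus artifact cancel — and half their
difference is the temporal-fine-structure (TFS) response, which keeps
exactly those components. Using the mean rather than the raw sum keeps
EFR/TFS amplitudes on the same uV scale as a single-polarity ERP
(``pos = efr + tfs``, ``neg = efr - tfs``).

Harmonic amplitudes are read from exact DFT bins without zero-padding or
windowing: because the epoch length is an integer number of F0 cycles,
``k*f0`` falls exactly on bin ``k * n_cycles_in_epoch``. Amplitudes are
scaled single-sided so a sinusoid of peak A reports RMS ``A/sqrt(2)``.
Harmonics 1-3 (128/256/384 Hz at the defaults) are taken from the EFR,
harmonics 4-7 (512-896 Hz) from the TFS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import EpochSet

__all__ = [
    "Erp",
    "DerivedResponses",
    "HarmonicSpectrum",
    "EFR_HARMONICS",
    "TFS_HARMONICS",
    "average_erp",
    "derive_efr_tfs",
    "harmonic_rms",
    "harmonic_spectrum",
]

EFR_HARMONICS = (1, 2, 3)
TFS_HARMONICS = (4, 5, 6, 7)


@dataclass
class Erp:
    waveform: np.ndarray
    n_averaged: int
    polarity: str


@dataclass
class DerivedResponses:
    """EFR and TFS waveforms derived from one polarity pair."""

    efr: np.ndarray
    tfs: np.ndarray

    @property
    def trial_len(self) -> int:
        return len(self.efr)


@dataclass
class HarmonicSpectrum:
    """Per-harmonic RMS amplitudes with their bin frequency and source wave."""

    rms: dict[int, float]
    bin_hz: dict[int, float]
    source: dict[int, str]       # harmonic -> "EFR" | "TFS"
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "harmonic": list(self.rms),
                "bin_hz": [self.bin_hz[k] for k in self.rms],
                "source": [self.source[k] for k in self.rms],
                "rms_uv": [self.rms[k] for k in self.rms],
            }
        )


def average_erp(epochs: EpochSet) -> Erp:
    """Sample-wise mean over retained trials only."""
    if epochs.n_retained < 1:
        raise ValueError("no retained trials to average")
    return Erp(
        waveform=epochs.retained_trials().mean(axis=0),
        n_averaged=epochs.n_retained,
        polarity=epochs.polarity,
    )


def _waveform(x) -> np.ndarray:
    return np.asarray(x.waveform if isinstance(x, Erp) else x, dtype=np.float64)


def derive_efr_tfs(erp_pos, erp_neg) -> DerivedResponses:
    """EFR = (pos+neg)/2, TFS = (pos-neg)/2 (mean convention)."""
    pos, neg = _waveform(erp_pos), _waveform(erp_neg)
    if len(pos) != len(neg):
        raise ValueError(
            f"polarity ERPs differ in length ({len(pos)} vs {len(neg)})"
        )
    return DerivedResponses(efr=(pos + neg) / 2.0, tfs=(pos - neg) / 2.0)


def harmonic_rms(waveform: np.ndarray, f0: float, fs: float,
                 harmonics=(1, 2, 3, 4, 5, 6, 7)) -> dict[int, float]:
    """RMS amplitude at each harmonic's exact DFT bin (no zero-padding).

    Requires each ``k*f0`` to fall exactly on a bin of the unpadded DFT,
    i.e. the waveform must span an integer number of F0 cycles.
    """
    w = np.asarray(waveform, dtype=np.float64)
    n = len(w)
    spectrum = np.fft.rfft(w)
    out: dict[int, float] = {}
    for k in harmonics:
        bin_f = k * f0 * n / fs
        b = int(round(bin_f))
        if abs(bin_f - b) > 1e-6:
            raise ValueError(
                f"harmonic {k} ({k * f0} Hz) does not fall on an exact DFT "
                f"bin for a {n}-sample waveform at fs={fs}"
            )
        if b > n // 2:
            raise ValueError(f"harmonic {k} exceeds the Nyquist frequency")
        # single-sided peak 2|X|/n, converted to RMS by /sqrt(2)
        out[k] = float(np.sqrt(2.0) * np.abs(spectrum[b]) / n)
    return out


def harmonic_spectrum(responses: DerivedResponses, f0: float, fs: float,
                      efr_harmonics=EFR_HARMONICS,
                      tfs_harmonics=TFS_HARMONICS) -> HarmonicSpectrum:
    """Merge EFR-bin and TFS-bin amplitudes into one labelled spectrum."""
    efr_rms = harmonic_rms(responses.efr, f0, fs, efr_harmonics)
    tfs_rms = harmonic_rms(responses.tfs, f0, fs, tfs_harmonics)
    rms = {**efr_rms, **tfs_rms}
    rms = dict(sorted(rms.items()))
    return HarmonicSpectrum(
        rms=rms,
        bin_hz={k: k * f0 for k in rms},
        source={k: ("EFR" if k in efr_harmonics else "TFS") for k in rms},
    )
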
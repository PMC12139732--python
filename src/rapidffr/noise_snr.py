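"""Bootstrap phase-cancellation noise floors and SNR.

With continuous stimulation there is neither inter-stimulus silence nor
off-harmonic spectral headroom to estimate the noise from, so the noise
floor is bootstrapped: windows one trial long are drawn at independent
uniform start offsets from the re-concatenated retained data of each
polarity and averaged into a "noise ERP". Because the draws are not
phase-locked to the stimulus cycle, the phase-locked response cancels in
the average (residual ~ 1/sqrt(n_trials)) and the averaged window carries
only noise. Each replicate yields noise-EFR/noise-TFS harmonic amplitudes;
the noise floor per harmonic is the median over ``n_boot`` replicates
(default 10000), harmonics 1-3 read from the noise-EFR and 4-7 from the
noise-TFS.

SNR per harmonic is ``20*log10(rms_signal / rms_noise)``.

Windows are drawn with replacement and may overlap: uniform independent
starts are exactly what makes the phase cancellation unbiased. Start
indices have support ``[0, len - trial_len]`` (0-based, inclusive).

Implementation note: ``noise_floor`` precomputes the DFT coefficient of
every candidate window at the harmonic bins (a short complex correlation
per harmonic), so each bootstrap replicate is a single indexed mean rather
than a time-domain re-average; the replicate-level RNG draw order matches
:func:`draw_noise_replicate` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .spectral import EFR_HARMONICS, TFS_HARMONICS, HarmonicSpectrum

__all__ = [
    "NoiseEstimate",
    "SnrResult",
    "draw_noise_replicate",
    "noise_floor",
    "snr_db",
    "compute_snr",
]

_ALL_HARMONICS = tuple(EFR_HARMONICS) + tuple(TFS_HARMONICS)


@dataclass
class NoiseEstimate:
    """Median bootstrap noise RMS per harmonic."""

    noise_rms: dict[int, float]
    n_boot: int
    n_trials: tuple[int, int]      # windows averaged per replicate (pos, neg)
    trial_len: int
    seed: int | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class SnrResult:
    snr_db: dict[int, float]
    signal_rms: dict[int, float]
    noise: NoiseEstimate


def _n_trials_pair(n_trials) -> tuple[int, int]:
    if np.isscalar(n_trials):
        return int(n_trials), int(n_trials)
    n_pos, n_neg = n_trials
    return int(n_pos), int(n_neg)


def _check_vectors(pos: np.ndarray, neg: np.ndarray, trial_len: int) -> None:
    for name, x in (("positive", pos), ("negative", neg)):
        if len(x) < trial_len:
            raise ValueError(
                f"{name}-polarity vector ({len(x)} samples) is shorter than "
                f"one trial ({trial_len} samples)"
            )


def _bin_indices(trial_len: int, f0: float, fs: float, harmonics) -> np.ndarray:
    bins = []
    for k in harmonics:
        bin_f = k * f0 * trial_len / fs
        b = int(round(bin_f))
        if abs(bin_f - b) > 1e-6:
            raise ValueError(
                f"harmonic {k} does not fall on an exact DFT bin for "
                f"{trial_len}-sample trials at fs={fs}"
            )
        bins.append(b)
    return np.asarray(bins)


def draw_noise_replicate(continuous_pos: np.ndarray, continuous_neg: np.ndarray,
                         n_trials, trial_len: int, rng: np.random.Generator,
                         f0: float, fs: float) -> HarmonicSpectrum:
    """One bootstrap replicate: noise-EFR/noise-TFS harmonic amplitudes.

    Reference time-domain path: draws ``n_trials`` windows per polarity at
    uniform start indices, averages them into noise ERPs, combines the
    polarities, and reads the harmonic bins.
    """
    pos = np.asarray(continuous_pos, dtype=np.float64)
    neg = np.asarray(continuous_neg, dtype=np.float64)
    _check_vectors(pos, neg, trial_len)
    n_pos, n_neg = _n_trials_pair(n_trials)
    offsets = np.arange(trial_len)

    starts_p = rng.integers(0, len(pos) - trial_len + 1, size=n_pos)
    erp_p = pos[starts_p[:, None] + offsets].mean(axis=0)
    starts_n = rng.integers(0, len(neg) - trial_len + 1, size=n_neg)
    erp_n = neg[starts_n[:, None] + offsets].mean(axis=0)

    from .spectral import DerivedResponses, harmonic_spectrum

    return harmonic_spectrum(
        DerivedResponses(efr=(erp_p + erp_n) / 2.0, tfs=(erp_p - erp_n) / 2.0),
        f0, fs,
    )


def _window_dft(x: np.ndarray, trial_len: int, bins: np.ndarray) -> np.ndarray:
    """DFT coefficient of every length-``trial_len`` window of ``x`` at the
    given bins; shape (n_windows, n_bins)."""
    t = np.arange(trial_len)
    cols = []
    for b in bins:
        kern = np.exp(-2j * np.pi * b * t / trial_len)
        # correlation: C[s] = sum_t x[s+t] * kern[t]
        cols.append(sps.oaconvolve(x, kern[::-1], mode="valid"))
    return np.stack(cols, axis=1)


def noise_floor(continuous_pos: np.ndarray, continuous_neg: np.ndarray,
                n_trials, trial_len: int, f0: float, fs: float,
                n_boot: int = 10000, seed: int | None = None,
                rng: np.random.Generator | None = None) -> NoiseEstimate:
    """Per-harmonic median over ``n_boot`` phase-cancellation replicates."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pos = np.asarray(continuous_pos, dtype=np.float64)
    neg = np.asarray(continuous_neg, dtype=np.float64)
    _check_vectors(pos, neg, trial_len)
    n_pos, n_neg = _n_trials_pair(n_trials)
    if rng is None:
        rng = np.random.default_rng(seed)
    bins = _bin_indices(trial_len, f0, fs, _ALL_HARMONICS)
    dft_p = _window_dft(pos, trial_len, bins)
    dft_n = _window_dft(neg, trial_len, bins)
    scale = np.sqrt(2.0) / trial_len

    efr = np.empty((n_boot, len(bins)))
    tfs = np.empty((n_boot, len(bins)))
    for i in range(n_boot):
        starts_p = rng.integers(0, len(pos) - trial_len + 1, size=n_pos)
        xp = dft_p[starts_p].mean(axis=0)
        starts_n = rng.integers(0, len(neg) - trial_len + 1, size=n_neg)
        xn = dft_n[starts_n].mean(axis=0)
        efr[i] = scale * np.abs((xp + xn) / 2.0)
        tfs[i] = scale * np.abs((xp - xn) / 2.0)

    med_efr = np.median(efr, axis=0)
    med_tfs = np.median(tfs, axis=0)
    noise_rms = {}
    for j, k in enumerate(_ALL_HARMONICS):
        noise_rms[k] = float(med_efr[j] if k in EFR_HARMONICS else med_tfs[j])
    return NoiseEstimate(
        noise_rms=noise_rms,
        n_boot=n_boot,
        n_trials=(n_pos, n_neg),
        trial_len=trial_len,
        seed=seed,
        meta={"efr_median": {k: float(med_efr[j]) for j, k in enumerate(_ALL_HARMONICS)},
              "tfs_median": {k: float(med_tfs[j]) for j, k in enumerate(_ALL_HARMONICS)}},
    )


def snr_db(signal_rms: float, noise_rms: float) -> float:
    """``20*log10(rms_signal / rms_noise)``."""
    if noise_rms <= 0:
        raise ValueError("noise_rms must be positive (SNR undefined)")
    if signal_rms < 0:
        raise ValueError("signal_rms must be non-negative")
    return float(20.0 * np.log10(signal_rms / noise_rms))


def compute_snr(spectrum: HarmonicSpectrum, noise: NoiseEstimate) -> SnrResult:
    """Per-harmonic SNR from a signal spectrum and a noise-floor estimate."""
    snrs = {k: snr_db(spectrum.rms[k], noise.noise_rms[k])
            for k in spectrum.rms if k in noise.noise_rms}
    return SnrResult(snr_db=snrs,
                     signal_rms={k: spectrum.rms[k] for k in snrs},
                     noise=noise)
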
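# Methods

## The measurement problem

The frequency-following response (FFR) is a scalp potential that tracks
sustained, phase-locked neural firing in the auditory brainstem during a
periodic sound. It is conventionally measured by presenting a short tone
burst a few thousand times, separated by silent inter-stimulus intervals
(ISIs), epoching the EEG around each burst, and averaging. Because the
response is tiny (tenths of a microvolt against microvolts of background
EEG), acquisition time is dominated by how many averageable response
periods fit into a session — and with an ISI roughly as long as the burst,
half of the session is silence.

The rapid protocol implemented here removes the silences: the stimulus — a
band-limited sawtooth, fundamental F0 = 128 Hz built from 30 harmonics at
amplitudes 1/k — plays continuously, and *every F0 period* of the recording
becomes one trial. At the default rates (F0 = 128 Hz, fs = 16384 Hz) a
cycle is exactly 128 samples (7.8125 ms), which is why F0 must divide fs:
cycle boundaries then fall on sample boundaries and single-cycle epochs can
be excised exactly, with no windowing or zero-padding, and harmonic
amplitudes read from exact DFT bins.

## Pipeline

1. **Drift correction.** The presentation and acquisition devices run on
   separate clocks. The drift ratio r is estimated from the sample span
   between reference triggers (block onset/offset for continuous runs,
   first/last burst onset for burst runs) divided by the stimulus-defined
   duration of that span; the EEG is resampled by 1/r (polyphase, rational
   approximation of the ratio to denominator ≤ 1e5). |r − 1| > 1% is
   treated as a trigger fault, not drift. A ratio of exactly 1 short-cuts
   to a copy.
2. **Epoching.** Rapid: consecutive non-overlapping 128-sample epochs
   starting round(10 ms · fs) = 164 samples after the block-onset trigger
   (the 10 ms skip accounts for neural transmission delay; any constant
   integer shift merely rotates response phase). Conventional: one epoch
   per burst at trigger + lag, where the lag maximises the
   cross-correlation of the provisional averaged response with an F0 sine
   on a one-sample grid over 5–15 ms; each epoch is baseline-corrected by
   the mean of the 7 ms pre-trigger window. For a steady periodic response
   the lag is identifiable only modulo one cycle (7.8 ms); since a
   whole-cycle phase rotation does not affect harmonic amplitudes, the
   in-window alias is harmless. The signed correlation maximum is used by
   default (the absolute maximum is an option, since response sine phase is
   not known a priori).
3. **Artifact rejection.** A trial is rejected when any sample deviates
   from 0 by *strictly more than* 35 µV ("more than" is read literally: a
   sample at exactly 35.0 µV is retained). The rule is idempotent and
   order-independent.
4. **Averaging and polarity decomposition.** Retained trials are averaged
   per polarity into ERPs. EFR = (pos + neg)/2, TFS = (pos − neg)/2 — the
   mean convention keeps both on the single-polarity µV scale
   (pos = EFR + TFS). Polarity-inverting components (cochlear microphonic,
   linear stimulus artifact) cancel exactly in the EFR.
5. **Harmonic amplitudes.** The unpadded DFT of the EFR/TFS waveform is
   read at the exact bins of k·F0; amplitude is scaled single-sided so a
   sinusoid of peak A reports RMS A/√2. Harmonics 1–3 (128–384 Hz) come
   from the EFR, harmonics 4–7 (512–896 Hz) from the TFS. For 7-cycle
   conventional epochs the bins are DFT indices 7k.
6. **Noise floor.** Continuous stimulation leaves neither silent intervals
   nor off-harmonic bins as a noise reference, so the floor is
   bootstrapped: per polarity, as many windows (one trial long) as there
   were retained trials are drawn with replacement at uniform start indices
   from the re-concatenated retained data (support [0, L − trial_len],
   0-based inclusive) and averaged; because the draws are not phase-locked,
   the evoked component cancels (residual ∝ 1/√n) and the averaged window
   estimates pure noise. Noise-EFR/noise-TFS amplitudes are computed per
   replicate; the floor per harmonic is the median over n_boot = 10000
   replicates. SNR = 20·log10(RMS_signal / RMS_noise).
7. **Reliability statistics.** Outlier screening removes values more than
   2.5 SD from their group mean (leave-in z-score, SD with ddof = 1,
   grouped per harmonic × condition). ICCs: one-way random single-measure
   ICC(1) with F test on (n−1, n(k−1)) df, and two-way random
   absolute-agreement single-measure ICC(A,1), whose denominator df use the
   Satterthwaite approximation evaluated at the estimated coefficient —
   the variant that yields non-integer df — with the standard F-bound 95%
   CI. The permutation test on an ICC difference shuffles the second
   column of each n×2 matrix independently per iteration, recomputes both
   ICCs, and counts strictly greater |null| values; with the strict
   inequality p-values are (slightly conservatively) uniform under the
   null. Holm correction is provided as a utility (via statsmodels).
8. **Chunked series.** Long continuous runs can be split into sequential
   equal-cycle chunks, each analysed independently (reject → average →
   spectra → bootstrap → SNR) with bootstrap seeds spawned from one parent
   seed — the design used to probe neural adaptation under sustained
   stimulation.

## Implementation notes

- The bootstrap precomputes each candidate window's DFT coefficient at the
  seven harmonic bins (complex correlation with a one-window kernel via
  overlap-add convolution), reducing every replicate to an indexed mean.
  The replicate-level RNG order (positive starts, then negative, one
  replicate at a time) is identical to the time-domain reference
  implementation, so the two agree to machine precision for the same seed.
- Windows may overlap and are drawn with replacement; independent uniform
  starts are what makes the phase cancellation unbiased in expectation.
- Numerical tie-breaks: the lag search takes the first maximum on the
  grid; trimming to an elapsed-time budget keeps floor(budget / SOA)
  trials (each trial charged its full stimulus-onset asynchrony, ISI
  included); ICC with zero within-subject variance returns exactly 1 with
  a degenerate (1, 1) CI.

## The simulator

Ground truth is required to validate parameter recovery, so recordings are
simulated rather than replayed: harmonic sinusoids at known RMS amplitudes
— polarity-invariant "envelope" components at harmonics 1–3 and
polarity-inverting "fine-structure" components at 4–7 — delayed 10 ms,
onset/offset-ramped over one cycle (mirroring the stimulus taper), and
phase-locked to each stimulus onset (bursts start a non-integer number of
cycles apart, so phase must reference the onset, not global time).
Additive noise is white Gaussian per polarity (optionally mixed with 1/f);
artifacts are Poisson-timed Hann pulses above the rejection threshold;
clock drift is modelled by evaluating the analytic response at
t = n/(fs·drift), which is exact (no interpolation error on the simulation
side). Continuous blocks carry onset and offset triggers; the block is
stimulated a few cycles longer than the analysed count so the 10 ms-skip
epoching sees pure steady state.

Default study conditions, chosen once as representative of a clean adult
recording: envelope amplitudes {0.12, 0.08, 0.05} µV, fine-structure
{0.05, 0.04, 0.03, 0.025} µV, broadband noise 2.5 µV RMS. At 7503 cycles
these give post-averaging SNRs of roughly 20–33 dB across harmonics. What
the simulator does *not* emulate: non-Gaussian and non-stationary EEG
background, real cochlear-microphonic waveforms, adaptation dynamics,
electrode/reference effects. Passing tests therefore demonstrate estimator
correctness and the method's statistical behaviour, not performance on any
particular empirical dataset.

Two deliberate deviations from physical completeness matter for tests:
with the default one-cycle response ramp, the 10 ms onset skip (1.28
cycles) overlaps the ramp tail (the ramp ends 17.8 ms after the trigger),
so the first ~1.3 epochs are attenuated and recovery is exact only to
~(1 cycle)/n_cycles; the machine-precision recovery identity is checked
with the ramp disabled.

## Property-suite design choices

- **Noise-floor oracle.** The library bootstrap is compared against an
  independently coded time-domain bootstrap using common random numbers
  (same seed, same draw semantics, different computation path). This makes
  the comparison sensitive to any defect in window extraction, polarity
  combination, scaling or the median — while excluding bootstrap
  Monte-Carlo noise from the tolerance. Statistical correctness is checked
  separately against the closed-form Rayleigh median
  σ_e·√(2 ln 2)/√N for white noise.
- **Time-matched comparison.** With equal elapsed time, the continuous
  schedule analyses ~1.82× as many cycles as the burst schedule
  (7503·128 vs 588·896 samples), predicting a 10·log10(1.82) ≈ 2.6 dB SNR
  advantage from averaging alone. The measurement uses a flat 0.03 µV
  harmonic profile — small enough that the bootstrap's signal-cancellation
  residual (quadratic in amplitude, and relatively ~7× larger for
  896-sample noise windows than 128-sample ones) does not bias the floors,
  yet large enough that every harmonic is well above its floor — and
  disables response onset ramps, since per-burst tapering costs the
  conventional arm a further ~1.3 dB (an onset-transient effect, real but
  distinct from the elapsed-time effect being predicted).
- **Scaled problem sizes.** The suite runs chunk analyses at 1875 cycles
  per chunk and bootstrap sizes of 200–2000 replicates; these sizes were
  chosen so the full property suite completes in about a minute while
  leaving each assertion's expected margin several times its Monte-Carlo
  standard error.

## Known limitations

- The bootstrap noise floor includes the 1/√n cancellation residual of any
  phase-locked signal present; at high signal-to-noise this inflates the
  floor (visibly so for the long windows of the conventional arm). This is
  a property of the estimator itself, shared with the original procedure.
- Elapsed-time trimming charges each trial its full SOA; published trial
  counts for a given elapsed-time budget depend on whether the trailing
  ISI is charged, so counts can differ by a trial or two from other
  implementations.
- The twoway ICC CI bounds follow the absolute-agreement F-bound
  construction; for coefficients at the boundary (MSE = 0) the CI
  degenerates to a point.
- EDF/BDF input requires MNE (optional extra); the native containers are
  NPZ and two-column CSV.
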
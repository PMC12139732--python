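# rapidffr

Analysis toolbox for the **rapid frequency-following response (FFR)**: a
continuous-stimulation, single-cycle-averaging protocol for recording the
brainstem's phase-locked response to periodic sound, together with the
conventional burst protocol, bootstrap noise-floor/SNR estimation, and
test-retest reliability statistics. It is aimed at auditory-neuroscience
and clinical-electrophysiology users who want a tested, reproducible
implementation of the whole chain — from stimulus synthesis to group-level
statistics — plus a ground-truth simulator so every stage can be validated
without human EEG.

## The method in brief

A band-limited sawtooth with fundamental F0 = 128 Hz (30 harmonics,
amplitudes 1/k) plays **continuously** in each polarity. Because F0 divides
the 16384 Hz sampling rate, one period is exactly 128 samples, and every
period of the recording becomes one trial:

- epoch the drift-corrected EEG into consecutive 128-sample cycles,
  starting 10 ms after block onset (neural transmission delay);
- reject trials exceeding ±35 µV; average the rest per polarity;
- combine polarities: EFR = (pos + neg)/2 (envelope response, cancels the
  cochlear microphonic), TFS = (pos − neg)/2 (temporal fine structure);
- read harmonic amplitudes from exact, unpadded DFT bins — harmonics 1–3
  from the EFR, 4–7 from the TFS;
- estimate the noise floor by a phase-cancellation bootstrap: average as
  many randomly-offset one-cycle windows as there were trials, so the
  phase-locked response cancels; take the per-bin median over 10000
  replicates; then SNR = 20·log10(RMS_signal / RMS_noise);
- quantify agreement and test-retest reliability with one-way and two-way
  (absolute agreement, Satterthwaite df) intraclass correlations, and
  compare ICCs between methods with a permutation test
  (p = #{|H0| > |obs|} / N).

A minute of continuous stimulation yields ~7500 single-cycle trials where
the burst protocol yields ~590 seven-cycle trials in the same elapsed time
— an SNR gain of 10·log10(cycle ratio) ≈ 2.6 dB from averaging alone, plus
whatever the absence of onset transients contributes.

See `docs/methods.md` for the full model, conventions, and limitations.

## Worked example

Simulate a one-minute recording pair (7503 cycles per polarity, known
harmonic amplitudes, 2.5 µV broadband noise) and analyse it:

```bash
ffr simulate --seed 3 --cycles 7503 -o rec
ffr snr --pos rec_pos.npz --neg rec_neg.npz --cycles 7503 \
        --nboot 2000 --seed 42 -o snr.csv
```

which prints:

```
 harmonic  bin_hz source   rms_uv  noise_rms_uv    snr_db  ...
        1   128.0    EFR 0.124539      0.002242 34.894192
        2   256.0    EFR 0.082696      0.002208 31.470427
        3   384.0    EFR 0.046970      0.002152 26.781479
        4   512.0    TFS 0.051132      0.002190 27.363137
        5   640.0    TFS 0.042141      0.002122 25.958913
        6   768.0    TFS 0.028401      0.002095 22.643806
        7   896.0    TFS 0.025031      0.002142 21.351280
```

`rms_uv` is the recovered response amplitude per harmonic — compare with
the simulator's ground truth of 0.12/0.08/0.05 µV (envelope, EFR rows) and
0.05/0.04/0.03/0.025 µV (fine structure, TFS rows); each is recovered to
within its noise floor (`noise_rms_uv`, the bootstrap median ≈ 0.0022 µV
at this trial count). `snr_db` is the per-harmonic SNR; ~35 dB at F0
reflects 7503 averaged cycles of a 0.12 µV component in 2.5 µV noise.

The same interface covers the burst protocol (`--mode conventional`, with
automatic 5–15 ms lag search and 7 ms baseline correction), stimulus
generation (`ffr stimgen`), ICCs and permutation tests on tidy CSV tables
(`ffr icc`, `ffr permtest`), and sequential-chunk analyses of long
recordings (`ffr chunks`). Library use mirrors the CLI:

```python
from rapidffr import SimulationConfig, simulate_recording_pair, analyze_rapid
cfg = SimulationConfig(n_cycles=7503, seed=3)
pos, neg = simulate_recording_pair(cfg)
result = analyze_rapid(pos, neg, n_cycles=7503, n_boot=2000, seed=42)
print(result.snr.snr_db)
```

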
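# cvep — code-modulated VEP decoding with chaotic and m-sequence codes

Code-modulated visual evoked potentials (c-VEP) drive brain–computer
interfaces by flickering a stimulus with a broadband binary code; the
attended target is identified by matching the EEG response to the code's
lagged versions.  The classical modulation code is a 31-bit m-sequence,
whose near-Dirac circular autocorrelation makes lagged copies separable —
but whose low/medium-frequency flicker content is visually fatiguing.
This package implements an alternative: a 31-bit *chaotic* binary code
derived from the logistic map

    x(i+1) = A · x(i) · (1 − x(i)),        x(0) = 0.015, A = 3.882

where each iterate is thresholded at 0.5 (x > 0.5 → bit 0, else bit 1)
and immediately followed by its one's complement, which balances the
code and shifts its spectral energy above 30 Hz where flicker is barely
perceptible.

The package provides the full analysis pipeline around these codes:

- **codes** — m-sequence (LFSR) and logistic-map chaotic code generation,
  circular 8-bit lagged target sets (4 targets at 90 bits/s), correlation
  functions and band-partitioned amplitude spectra;
- **synthdata** — simulated 4-channel occipital EEG (Oz, O1, O2, Pz):
  lag-preserving evoked responses (code waveform ⊛ evoked kernel) in
  pink+white noise at a prescribed SNR, 10 trials × 18 epochs per target;
  synthetic visual-analogue fatigue (VAS) tables;
- **preproc** — zero-phase Butterworth band-pass (2–40 Hz, order 8),
  linear detrending, trigger-aligned trial and epoch extraction;
- **decode_cca** — template matching by canonical correlation analysis:
  per-target templates T_i (mean training epoch), feature
  ρ_i = mean of the canonical correlations between the averaged test
  epochs and T_i, argmax identification;
- **decode_stb** — spatiotemporal LCMV beamforming: per-target activation
  patterns a_i (concatenated mean epochs), weights
  w_i = Σ⁻¹a_i / (a_iᵀΣ⁻¹a_i) under the unit-gain constraint
  a_iᵀw_i = 1, scores y_i = s·w_i;
- **evaluate** — 10-fold cross-validated accuracy vs stimulation time
  (0.344 s to 6.2 s), Wilcoxon signed-rank, paired t, repeated-measures
  ANOVA with Greenhouse–Geisser correction, Bonferroni post hocs
  (α = 0.008);
- **pipeline / cli** — reproducible end-to-end runs from a single seed.

## Worked example

```bash
$ cvep codes generate --family chaotic
1010010110011001010110010110100
{"family": "chaotic", "label": "Ch1", "length": 31, "rate_hz": 90.0, "duration_s": 0.34444444444444444}
```

The 31 bits are the logistic-map code (bit 1 = light, 0 = dark), one
period of which lasts 0.344 s at 90 bits/s.  Its spectral energy splits
into low [0, 10) / medium [10, 30] / high (30, 45] Hz fractions of
0.495 / 0.186 / 0.320, against 0.613 / 0.226 / 0.161 for the m-sequence
`1111100110100100001010111011000` — the chaotic code moves flicker
energy into the high band, which is why it is less fatiguing.

A full synthetic study — simulate EEG for both code families, decode
with CCA and STB under 10-fold cross-validation, and run the statistical
battery:

```python
from cvep import RunConfig, run_full_pipeline
run_full_pipeline(RunConfig(seed=1, n_seeds=20), "results/run1")
```

This writes per-subject accuracy curves (`curve_<family>_<decoder>.csv`),
a per-stimulation-time Wilcoxon comparison of the decoders
(`comparison_<family>.csv`, 18 rows from 0.344 s to 6.19 s), a synthetic
VAS table with its fatigue statistics (`vas_stats.json`), and a
checksummed manifest.  At the default −5 dB simulation SNR the chaotic
family decodes at ≈92% (CCA) and 100% (STB) mean accuracy for full
6.2-s trials; a signal-free control sits at the 25% chance level of the
4-target task.

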
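# freqtagsl

Frequency-tagged EEG analysis of infant visual statistical learning, with
a matched synthetic-data generator.

When shapes are shown at 6 Hz and secretly grouped into fixed pairs
("doublets") occurring at 3 Hz, an infant brain that has picked up the
pair structure entrains not only at the stimulus rate but also at the
doublet rate. This package implements the full analysis chain for that
design — for developmental-EEG researchers who want a tested, seeded
reference implementation, and for methodologists who want to study its
statistical behaviour on synthetic data:

* **paradigm** — doublet assignment, pseudo-random familiarization
  streams (no immediate doublet repetition; within-doublet TP = 1,
  between-doublet TP = 1/3), test schedules, session stopping rules;
* **spectral** — FFT amplitude spectra of 20-s blocks (0.05-Hz bins) and
  the neighbour-bin SNR: `SNR(f) = amp(f) / mean(amp at the 10
  surrounding bins, skipping the 2 adjacent)`;
* **blocks** — the two-criterion valid-block filter (6-Hz occipital
  SNR > 2 and ≥ 7 s looking), ≥ 2 valid blocks per participant,
  renumbering, truncation at 8, grand-mean centring;
* **harmonics** — Wilcoxon selection of base (6, 12, 18, 24 Hz) and
  doublet (3, 9, 15, 21 Hz) harmonics with the non-overlap rule;
* **roi** — permutation maximum-statistics thresholds on whole-scalp SNR
  topographies and conjunction ROI derivation;
* **aggregate** — ROI/harmonic-averaged SNR and the learning index
  `LI = ln(doublet SNR) − ln(base SNR)`;
* **behaviour** — test-phase looking times, novelty-preference scores,
  Holm-corrected one-sample t-tests;
* **models** — random-intercept linear mixed models (e.g.
  `log base SNR ~ Timepoint × Block order + Looking time +
  (1 | participant)`), stepwise selection by LRT/AIC, marginal contrasts,
  simple slopes, ICC;
* **synth** — longitudinal cohorts (30/27/23 infants with monotone
  attrition) with block-level outcomes drawn from the fitted models used
  as generative truth, and optionally full 128-channel waveforms
  (calibrated sinusoids on an occipital topography plus 1/f noise).

## Worked example

```python
from freqtagsl import (
    simulate_cohort, finalize_block_table, fit_lmm,
    BASE_SNR_MODEL, LEARNING_INDEX_MODEL,
)

cohort = simulate_cohort(master_seed=7, mode="fast")
table = finalize_block_table(cohort.blocks)
print(f"{len(cohort.sessions)} sessions, "
      f"{table.attrs['filter_report']['n_recorded']} blocks recorded, "
      f"{len(table)} retained")

fit = fit_lmm(BASE_SNR_MODEL, table)
print(fit.summary_table().round(3))
print(f"ICC = {fit.icc:.2f}")
```

prints

```
80 sessions, 642 blocks recorded, 492 retained
                  estimate     se  ci_low  ci_high       t      p
Intercept            0.295  0.028   0.239    0.351  10.376  0.000
T2                   0.083  0.023   0.037    0.128   3.579  0.000
T3                   0.016  0.025  -0.032    0.064   0.645  0.519
centred_order       -0.020  0.008  -0.036   -0.004  -2.383  0.018
T2:centred_order     0.004  0.012  -0.019    0.028   0.378  0.705
T3:centred_order     0.004  0.013  -0.020    0.029   0.323  0.747
centred_looking      0.028  0.004   0.020    0.035   7.237  0.000
ICC = 0.27
```

Reading the output: this simulated cohort of 80 sessions retains 492
analysable blocks after the validity filter. The base-frequency response
is elevated at 6 months relative to 3 months (T2 = +0.083 log-SNR),
declines over familiarization blocks (−0.020 per block), and tracks
looking time (+0.028 per second of attention); about 27% of its variance
is between infants (ICC). These estimates recover the generative
coefficients (0.100, −0.024, 0.029, ICC 0.23) within their standard
errors — one draw of the sampling variability the mixed model is
quantifying.

The same chain runs from the command line:

```sh
freqtagsl run-all --seed 7 --fast-mode --out runs/demo
freqtagsl run-all --seed 7 --full-mode --out runs/demo-waveforms   # slower
freqtagsl report --out runs/demo
```

`--full-mode` synthesizes every block as a 128-channel waveform and runs
the spectral, harmonic-selection and permutation-ROI stages on the
measured spectra; `--fast-mode` emits block-level features directly and
uses the a-priori occipital set with the canonical harmonic sets.

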
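# Methods

`freqtagsl` implements a frequency-tagging analysis of visual statistical
learning in infancy, together with a generative model of the data such an
experiment produces. This note documents the science the code encodes, the
choices that were genuinely open, and what the synthetic benchmark does and
does not establish.

## The paradigm

Eight shapes are shown one at a time at 6 Hz. The shapes are grouped into
four fixed *doublets*: within a doublet the transitional probability (TP)
from the leading to the trailing shape is 1; across doublets the next
doublet is drawn uniformly among the three doublets different from the
current one, so the TP from a doublet-final shape to another doublet's
initial shape is 1/3. A familiarization block lasts 24 s (144 shapes) with
2-s fades; only the central 20 s (120 shapes) is analysed. Sessions run a
minimum of 8 and a maximum of 15 blocks, adding blocks until 120 s of
cumulative looking is reached. The test phase alternates four familiar and
four novel doublets (starting familiar), 7 s and 42 shapes per trial.

Novel test pairs are built by recombining a leading shape with the trailing
shape of a different doublet (a uniform derangement of the four trailing
positions). This preserves within-doublet position, guarantees each shape
is used once, and guarantees the pair never occurred as an adjacent ordered
pair during familiarization, where the only adjacent pairs are
(lead, trail) within doublets and (trail, lead') across them. Whether the
original experiment preserved position is not decidable from its
description; position-preserving recombination is one admissible reading
and isolates pairing novelty from positional novelty. It is configurable
in the sense that any schedule satisfying the alternation and novelty
constraints can be supplied downstream.

## Spectral measurement

A 20-s block at 1000 Hz gives 0.05-Hz resolution, so every tagged
frequency (multiples of 3 Hz) falls exactly on a bin; with a rectangular
window and per-channel mean removal the tagged components are
leakage-free, which is why no taper is applied. One-sided amplitudes are
2|X_k|/N (DC and Nyquist not doubled); the normalization convention is
irrelevant to any SNR (a ratio) but is fixed for reproducibility.

The SNR at bin k is the amplitude at k divided by the mean amplitude of
the 10 surrounding bins, 5 per side, excluding the 2 bins adjacent to k
(which can carry residual signal energy in real recordings). Bins whose
neighbourhood leaves the spectrum (the first and last 6 bins) are masked
undefined rather than computed from a shrunken neighbourhood, which would
bias the statistic; all analysed frequencies are interior. A zero
neighbourhood mean yields an undefined (masked) value, not an exception.

Note a structural property used repeatedly below: under pure noise the
neighbour-ratio SNR does not have mean 1 but E[N]·E[1/D] ≈ 1.027 for 10
Rayleigh neighbour bins (Jensen's inequality applied to 1/D). "SNR = 1"
is therefore the right *scale* for no signal but not the exact null mean.

## Valid blocks and the analysis table

A block is valid when (a) 6-Hz SNR exceeds 2 (strict) in at least one of
the ten a-priori medial occipital electrodes {69, 70, 73, 74, 75, 81, 82,
83, 88, 89} of a 128-channel geodesic net, and (b) the infant looked at
least 7 s of the 20-s core. Participants contribute a timepoint only with
at least two valid blocks. Valid blocks are renumbered by relative
position, truncated at order 8, and block order and looking time are
mean-centred. Centring is computed dataset-wide over all retained rows
(one grand mean), not per timepoint: the description of the original
analysis does not stratify, and a single constant keeps the intercept
interpretable at the average block position and average attention. The
constants are recorded in the table's metadata.

## Harmonic selection and ROI

Responses are quantified not only at 6 and 3 Hz but at their harmonics in
3–24 Hz. Doublet quantification uses only harmonics not shared with the
base response (9, 15, 21 Hz besides 3 Hz), since every multiple of 6 Hz
contains stimulus-driven energy. A frequency is retained when a one-sided
Wilcoxon signed-rank test of per-subject mean SNR > 1 is significant
(exact null for n ≤ 25, normal approximation with continuity correction
above; an all-tied sample is never retained). The unit of analysis — the
subject mean over that subject's valid blocks and the ten a-priori
occipital channels — is a choice this package fixes and documents: harmonic
selection happens before any ROI exists, and the a-priori set is the only
channel set defined that early. By default a frequency must be significant
at every timepoint (joint selection); per-timepoint selection is available.

The ROI is derived by permutation maximum statistics on group-averaged
whole-scalp SNR topographies. For each of 10 000 permutations every
subject's topography is independently replaced with a unit topography with
probability 0.5; the maximum of the group-averaged topography across
electrodes is recorded, and the significance threshold is the 95th
empirical percentile (linear interpolation between order statistics) of
these maxima. Electrodes whose observed group mean strictly exceeds the
threshold are significant. The observed assignment is not force-included
in the null; with 10 000 draws its inclusion changes the threshold by less
than one order statistic. The ROI keeps electrodes significant at *both*
3 and 6 Hz in at least 2 of 3 timepoints ("multiple timepoints" is not
quantified in the source description; ≥ 2 is the default and an argument).

## Aggregation and the learning index

Per block, SNR is averaged across ROI electrodes at each selected
harmonic, then across harmonics (equal weights; no weighting scheme is
defined by the paradigm). The learning index is

    LI = ln(doublet SNR) − ln(base SNR),

the natural-log ratio of structure-related to stimulus-driven entrainment.
It is zero when the two responses are equal, invariant to overall signal
scale, strictly increasing in the doublet response and decreasing in the
base response. It normalizes for global responsiveness, not a pure
learning measure — it is intended as a complement to the doublet response,
not a replacement.

## Mixed models

Block-level outcomes are modelled with random-intercept LMMs
(REML; treatment coding, T1 reference):

* log base SNR ~ Timepoint × Block order + Looking time + (1 | participant)
* log doublet SNR ~ Timepoint × Block order + Looking time + (1 | participant)
* learning index ~ Timepoint + Block order + (1 | participant)
* preference score ~ Learning index × Timepoint (+ (1 | participant))

Wald 95% CIs are b ± 1.96·SE. t statistics use residual degrees of
freedom (n − k fixed effects); with ≈ 480 residual df this matches
finite-sample-corrected df approximations to the reported precision, and
exact Kenward-Roger is deliberately out of scope. ICC is
σ²_intercept / (σ²_intercept + σ²_residual). Stepwise selection refits
nested ladders by ML and adopts a step when the likelihood-ratio p < .05
or ΔAIC < −2 (MixedLM does not define AIC; −2·llf + 2·(k + 2) is used).
Marginal timepoint contrasts are evaluated at −1 SD / mean / +1 SD of
centred block order (a ±2 SD grid for robustness), Holm- or
Tukey-adjusted within grid point; simple slopes of preference on the
learning index come from the coefficient covariance, Tukey-adjusted
pairwise. When the random-intercept variance of the brain–behaviour model
estimates to zero, the model is refit by OLS and flagged — the fixed
effects are numerically unchanged and the refit avoids an
overparameterized variance component.

## The generative model

The synthetic cohort emulates the study conditions the analysis assumes:

* **Cohort**: 30 infants at T1, a random 27-subset at T2, a random
  23-subset of those at T3 (monotone attrition), 80 sessions in total.
* **Blocks**: each session draws up to 15 blocks; a block is invalid with
  probability 0.236 (giving the long-run valid fraction of 76.4%), split
  evenly between low-looking (uniform 2–6.9 s) and suppressed-response
  failures. Valid-block core looking is 20 − Exp(3) s resampled to
  ≥ 7 s — near-ceiling looking, matching the reported per-block means.
  The stopping rule is applied to extended-block looking approximated as
  1.2 × core looking (fade looking proportional to core looking).
* **Outcomes**: per-block log base and log doublet SNR are drawn from the
  two fitted LMMs used as generative truth (fixed effects, independent
  per-subject random intercepts, Gaussian residuals), with covariates
  centred exactly as the analysis will centre them, so the analysis chain
  recovers the generating coefficients without centring mismatch. The
  learning index is derived as the difference of the two logs; its implied
  T3 effect is 0.083 − 0.002 = 0.081. Blocks outside the analysis set
  carry placeholder outcomes near SNR = 1.
* **Behaviour**: for sessions that reach the test phase, eight alternating
  trial looking times are drawn with familiar mean 3.5 s (mid-trial, so
  the [0, 7] s truncation stays mild) and trial SD 1.414 s, chosen so the
  4-vs-4 preference score has SD ≈ 1 s, the scale of the reported
  per-timepoint standard errors. The novel-trial mean is shifted by
  slope(timepoint) × learning index + intercept(timepoint), with the
  fitted simple slopes (−0.969, 1.672, 4.421) and per-timepoint intercepts
  as defaults, so the expected preference score follows the configured
  linear link exactly when truncation is inactive.
* **Waveforms (full mode)**: each block is 128 channels × 20 s of 1/f
  noise (amplitude envelope f^(−1) plus a white floor, circular complex
  Gaussian spectral coefficients) plus sinusoids at 6/12/18/24 Hz and
  3/9/15/21 Hz on a stylized occipital topography (unit plateau on the ten
  a-priori electrodes, raised-cosine half-gain fringe, zero elsewhere —
  only the shape matters, since SNR is amplitude-invariant). Sinusoid
  amplitudes are calibrated by inverting the Rice mean of
  |a·e^{iφ} + Z| so that the *measured* mean SNR at the tagged bin hits
  the target, including a second-order correction for E[1/D] of the
  neighbour mean (≈ +2.7%). Per-block log-SNR targets below zero cannot
  be represented by a non-negative amplitude and are floored at zero
  signal; full mode also layers measurement noise on top of the
  generative residual. Full mode therefore exercises the spectral chain;
  statistical calibration studies use fast mode, which emits the
  block-level outcomes directly.

**What the synthetic data does not emulate**: artifacts (blinks, motion),
channel interpolation, volume-conducted channel correlations (noise is
independent across channels), residual autocorrelation across blocks
beyond the random intercept, the harmonic-dominance shifts across age
(all harmonics carry equal target SNR), and any model misspecification —
the analysis model is exactly the generative model. Passing recovery
tests therefore demonstrates the chain is self-consistent and unbiased
under its assumptions, not that those assumptions hold for real infant
EEG.

## Problem sizes used in the checks

The distributed checks run the sequence statistics on 1000 generated
blocks (≈ 1.4 × 10⁵ transitions), the parameter-recovery study on 100
cohorts in fast mode, waveform-level calibration checks on 60–80 blocks,
and the end-to-end waveform pipeline on a reduced, stronger-signal cohort
(8/7/6 subjects) — sizes at which the Monte-Carlo error is well inside
each asserted tolerance.

## Known limitations

* **The "SNR > 1" null is not exact.** Under pure noise the neighbour-
  ratio SNR has mean ≈ 1.027, not 1. Consequently the two calibration
  claims one might hope for do not hold, and the corresponding checks in
  the acceptance suite fail by honest measurement: (a) the Wilcoxon
  harmonic-selection test rejects far above its nominal α under pure noise
  once SNR values are averaged over blocks and channels (measured ≈ 0.69
  at α = .05 with 30 subjects and 60 ratios behind each subject mean),
  because averaging shrinks the dispersion around the biased mean; (b) the
  replace-with-ones permutation scheme is anticonservative (measured
  family-wise rate ≈ 0.96 at nominal .05 over 500 null datasets), both
  because the unit topography sits below the true null mean and, more
  fundamentally, because replacing a noisy topography with an exact
  constant halves the permutation variance relative to the sampling
  variance of the observed mean. These are properties of the published
  procedure itself, faithfully implemented; in practice the procedure is
  used to *rank* electrodes where signal is overwhelming (observed SNR
  well above any threshold), not to control a delicate error rate.
* At very small subject counts the same permutation scheme can become
  unable to reject anywhere (leave-half-out means exceed the full-sample
  mean), which is why the reduced end-to-end demonstration uses a
  stronger tagged response than the study defaults.
* The learning index inherits the ratio bias of its inputs near the noise
  floor; it is analysed only on valid blocks, where the base response is
  by construction well above noise.
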
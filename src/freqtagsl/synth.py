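"""Synthetic longitudinal cohorts of frequency-tagged infant EEG.

The generator emulates the study conditions the analysis assumes: a
longitudinal cohort (30/27/23 infants at 3/6/9 months with monotone
attrition), per-session familiarization blocks governed by the stopping
rule, an invalid-block process, per-block looking times, block-level
log-SNR outcomes drawn from random-intercept LMMs whose fixed effects
default to the fitted base- and doublet-frequency models, and a
per-timepoint linear link from the neural learning index to the
behavioural novelty-preference score.

Two modes share the identical cohort structure:

* **fast** — block-level log-SNR outcomes are emitted directly from the
  generative LMMs (the model residual is the measurement noise);
* **full** — each block is synthesized as a 128-channel, 20-s waveform
  (calibrated sinusoids at the tagged harmonics on an occipital
  topography plus 1/f noise) and measured through the spectral chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special

from . import blocks as blocks_mod
from . import spectral
from .channels import N_CHANNELS, OCCIPITAL_APRIORI, OCCIPITAL_FRINGE, channel_indices
from .paradigm import InvalidInputError, apply_stopping_rule

BASE_HARMONICS = (6.0, 12.0, 18.0, 24.0)
DOUBLET_HARMONICS = (3.0, 9.0, 15.0, 21.0)
CANDIDATE_FREQS = tuple(sorted(BASE_HARMONICS + DOUBLET_HARMONICS))

#: E|Z| / component-sd for a circular complex Gaussian (Rayleigh mean)
_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)
#: squared coefficient of variation of a Rayleigh amplitude
_RAYLEIGH_CV2 = 4.0 / math.pi - 1.0


@dataclass(frozen=True)
class LmmEffects:
    """Fixed effects and variance components of one generative LMM."""

    intercept: float
    t2: float
    t3: float
    block_order: float
    looking: float
    t2_block: float
    t3_block: float
    intercept_sd: float
    resid_sd: float

    def linear_predictor(self, timepoint, centred_order, centred_looking) -> np.ndarray:
        tp = np.asarray(timepoint)
        bo = np.asarray(centred_order, dtype=float)
        lk = np.asarray(centred_looking, dtype=float)
        is2, is3 = (tp == "T2").astype(float), (tp == "T3").astype(float)
        return (
            self.intercept + self.t2 * is2 + self.t3 * is3
            + self.block_order * bo + self.looking * lk
            + self.t2_block * is2 * bo + self.t3_block * is3 * bo
        )


@dataclass(frozen=True)
class BehaviourLink:
    """Per-timepoint linear link from learning index to preference score."""

    slopes: Mapping[str, float]
    intercepts: Mapping[str, float]
    familiar_mean_s: float = 3.5  # mid-trial: keeps [0, 7] truncation mild
    trial_sd_s: float = 1.414  # -> preference-score sd ~ 1 s over 4+4 trials


@dataclass(frozen=True)
class CohortDesign:
    n_per_timepoint: tuple[int, int, int] = (30, 27, 23)
    invalid_block_probability: float = 0.236
    looking_ceiling_s: float = 20.0
    looking_exponential_scale_s: float = 3.0
    looking_minimum_s: float = 7.0
    invalid_looking_range_s: tuple[float, float] = (2.0, 6.9)


@dataclass(frozen=True)
class NoiseModel:
    """1/f amplitude envelope with a white floor, per channel."""

    exponent: float = 1.0
    scale: float = 1.0
    white_floor: float = 0.2
    fs: float = spectral.FS_HZ
    n_samples: int = spectral.N_SAMPLES
    n_channels: int = N_CHANNELS

    def envelope(self, freqs: np.ndarray) -> np.ndarray:
        """Expected noise amplitude-spectrum value at each frequency."""
        env = np.full_like(freqs, self.white_floor, dtype=float)
        pos = freqs > 0
        env[pos] += self.scale * freqs[pos] ** (-self.exponent)
        env[~pos] = 0.0
        return env


def _default_base() -> LmmEffects:
    return LmmEffects(  # fitted base-frequency (6 Hz + harmonics) model
        intercept=0.302, t2=0.100, t3=0.002, block_order=-0.024,
        looking=0.029, t2_block=0.001, t3_block=0.025,
        intercept_sd=math.sqrt(0.013), resid_sd=math.sqrt(0.043),
    )


def _default_doublet() -> LmmEffects:
    return LmmEffects(  # fitted doublet-frequency (3 Hz + harmonics) model
        intercept=0.152, t2=0.060, t3=0.083, block_order=-0.013,
        looking=0.018, t2_block=-0.006, t3_block=0.027,
        intercept_sd=math.sqrt(0.010), resid_sd=math.sqrt(0.042),
    )


def _default_behaviour() -> BehaviourLink:
    # simple slopes and per-timepoint intercepts of the preference ~
    # learning index x timepoint regression
    return BehaviourLink(
        slopes={"T1": -0.969, "T2": 1.672, "T3": 4.421},
        intercepts={"T1": -0.070, "T2": 0.692, "T3": 0.484},
    )


@dataclass(frozen=True)
class GenerativeParams:
    base: LmmEffects = field(default_factory=_default_base)
    doublet: LmmEffects = field(default_factory=_default_doublet)
    behaviour: BehaviourLink = field(default_factory=_default_behaviour)
    cohort: CohortDesign = field(default_factory=CohortDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def with_overrides(self, **kwargs) -> "GenerativeParams":
        return replace(self, **kwargs)


def channel_gain_map(
    plateau: tuple[int, ...] = OCCIPITAL_APRIORI,
    fringe: tuple[int, ...] = OCCIPITAL_FRINGE,
) -> np.ndarray:
    """Stylized occipital topography: unit plateau with raised-cosine fringe.

    Gain 1 on the a-priori medial occipital electrodes, cos^2(pi/4) = 0.5
    on the surrounding ring, 0 elsewhere.  Scaling the whole map leaves
    every measured SNR unchanged (SNR is an amplitude ratio), so only the
    shape matters.
    """
    gain = np.zeros(N_CHANNELS)
    gain[channel_indices(plateau)] = 1.0
    gain[channel_indices(fringe)] = math.cos(math.pi / 4.0) ** 2
    return gain


def rice_mean(a: float, sigma: float) -> float:
    """Mean of |a e^{i phi} + Z|, Z circular complex normal, component sd sigma."""
    if sigma < 0 or a < 0:
        raise InvalidInputError("amplitude and sigma must be non-negative")
    if sigma == 0:
        return a
    x = -(a * a) / (2.0 * sigma * sigma)
    t = -x / 2.0
    # Laguerre L_{1/2}(x) via exponentially scaled Bessel functions
    laguerre = math.exp(x / 2.0 + t) * ((1 - x) * special.ive(0, t) - x * special.ive(1, t))
    return sigma * _RAYLEIGH_MEAN * laguerre


def calibrate_amplitude(target_snr: float, noise_floor_amp: float, noise_sd: float) -> float:
    """Sinusoid amplitude whose expected tagged-bin amplitude hits a target SNR.

    Solves E|a e^{i phi} + Z| = target_snr * noise_floor_amp for a, with
    Z the complex spectral noise at the tagged bin (component sd
    `noise_sd`).  Relative tolerance 1e-6.
    """
    if target_snr < 1.0:
        raise InvalidInputError("target SNR must be >= 1 (noise alone attains 1)")
    if noise_floor_amp <= 0:
        raise InvalidInputError("noise floor amplitude must be positive")
    target_amp = target_snr * noise_floor_amp
    if noise_sd == 0:
        return target_amp
    if target_amp <= rice_mean(0.0, noise_sd):
        return 0.0
    hi = target_amp + 5.0 * noise_sd
    return float(
        optimize.brentq(
            lambda a: rice_mean(a, noise_sd) - target_amp, 0.0, hi,
            xtol=1e-12, rtol=1e-10,
        )
    )


@dataclass(frozen=True)
class EEGBlock:
    """One synthesized 20-s, 128-channel familiarization-block core."""

    data: np.ndarray
    fs: float
    subject_id: str
    timepoint: str
    raw_block_index: int
    looking_s: float


class BlockSNR:
    """Reduced per-block SNR container: values at the candidate harmonics.

    Quacks like an :class:`~freqtagsl.spectral.SNRSpectrum` for the
    aggregation and validation steps (`snr_at`), at a fraction of the
    memory.
    """

    def __init__(self, freqs: tuple[float, ...], values: np.ndarray):
        self._index = {float(f): i for i, f in enumerate(freqs)}
        self.values = values  # [channels x len(freqs)]

    def snr_at(self, freq_hz: float) -> np.ndarray:
        if float(freq_hz) not in self._index:
            raise InvalidInputError(f"no stored SNR at {freq_hz} Hz")
        return self.values[:, self._index[float(freq_hz)]]


def _signal_amplitudes(
    noise: NoiseModel, target_snr: float, gain: np.ndarray, freq: float
) -> np.ndarray:
    """Per-channel sinusoid amplitude so the expected measured SNR matches.

    The per-channel target is 1 + gain * (target_snr - 1).  The expected
    measured SNR is E[N] * E[1/D]; the second factor is expanded to
    second order in the noise of D (the mean of the 10 neighbour-bin
    amplitudes), giving the small correction (1 + CV^2(D)) applied here.
    """
    freqs = np.fft.rfftfreq(noise.n_samples, d=1.0 / noise.fs)
    spacing = freqs[1] - freqs[0]
    k = int(round(freq / spacing))
    neigh = np.array([k + o for o in spectral.NEIGHBOUR_OFFSETS])
    env_neigh = noise.envelope(freqs[neigh])
    floor = float(env_neigh.mean())                       # E[D]
    var_d = float((env_neigh**2).sum()) * _RAYLEIGH_CV2 / len(neigh) ** 2
    cv2 = var_d / floor**2
    sigma_bin = noise.envelope(np.array([freq]))[0] / _RAYLEIGH_MEAN

    amps = np.zeros_like(gain)
    for g in np.unique(gain):
        s_c = 1.0 + g * (target_snr - 1.0)
        target_amp = s_c * floor / (1.0 + cv2)
        if target_amp <= rice_mean(0.0, sigma_bin):
            a = 0.0  # sub-floor targets cannot be represented: zero signal
        else:
            hi = target_amp + 5.0 * sigma_bin
            a = float(optimize.brentq(
                lambda a: rice_mean(a, sigma_bin) - target_amp, 0.0, hi,
                xtol=1e-12, rtol=1e-10,
            ))
        amps[gain == g] = a
    return amps


def simulate_block_eeg(
    params: GenerativeParams,
    block_meta: Mapping,
    target_log_base_snr: float,
    target_log_doublet_snr: float,
    rng: np.random.Generator,
    gain: np.ndarray | None = None,
) -> EEGBlock:
    """Synthesize one block: tagged sinusoids on an occipital map + 1/f noise.

    The expected measured log SNR (ROI mean over plateau channels, then
    harmonic mean) matches the targets; per-block log targets below 0
    are floored at zero signal amplitude.
    """
    noise = params.noise
    gain = channel_gain_map() if gain is None else np.asarray(gain, dtype=float)
    if gain.max() > 0:
        gain = gain / gain.max()  # only the shape matters: SNR is a ratio
    n, fs = noise.n_samples, noise.fs
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    # noise: complex spectral coefficients with 1/f amplitude envelope
    sigma = noise.envelope(freqs) / _RAYLEIGH_MEAN
    coef = (n / 2.0) * sigma * (
        rng.standard_normal((noise.n_channels, freqs.size))
        + 1j * rng.standard_normal((noise.n_channels, freqs.size))
    )
    coef[:, 0] = 0.0

    # tagged sinusoids are exact at their bins (integer cycles in 20 s), so
    # a cosine of amplitude a and phase phi adds (N/2) a e^{i phi} to its bin
    spacing = freqs[1] - freqs[0]
    for harmonics, target_log in (
        (BASE_HARMONICS, target_log_base_snr),
        (DOUBLET_HARMONICS, target_log_doublet_snr),
    ):
        target_snr = math.exp(target_log)
        for f in harmonics:
            amps = _signal_amplitudes(noise, target_snr, gain, f)
            phases = rng.uniform(0.0, 2.0 * math.pi, noise.n_channels)
            k = int(round(f / spacing))
            coef[:, k] += (n / 2.0) * amps * np.exp(1j * phases)
    data = np.fft.irfft(coef, n=n, axis=1)

    return EEGBlock(
        data=data, fs=fs,
        subject_id=block_meta.get("subject_id", "S00"),
        timepoint=block_meta.get("timepoint", "T1"),
        raw_block_index=int(block_meta.get("raw_block_index", 1)),
        looking_s=float(block_meta.get("looking_s", 20.0)),
    )


def null_snr_topographies(
    n_subjects: int,
    n_blocks: int = 6,
    n_electrodes: int = N_CHANNELS,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Subject-mean SNR topographies under pure noise (no tagged signal).

    Each (subject, electrode, block) SNR is drawn as |Z0| / mean(|Z1..Z10|)
    with iid circular complex Gaussian spectral bins — the exact sampling
    distribution of the neighbour-ratio SNR on a locally flat noise
    spectrum — and averaged over `n_blocks` blocks per subject.  Note the
    mean of this null ratio is slightly above 1 (E[1/D] > 1/E[D]).
    """
    rng = np.random.default_rng() if rng is None else rng
    shape = (n_subjects, n_electrodes, n_blocks)
    num = np.abs(
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )
    den = np.abs(
        rng.standard_normal(shape + (10,)) + 1j * rng.standard_normal(shape + (10,))
    ).mean(axis=-1)
    return (num / den).mean(axis=-1)


@dataclass
class SyntheticCohort:
    """Long-format synthetic cohort: blocks, sessions, and test trials."""

    blocks: pd.DataFrame
    sessions: pd.DataFrame
    tests: pd.DataFrame
    params: GenerativeParams
    master_seed: int | None
    mode: str
    snr_features: dict | None = None  # (subject, timepoint, raw_idx) -> BlockSNR

    def block_pairs(self):
        """(BlockSNR, meta) pairs for the analysis chain (full mode only)."""
        if self.snr_features is None:
            raise InvalidInputError("no waveform-derived SNR features (fast mode)")
        for _, row in self.blocks.iterrows():
            key = (row.subject_id, row.timepoint, row.raw_block_index)
            meta = dict(
                subject_id=row.subject_id, timepoint=row.timepoint,
                raw_block_index=row.raw_block_index, looking_s=row.looking_s,
            )
            yield self.snr_features[key], meta


def _draw_core_looking(rng: np.random.Generator, design: CohortDesign) -> float:
    """Near-ceiling looking time on [minimum, ceiling] for a valid block."""
    while True:
        x = design.looking_ceiling_s - rng.exponential(design.looking_exponential_scale_s)
        if x >= design.looking_minimum_s:
            return float(x)


def _simulate_structure(
    params: GenerativeParams, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subjects, sessions, raw blocks, looking times and validity flags."""
    design = params.cohort
    n1, n2, n3 = design.n_per_timepoint
    subjects = [f"S{i + 1:02d}" for i in range(n1)]
    at_t2 = sorted(rng.choice(subjects, size=n2, replace=False))
    at_t3 = sorted(rng.choice(at_t2, size=n3, replace=False))
    roster = {"T1": subjects, "T2": at_t2, "T3": at_t3}

    block_rows, session_rows = [], []
    for tp in ("T1", "T2", "T3"):
        for sid in roster[tp]:
            per_block = []
            for k in range(1, 16):
                invalid = rng.random() < design.invalid_block_probability
                if invalid and rng.random() < 0.5:
                    looking = float(rng.uniform(*design.invalid_looking_range_s))
                    electro = True   # fails on looking alone
                else:
                    looking = _draw_core_looking(rng, design)
                    electro = not invalid
                per_block.append((k, looking, electro))
            # looking during fades assumed proportional to core looking
            ext_looking = [min(24.0, lk * 1.2) for _, lk, _ in per_block]
            plan = apply_stopping_rule(ext_looking)
            session_rows.append(
                dict(subject_id=sid, timepoint=tp,
                     n_blocks_shown=plan.n_blocks_shown,
                     cumulative_looking_s=plan.cumulative_looking_s,
                     reached_test=plan.reached_test)
            )
            for k, looking, electro in per_block[: plan.n_blocks_shown]:
                block_rows.append(
                    dict(subject_id=sid, timepoint=tp, raw_block_index=k,
                         looking_s=looking, electrophys_pass=electro)
                )
    return pd.DataFrame(block_rows), pd.DataFrame(session_rows)


def simulate_test_behaviour(
    params: GenerativeParams,
    subject_learning_index: float,
    timepoint: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Eight alternating test-trial looking times for one session.

    The expected preference score (novel minus familiar mean looking)
    equals slope(timepoint) * learning index + intercept(timepoint);
    trial times are truncated to [0, 7] s.
    """
    link = params.behaviour
    shift = (
        link.slopes[timepoint] * subject_learning_index + link.intercepts[timepoint]
    )
    rows = []
    for j in range(8):
        trial_type = "familiar" if j % 2 == 0 else "novel"
        mu = link.familiar_mean_s + (shift if trial_type == "novel" else 0.0)
        x = mu if link.trial_sd_s == 0 else rng.normal(mu, link.trial_sd_s)
        rows.append(
            dict(trial_index=j + 1, trial_type=trial_type,
                 looking_s=float(np.clip(x, 0.0, 7.0)))
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    params: GenerativeParams | None = None,
    master_seed: int | None = 0,
    mode: str = "fast",
) -> SyntheticCohort:
    """Simulate one longitudinal cohort.

    Outcomes for analysis-retained blocks are drawn from the generative
    LMMs with covariates centred exactly as the analysis will centre
    them, so the analysis chain recovers the generating fixed effects
    without centring mismatch.  Non-retained blocks carry placeholder
    outcomes near SNR = 1.  In full mode every block is additionally
    synthesized as a waveform and measured through the spectral chain
    into per-block SNR features at the candidate harmonics.
    """
    params = GenerativeParams() if params is None else params
    if mode not in ("fast", "full"):
        raise InvalidInputError("mode must be 'fast' or 'full'")
    ss = np.random.SeedSequence(master_seed)
    rng_struct, rng_out, rng_beh, rng_eeg = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    blocks, sessions = _simulate_structure(params, rng_struct)

    # analysis-equivalent filtering to obtain the centred covariates
    probe = blocks.copy()
    probe["log_base_snr"] = np.nan
    probe["log_doublet_snr"] = np.nan
    retained = blocks_mod.finalize_block_table(probe)

    subjects = sorted(blocks["subject_id"].unique())
    b_base = dict(zip(subjects, rng_out.normal(0.0, params.base.intercept_sd, len(subjects))))
    b_doub = dict(zip(subjects, rng_out.normal(0.0, params.doublet.intercept_sd, len(subjects))))

    mu_base = params.base.linear_predictor(
        retained["timepoint"], retained["centred_order"], retained["centred_looking"]
    )
    mu_doub = params.doublet.linear_predictor(
        retained["timepoint"], retained["centred_order"], retained["centred_looking"]
    )
    ranef_b = retained["subject_id"].map(b_base).to_numpy()
    ranef_d = retained["subject_id"].map(b_doub).to_numpy()
    y_base = mu_base + ranef_b + rng_out.normal(0.0, params.base.resid_sd, len(retained))
    y_doub = mu_doub + ranef_d + rng_out.normal(0.0, params.doublet.resid_sd, len(retained))

    key_cols = ["subject_id", "timepoint", "raw_block_index"]
    outcome = retained[key_cols].copy()
    outcome["log_base_snr"] = np.asarray(y_base)
    outcome["log_doublet_snr"] = np.asarray(y_doub)
    blocks = blocks.merge(outcome, on=key_cols, how="left")
    # placeholder outcomes near SNR = 1 for blocks outside the analysis set
    miss = blocks["log_base_snr"].isna()
    blocks.loc[miss, "log_base_snr"] = rng_out.normal(0.0, 0.1, int(miss.sum()))
    blocks.loc[miss, "log_doublet_snr"] = rng_out.normal(0.0, 0.1, int(miss.sum()))

    # test-phase behaviour driven by the subject's mean learning index
    li_map = (
        (outcome["log_doublet_snr"] - outcome["log_base_snr"])
        .groupby([outcome["subject_id"], outcome["timepoint"]]).mean()
    )
    test_rows = []
    for _, sess in sessions.iterrows():
        key = (sess.subject_id, sess.timepoint)
        if not sess.reached_test or key not in li_map.index:
            continue
        trials = simulate_test_behaviour(params, float(li_map[key]), sess.timepoint, rng_beh)
        trials.insert(0, "timepoint", sess.timepoint)
        trials.insert(0, "subject_id", sess.subject_id)
        test_rows.append(trials)
    tests = (
        pd.concat(test_rows, ignore_index=True)
        if test_rows
        else pd.DataFrame(columns=["subject_id", "timepoint", "trial_index", "trial_type", "looking_s"])
    )

    snr_features = None
    if mode == "full":
        snr_features = {}
        gain = channel_gain_map()
        child_seeds = ss.spawn(len(blocks))
        for (idx, row), seed in zip(blocks.iterrows(), child_seeds):
            rng_blk = np.random.default_rng(seed)
            if row.electrophys_pass:
                tb, td = row.log_base_snr, row.log_doublet_snr
            else:
                tb, td = 0.0, 0.0  # suppressed tagged response
            eeg = simulate_block_eeg(
                params, row.to_dict(), max(tb, 0.0), max(td, 0.0), rng_blk, gain=gain
            )
            snr = spectral.snr_spectrum(spectral.amplitude_spectrum(eeg))
            vals = np.column_stack([snr.snr_at(f) for f in CANDIDATE_FREQS])
            if not row.electrophys_pass:
                # enforce the suppressed 6-Hz response on the a-priori set
                occ = channel_indices(OCCIPITAL_APRIORI)
                col6 = CANDIDATE_FREQS.index(6.0)
                vals[occ, col6] = np.minimum(vals[occ, col6], 1.5)
            key = (row.subject_id, row.timepoint, row.raw_block_index)
            snr_features[key] = BlockSNR(CANDIDATE_FREQS, vals)

    return SyntheticCohort(
        blocks=blocks, sessions=sessions, tests=tests, params=params,
        master_seed=master_seed, mode=mode, snr_features=snr_features,
    )
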
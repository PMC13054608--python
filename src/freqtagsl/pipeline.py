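"""End-to-end orchestration: simulate -> spectra -> validate -> harmonics
-> ROI -> aggregate -> models -> behaviour, as one seeded, logged run.

All analysis constants default to the protocol's values (SNR criterion
2, looking criterion 7 s, alpha 0.05, 10 000 permutations, candidate
range 3-24 Hz, truncation at 8 valid blocks, minimum 2 valid blocks,
120-s familiarization criterion, 8-15 blocks); every default is
overridable through :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour as behaviour_mod
from . import blocks as blocks_mod
from . import harmonics as harmonics_mod
from . import models as models_mod
from . import roi as roi_mod
from . import synth
from .channels import OCCIPITAL_APRIORI
from .paradigm import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    master_seed: int = 0
    mode: str = "fast"                  # "fast" | "full"
    snr_criterion: float = 2.0
    looking_criterion_s: float = 7.0
    alpha: float = 0.05
    n_perm: int = 10_000
    candidate_freqs: tuple[float, ...] = synth.CANDIDATE_FREQS
    roi_min_timepoints: int = 2
    max_valid_order: int = 8
    min_valid_blocks: int = 2
    familiarization_criterion_s: float = 120.0
    min_blocks: int = 8
    max_blocks: int = 15
    out_dir: str | None = None
    generative: synth.GenerativeParams = field(default_factory=synth.GenerativeParams)

    def validate(self) -> None:
        if self.mode not in ("fast", "full"):
            raise InvalidInputError(f"unknown mode {self.mode!r}")
        if self.n_perm < 1:
            raise InvalidInputError("n_perm must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError("alpha must lie in (0, 1)")
        if self.min_blocks > self.max_blocks:
            raise InvalidInputError("min_blocks cannot exceed max_blocks")


@dataclass
class RunArtifacts:
    config: RunConfig
    cohort: synth.SyntheticCohort
    block_table: pd.DataFrame
    harmonic_selection: harmonics_mod.HarmonicSelection | None
    roi_electrodes: tuple[int, ...]
    roi_reports: dict
    model_fits: dict
    behaviour_tests: pd.DataFrame
    manifest: dict


def _subject_mean_snr(cohort, block_table, freqs, channels=None):
    """Per-subject mean SNR over retained blocks, per timepoint.

    Returns {timepoint: DataFrame [subjects x freqs]} averaged over the
    given channels (a-priori occipital by default) or, with
    channels=None... the caller decides; used by harmonic selection and
    topographies.
    """
    from .channels import channel_indices

    idx = channel_indices(channels if channels is not None else OCCIPITAL_APRIORI)
    out: dict[str, pd.DataFrame] = {}
    keys = set(
        map(tuple, block_table[["subject_id", "timepoint", "raw_block_index"]].to_numpy())
    )
    for tp in sorted(block_table["timepoint"].unique()):
        rows: dict[str, dict] = {}
        for snr, meta in cohort.block_pairs():
            if meta["timepoint"] != tp:
                continue
            if (meta["subject_id"], meta["timepoint"], meta["raw_block_index"]) not in keys:
                continue
            acc = rows.setdefault(meta["subject_id"], {f: [] for f in freqs})
            for f in freqs:
                acc[f].append(np.asarray(snr.snr_at(f))[idx].mean())
        out[tp] = pd.DataFrame(
            {f: {s: float(np.mean(v[f])) for s, v in rows.items()} for f in freqs}
        )
    return out


def _subject_topographies(cohort, block_table, freq):
    """{timepoint: [subjects x 128] array} of subject-mean whole-scalp SNR."""
    keys = set(
        map(tuple, block_table[["subject_id", "timepoint", "raw_block_index"]].to_numpy())
    )
    out = {}
    for tp in sorted(block_table["timepoint"].unique()):
        per_subject: dict[str, list] = {}
        for snr, meta in cohort.block_pairs():
            if meta["timepoint"] != tp:
                continue
            if (meta["subject_id"], meta["timepoint"], meta["raw_block_index"]) not in keys:
                continue
            per_subject.setdefault(meta["subject_id"], []).append(np.asarray(snr.snr_at(freq)))
        out[tp] = np.vstack([np.mean(v, axis=0) for _, v in sorted(per_subject.items())])
    return out


def run_pipeline(config: RunConfig | None = None) -> RunArtifacts:
    """Run the full analysis chain on one simulated cohort.

    Deterministic given the master seed; stage seeds are split from it
    with ``numpy.random.SeedSequence``.  In fast mode the harmonic- and
    ROI-derivation stages are skipped (there are no waveforms) and the
    protocol's a-priori occipital set with the canonical harmonic sets
    is used for aggregation.
    """
    config = RunConfig() if config is None else config
    config.validate()
    ss = np.random.SeedSequence(config.master_seed)
    seed_cohort, seed_perm = ss.spawn(2)

    logger.info("simulating cohort (mode=%s, seed=%s)", config.mode, config.master_seed)
    cohort = synth.simulate_cohort(
        params=config.generative, master_seed=config.master_seed, mode=config.mode
    )
    n_sessions = len(cohort.sessions)

    harmonic_selection = None
    roi_reports: dict = {}
    if config.mode == "full":
        # provisional block table with a-priori ROI/harmonics to define the
        # valid-block set used by harmonic selection and topographies
        provisional = blocks_mod.build_block_table(
            cohort.block_pairs(), OCCIPITAL_APRIORI,
            synth.BASE_HARMONICS, synth.DOUBLET_HARMONICS,
            snr_criterion=config.snr_criterion,
            looking_criterion_s=config.looking_criterion_s,
            min_valid_blocks=config.min_valid_blocks,
            max_valid_order=config.max_valid_order,
        )
        snr_tables = _subject_mean_snr(cohort, provisional, config.candidate_freqs)
        harmonic_selection = harmonics_mod.select_harmonics(snr_tables, alpha=config.alpha)
        base_set = harmonic_selection.base_set or synth.BASE_HARMONICS
        doublet_set = harmonic_selection.doublet_set or synth.DOUBLET_HARMONICS

        rng_perm = np.random.default_rng(seed_perm)
        significance = {}
        for f in (3.0, 6.0):
            for tp, topo in _subject_topographies(cohort, provisional, f).items():
                res = roi_mod.max_stat_threshold(
                    topo, n_perm=config.n_perm, alpha=config.alpha, rng=rng_perm
                )
                significance[(tp, f)] = res.significant_electrodes
                roi_reports[f"{tp}_{f:g}Hz"] = res.report()
        roi_electrodes = roi_mod.derive_roi(
            significance, min_timepoints=config.roi_min_timepoints
        )
        block_table = blocks_mod.build_block_table(
            cohort.block_pairs(), roi_electrodes, base_set, doublet_set,
            snr_criterion=config.snr_criterion,
            looking_criterion_s=config.looking_criterion_s,
            min_valid_blocks=config.min_valid_blocks,
            max_valid_order=config.max_valid_order,
        )
    else:
        roi_electrodes = OCCIPITAL_APRIORI
        block_table = blocks_mod.finalize_block_table(
            cohort.blocks,
            min_valid_blocks=config.min_valid_blocks,
            max_valid_order=config.max_valid_order,
            looking_criterion_s=config.looking_criterion_s,
        )

    model_fits = {
        "base_snr": models_mod.fit_lmm(models_mod.BASE_SNR_MODEL, block_table),
        "doublet_snr": models_mod.fit_lmm(models_mod.DOUBLET_SNR_MODEL, block_table),
        "learning_index": models_mod.fit_lmm(models_mod.LEARNING_INDEX_MODEL, block_table),
    }

    behaviour_tests = pd.DataFrame()
    if not cohort.tests.empty:
        scores = {}
        pref_rows = []
        for (sid, tp), trials in cohort.tests.groupby(["subject_id", "timepoint"]):
            ps = behaviour_mod.preference_from_trials(trials)
            scores.setdefault(tp, []).append(ps.score)
            pref_rows.append(dict(subject_id=sid, timepoint=tp, preference_score=ps.score))
        behaviour_tests = behaviour_mod.timepoint_tests(scores)
        pref = pd.DataFrame(pref_rows)
        li = (
            block_table.groupby(["subject_id", "timepoint"])["learning_index"]
            .mean().rename("learning_index").reset_index()
        )
        pref = pref.merge(li, on=["subject_id", "timepoint"], how="inner")
        if len(pref) >= 10:
            fit = models_mod.fit_lmm(models_mod.PREFERENCE_LI_MODEL, pref)
            model_fits["preference_learning"] = fit
            if any(f"learning_index:{tp}" in fit.params.index for tp in ("T2", "T3")):
                model_fits["simple_slopes"] = models_mod.simple_slopes(fit)

    report = block_table.attrs.get("filter_report", {})
    manifest = {
        "master_seed": config.master_seed,
        "mode": config.mode,
        "config": dataclasses.asdict(config),
        "n_sessions": int(n_sessions),
        "blocks": report,
        "roi_electrodes": [int(e) for e in roi_electrodes],
    }
    logger.info(
        "pipeline done: %s sessions, %s blocks recorded, %s retained",
        n_sessions, report.get("n_recorded"), report.get("n_retained"),
    )
    return RunArtifacts(
        config=config, cohort=cohort, block_table=block_table,
        harmonic_selection=harmonic_selection, roi_electrodes=tuple(roi_electrodes),
        roi_reports=roi_reports, model_fits=model_fits,
        behaviour_tests=behaviour_tests, manifest=manifest,
    )


def write_artifacts(artifacts: RunArtifacts, out_dir: str | Path) -> None:
    """Write CSV/JSON run outputs (byte-stable for a fixed seed)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    artifacts.block_table.to_csv(out / "block_table.csv", index=False)
    artifacts.cohort.blocks.to_csv(out / "cohort_blocks.csv", index=False)
    artifacts.cohort.sessions.to_csv(out / "cohort_sessions.csv", index=False)
    artifacts.cohort.tests.to_csv(out / "cohort_tests.csv", index=False)

    def dump(name: str, obj) -> None:
        (out / name).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")

    dump("manifest.json", artifacts.manifest)
    if artifacts.harmonic_selection is not None:
        dump("harmonics_report.json", artifacts.harmonic_selection.report())
    if artifacts.roi_reports:
        dump("roi_report.json", artifacts.roi_reports)
    dump(
        "models_report.json",
        {
            name: (fit.report() if isinstance(fit, models_mod.ModelFit)
                   else fit.to_dict(orient="records"))
            for name, fit in artifacts.model_fits.items()
        },
    )
    if not artifacts.behaviour_tests.empty:
        dump("behaviour_report.json", artifacts.behaviour_tests.to_dict(orient="records"))
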
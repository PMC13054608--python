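"""Test-phase looking times, preference scores, and per-timepoint tests.

Looking is coded at 100-ms resolution over each 7-s test trial.  The
preference score is mean looking at novel trials minus mean looking at
familiar trials (positive = novelty preference).  Per-timepoint
one-sample t-tests against zero are Holm-Bonferroni corrected across the
three timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .paradigm import InvalidInputError

logger = logging.getLogger(__name__)

SAMPLE_PERIOD_S = 0.1
TRIAL_DURATION_S = 7.0
MAX_SAMPLES = int(TRIAL_DURATION_S / SAMPLE_PERIOD_S)


@dataclass(frozen=True)
class PreferenceScore:
    score: float
    mean_novel: float
    mean_familiar: float


def trial_looking_time(timeline: Sequence[bool] | np.ndarray) -> float:
    """Total looking time (s) from a boolean 100-ms looking timeline."""
    t = np.asarray(timeline, dtype=bool)
    if t.size > MAX_SAMPLES:
        raise InvalidInputError(f"timeline longer than {MAX_SAMPLES} samples (7 s)")
    return float(SAMPLE_PERIOD_S * t.sum())


def preference_score(
    novel: Sequence[float], familiar: Sequence[float]
) -> PreferenceScore:
    """Preference score from per-trial looking times (seconds)."""
    novel = np.asarray(novel, dtype=float)
    familiar = np.asarray(familiar, dtype=float)
    if novel.size == 0 or familiar.size == 0:
        raise InvalidInputError("need at least one trial of each type")
    return PreferenceScore(
        score=float(novel.mean() - familiar.mean()),
        mean_novel=float(novel.mean()),
        mean_familiar=float(familiar.mean()),
    )


def preference_from_trials(trials: pd.DataFrame) -> PreferenceScore:
    """Preference score from a trial table with trial_type and looking_s."""
    novel = trials.loc[trials["trial_type"] == "novel", "looking_s"]
    familiar = trials.loc[trials["trial_type"] == "familiar", "looking_s"]
    return preference_score(novel.to_numpy(), familiar.to_numpy())


def timepoint_tests(
    scores_by_timepoint: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Two-sided one-sample t-tests of preference scores against zero.

    Returns one row per timepoint with mean, SE, t, df, 95% CI, raw p,
    and Holm-adjusted p (family = the tested timepoints, adjusted p
    capped at 1).  Timepoints with < 2 scores are skipped with a warning.
    """
    rows = []
    for tp, scores in scores_by_timepoint.items():
        x = np.asarray(scores, dtype=float)
        if x.size < 2:
            logger.warning("timepoint %s skipped: fewer than 2 scores", tp)
            continue
        res = stats.ttest_1samp(x, 0.0)
        se = x.std(ddof=1) / np.sqrt(x.size)
        lo, hi = res.confidence_interval(0.95)
        rows.append(
            dict(
                timepoint=tp, n=int(x.size), mean=float(x.mean()), se=float(se),
                t=float(res.statistic), df=int(x.size - 1),
                ci_low=float(lo), ci_high=float(hi), p=float(res.pvalue),
            )
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out
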
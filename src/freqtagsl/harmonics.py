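"""Harmonic selection via one-sample Wilcoxon tests against SNR = 1.

Candidate frequencies are the multiples of 3 Hz in [3, 24].  A frequency
is retained when the one-sided Wilcoxon signed-rank test of per-subject
mean SNR > 1 is significant; retained frequencies are partitioned into
base harmonics (multiples of 6 Hz) and doublet harmonics (multiples of
3 Hz that are not multiples of 6), so doublet quantification never
includes frequencies shared with the base response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import InvalidInputError

logger = logging.getLogger(__name__)

CANDIDATE_FREQS = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0)
#: exact signed-rank null up to this many subjects, normal approximation
#: with continuity correction above
EXACT_N_MAX = 25


@dataclass(frozen=True)
class HarmonicSelection:
    base_set: tuple[float, ...]
    doublet_set: tuple[float, ...]
    pvalues: pd.DataFrame  # index: frequency, columns: timepoint (or "all")
    alpha: float = 0.05
    candidate_range: tuple[float, float] = (3.0, 24.0)

    def report(self) -> dict:
        return {
            "candidate_range_hz": list(self.candidate_range),
            "alpha": self.alpha,
            "p_values": {
                str(tp): {f"{f:g}": float(p) for f, p in self.pvalues[tp].items()}
                for tp in self.pvalues.columns
            },
            "base_set_hz": [float(f) for f in self.base_set],
            "doublet_set_hz": [float(f) for f in self.doublet_set],
        }


def wilcoxon_greater_than_one(values: np.ndarray) -> float:
    """One-sided signed-rank p-value for median(SNR) > 1.

    Uses the exact null for n <= 25 and the normal approximation with
    continuity correction above.  A degenerate all-tied sample (every
    difference exactly zero) carries no evidence and returns p = 1.
    """
    diffs = np.asarray(values, dtype=float) - 1.0
    nonzero = diffs[diffs != 0.0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if diffs.size <= EXACT_N_MAX and nonzero.size == diffs.size else "approx"
    if method == "exact":
        try:
            res = stats.wilcoxon(diffs, alternative="greater", method="exact")
        except ValueError:  # ties: fall back to the approximate null
            res = stats.wilcoxon(diffs, alternative="greater", method="approx", correction=True)
    else:
        res = stats.wilcoxon(diffs, alternative="greater", method="approx", correction=True)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def select_harmonics(
    per_subject_mean_snr: pd.DataFrame | Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    joint: bool = True,
) -> HarmonicSelection:
    """Select base and doublet harmonics from per-subject mean SNR.

    `per_subject_mean_snr` is a [subjects x frequencies] table (columns
    are frequencies in Hz) or a mapping timepoint -> such a table.  With
    `joint=True` (default) a frequency must be significant at every
    timepoint; otherwise selection is per-timepoint and a frequency is
    retained when significant at any timepoint.

    The per-subject mean is intended to be taken over the subject's
    valid blocks and the ten a-priori occipital electrodes.
    """
    if isinstance(per_subject_mean_snr, pd.DataFrame):
        tables: dict[str, pd.DataFrame] = {"all": per_subject_mean_snr}
    else:
        tables = dict(per_subject_mean_snr)
    if not tables:
        raise InvalidInputError("no SNR tables given")

    freqs = sorted(float(f) for f in next(iter(tables.values())).columns)
    for f in freqs:
        if not np.isclose(f / 3.0, round(f / 3.0)) or not (3.0 <= f <= 24.0):
            raise InvalidInputError(f"candidate frequency {f} Hz not a multiple of 3 in [3, 24]")

    pvals = pd.DataFrame(index=freqs, columns=list(tables), dtype=float)
    for tp, table in tables.items():
        if len(table) < 6:
            raise InvalidInputError("need at least 6 subjects for the signed-rank test")
        for f in freqs:
            pvals.loc[f, tp] = wilcoxon_greater_than_one(table[f].to_numpy())

    sig = (pvals < alpha).all(axis=1) if joint else (pvals < alpha).any(axis=1)
    retained = [f for f in freqs if sig[f]]
    base = tuple(f for f in retained if np.isclose(f % 6.0, 0.0))
    doublet = tuple(f for f in retained if not np.isclose(f % 6.0, 0.0))
    logger.info("harmonic selection: base=%s doublet=%s", base, doublet)
    return HarmonicSelection(
        base_set=base, doublet_set=doublet, pvalues=pvals, alpha=alpha,
        candidate_range=(min(freqs), max(freqs)),
    )
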
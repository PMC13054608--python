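"""Permutation maximum-statistics thresholding of SNR topographies.

The family-wise threshold for "SNR > 1 somewhere on the scalp" is the
95th percentile of the permutation distribution of the maximum
group-averaged SNR across electrodes, where each permutation replaces
each subject's whole-scalp topography with a unit topography with
probability 0.5.  Electrodes whose observed group mean exceeds the
threshold are significant; the ROI is derived from electrodes
significant at both the doublet (3 Hz) and base (6 Hz) frequencies in at
least two of the three timepoints.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .channels import channel_labels
from .paradigm import InvalidInputError

logger = logging.getLogger(__name__)

N_PERMUTATIONS = 10_000
ALPHA = 0.05


class EmptyROIError(ValueError):
    """Raised when the ROI derivation rule selects no electrode."""


@dataclass(frozen=True)
class MaxStatResult:
    null_max: np.ndarray
    threshold: float
    significant_electrodes: tuple[int, ...]  # 1-based labels
    alpha: float
    n_perm: int
    group_mean: np.ndarray

    def report(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "threshold": float(self.threshold),
            "significant_electrodes": list(self.significant_electrodes),
            "quantile_convention": "linear interpolation between order statistics",
        }


def max_stat_threshold(
    topographies: np.ndarray,
    n_perm: int = N_PERMUTATIONS,
    alpha: float = ALPHA,
    rng: np.random.Generator | None = None,
) -> MaxStatResult:
    """Maximum-statistic permutation threshold for one frequency/timepoint.

    `topographies` is [subjects x electrodes] of subject-mean SNR.  For
    each permutation every subject's topography is independently replaced
    by an all-ones topography with probability 0.5; the maximum of the
    resulting group-averaged topography is recorded, and the threshold is
    the (1 - alpha) empirical quantile of the n_perm maxima.  Electrodes
    whose observed group mean strictly exceeds the threshold are
    significant.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must lie in (0, 1)")
    topo = np.asarray(topographies, dtype=float)
    if topo.ndim != 2 or topo.shape[0] < 2:
        raise InvalidInputError("need a [subjects x electrodes] array with >= 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} gives a coarse permutation null", stacklevel=2)
    rng = np.random.default_rng() if rng is None else rng

    n_subj = topo.shape[0]
    keep = rng.random((n_perm, n_subj)) < 0.5  # True: subject keeps real topography
    # group mean per permutation: kept subjects contribute their row, the
    # replaced ones contribute 1 at every electrode
    perm_means = (keep.astype(float) @ topo + (~keep).sum(axis=1)[:, None]) / n_subj
    null_max = perm_means.max(axis=1)
    threshold = float(np.quantile(null_max, 1.0 - alpha))

    group_mean = topo.mean(axis=0)
    sig = channel_labels(np.flatnonzero(group_mean > threshold))
    return MaxStatResult(
        null_max=null_max, threshold=threshold, significant_electrodes=sig,
        alpha=alpha, n_perm=n_perm, group_mean=group_mean,
    )


def derive_roi(
    significance: Mapping[tuple[str, float], Sequence[int]],
    frequencies: tuple[float, float] = (3.0, 6.0),
    min_timepoints: int = 2,
) -> tuple[int, ...]:
    """Conjunction ROI rule over the significance map.

    An electrode enters the ROI when it is significant at BOTH
    frequencies (doublet and base) in at least `min_timepoints`
    timepoints.  Raises :class:`EmptyROIError` when nothing qualifies.
    """
    lo, hi = frequencies
    timepoints = sorted({tp for tp, _ in significance})
    needed = {(tp, f) for tp in timepoints for f in frequencies}
    missing = needed - set(significance)
    if len(timepoints) < min_timepoints or missing:
        raise InvalidInputError(
            f"significance map must cover {lo:g} and {hi:g} Hz at >= {min_timepoints} timepoints"
        )
    counts: dict[int, int] = {}
    for tp in timepoints:
        both = set(significance[(tp, lo)]) & set(significance[(tp, hi)])
        for e in both:
            counts[e] = counts.get(e, 0) + 1
    roi = tuple(sorted(e for e, c in counts.items() if c >= min_timepoints))
    if not roi:
        raise EmptyROIError("no electrode significant at both frequencies in enough timepoints")
    logger.info("derived ROI: %s", roi)
    return roi
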
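"""ROI/harmonic aggregation of SNR and the learning index.

The per-block base (doublet) SNR is the SNR averaged first across ROI
electrodes at each selected harmonic, then across harmonics.  The
learning index is the difference of the natural logs of the combined
doublet- and base-frequency SNR, i.e. the log of their ratio: it
captures the relative dominance of structure-related entrainment over
stimulus-driven entrainment and is invariant to overall signal scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .channels import channel_indices
from .paradigm import InvalidInputError


@dataclass(frozen=True)
class CombinedSNR:
    base_snr: float
    doublet_snr: float

    @property
    def log_base_snr(self) -> float:
        return math.log(self.base_snr)

    @property
    def log_doublet_snr(self) -> float:
        return math.log(self.doublet_snr)


@dataclass(frozen=True)
class LearningIndexValue:
    li: float


def combined_snr(snr, roi: Iterable[int], harmonic_set: Iterable[float]) -> float:
    """Mean SNR over ROI electrodes, then over selected harmonics.

    `snr` is anything with `snr_at(freq_hz) -> per-channel vector`
    (an :class:`~freqtagsl.spectral.SNRSpectrum` or a reduced per-harmonic
    container); `roi` holds 1-based electrode labels.
    """
    roi = list(roi)
    harmonics = list(harmonic_set)
    if not roi or not harmonics:
        raise InvalidInputError("ROI and harmonic set must be non-empty")
    idx = channel_indices(roi)
    per_harmonic = []
    for f in harmonics:
        vals = np.asarray(snr.snr_at(f), dtype=float)[idx]
        if np.any(~np.isfinite(vals)):
            raise InvalidInputError(f"undefined SNR at {f} Hz in the ROI")
        per_harmonic.append(vals.mean())
    return float(np.mean(per_harmonic))


def learning_index(base_snr: float, doublet_snr: float) -> LearningIndexValue:
    """Learning index: ln(doublet SNR) - ln(base SNR)."""
    if base_snr <= 0 or doublet_snr <= 0:
        raise InvalidInputError("SNR values must be strictly positive")
    return LearningIndexValue(li=math.log(doublet_snr) - math.log(base_snr))
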
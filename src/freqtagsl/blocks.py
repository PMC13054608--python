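"""Valid-block filtering and construction of the block-level analysis table.

A familiarization block is valid if (a) the 6-Hz SNR exceeds 2 in at
least one of the ten a-priori occipital electrodes and (b) the infant
looked for at least 7 s of the 20-s core.  Participants contribute a
timepoint only with >= 2 valid blocks; valid blocks are renumbered by
relative position, truncated at 8, and block order and looking time are
grand-mean centred over the retained rows (one dataset-wide mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import combined_snr
from .channels import OCCIPITAL_APRIORI, channel_indices
from .paradigm import InvalidInputError

logger = logging.getLogger(__name__)

SNR_CRITERION = 2.0
LOOKING_CRITERION_S = 7.0
MIN_VALID_BLOCKS = 2
MAX_VALID_ORDER = 8

#: columns of the tidy block-feature table
FEATURE_COLUMNS = [
    "subject_id", "timepoint", "raw_block_index", "valid_order",
    "centred_order", "looking_s", "centred_looking",
    "log_base_snr", "log_doublet_snr", "learning_index",
]


@dataclass(frozen=True)
class BlockValidity:
    electrophys_pass: bool
    looking_pass: bool

    @property
    def valid(self) -> bool:
        return self.electrophys_pass and self.looking_pass


def validate_block(
    snr,
    looking_s: float,
    channels: Sequence[int] = OCCIPITAL_APRIORI,
    snr_criterion: float = SNR_CRITERION,
    looking_criterion_s: float = LOOKING_CRITERION_S,
) -> BlockValidity:
    """Two-criterion block validation (electrophysiological + behavioural)."""
    vals = np.asarray(snr.snr_at(6.0), dtype=float)[channel_indices(channels)]
    electro = bool(np.any(vals > snr_criterion))
    return BlockValidity(electrophys_pass=electro, looking_pass=looking_s >= looking_criterion_s)


def build_block_table(
    blocks: Iterable[tuple[object, Mapping]],
    roi: Sequence[int],
    base_harmonics: Sequence[float],
    doublet_harmonics: Sequence[float],
    snr_criterion: float = SNR_CRITERION,
    looking_criterion_s: float = LOOKING_CRITERION_S,
    min_valid_blocks: int = MIN_VALID_BLOCKS,
    max_valid_order: int = MAX_VALID_ORDER,
) -> pd.DataFrame:
    """Analysis table from per-block SNR containers.

    `blocks` yields (snr, meta) where `snr` provides `snr_at(freq)` and
    `meta` has keys subject_id, timepoint, raw_block_index, looking_s.
    Returns one row per retained block with centred covariates; centring
    constants and filter counts live in ``df.attrs``.
    """
    if not list(roi) or not list(base_harmonics) or not list(doublet_harmonics):
        raise InvalidInputError("ROI and harmonic sets must be non-empty")
    rows = []
    for snr, meta in blocks:
        validity = validate_block(
            snr, meta["looking_s"],
            snr_criterion=snr_criterion, looking_criterion_s=looking_criterion_s,
        )
        row = dict(
            subject_id=meta["subject_id"],
            timepoint=meta["timepoint"],
            raw_block_index=meta["raw_block_index"],
            looking_s=float(meta["looking_s"]),
            electrophys_pass=validity.electrophys_pass,
            looking_pass=validity.looking_pass,
        )
        if validity.valid:
            base = combined_snr(snr, roi, base_harmonics)
            doublet = combined_snr(snr, roi, doublet_harmonics)
            row.update(log_base_snr=np.log(base), log_doublet_snr=np.log(doublet))
        rows.append(row)
    return finalize_block_table(
        pd.DataFrame(rows),
        min_valid_blocks=min_valid_blocks,
        max_valid_order=max_valid_order,
        looking_criterion_s=looking_criterion_s,
    )


def finalize_block_table(
    records: pd.DataFrame,
    min_valid_blocks: int = MIN_VALID_BLOCKS,
    max_valid_order: int = MAX_VALID_ORDER,
    looking_criterion_s: float = LOOKING_CRITERION_S,
) -> pd.DataFrame:
    """Filter, renumber, truncate and centre per-block records.

    `records` needs columns subject_id, timepoint, raw_block_index,
    looking_s, electrophys_pass, log_base_snr, log_doublet_snr (an
    optional boolean `looking_pass` overrides the looking criterion).
    This is also the entry point for fast-mode synthetic cohorts, whose
    generator emits these columns directly.
    """
    df = records.copy()
    if "looking_pass" not in df:
        df["looking_pass"] = df["looking_s"] >= looking_criterion_s
    df["valid"] = df["electrophys_pass"] & df["looking_pass"]

    report = {
        "n_recorded": int(len(df)),
        "n_electrophys_fail": int((~df["electrophys_pass"]).sum()),
        "n_looking_fail": int((~df["looking_pass"]).sum()),
        "n_valid": int(df["valid"].sum()),
        "per_timepoint": {
            str(tp): {
                "n_recorded": int(len(g)),
                "n_electrophys_fail": int((~g["electrophys_pass"]).sum()),
                "n_looking_fail": int((~g["looking_pass"]).sum()),
                "n_valid": int(g["valid"].sum()),
            }
            for tp, g in df.groupby("timepoint")
        },
    }

    valid = df[df["valid"]].copy()
    valid = valid.sort_values(["subject_id", "timepoint", "raw_block_index"])
    counts = valid.groupby(["subject_id", "timepoint"])["raw_block_index"].transform("size")
    valid = valid[counts >= min_valid_blocks].copy()
    valid["valid_order"] = (
        valid.groupby(["subject_id", "timepoint"]).cumcount() + 1
    )
    valid = valid[valid["valid_order"] <= max_valid_order].copy()

    if valid.empty:
        logger.warning("no blocks retained after filtering")
        out = pd.DataFrame(columns=FEATURE_COLUMNS)
        out.attrs["filter_report"] = report
        return out

    order_mean = float(valid["valid_order"].mean())
    looking_mean = float(valid["looking_s"].mean())
    valid["centred_order"] = valid["valid_order"] - order_mean
    valid["centred_looking"] = valid["looking_s"] - looking_mean
    valid["learning_index"] = valid["log_doublet_snr"] - valid["log_base_snr"]

    out = valid[FEATURE_COLUMNS].reset_index(drop=True)
    report["n_retained"] = int(len(out))
    out.attrs["grand_mean_order"] = order_mean
    out.attrs["grand_mean_looking"] = looking_mean
    out.attrs["filter_report"] = report
    return out
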
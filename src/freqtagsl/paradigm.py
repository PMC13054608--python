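"""Stimulus protocol: doublet assignment, pseudo-random streams, test schedules.

The familiarization stream presents 8 shapes at 6 Hz, organised in 4
deterministic doublets (leading shape always followed by its trailing
shape), so the transitional probability (TP) is 1 within doublets and
1/3 between doublets.  A 20-s analysed core (120 shapes) is flanked by
2-s fades, giving 144 shapes per 24-s extended block.  The test phase
alternates familiar and novel doublets, 42 shapes per 7-s trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

#: shapes per second during familiarization and test
PRESENTATION_RATE_HZ = 6.0
#: shapes per extended 24-s familiarization block (2-s fades included)
FAMILIARIZATION_LENGTH = 144
#: shapes in the triggered 20-s core
CORE_LENGTH = 120
#: 0-based slice [start, stop) of the core within the 144-item stream
CORE_START, CORE_STOP = 12, 132
#: shapes per 7-s test trial (1-s fades included)
TEST_TRIAL_LENGTH = 42
#: familiarization session bounds and cumulative looking criterion
MIN_BLOCKS, MAX_BLOCKS, LOOKING_CRITERION_S = 8, 15, 120.0
#: extended block duration, upper bound on per-block looking
EXTENDED_BLOCK_S = 24.0


class InvalidInputError(ValueError):
    """Raised when a protocol operation receives ill-formed input."""


@dataclass(frozen=True)
class DoubletSet:
    """Four ordered (leading, trailing) shape pairs over 8 distinct shapes."""

    pairs: tuple[tuple[Hashable, Hashable], ...]
    timepoint: str = "T1"

    def __post_init__(self) -> None:
        flat = [s for pair in self.pairs for s in pair]
        if len(self.pairs) != 4 or len(set(flat)) != 8:
            raise InvalidInputError(
                "a DoubletSet needs 4 pairs covering 8 distinct shapes"
            )

    @property
    def shapes(self) -> tuple[Hashable, ...]:
        return tuple(s for pair in self.pairs for s in pair)

    @property
    def leading(self) -> tuple[Hashable, ...]:
        return tuple(p[0] for p in self.pairs)

    @property
    def trailing(self) -> tuple[Hashable, ...]:
        return tuple(p[1] for p in self.pairs)


@dataclass(frozen=True)
class ShapeSequence:
    """An ordered shape stream with its analysed core delimited."""

    items: tuple[Hashable, ...]
    presentation_rate: float = PRESENTATION_RATE_HZ
    core_start: int = CORE_START
    core_stop: int = CORE_STOP
    fade_s: float = 2.0

    @property
    def core(self) -> tuple[Hashable, ...]:
        return self.items[self.core_start : self.core_stop]


@dataclass(frozen=True)
class TransitionMatrix:
    """Empirical transitional probabilities tp[from, to].

    Rows exist only for shapes observed at least once as a predecessor;
    absent predecessors are reported as absent rather than zero-filled.
    """

    tp: pd.DataFrame

    def prob(self, a: Hashable, b: Hashable) -> float:
        if a not in self.tp.index:
            raise KeyError(f"shape {a!r} never observed as a predecessor")
        return float(self.tp.loc[a, b]) if b in self.tp.columns else 0.0

    @property
    def predecessors(self) -> tuple[Hashable, ...]:
        return tuple(self.tp.index)


@dataclass(frozen=True)
class TestTrial:
    trial_type: str  # "familiar" | "novel"
    pair: tuple[Hashable, Hashable]
    items: tuple[Hashable, ...] = field(default=())


@dataclass(frozen=True)
class TestSchedule:
    """Eight alternating test trials, starting familiar."""

    trials: tuple[TestTrial, ...]

    def __post_init__(self) -> None:
        types = [t.trial_type for t in self.trials]
        if types != ["familiar", "novel"] * 4:
            raise InvalidInputError("test schedule must alternate F,N starting familiar")


@dataclass(frozen=True)
class SessionPlan:
    n_blocks_shown: int
    cumulative_looking_s: float
    reached_test: bool


def assign_doublets(
    shape_ids: Sequence[Hashable], rng: np.random.Generator, timepoint: str = "T1"
) -> DoubletSet:
    """Randomly pair 8 shapes into 4 ordered doublets.

    The assignment is drawn once per participant and reused across all
    blocks of that participant's session.
    """
    ids = list(shape_ids)
    if len(ids) != 8 or len(set(ids)) != 8:
        raise InvalidInputError("exactly 8 distinct shape ids required")
    perm = rng.permutation(8)
    pairs = tuple((ids[perm[2 * k]], ids[perm[2 * k + 1]]) for k in range(4))
    return DoubletSet(pairs=pairs, timepoint=timepoint)


def generate_familiarization_block(
    doublets: DoubletSet, rng: np.random.Generator
) -> ShapeSequence:
    """One 144-shape extended block: 72 doublets, no immediate repetition.

    Each slot is drawn uniformly among the 3 doublets different from the
    previous slot (the first slot uniform over all 4), which yields the
    inter-doublet TP of 1/3.
    """
    labels = sample_doublet_labels(rng)
    items: list[Hashable] = []
    for lab in labels:
        items.extend(doublets.pairs[lab])
    return ShapeSequence(items=tuple(items))


def sample_doublet_labels(rng: np.random.Generator, n_slots: int = 72) -> np.ndarray:
    """Pseudo-random doublet ordering: uniform among the 3 non-repeating choices."""
    labels = np.empty(n_slots, dtype=np.int64)
    labels[0] = rng.integers(4)
    for k in range(1, n_slots):
        step = rng.integers(3)  # offset 1..3 from previous, mod 4 skips repeats
        labels[k] = (labels[k - 1] + 1 + step) % 4
    return labels


def parse_doublet_labels(seq: ShapeSequence, doublets: DoubletSet) -> np.ndarray:
    """Parse a familiarization stream back into its 72 doublet labels."""
    pair_index = {pair: k for k, pair in enumerate(doublets.pairs)}
    if len(seq.items) % 2:
        raise InvalidInputError("stream length must be even")
    labels = []
    for i in range(0, len(seq.items), 2):
        pair = (seq.items[i], seq.items[i + 1])
        if pair not in pair_index:
            raise InvalidInputError(f"slot {i // 2}: {pair!r} is not a doublet")
        labels.append(pair_index[pair])
    return np.asarray(labels)


def empirical_transition_matrix(
    seq: ShapeSequence | Sequence[Hashable] | Sequence[ShapeSequence],
) -> TransitionMatrix:
    """Empirical TP matrix: tp[a, b] = count(a -> b) / count(a -> anything).

    Accepts one sequence or a list of sequences; transitions are counted
    within each sequence only (no transition across sequence boundaries).
    """
    seqs: list[Sequence[Hashable]]
    if isinstance(seq, ShapeSequence):
        seqs = [seq.items]
    elif len(seq) and isinstance(seq[0], ShapeSequence):  # type: ignore[index]
        seqs = [s.items for s in seq]  # type: ignore[union-attr]
    else:
        seqs = [seq]  # type: ignore[list-item]

    frm: list[Hashable] = []
    to: list[Hashable] = []
    for s in seqs:
        items = list(s)
        frm.extend(items[:-1])
        to.extend(items[1:])
    if not frm:
        raise InvalidInputError("need at least one observed transition")
    counts = pd.crosstab(pd.Series(frm, name="from"), pd.Series(to, name="to"))
    tp = counts.div(counts.sum(axis=1), axis=0)
    return TransitionMatrix(tp=tp)


def generate_test_schedule(
    doublets: DoubletSet, rng: np.random.Generator
) -> TestSchedule:
    """Alternating familiar/novel test trials, starting familiar.

    Novel pairs recombine a leading shape with the trailing shape of a
    different doublet (uniform over the 9 derangements), so each shape is
    used once, positions are preserved, and no novel pair ever occurred
    as an adjacent ordered pair during familiarization.
    """
    fam_order = rng.permutation(4)
    # uniform derangement of 4 by rejection (9/24 acceptance)
    while True:
        perm = rng.permutation(4)
        if not np.any(perm == np.arange(4)):
            break
    novel_pairs = [(doublets.leading[i], doublets.trailing[perm[i]]) for i in range(4)]
    novel_order = rng.permutation(4)

    trials: list[TestTrial] = []
    for k in range(4):
        fpair = doublets.pairs[fam_order[k]]
        npair = novel_pairs[novel_order[k]]
        trials.append(TestTrial("familiar", fpair, fpair * (TEST_TRIAL_LENGTH // 2)))
        trials.append(TestTrial("novel", npair, npair * (TEST_TRIAL_LENGTH // 2)))
    return TestSchedule(trials=tuple(trials))


def familiarization_adjacent_pairs(doublets: DoubletSet) -> set[tuple[Hashable, Hashable]]:
    """All ordered shape pairs that can appear adjacently during familiarization."""
    pairs = set(doublets.pairs)
    for i, (_, t) in enumerate(doublets.pairs):
        for j, (l, _) in enumerate(doublets.pairs):
            if i != j:
                pairs.add((t, l))
    return pairs


def apply_stopping_rule(
    per_block_looking: Sequence[float],
    min_blocks: int = MIN_BLOCKS,
    max_blocks: int = MAX_BLOCKS,
    criterion_s: float = LOOKING_CRITERION_S,
) -> SessionPlan:
    """Familiarization stopping rule on cumulative per-block looking.

    A minimum of `min_blocks` blocks is always shown; blocks are added
    until cumulative looking reaches `criterion_s`, up to `max_blocks`.
    The test phase is reached iff the criterion is met within the cap.
    """
    looking = np.asarray(per_block_looking, dtype=float)
    if looking.size and (np.any(looking < 0) or np.any(looking > EXTENDED_BLOCK_S)):
        raise InvalidInputError(f"per-block looking must lie in [0, {EXTENDED_BLOCK_S}] s")
    cum = np.cumsum(looking)
    limit = min(max_blocks, looking.size)
    reached_at = None
    for k in range(limit):
        if cum[k] >= criterion_s:
            reached_at = k + 1
            break
    if reached_at is None:
        n_shown = limit
        reached = False
    else:
        n_shown = min(max(min_blocks, reached_at), limit)
        reached = True
    total = float(cum[n_shown - 1]) if n_shown else 0.0
    return SessionPlan(n_blocks_shown=n_shown, cumulative_looking_s=total, reached_test=reached)


def schedule_event_table(
    seq: ShapeSequence, doublets: DoubletSet, block_index: int
) -> pd.DataFrame:
    """Export a block as an event table (time, shape, doublet, phase)."""
    labels = parse_doublet_labels(seq, doublets)
    rows = []
    dt = 1.0 / seq.presentation_rate
    for i, shape in enumerate(seq.items):
        phase = (
            "fade_in" if i < seq.core_start
            else "fade_out" if i >= seq.core_stop
            else "core"
        )
        rows.append(
            dict(
                time_s=i * dt,
                shape_id=shape,
                doublet_id=int(labels[i // 2]),
                phase=phase,
                block_index=block_index,
            )
        )
    return pd.DataFrame(rows)
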
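"""EGI-128 channel conventions shared across modules.

Electrode labels are 1-based (1..128) throughout the public API, matching
the net's electrode numbering; 0-based array indexing is internal.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

N_CHANNELS = 128

#: a-priori medial occipital electrode set used for block validation and
#: harmonic selection (defined before any ROI exists)
OCCIPITAL_APRIORI = (69, 70, 73, 74, 75, 81, 82, 83, 88, 89)

#: ring of electrodes neighbouring the a-priori occipital set, used by the
#: synthetic topography taper
OCCIPITAL_FRINGE = (66, 67, 68, 71, 72, 76, 77, 78, 84, 90)


def channel_indices(labels: Iterable[int]) -> np.ndarray:
    """0-based array indices for 1-based electrode labels."""
    labs = np.asarray(list(labels), dtype=int)
    if labs.size and (labs.min() < 1 or labs.max() > N_CHANNELS):
        raise ValueError(f"electrode labels must lie in 1..{N_CHANNELS}")
    return labs - 1


def channel_labels(indices: Sequence[int]) -> tuple[int, ...]:
    """1-based electrode labels for 0-based array indices."""
    return tuple(int(i) + 1 for i in indices)
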
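"""Blocked alternating criterion (BAC) randomization.

Under BAC the phase boundaries (and hence phase lengths) are fixed — they
may be set response-guidedly during the experiment — and the randomization
acts on *which* of two adjacent criterion levels comes first.  The
intervention phases are paired into ``B`` consecutive blocks of two; within
each block the two criterion levels are kept or swapped independently, so
there are exactly ``2**B`` admissible criterion orders.  Mini-reversals are
built in: whenever a block is swapped, the more stringent criterion of the
pair precedes the less stringent one.

With fewer than five blocks (ten phases) the smallest attainable p-value,
``1 / 2**B``, exceeds .05, so a warning is emitted below ten phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import InterventionSeries
from .statistic import Assignment, RandomizationResult, mad, randomization_pvalue


class OddPhaseCountError(ValueError):
    """BAC with blocks of two requires an even number of intervention phases."""


@dataclass(frozen=True)
class BACDesign:
    """Blocks of two criterion levels over fixed phase lengths.

    ``criterion_levels`` records the observed (actual) order; block ``b``
    spans phase positions ``2b`` and ``2b + 1``.
    """

    phase_lengths: tuple[int, ...]
    criterion_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase_lengths", tuple(int(k) for k in self.phase_lengths))
        object.__setattr__(
            self, "criterion_levels", tuple(float(c) for c in self.criterion_levels)
        )
        if len(self.phase_lengths) != len(self.criterion_levels):
            raise ValueError("phase_lengths and criterion_levels must have equal count")
        if len(self.phase_lengths) < 2 or len(self.phase_lengths) % 2 != 0:
            raise OddPhaseCountError(
                f"BAC needs an even number (>= 2) of intervention phases, got "
                f"{len(self.phase_lengths)}"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.phase_lengths) // 2

    @property
    def n_randomizations(self) -> int:
        return 2**self.n_blocks


def make_blocks(series: InterventionSeries) -> BACDesign:
    """Pair consecutive intervention phases into blocks of two."""
    return BACDesign(
        phase_lengths=series.phase_lengths,
        criterion_levels=series.criterion_levels,
    )


def enumerate_orders(design: BACDesign) -> np.ndarray:
    """All ``2**B`` criterion-level orders as an array of shape ``(2**B, I)``.

    Deterministic binary-counting order: row ``r`` swaps block ``b`` iff bit
    ``b`` of ``r`` is set, with block 1 as the least significant bit.  Row 0
    is the observed order.
    """
    B = design.n_blocks
    levels = np.asarray(design.criterion_levels, dtype=float)
    swapped = levels.reshape(B, 2)[:, ::-1].ravel()
    orders = np.empty((2**B, 2 * B), dtype=float)
    for r in range(2**B):
        for b in range(B):
            src = swapped if (r >> b) & 1 else levels
            orders[r, 2 * b : 2 * b + 2] = src[2 * b : 2 * b + 2]
    return orders


def order_index(bits) -> int:
    """Row index in :func:`enumerate_orders` of the order with the given swaps."""
    return int(sum(int(b) << i for i, b in enumerate(bits)))


def reference_profiles(design: BACDesign) -> np.ndarray:
    """Per-occasion criterion profiles of all orders, shape ``(2**B, m)``."""
    return np.repeat(enumerate_orders(design), design.phase_lengths, axis=1)


def bac_test(series: InterventionSeries) -> RandomizationResult:
    """BAC randomization test of criterion tracking.

    Always systematic: the reference distribution is the MAD of the scores
    against all ``2**B`` within-block criterion orders, the phase lengths
    staying attached to their positions.
    """
    design = make_blocks(series)
    if series.n_phases < 10:
        warnings.warn(
            f"with {series.n_phases} phases ({design.n_blocks} blocks) the "
            f"smallest attainable p-value is 1/{design.n_randomizations} > .05; "
            "at least ten phases (five blocks) are recommended",
            UserWarning,
            stacklevel=2,
        )
    scores = np.asarray(series.scores, dtype=float)
    observed = mad(scores, Assignment(series.phase_lengths, series.criterion_levels))
    profiles = reference_profiles(design)
    reference = np.mean(np.abs(scores[None, :] - profiles), axis=1)
    p = randomization_pvalue(observed, reference)
    return RandomizationResult(
        observed=observed,
        reference=reference,
        p_value=p,
        mode="systematic",
        n_randomizations=reference.size,
    )
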
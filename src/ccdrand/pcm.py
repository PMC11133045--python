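"""Phase change moment (PCM) randomization for changing criterion designs.

Under PCM the order of the criterion levels is fixed in advance and the
*moments* at which the criterion changes are randomized.  With ``m``
intervention measurements, ``I`` phases, and per-phase length bounds
``k_min <= k <= k_max``, the admissible randomizations are exactly the
integer compositions of ``m`` into ``I`` parts within those bounds.  When
the maximum is non-binding the count has the stars-and-bars closed form::

    C(m - I*k_min + I - 1, I - 1)

and in general it is computed by dynamic programming over (remaining sum,
remaining phases).  The same DP table supports exact uniform sampling of a
composition by sequential conditional draws — never rejection sampling,
which degenerates badly because early phase lengths constrain later ones.

The reference distribution of the test is the MAD statistic evaluated over
every admissible composition (systematic mode) or over an i.i.d. uniform
Monte Carlo sample of compositions (Monte Carlo mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .data import InterventionSeries
from .statistic import Assignment, RandomizationResult, mad, randomization_pvalue

#: Default size limit above which systematic enumeration refuses to run.
ENUMERATION_CAP = 10**6


class InfeasibleDesignError(ValueError):
    """No composition of ``m`` into ``I`` parts satisfies the length bounds."""


@dataclass(frozen=True)
class PCMDesign:
    """The admissible set of phase-length compositions.

    Parameters
    ----------
    m
        Total number of intervention measurements.
    n_phases
        Number of intervention phases, at least 2.
    k_min
        Minimum phase length (default 3, the conventional floor for
        demonstrating criterion attainment).
    k_max
        Maximum phase length.  Defaults to ``m - (n_phases - 1) * k_min``,
        the largest value any single phase can take when all others are at
        the minimum, which leaves the admissible set unchanged.
    """

    m: int
    n_phases: int
    k_min: int = 3
    k_max: int | None = None

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise InfeasibleDesignError("PCM requires at least two phases")
        if self.k_min < 1:
            raise InfeasibleDesignError("minimum phase length must be positive")
        if self.k_max is None:
            object.__setattr__(self, "k_max", self.m - (self.n_phases - 1) * self.k_min)
        if self.k_max < self.k_min:
            raise InfeasibleDesignError(
                f"k_max={self.k_max} is smaller than k_min={self.k_min}"
            )
        if not (self.n_phases * self.k_min <= self.m <= self.n_phases * self.k_max):
            raise InfeasibleDesignError(
                f"no composition of m={self.m} into {self.n_phases} parts "
                f"within [{self.k_min}, {self.k_max}]"
            )

    def is_admissible(self, phase_lengths) -> bool:
        lengths = tuple(int(k) for k in phase_lengths)
        return (
            len(lengths) == self.n_phases
            and sum(lengths) == self.m
            and all(self.k_min <= k <= self.k_max for k in lengths)
        )


def _count_table(design: PCMDesign) -> list[list[int]]:
    """``ways[j][s]`` = number of compositions of ``s`` into ``j`` bounded parts.

    Exact Python integers; ``ways[design.n_phases][design.m]`` is the total
    randomization count.
    """
    m, lo, hi = design.m, design.k_min, design.k_max
    ways = [[0] * (m + 1) for _ in range(design.n_phases + 1)]
    ways[0][0] = 1
    for j in range(1, design.n_phases + 1):
        prev = ways[j - 1]
        cur = ways[j]
        for s in range(j * lo, min(m, j * hi) + 1):
            total = 0
            for k in range(lo, min(hi, s) + 1):
                total += prev[s - k]
            cur[s] = total
    return ways


def count_randomizations(design: PCMDesign) -> int:
    """Exact number of admissible phase-length compositions.

    Equals the closed form ``C(m - I*k_min + I - 1, I - 1)`` when ``k_max``
    is non-binding.
    """
    return _count_table(design)[design.n_phases][design.m]


def iter_compositions(design: PCMDesign) -> Iterator[tuple[int, ...]]:
    """Yield every admissible composition once, in lexicographic order."""
    m, I, lo, hi = design.m, design.n_phases, design.k_min, design.k_max
    prefix: list[int] = []

    def rec(remaining: int, phases_left: int):
        if phases_left == 1:
            if lo <= remaining <= hi:
                yield tuple(prefix) + (remaining,)
            return
        # prune: the remaining phases must be able to absorb what is left
        k_lo = max(lo, remaining - (phases_left - 1) * hi)
        k_hi = min(hi, remaining - (phases_left - 1) * lo)
        for k in range(k_lo, k_hi + 1):
            prefix.append(k)
            yield from rec(remaining - k, phases_left - 1)
            prefix.pop()

    yield from rec(m, I)


def enumerate_compositions(
    design: PCMDesign, cap: int = ENUMERATION_CAP
) -> list[tuple[int, ...]]:
    """All admissible compositions in lexicographic order.

    Raises
    ------
    ValueError
        If the admissible set exceeds ``cap`` — switch to Monte Carlo mode.
    """
    count = count_randomizations(design)
    if count > cap:
        raise ValueError(
            f"{count} admissible compositions exceed the enumeration cap "
            f"({cap}); use Monte Carlo mode instead"
        )
    return list(iter_compositions(design))


def sample_compositions(
    design: PCMDesign, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` compositions i.i.d. uniformly from the admissible set.

    Sequential conditional sampling: phase ``i``'s length is drawn with
    probability proportional to the number of completions of the remaining
    phases (from the DP count table), so every admissible composition has
    probability exactly ``1 / count_randomizations(design)``.

    Returns an integer array of shape ``(size, n_phases)``.
    """
    if size < 1:
        raise ValueError("size must be positive")
    m, I, lo, hi = design.m, design.n_phases, design.k_min, design.k_max
    ways = _count_table(design)
    n_lengths = hi - lo + 1
    out = np.empty((size, I), dtype=np.int64)
    remaining = np.full(size, m, dtype=np.int64)
    for i in range(I - 1):
        left = I - i - 1  # phases after this one
        # probability table indexed by remaining sum: P[s, k-lo] ∝ ways[left][s-k]
        smax = min(m, (left + 1) * hi)
        prob = np.zeros((smax + 1, n_lengths), dtype=float)
        for s in range((left + 1) * lo, smax + 1):
            row = [
                float(ways[left][s - k]) if lo <= k <= min(hi, s) else 0.0
                for k in range(lo, hi + 1)
            ]
            prob[s] = row
        cdf = np.cumsum(prob[remaining], axis=1)
        totals = cdf[:, -1]
        u = rng.random(size) * totals
        draw = (u[:, None] >= cdf).sum(axis=1)  # index into lo..hi
        k = lo + draw
        out[:, i] = k
        remaining -= k
    out[:, I - 1] = remaining
    return out


def sample_composition(design: PCMDesign, rng: np.random.Generator) -> tuple[int, ...]:
    """One composition drawn uniformly from the admissible set."""
    return tuple(int(k) for k in sample_compositions(design, 1, rng)[0])


def _profiles(
    compositions: np.ndarray, criterion_levels, m: int
) -> np.ndarray:
    """Per-occasion criterion profiles ``c(t)`` for many compositions at once.

    ``compositions`` has shape ``(R, I)``; the result has shape ``(R, m)``
    where row ``r`` repeats ``criterion_levels[i]`` over the occasions of
    phase ``i`` under composition ``r``.
    """
    comps = np.asarray(compositions, dtype=np.int64)
    levels = np.asarray(criterion_levels, dtype=float)
    bounds = np.cumsum(comps, axis=1)  # (R, I)
    pos = np.arange(m)
    phase_index = (bounds[:, :, None] <= pos[None, None, :]).sum(axis=1)  # (R, m)
    return levels[phase_index]


def reference_profiles(design: PCMDesign, criterion_levels, cap: int = ENUMERATION_CAP) -> np.ndarray:
    """Criterion profiles of every admissible composition (systematic mode)."""
    comps = np.array(enumerate_compositions(design, cap=cap), dtype=np.int64)
    return _profiles(comps, criterion_levels, design.m)


def pcm_test(
    series: InterventionSeries,
    design: PCMDesign | None = None,
    mode: str = "systematic",
    mc_samples: int = 1000,
    rng: np.random.Generator | None = None,
    k_min: int = 3,
    k_max: int | None = None,
    cap: int = ENUMERATION_CAP,
) -> RandomizationResult:
    """PCM randomization test of criterion tracking.

    The observed MAD is computed under the actual phase lengths with the
    criterion levels fixed in their observed order; the reference
    distribution is the MAD over every admissible composition
    (``mode="systematic"``) or over ``mc_samples`` uniformly sampled
    compositions plus the observed one (``mode="monte_carlo"``, p-value
    ``(1 + #{sampled MAD <= observed}) / (mc_samples + 1)``).

    Parameters
    ----------
    series
        The intervention scores with their actual phase lengths and
        criterion levels (baseline already removed).
    design
        The admissible composition set.  Built from ``series`` with
        ``k_min``/``k_max`` when omitted.
    """
    if design is None:
        design = PCMDesign(m=series.m, n_phases=series.n_phases, k_min=k_min, k_max=k_max)
    if not design.is_admissible(series.phase_lengths):
        raise ValueError(
            f"observed phase lengths {series.phase_lengths} are not admissible "
            f"under the design (m={design.m}, I={design.n_phases}, "
            f"k in [{design.k_min}, {design.k_max}])"
        )
    scores = np.asarray(series.scores, dtype=float)
    observed = mad(scores, Assignment(series.phase_lengths, series.criterion_levels))

    if mode == "systematic":
        profiles = reference_profiles(design, series.criterion_levels, cap=cap)
        reference = np.mean(np.abs(scores[None, :] - profiles), axis=1)
        p = randomization_pvalue(observed, reference)
    elif mode == "monte_carlo":
        if rng is None:
            raise ValueError("Monte Carlo mode requires a seeded rng")
        comps = sample_compositions(design, mc_samples, rng)
        profiles = _profiles(comps, series.criterion_levels, design.m)
        sampled = np.mean(np.abs(scores[None, :] - profiles), axis=1)
        reference = np.concatenate([sampled, [observed]])
        p = randomization_pvalue(observed, reference)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'systematic' or 'monte_carlo'")

    return RandomizationResult(
        observed=observed,
        reference=reference,
        p_value=p,
        mode=mode,
        n_randomizations=reference.size,
    )
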
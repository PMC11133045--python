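"""Monte Carlo estimation of type I error rates and statistical power.

Data-generating model
---------------------
Criterion levels form a staircase above a baseline level: phase ``i`` has
criterion ``baseline_level + i * increment`` (optionally with a
mini-reversal: the penultimate phase steps back one increment and the last
phase resumes the staircase).  Errors are Gaussian AR(1).  By default the
simulation uses standard-normal innovations (the convention of the
single-case simulation literature), under which positive serial dependence
also inflates the marginal noise — one reason power is lowest for
positive autocorrelation.  Conditions can instead request a
marginally-standardised process (``standardize_noise=True``, unit marginal
variance at every ``phi``) to decouple dependence from noise magnitude.

*Effect* replicates track the criteria: ``y_t = c(t) + s(t) * z_t`` with a
phase-specific noise scale proportional to the programmed elevation of the
criterion above the baseline level, ``s(t) = variability * |c(t) -
baseline_level|`` — more ambitious criteria come with proportionally more
variability.  Because both the signal (the criterion steps) and the noise
scale are linear in the increment, power is invariant to the increment's
units: one-unit and five-unit staircases are statistically identical
designs.  *Null* replicates are flat: ``y_t = L + s * z_t`` with ``s =
variability * |L - baseline_level|`` where ``L`` is the length-weighted
average of the criterion levels, so the criterion labels used by the test
mismatch the data equally everywhere.

Rejection rates
---------------
For each replicate an actual assignment is realised (BAC: a fair coin per
block decides the within-block criterion order; PCM: the phase lengths are
either fixed to the condition's pattern vector, as when a planned pattern
is treated as the actual data, or drawn uniformly from the admissible
composition set when ``randomize_actual`` is set), the series is generated
under that assignment, the randomization test is applied, and the
rejection rate is the proportion of replicates with ``p <= alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import bac as _bac
from . import pcm as _pcm
from .data import InterventionSeries
from .statistic import Assignment, mad

#: Largest series length for which the PCM reference set is enumerated
#: systematically inside the simulation; longer series use Monte Carlo
#: references of ``mc_samples`` compositions.
SYSTEMATIC_LIMIT = 36


# ---------------------------------------------------------------------------
# deterministic building blocks
# ---------------------------------------------------------------------------

def build_criteria(
    n_phases: int,
    baseline_level: float = 10.0,
    increment: float = 5.0,
    reversal: bool = False,
) -> tuple[float, ...]:
    """Criterion staircase for ``n_phases`` intervention phases.

    Without a reversal, phase ``i`` (1-based) has criterion
    ``baseline_level + i * increment``.  With a reversal (requires at least
    four phases), the penultimate phase steps back one increment below the
    phase before it and the last phase resumes the staircase one increment
    above it.
    """
    if n_phases < 2:
        raise ValueError("at least two intervention phases are required")
    levels = [baseline_level + i * increment for i in range(1, n_phases + 1)]
    if reversal:
        if n_phases < 4:
            raise ValueError("a mini-reversal requires at least four intervention phases")
        anchor = levels[n_phases - 3]
        levels[n_phases - 2] = anchor - increment
        levels[n_phases - 1] = anchor + increment
    return tuple(levels)


def build_phase_lengths(
    n_phases: int, m: int, pattern: str = "uniform"
) -> tuple[int, ...]:
    """Deterministic phase-length vector of a given pattern summing to ``m``.

    ``uniform``
        all phases equal (requires ``n_phases`` to divide ``m``);
    ``increasing``
        first phase at the minimum of 3, surplus beyond 3 per phase handed
        out one unit at a time cycling over the phases from last to second,
        giving a nondecreasing vector;
    ``triangular``
        all phases start at 3 and surplus units go greedily to the phase
        whose current length plus distance from the centre is smallest
        (ties to the most central, then earliest, phase), concentrating
        length in the middle.

    Every entry is at least 3 and the entries sum to ``m``.
    """
    if n_phases < 2:
        raise ValueError("at least two phases are required")
    if m < 3 * n_phases:
        raise ValueError(
            f"series length {m} cannot give {n_phases} phases of at least 3"
        )
    if pattern == "uniform":
        if m % n_phases != 0:
            raise ValueError(
                f"uniform pattern needs {n_phases} to divide {m}"
            )
        return (m // n_phases,) * n_phases
    lengths = [3] * n_phases
    surplus = m - 3 * n_phases
    if pattern == "increasing":
        order = list(range(n_phases - 1, 0, -1))  # last phase first, never the first
        i = 0
        while surplus > 0:
            lengths[order[i % len(order)]] += 1
            surplus -= 1
            i += 1
        return tuple(lengths)
    if pattern == "triangular":
        centre = (n_phases - 1) / 2.0
        dist = [abs(i - centre) for i in range(n_phases)]
        while surplus > 0:
            key = [(lengths[i] - 3 + dist[i], dist[i], i) for i in range(n_phases)]
            lengths[min(range(n_phases), key=lambda i: key[i])] += 1
            surplus -= 1
        return tuple(lengths)
    raise ValueError(f"unknown pattern {pattern!r}")


def generate_ar1(
    n: int,
    phi: float,
    rng: np.random.Generator,
    size: int = 1,
    standardize: bool = True,
) -> np.ndarray:
    """Stationary Gaussian AR(1) noise ``z_t = phi * z_{t-1} + u_t``.

    With ``standardize=True`` the innovations have variance ``1 - phi**2``
    (and ``z_1`` is standard normal), so every ``z_t`` is marginally
    N(0, 1) with lag-1 autocorrelation ``phi`` — the noise scale is
    comparable across autocorrelation levels.  With ``standardize=False``
    the innovations are standard normal, the convention of much of the
    single-case simulation literature, giving marginal variance
    ``1 / (1 - phi**2)``: serial dependence then also inflates the noise.
    Returns shape ``(size, n)`` (or ``(n,)`` when ``size == 1``).
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not -1.0 < phi < 1.0:
        raise ValueError("phi must lie strictly inside (-1, 1)")
    e = rng.standard_normal((size, n))
    if standardize:
        e[:, 1:] *= math.sqrt(1.0 - phi * phi)
    z = lfilter([1.0], [1.0, -phi], e, axis=1)
    return z[0] if size == 1 else z


# ---------------------------------------------------------------------------
# condition grid types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation grid.

    The phase-length layout is given either explicitly (``phase_lengths``)
    or as a pattern: ``phase_length`` fixes a uniform per-phase length, or
    ``m`` plus ``pattern`` derives the vector via
    :func:`build_phase_lengths`.
    """

    procedure: Literal["pcm", "bac"]
    n_phases: int
    phase_lengths: tuple[int, ...] | None = None
    phase_length: int | None = None
    m: int | None = None
    pattern: str = "uniform"
    baseline_level: float = 10.0
    increment: float = 5.0
    variability: float = 0.25
    phi: float = 0.0
    effect: bool = True
    reversal: bool = False
    replications: int = 1000
    alpha: float = 0.05
    k_min: int = 3
    pcm_mode: Literal["auto", "systematic", "monte_carlo"] = "auto"
    mc_samples: int = 1000
    randomize_actual: bool = False
    standardize_noise: bool = False

    def resolved_lengths(self) -> tuple[int, ...]:
        if self.phase_lengths is not None:
            lengths = tuple(int(k) for k in self.phase_lengths)
            if len(lengths) != self.n_phases:
                raise ValueError("phase_lengths does not match n_phases")
            return lengths
        if self.phase_length is not None:
            return (int(self.phase_length),) * self.n_phases
        if self.m is not None:
            return build_phase_lengths(self.n_phases, self.m, self.pattern)
        raise ValueError(
            "condition needs phase_lengths, phase_length, or m with a pattern"
        )

    def resolved_m(self) -> int:
        return sum(self.resolved_lengths())

    def criteria(self) -> tuple[float, ...]:
        return build_criteria(
            self.n_phases, self.baseline_level, self.increment, self.reversal
        )

    def validate(self) -> None:
        lengths = self.resolved_lengths()
        if self.procedure == "bac" and self.n_phases % 2 != 0:
            raise ValueError("BAC requires an even number of phases")
        if self.procedure == "pcm":
            design = _pcm.PCMDesign(sum(lengths), self.n_phases, self.k_min)
            if not design.is_admissible(lengths):
                raise ValueError(
                    f"actual lengths {lengths} are not admissible under "
                    f"k_min={self.k_min}"
                )
        if self.reversal and self.n_phases < 4:
            raise ValueError("a reversal requires at least four phases")
        if self.variability < 0:
            raise ValueError("variability must be nonnegative")


@dataclass(frozen=True)
class SimulationEstimate:
    """Rejection-rate estimate for one condition."""

    condition: SimulationCondition
    rejection_rate: float
    mc_se: float
    n_randomizations: int

    @staticmethod
    def from_rejections(
        condition: SimulationCondition, rejections: int, n_randomizations: int
    ) -> "SimulationEstimate":
        r = rejections / condition.replications
        se = math.sqrt(r * (1.0 - r) / condition.replications)
        return SimulationEstimate(condition, r, se, n_randomizations)


# ---------------------------------------------------------------------------
# series generators
# ---------------------------------------------------------------------------

def _noise(condition: SimulationCondition, n: int, rng: np.random.Generator) -> np.ndarray:
    return generate_ar1(n, condition.phi, rng, standardize=condition.standardize_noise)


def generate_effect_series(
    condition: SimulationCondition,
    rng: np.random.Generator,
    assignment: Assignment | None = None,
) -> InterventionSeries:
    """Series tracking the criteria with elevation-proportional noise.

    ``y_t = c(t) + variability * |c(t) - baseline_level| * z_t``.  One
    continuous AR(1) stream spans the whole series (serial dependence is not
    reset at phase changes); only the noise *scale* changes with the phase
    criterion's distance from baseline.
    """
    if assignment is None:
        assignment = Assignment(condition.resolved_lengths(), condition.criteria())
    profile = assignment.criterion_profile()
    z = _noise(condition, profile.size, rng)
    scale = condition.variability * np.abs(profile - condition.baseline_level)
    y = profile + scale * z
    return InterventionSeries(
        scores=tuple(y),
        phase_lengths=assignment.phase_lengths,
        criterion_levels=assignment.criterion_levels,
    )


def null_level(assignment: Assignment) -> float:
    """Length-weighted average of the criterion levels.

    This is the flat level of the no-effect data; it reduces to the simple
    average of the criteria when all phases have equal length.
    """
    return float(np.mean(assignment.criterion_profile()))


def generate_null_series(
    condition: SimulationCondition,
    rng: np.random.Generator,
    assignment: Assignment | None = None,
) -> InterventionSeries:
    """Flat series at the weighted-average criterion level.

    ``y_t = L + variability * |L - baseline_level| * z_t`` with constant
    noise scale; the criterion labels are retained so the test sees the
    usual phase/criterion structure even though the data carry no effect.

    ``L`` is always computed from the condition's nominal phase lengths:
    under the null hypothesis the data-generating process must not depend
    on the realised randomization, so when the actual assignment is drawn
    at random (``randomize_actual``) the flat level stays fixed and the
    test remains exactly valid.  The ``assignment`` argument only sets the
    phase/criterion labels attached to the returned series.
    """
    L = null_level(Assignment(condition.resolved_lengths(), condition.criteria()))
    if assignment is None:
        assignment = Assignment(condition.resolved_lengths(), condition.criteria())
    m = assignment.m
    z = _noise(condition, m, rng)
    y = L + condition.variability * abs(L - condition.baseline_level) * z
    return InterventionSeries(
        scores=tuple(y),
        phase_lengths=assignment.phase_lengths,
        criterion_levels=assignment.criterion_levels,
    )


def _generate(condition, rng, assignment) -> InterventionSeries:
    if condition.effect:
        return generate_effect_series(condition, rng, assignment)
    return generate_null_series(condition, rng, assignment)


# ---------------------------------------------------------------------------
# rejection-rate engine
# ---------------------------------------------------------------------------

def _pcm_resolved_mode(condition: SimulationCondition, m: int) -> str:
    if condition.pcm_mode != "auto":
        return condition.pcm_mode
    return "systematic" if m <= SYSTEMATIC_LIMIT else "monte_carlo"


def _estimate_pcm(condition: SimulationCondition, rng: np.random.Generator) -> SimulationEstimate:
    lengths = condition.resolved_lengths()
    criteria = condition.criteria()
    m = sum(lengths)
    design = _pcm.PCMDesign(m, condition.n_phases, condition.k_min)
    mode = _pcm_resolved_mode(condition, m)
    n_rand = _pcm.count_randomizations(design)

    ref_profiles = None
    if mode == "systematic":
        ref_profiles = _pcm.reference_profiles(design, criteria)

    if condition.randomize_actual:
        actual = _pcm.sample_compositions(design, condition.replications, rng)
    else:
        actual = np.broadcast_to(
            np.asarray(lengths, dtype=np.int64), (condition.replications, len(lengths))
        )

    rejections = 0
    for r in range(condition.replications):
        assignment = Assignment(tuple(int(k) for k in actual[r]), criteria)
        series = _generate(condition, rng, assignment)
        scores = np.asarray(series.scores)
        observed = mad(scores, assignment)
        if mode == "systematic":
            ref = np.mean(np.abs(scores[None, :] - ref_profiles), axis=1)
            p = np.count_nonzero(ref <= observed) / ref.size
        else:
            comps = _pcm.sample_compositions(design, condition.mc_samples, rng)
            profiles = _pcm._profiles(comps, criteria, m)
            sampled = np.mean(np.abs(scores[None, :] - profiles), axis=1)
            p = (1 + np.count_nonzero(sampled <= observed)) / (condition.mc_samples + 1)
        if p <= condition.alpha:
            rejections += 1
    return SimulationEstimate.from_rejections(condition, rejections, n_rand)


def _estimate_bac(condition: SimulationCondition, rng: np.random.Generator) -> SimulationEstimate:
    lengths = condition.resolved_lengths()
    criteria = condition.criteria()
    design = _bac.BACDesign(lengths, criteria)
    orders = _bac.enumerate_orders(design)
    profiles = _bac.reference_profiles(design)  # (2**B, m)
    B = design.n_blocks
    weights = 1 << np.arange(B)

    rejections = 0
    for r in range(condition.replications):
        bits = rng.integers(0, 2, size=B)
        idx = int(bits @ weights)
        actual_profile = profiles[idx]
        assignment = Assignment(lengths, tuple(orders[idx]))
        series = _generate(condition, rng, assignment)
        scores = np.asarray(series.scores)
        observed = float(np.mean(np.abs(scores - actual_profile)))
        ref = np.mean(np.abs(scores[None, :] - profiles), axis=1)
        p = np.count_nonzero(ref <= observed) / ref.size
        if p <= condition.alpha:
            rejections += 1
    return SimulationEstimate.from_rejections(condition, rejections, design.n_randomizations)


def estimate_rejection_rate(
    condition: SimulationCondition, rng: np.random.Generator
) -> SimulationEstimate:
    """Rejection rate (power, or type I error under the null) for one condition.

    Runs ``condition.replications`` independent generate-and-test cycles and
    returns the proportion of replicates with ``p <= condition.alpha``
    together with its binomial Monte Carlo standard error.
    """
    condition.validate()
    if condition.procedure == "pcm":
        return _estimate_pcm(condition, rng)
    if condition.procedure == "bac":
        return _estimate_bac(condition, rng)
    raise ValueError(f"unknown procedure {condition.procedure!r}")


def run_condition_grid(
    conditions: Sequence[SimulationCondition], seed: int
) -> pd.DataFrame:
    """Estimate every condition of a grid, one substream per condition.

    The RNG substream of condition ``i`` is ``SeedSequence([seed, i])``, so
    the output table is reproducible given the master seed and independent
    of the order in which conditions are evaluated.
    """
    rows = []
    for i, condition in enumerate(conditions):
        try:
            condition.validate()
        except ValueError as exc:
            raise ValueError(f"condition {i} is invalid: {exc}") from exc
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        est = estimate_rejection_rate(condition, rng)
        lengths = condition.resolved_lengths()
        rows.append(
            {
                "procedure": condition.procedure,
                "n_phases": condition.n_phases,
                "m": sum(lengths),
                "pattern": condition.pattern if condition.phase_lengths is None else "explicit",
                "phase_lengths": "-".join(str(k) for k in lengths),
                "variability": condition.variability,
                "phi": condition.phi,
                "increment": condition.increment,
                "effect": condition.effect,
                "reversal": condition.reversal,
                "replications": condition.replications,
                "n_randomizations": est.n_randomizations,
                "rate": est.rejection_rate,
                "se": est.mc_se,
            }
        )
    return pd.DataFrame(rows)
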
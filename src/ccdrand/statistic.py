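"""Test statistic and p-value contract shared by the PCM and BAC procedures.

The statistic is the mean absolute deviation (MAD) of the intervention
measurements from their phase criterion levels, pooled over all ``m``
occasions::

    MAD = (1/m) * sum_t | y_t - c(t) |

where ``c(t)`` is the criterion of the phase containing occasion ``t``.  A
small MAD means close tracking of the criterion, so the randomization
p-value is one-sided in the lower tail: the proportion of reference
statistics as small or smaller than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Assignment:
    """One admissible randomization: phase lengths plus criterion levels.

    Under PCM the lengths vary across randomizations and the criterion
    levels stay fixed; under BAC the lengths are fixed and the levels vary.
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

    @property
    def m(self) -> int:
        return sum(self.phase_lengths)

    def criterion_profile(self) -> np.ndarray:
        """The per-occasion criterion ``c(t)`` as a length-``m`` array."""
        return np.repeat(self.criterion_levels, self.phase_lengths)


def mad(scores, assignment: Assignment) -> float:
    """Mean absolute deviation of ``scores`` from the assignment's criteria.

    Each occasion is weighted equally (pooled over measurements, not
    averaged per phase), so phases contribute proportionally to their
    length.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if assignment.m != scores.size:
        raise ValueError(
            f"assignment covers {assignment.m} occasions but there are "
            f"{scores.size} scores"
        )
    return float(np.mean(np.abs(scores - assignment.criterion_profile())))


def randomization_pvalue(observed: float, reference) -> float:
    """Lower-tail randomization p-value.

    ``p = #{r in reference : r <= observed} / len(reference)``.  Ties are
    compared with exact ``<=`` on binary floating point; reference values
    are expected to come from the same code path as the observed statistic,
    so exact ties are reproducible.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.size == 0:
        raise ValueError("reference distribution is empty")
    return float(np.count_nonzero(reference <= observed) / reference.size)


@dataclass(frozen=True)
class RandomizationResult:
    """Outcome of a randomization test.

    Attributes
    ----------
    observed
        MAD under the actual assignment.
    reference
        The reference distribution of MAD values (includes the observed
        assignment's statistic under systematic enumeration; includes the
        observed statistic itself in Monte Carlo mode).
    p_value
        Lower-tail p-value.
    mode
        ``"systematic"`` or ``"monte_carlo"``.
    n_randomizations
        Size of the reference distribution (the p-value denominator).
    """

    observed: float
    reference: np.ndarray
    p_value: float
    mode: str
    n_randomizations: int
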
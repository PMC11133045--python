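"""Data containers and delimited-text I/O for changing criterion design (CCD) series.

A changing criterion design observes one behaviour over ``n`` measurement
occasions.  After an optional baseline phase, a performance criterion is set
and then stepped up (or down) across successive intervention phases.  The
on-disk layout is a delimited table with four columns:

``Phase``
    successive labels marking the phases (e.g. ``A, A, ..., B, B, ...``);
``Session``
    the measurement occasion, an increasing integer index;
``Scores``
    the observed measurements;
``Criterion``
    the criterion level in force during each phase.  Baseline occasions have
    no criterion, encoded as empty cells.

Both randomization procedures implemented in this package operate on the
intervention occasions only, so :func:`strip_baseline` converts a validated
:class:`CCDSeries` into the compact :class:`InterventionSeries` used by the
test routines.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("Phase", "Session", "Scores", "Criterion")


class CCDSchemaError(ValueError):
    """The table does not have the required column layout."""


class CCDValidationError(ValueError):
    """The table has the right columns but the values violate an invariant."""


def _phase_runs(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    """Contiguous runs of phase labels as ``(label, start, stop)`` slices."""
    runs = []
    start = 0
    for label, group in itertools.groupby(labels):
        length = sum(1 for _ in group)
        runs.append((label, start, start + length))
        start += length
    return runs


@dataclass
class CCDSeries:
    """One observed changing-criterion data set, including any baseline.

    Parameters
    ----------
    phase_labels
        One phase identifier per measurement occasion.  Labels must form
        contiguous runs: a phase never restarts after another phase began.
    sessions
        Measurement-occasion indices, strictly increasing integers.  They are
        metadata only; all analysis uses row order.
    scores
        The observed measurements, one real number per occasion.
    criteria
        The criterion level per occasion, constant within each phase.
        ``NaN`` marks baseline occasions (no criterion in force).
    baseline_label
        Optional explicit label of the baseline phase.  When ``None``, the
        first phase is treated as baseline iff all its criterion cells are
        missing.
    """

    phase_labels: list[str]
    sessions: np.ndarray
    scores: np.ndarray
    criteria: np.ndarray
    baseline_label: str | None = None

    def __post_init__(self) -> None:
        self.phase_labels = [str(p) for p in self.phase_labels]
        self.sessions = np.asarray(self.sessions, dtype=int)
        self.scores = np.asarray(self.scores, dtype=float)
        self.criteria = np.asarray(self.criteria, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n = len(self.phase_labels)
        if n < 1:
            raise CCDValidationError("series must contain at least one occasion")
        for name, col in (
            ("Session", self.sessions),
            ("Scores", self.scores),
            ("Criterion", self.criteria),
        ):
            if len(col) != n:
                raise CCDValidationError(
                    f"column {name!r} has length {len(col)}, expected {n}"
                )
        if np.isnan(self.scores).any():
            raise CCDValidationError("missing scores are not allowed")
        if np.any(np.diff(self.sessions) <= 0):
            raise CCDValidationError("sessions must be strictly increasing")

        runs = _phase_runs(self.phase_labels)
        seen = set()
        for label, _, _ in runs:
            if label in seen:
                raise CCDValidationError(
                    f"phase {label!r} is not contiguous (phases must not interleave)"
                )
            seen.add(label)

        baseline_index = self._baseline_run_index(runs)
        for i, (label, start, stop) in enumerate(runs):
            crit = self.criteria[start:stop]
            if i == baseline_index:
                continue
            if np.isnan(crit).any():
                raise CCDValidationError(
                    f"phase {label!r} has missing criterion values but is not the baseline"
                )
            if np.unique(crit).size != 1:
                raise CCDValidationError(
                    f"criterion is not constant within phase {label!r}"
                )

    def _baseline_run_index(self, runs: list[tuple[str, int, int]]) -> int | None:
        """Index of the baseline run among the phase runs, or ``None``."""
        if self.baseline_label is not None:
            for i, (label, _, _) in enumerate(runs):
                if label == self.baseline_label:
                    if i != 0:
                        raise CCDValidationError(
                            "a baseline phase must be the first phase of the series"
                        )
                    return i
            raise CCDValidationError(
                f"baseline label {self.baseline_label!r} not found in Phase column"
            )
        # Implicit detection: the first run is baseline iff its criterion
        # cells are all missing.
        label, start, stop = runs[0]
        if np.isnan(self.criteria[start:stop]).all():
            return 0
        return None

    # -- derived views ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.phase_labels)

    def phase_table(self) -> pd.DataFrame:
        """Per-phase summary: label, length, criterion (NaN for baseline)."""
        runs = _phase_runs(self.phase_labels)
        baseline_index = self._baseline_run_index(runs)
        rows = []
        for i, (label, start, stop) in enumerate(runs):
            crit = np.nan if i == baseline_index else float(self.criteria[start])
            rows.append(
                {
                    "phase": label,
                    "length": stop - start,
                    "criterion": crit,
                    "baseline": i == baseline_index,
                }
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Phase": self.phase_labels,
                "Session": self.sessions,
                "Scores": self.scores,
                "Criterion": self.criteria,
            }
        )


@dataclass(frozen=True)
class InterventionSeries:
    """The intervention occasions of a CCD series, baseline removed.

    ``phase_lengths`` and ``criterion_levels`` record the actual assignment
    realised in the experiment: one entry per intervention phase, in temporal
    order, with ``sum(phase_lengths) == len(scores)``.
    """

    scores: tuple[float, ...]
    phase_lengths: tuple[int, ...]
    criterion_levels: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        object.__setattr__(
            self, "phase_lengths", tuple(int(k) for k in self.phase_lengths)
        )
        object.__setattr__(
            self,
            "criterion_levels",
            tuple(float(c) for c in self.criterion_levels),
        )
        if len(self.phase_lengths) != len(self.criterion_levels):
            raise CCDValidationError(
                "phase_lengths and criterion_levels must have equal count"
            )
        if len(self.phase_lengths) < 2:
            raise CCDValidationError(
                "randomization requires at least two intervention phases"
            )
        if any(k < 1 for k in self.phase_lengths):
            raise CCDValidationError("phase lengths must be positive")
        if sum(self.phase_lengths) != len(self.scores):
            raise CCDValidationError(
                f"phase lengths sum to {sum(self.phase_lengths)} but there are "
                f"{len(self.scores)} scores"
            )

    @property
    def m(self) -> int:
        """Total number of intervention measurements."""
        return len(self.scores)

    @property
    def n_phases(self) -> int:
        return len(self.phase_lengths)


def strip_baseline(series: CCDSeries) -> InterventionSeries:
    """Drop the baseline phase (if any) and extract the intervention layout.

    Raises
    ------
    CCDValidationError
        If fewer than two intervention phases remain — no randomization test
        is possible in that case.
    """
    runs = _phase_runs(series.phase_labels)
    baseline_index = series._baseline_run_index(runs)
    lengths, levels, scores = [], [], []
    for i, (label, start, stop) in enumerate(runs):
        if i == baseline_index:
            continue
        lengths.append(stop - start)
        levels.append(float(series.criteria[start]))
        scores.extend(series.scores[start:stop].tolist())
    if len(lengths) < 2:
        raise CCDValidationError(
            "fewer than two intervention phases: no randomization possible"
        )
    return InterventionSeries(
        scores=tuple(scores),
        phase_lengths=tuple(lengths),
        criterion_levels=tuple(levels),
    )


def read_ccd_table(
    path: str | Path,
    delimiter: str | None = None,
    baseline_label: str | None = None,
) -> CCDSeries:
    """Read a ``Phase,Session,Scores,Criterion`` table into a :class:`CCDSeries`.

    Parameters
    ----------
    path
        Delimited text file with a header row.  Comma is the default
        delimiter; tab-delimited files are detected automatically when
        ``delimiter`` is ``None``.
    delimiter
        Explicit delimiter overriding detection.
    baseline_label
        Explicit phase label to treat as baseline.  By default the first
        phase is baseline iff its Criterion cells are all empty.
    """
    path = Path(path)
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CCDSchemaError(
            f"missing required column(s) {missing!r}; header must contain "
            f"{list(REQUIRED_COLUMNS)!r} (case-sensitive)"
        )
    return CCDSeries(
        phase_labels=df["Phase"].astype(str).tolist(),
        sessions=df["Session"].to_numpy(),
        scores=df["Scores"].to_numpy(dtype=float),
        criteria=pd.to_numeric(df["Criterion"], errors="coerce").to_numpy(dtype=float),
        baseline_label=baseline_label,
    )


def write_ccd_table(series: CCDSeries, path: str | Path, delimiter: str = ",") -> None:
    """Write a series back to the standard four-column layout.

    Baseline criterion cells are written empty, so a round trip through
    :func:`read_ccd_table` reproduces the series exactly.
    """
    series.to_frame().to_csv(path, sep=delimiter, index=False)
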
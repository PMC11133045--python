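import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def brute_force_compositions(m, n_phases, k_min, k_max=None):
    """Independent oracle: all compositions of m into bounded parts, by
    placing phase boundaries with itertools (no shared code with the DP)."""
    if k_max is None:
        k_max = m - (n_phases - 1) * k_min
    out = []
    for cuts in itertools.combinations(range(1, m), n_phases - 1):
        bounds = (0,) + cuts + (m,)
        lengths = tuple(b - a for a, b in zip(bounds, bounds[1:]))
        if all(k_min <= k <= k_max for k in lengths):
            out.append(lengths)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


# Layout mirroring the worked exercise-adherence example: 12 baseline
# occasions then 37 intervention occasions over 10 criterion phases, with
# repeated criterion levels across the five blocks of two.
ANN_PHASE_LENGTHS = (6, 3, 3, 3, 3, 3, 3, 3, 3, 7)
ANN_CRITERIA = (1.0, 2.0, 3.0, 4.0, 3.0, 5.0, 6.0, 7.0, 6.0, 8.0)
ANN_BASELINE_POINTS = 12


def ann_layout_frame(rng=None):
    """A 49-row Phase/Session/Scores/Criterion table with the example layout."""
    if rng is None:
        rng = np.random.default_rng(7)
    labels = ["BL"] * ANN_BASELINE_POINTS
    criteria = [np.nan] * ANN_BASELINE_POINTS
    for i, (k, c) in enumerate(zip(ANN_PHASE_LENGTHS, ANN_CRITERIA)):
        labels += [chr(ord("C") + i)] * k
        criteria += [c] * k
    n = len(labels)
    scores = np.clip(
        np.array([0.5] * ANN_BASELINE_POINTS + list(np.repeat(ANN_CRITERIA, ANN_PHASE_LENGTHS)))
        + rng.normal(0, 0.3, size=n),
        0,
        8,
    )
    return pd.DataFrame(
        {"Phase": labels, "Session": np.arange(1, n + 1), "Scores": scores, "Criterion": criteria}
    )


@pytest.fixture
def ann_table(tmp_path):
    path = tmp_path / "ann.csv"
    ann_layout_frame().to_csv(path, index=False)
    return path
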
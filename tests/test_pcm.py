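import math

import numpy as np
import pytest

from ccdrand import (
    Assignment,
    InterventionSeries,
    PCMDesign,
    count_randomizations,
    enumerate_compositions,
    pcm_test,
    sample_composition,
    sample_compositions,
)
from ccdrand.pcm import InfeasibleDesignError

from conftest import brute_force_compositions


def matched_series(lengths, criteria):
    """Scores exactly equal to their phase criteria: the observed assignment
    is the unique MAD minimiser whenever adjacent criteria differ."""
    scores = tuple(np.repeat(criteria, lengths))
    return InterventionSeries(scores, tuple(lengths), tuple(criteria))


class TestCounting:
    def test_matches_closed_form_when_max_is_nonbinding(self):
        for m, I, k in [(37, 10, 3), (20, 4, 3), (25, 5, 2), (18, 3, 1)]:
            design = PCMDesign(m, I, k)
            assert count_randomizations(design) == math.comb(m - I * k + I - 1, I - 1)

    def test_single_admissible_composition(self):
        assert count_randomizations(PCMDesign(12, 4, 3)) == 1

    def test_binding_maximum_reduces_the_count(self):
        unbounded = count_randomizations(PCMDesign(20, 4, 3))
        bounded = count_randomizations(PCMDesign(20, 4, 3, 6))
        assert bounded == len(brute_force_compositions(20, 4, 3, 6))
        assert bounded < unbounded == 165

    @pytest.mark.parametrize(
        "m, I, k_min, k_max",
        [(11, 4, 3, None), (10, 2, 6, None), (10, 3, 1, 2), (5, 2, 1, 0)],
    )
    def test_infeasible_designs_error(self, m, I, k_min, k_max):
        with pytest.raises(InfeasibleDesignError):
            PCMDesign(m, I, k_min, k_max)


class TestEnumeration:
    def test_lexicographic_order_and_size(self):
        comps = enumerate_compositions(PCMDesign(15, 4, 3, 6))
        assert len(comps) == 20
        assert comps[0] == (3, 3, 3, 6)
        assert comps[-1] == (6, 3, 3, 3)
        assert comps == sorted(comps)
        assert len(set(comps)) == len(comps)

    def test_degenerate_design_enumerates_one_composition(self):
        assert enumerate_compositions(PCMDesign(6, 2, 3)) == [(3, 3)]

    def test_cap_exceeded_points_to_monte_carlo(self):
        with pytest.raises(ValueError, match="Monte Carlo"):
            enumerate_compositions(PCMDesign(40, 8, 3), cap=1000)

    def test_agrees_with_brute_force_on_small_designs(self, rng):
        for _ in range(50):
            I = int(rng.integers(2, 6))
            k = int(rng.integers(1, 5))
            m = int(rng.integers(I * k, 21)) if I * k <= 20 else None
            if m is None:
                continue
            design = PCMDesign(m, I, k)
            assert enumerate_compositions(design) == sorted(
                brute_force_compositions(m, I, k)
            )


class TestSampling:
    def test_forced_composition(self, rng):
        for _ in range(10):
            assert sample_composition(PCMDesign(12, 4, 3), rng) == (3, 3, 3, 3)

    def test_samples_are_admissible(self, rng):
        design = PCMDesign(19, 5, 3, 7)
        draws = sample_compositions(design, 500, rng)
        assert draws.sum(axis=1).tolist() == [19] * 500
        assert draws.min() >= 3 and draws.max() <= 7

    def test_sampling_is_reproducible_for_a_fixed_seed(self):
        design = PCMDesign(30, 5, 3)
        a = sample_compositions(design, 100, np.random.default_rng(5))
        b = sample_compositions(design, 100, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestPCMTest:
    def test_identical_assignments_give_p_one(self):
        # constant scores with all criterion levels equal: every composition
        # yields exactly the same MAD
        series = InterventionSeries((5.0,) * 12, (3, 3, 3, 3), (5.0, 5.0, 5.0, 5.0))
        result = pcm_test(series, design=PCMDesign(12, 4, 1))
        assert result.p_value == 1.0
        assert np.unique(result.reference).size == 1

    def test_unique_minimum_gives_one_over_R(self):
        series = matched_series((3, 4, 5, 3), (15.0, 20.0, 25.0, 30.0))
        result = pcm_test(series, design=PCMDesign(15, 4, 3, 6))
        assert result.n_randomizations == 20
        assert result.observed == 0.0
        assert result.p_value == pytest.approx(1 / 20)

    def test_monte_carlo_includes_observed_in_reference(self):
        series = matched_series((6, 3, 3, 3, 3, 3, 3, 3, 3, 7), tuple(range(1, 11)))
        result = pcm_test(
            series, mode="monte_carlo", mc_samples=200, rng=np.random.default_rng(3)
        )
        assert result.n_randomizations == 201
        assert result.p_value >= 1 / 201
        assert result.p_value <= 3 / 201  # observed MAD 0 is (near-)minimal

    def test_monte_carlo_without_rng_is_an_error(self):
        series = matched_series((3, 3), (1.0, 2.0))
        with pytest.raises(ValueError, match="rng"):
            pcm_test(series, mode="monte_carlo")

    def test_inadmissible_observed_lengths_error(self):
        series = matched_series((2, 13), (1.0, 2.0))
        with pytest.raises(ValueError, match="not admissible"):
            pcm_test(series, k_min=3)

    def test_systematic_above_cap_is_an_error(self):
        series = matched_series((5,) * 8, tuple(range(8)))
        with pytest.raises(ValueError, match="Monte Carlo"):
            pcm_test(series, cap=100)
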
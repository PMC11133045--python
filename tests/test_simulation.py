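import numpy as np
import pytest

from ccdrand import (
    Assignment,
    SimulationCondition,
    build_criteria,
    build_phase_lengths,
    estimate_rejection_rate,
    generate_ar1,
    generate_effect_series,
    generate_null_series,
    run_condition_grid,
)
from ccdrand.simulation import null_level


class TestCriteriaStaircase:
    def test_plain_staircase(self):
        assert build_criteria(4, 10, 5) == (15, 20, 25, 30)

    def test_mini_reversal_steps_back_then_resumes(self):
        assert build_criteria(4, 10, 5, reversal=True) == (15, 20, 15, 25)
        assert build_criteria(6, 10, 5, reversal=True) == (15, 20, 25, 30, 25, 35)

    def test_zero_increment_gives_constant_criteria(self):
        assert build_criteria(3, 10, 0) == (10, 10, 10)

    def test_reversal_needs_four_phases(self):
        with pytest.raises(ValueError, match="four"):
            build_criteria(3, 10, 5, reversal=True)


class TestPhaseLengthPatterns:
    @pytest.mark.parametrize(
        "I, m, pattern, expected",
        [
            (4, 16, "uniform", (4, 4, 4, 4)),
            (4, 20, "increasing", (3, 5, 6, 6)),
            (5, 19, "triangular", (3, 4, 5, 4, 3)),
            (5, 15, "triangular", (3, 3, 3, 3, 3)),
        ],
    )
    def test_documented_patterns(self, I, m, pattern, expected):
        assert build_phase_lengths(I, m, pattern) == expected

    def test_uniform_requires_divisibility(self):
        with pytest.raises(ValueError, match="divide"):
            build_phase_lengths(4, 18, "uniform")

    def test_too_short_series_is_an_error(self):
        with pytest.raises(ValueError, match="at least 3"):
            build_phase_lengths(5, 14)

    @pytest.mark.parametrize("pattern", ["increasing", "triangular"])
    @pytest.mark.parametrize("I", [3, 4, 5, 6, 7])
    @pytest.mark.parametrize("m_extra", [0, 1, 5, 11])
    def test_patterns_respect_sum_and_minimum(self, pattern, I, m_extra):
        m = 3 * I + m_extra
        lengths = build_phase_lengths(I, m, pattern)
        assert sum(lengths) == m
        assert min(lengths) >= 3
        if pattern == "increasing":
            assert list(lengths) == sorted(lengths)
        else:
            mid = (I - 1) // 2
            assert lengths[mid] == max(lengths)
            assert lengths[0] <= lengths[mid] and lengths[-1] <= lengths[mid]


class TestAR1:
    def test_zero_phi_is_iid_standard_normal(self, rng):
        z = generate_ar1(100_000, 0.0, rng)
        assert np.var(z) == pytest.approx(1.0, abs=0.02)
        assert np.corrcoef(z[:-1], z[1:])[0, 1] == pytest.approx(0.0, abs=0.02)

    def test_positive_phi_has_matching_lag1_autocorrelation(self, rng):
        z = generate_ar1(100_000, 0.3, rng)
        assert np.corrcoef(z[:-1], z[1:])[0, 1] == pytest.approx(0.3, abs=0.02)
        assert np.var(z) == pytest.approx(1.0, abs=0.02)

    def test_negative_phi_is_stationary_with_unit_variance(self, rng):
        z = generate_ar1(100_000, -0.3, rng)
        assert np.var(z) == pytest.approx(1.0, abs=0.02)
        assert np.corrcoef(z[:-1], z[1:])[0, 1] == pytest.approx(-0.3, abs=0.02)

    @pytest.mark.parametrize("phi", [1.0, -1.0, 1.5])
    def test_nonstationary_phi_is_an_error(self, rng, phi):
        with pytest.raises(ValueError, match="phi"):
            generate_ar1(10, phi, rng)


class TestSeriesGenerators:
    def condition(self, **kw):
        defaults = dict(procedure="bac", n_phases=4, phase_length=3, variability=0.10, phi=0.0)
        defaults.update(kw)
        return SimulationCondition(**defaults)

    def test_zero_variability_reproduces_criteria_exactly(self, rng):
        series = generate_effect_series(self.condition(variability=0.0), rng)
        np.testing.assert_array_equal(
            np.asarray(series.scores),
            Assignment(series.phase_lengths, series.criterion_levels).criterion_profile(),
        )

    def test_effect_noise_scale_tracks_criterion_elevation(self, rng):
        # per-phase sample SD over many replicates matches
        # variability * (criterion - baseline)
        cond = self.condition(variability=0.10)
        reps = 10_000
        draws = np.array([generate_effect_series(cond, rng).scores for _ in range(reps)])
        profile = Assignment(cond.resolved_lengths(), cond.criteria()).criterion_profile()
        sd = draws.std(axis=0)
        np.testing.assert_allclose(sd, 0.10 * (profile - 10.0), rtol=0.03)
        # unbiased around the criterion levels
        np.testing.assert_allclose(draws.mean(axis=0), profile, atol=0.05)

    @pytest.mark.parametrize(
        "criteria, lengths, expected",
        [((5.0, 10.0, 15.0, 20.0), (3, 3, 3, 3), 12.5), ((15.0, 20.0), (3, 1), 16.25)],
    )
    def test_null_level_is_length_weighted_average(self, criteria, lengths, expected):
        assert null_level(Assignment(lengths, criteria)) == pytest.approx(expected)

    def test_zero_variability_null_series_is_constant_at_weighted_average(self, rng):
        cond = self.condition(variability=0.0, effect=False)
        series = generate_null_series(cond, rng)
        L = null_level(Assignment(cond.resolved_lengths(), cond.criteria()))
        np.testing.assert_array_equal(np.asarray(series.scores), np.full(12, L))

    def test_null_level_ignores_the_realised_assignment(self, rng):
        # the no-effect data level is a property of the condition, not of the
        # per-replicate randomization (otherwise exact validity breaks)
        cond = SimulationCondition(
            procedure="pcm", n_phases=2, phase_length=5, variability=0.0, effect=False
        )
        skew = Assignment((7, 3), cond.criteria())
        series = generate_null_series(cond, rng, assignment=skew)
        L = null_level(Assignment((5, 5), cond.criteria()))
        assert series.phase_lengths == (7, 3)
        np.testing.assert_array_equal(np.asarray(series.scores), np.full(10, L))


class TestRejectionRates:
    def test_zero_variability_effect_is_always_detected(self):
        cond = SimulationCondition(
            procedure="pcm",
            n_phases=4,
            phase_lengths=(3, 4, 5, 3),
            variability=0.0,
            replications=50,
        )
        est = estimate_rejection_rate(cond, np.random.default_rng(0))
        assert est.n_randomizations >= 20
        assert est.rejection_rate == 1.0

    def test_grid_runs_and_echoes_conditions(self):
        conds = [
            SimulationCondition(procedure="bac", n_phases=10, phase_length=3, replications=20),
            SimulationCondition(procedure="pcm", n_phases=4, phase_length=4, replications=20),
        ]
        table = run_condition_grid(conds, seed=3)
        assert len(table) == 2
        assert table["procedure"].tolist() == ["bac", "pcm"]
        assert table["n_randomizations"].tolist() == [32, 35]
        assert ((table["rate"] >= 0) & (table["rate"] <= 1)).all()

    def test_grid_is_deterministic_given_the_master_seed(self):
        conds = [
            SimulationCondition(procedure="bac", n_phases=10, phase_length=3, replications=50),
            SimulationCondition(
                procedure="pcm", n_phases=4, phase_length=4, replications=50, randomize_actual=True
            ),
        ]
        a = run_condition_grid(conds, seed=42)
        b = run_condition_grid(conds, seed=42)
        assert a.equals(b)

    def test_invalid_condition_is_named_by_index(self):
        good = SimulationCondition(procedure="bac", n_phases=10, phase_length=3, replications=10)
        bad = SimulationCondition(procedure="bac", n_phases=5, phase_length=3, replications=10)
        with pytest.raises(ValueError, match="condition 1"):
            run_condition_grid([good, bad], seed=0)

    def test_monte_carlo_reference_used_above_systematic_limit(self):
        cond = SimulationCondition(
            procedure="pcm",
            n_phases=7,
            phase_length=6,  # m = 42, beyond the systematic limit of 36
            variability=0.0,
            replications=5,
            mc_samples=200,
        )
        est = estimate_rejection_rate(cond, np.random.default_rng(1))
        assert est.rejection_rate == 1.0
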
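"""Unit tests for the stochastic branching engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clonesim import (
    GrowthOutcome,
    ModelParams,
    PopulationState,
    TreatmentPolicy,
    birth_death_probs,
    critical_intensity,
    fitness,
    grow_to_size,
    outcome_probs,
    resect,
    step,
)


class TestFitness:
    @pytest.mark.parametrize(
        "i, j, sigma, s, c, expected",
        [
            (0, 0, 0.0, 0.004, 0.001, 0.004),   # founder driver only
            (0, 1, 0.02, 0.004, 0.001, 0.003),  # resistant: sigma drops out, pays c
            (1, 0, 0.008, 0.004, 0.001, 0.0),   # 2s - sigma balance point
        ],
    )
    def test_formula(self, i, j, sigma, s, c, expected):
        p = ModelParams(driver_advantage=s, resistance_cost=c, max_extra_drivers=5)
        assert fitness(i, j, sigma, p) == pytest.approx(expected)

    def test_resistant_fitness_independent_of_sigma(self, params5):
        values = {fitness(2, 1, sig, params5) for sig in (0.0, 0.004, 0.02, 0.1)}
        assert len(values) == 1

    def test_invalid_arguments(self, params5):
        with pytest.raises(ValueError):
            fitness(params5.max_extra_drivers + 1, 0, 0.0, params5)
        with pytest.raises(ValueError):
            fitness(-1, 0, 0.0, params5)
        with pytest.raises(ValueError):
            fitness(0, 0, -0.01, params5)
        with pytest.raises(ValueError):
            fitness(0, 2, 0.0, params5)


class TestBirthDeath:
    @pytest.mark.parametrize(
        "f, b, d",
        [(0.0, 0.5, 0.5), (0.004, 0.502, 0.498), (-1.0, 0.0, 1.0)],
    )
    def test_split(self, f, b, d):
        got_b, got_d = birth_death_probs(f)
        assert got_b == pytest.approx(b)
        assert got_d == pytest.approx(d)
        assert got_b + got_d == pytest.approx(1.0)

    def test_clips_with_warning(self):
        with pytest.warns(RuntimeWarning):
            b, d = birth_death_probs(1.5)
        assert (b, d) == (1.0, 0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            birth_death_probs(float("nan"))


class TestOutcomeProbs:
    def test_lattice_corner_has_no_mutation(self, params5):
        probs = outcome_probs(params5.max_extra_drivers, 1, 0.0, params5)
        assert probs.p_div_driver == 0.0
        assert probs.p_div_resist == 0.0
        assert sum(probs) == pytest.approx(1.0)

    def test_driver_division_probability(self, params5):
        # b * u with b = (1 + s)/2 at the untreated baseline
        probs = outcome_probs(0, 0, 0.0, params5)
        assert probs.p_div_driver == pytest.approx(0.502 * 3.4e-5)

    def test_mutation_free_reduction(self):
        p = ModelParams(max_extra_drivers=3, driver_mut_rate=0.0, resistance_mut_rate=0.0)
        probs = outcome_probs(1, 0, 0.006, p)
        b, d = birth_death_probs(fitness(1, 0, 0.006, p))
        assert probs.p_div_plain == pytest.approx(b)
        assert probs.p_death == pytest.approx(d)

    def test_mutation_rates_bounded(self):
        with pytest.raises(ValueError):
            ModelParams(driver_mut_rate=0.7, resistance_mut_rate=0.5)


class TestStep:
    def test_expected_growth_factor(self, params5):
        """Mean one-step total over 10^3 trials matches 1e6 * (1 + s)
        within 3 standard errors."""
        rng = np.random.default_rng(42)
        policy = TreatmentPolicy.none()
        totals = np.empty(1000)
        for k in range(1000):
            state = PopulationState.uniform_lesion(params5, 10**6)
            totals[k] = step(state, policy, params5, rng).total
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - 10**6 * 1.004) < 3 * se

    def test_no_mutation_stays_in_subclone(self, rng):
        p = ModelParams(max_extra_drivers=4, driver_mut_rate=0.0, resistance_mut_rate=0.0)
        state = PopulationState.empty(p)
        state.counts[2, 0] = 5000
        nxt = step(state, TreatmentPolicy.none(), p, rng)
        occupied = np.argwhere(nxt.counts > 0)
        assert all((i, j) == (2, 0) for i, j in occupied)
        assert nxt.step_index == 1

    def test_fate_frequencies_match_probabilities(self):
        """Aggregate fates of 10^5 independent cells pass a chi-square
        goodness-of-fit test at alpha = 0.001.

        Mutation rates are boosted so every fate category has a large
        expected count; the fates are recovered exactly from the next
        state because each fate writes to a distinct subclone.
        """
        from scipy.stats import chisquare

        p = ModelParams(max_extra_drivers=2, driver_mut_rate=0.05, resistance_mut_rate=0.03)
        n = 100_000
        state = PopulationState.empty(p)
        state.counts[0, 0] = n
        rng = np.random.default_rng(7)
        nxt = step(state, TreatmentPolicy.none(), p, rng)
        drivers = nxt.counts[1, 0]
        resists = nxt.counts[0, 1]
        plain = (nxt.counts[0, 0] - drivers - resists) // 2
        deaths = n - plain - drivers - resists
        probs = outcome_probs(0, 0, 0.0, p)
        expected = np.array(probs) * n
        stat = chisquare([deaths, plain, drivers, resists], expected)
        assert stat.pvalue > 0.001

    def test_no_back_mutation(self, rng):
        p = ModelParams(max_extra_drivers=3, resistance_mut_rate=0.0)
        state = PopulationState.uniform_lesion(p, 10**4)
        for _ in range(200):
            state = step(state, TreatmentPolicy.constant(0.002), p, rng)
        assert state.counts[:, 1].sum() == 0

    def test_counts_stay_integral_nonnegative(self, params5, rng):
        state = PopulationState.uniform_lesion(params5, 12345, 7)
        for _ in range(50):
            state = step(state, TreatmentPolicy.constant(0.01), params5, rng)
            assert state.counts.dtype == np.int64
            assert (state.counts >= 0).all()

    def test_fixed_seed_bit_reproducible(self, params5):
        def run(seed):
            rng = np.random.default_rng(seed)
            state = PopulationState.uniform_lesion(params5, 10**5, 10)
            for _ in range(100):
                state = step(state, TreatmentPolicy.constant(0.006), params5, rng)
            return state.counts

        assert np.array_equal(run(99), run(99))
        assert not np.array_equal(run(99), run(100))


class TestGrowToSize:
    def test_start_at_target_is_identity(self, params5, rng):
        state = PopulationState.uniform_lesion(params5, 1000)
        res = grow_to_size(state, 1000, TreatmentPolicy.none(), params5, rng)
        assert res.outcome is GrowthOutcome.REACHED
        assert res.steps == 0
        assert np.array_equal(res.state.counts, state.counts)

    def test_extinction_probability_single_founder(self, params_single):
        """Survival of a supercritical single-type process: the classic
        d/b = (1 - s)/(1 + s) extinction probability, checked against a
        brute-force replicate count within a 4-sigma binomial band."""
        rng = np.random.default_rng(2024)
        n = 10_000
        extinct = 0
        for _ in range(n):
            start = PopulationState.single_cell(params_single)
            res = grow_to_size(start, 10**4, TreatmentPolicy.none(), params_single, rng)
            extinct += res.outcome is GrowthOutcome.EXTINCT
        q = (1 - 0.004) / (1 + 0.004)
        se = np.sqrt(q * (1 - q) / n)
        assert abs(extinct / n - q) < 4 * se

    def test_deterministic_growth_time(self, params_single, rng):
        """Large-population growth is essentially deterministic:
        1e6 -> 1e9 untreated in ~ln(1000)/ln(1.004) = 1731 steps."""
        for _ in range(3):
            state = PopulationState.uniform_lesion(params_single, 10**6)
            res = grow_to_size(state, 10**9, TreatmentPolicy.none(), params_single, rng)
            assert res.outcome is GrowthOutcome.REACHED
            assert abs(res.steps - 1731) <= 6
            assert params_single.years(res.steps) == pytest.approx(18.97, abs=0.1)

    def test_horizon_distinct_from_extinction(self, params_single, rng):
        state = PopulationState.uniform_lesion(params_single, 10**6)
        res = grow_to_size(state, 10**9, TreatmentPolicy.none(), params_single, rng, max_steps=10)
        assert res.outcome is GrowthOutcome.HORIZON
        assert res.steps == 10
        assert res.state.total > 0

    def test_checkpoints_record_resistant_counts(self, params5, rng):
        state = PopulationState.uniform_lesion(params5, 10**5, 50)
        res = grow_to_size(
            state, 10**9, TreatmentPolicy.none(), params5, rng,
            max_steps=20, checkpoint_steps=(0, 10),
        )
        assert set(res.checkpoints) == {0, 10}
        assert res.checkpoints[0] == 50


class TestResect:
    def test_full_residual_is_identity(self, params5, rng):
        state = PopulationState.uniform_lesion(params5, 5000, 500)
        out = resect(state, 5000, rng)
        assert np.array_equal(out.counts, state.counts)

    def test_single_subclone(self, params5, rng):
        state = PopulationState.uniform_lesion(params5, 10**6)
        out = resect(state, 10**3, rng)
        assert out.counts[0, 0] == 10**3
        assert out.total == 10**3

    def test_residual_exceeding_total_rejected(self, params5, rng):
        state = PopulationState.uniform_lesion(params5, 100)
        with pytest.raises(ValueError):
            resect(state, 101, rng)

    def test_proportions_conserved_in_expectation(self, params5):
        """90/10 two-subclone tumour resected to 1e4 cells: the mean
        minority fraction over 10^3 trials is 0.10 within 3 SE, and the
        total is conserved exactly every time."""
        rng = np.random.default_rng(11)
        state = PopulationState.empty(params5)
        state.counts[0, 0] = 900_000
        state.counts[3, 1] = 100_000
        fracs = np.empty(1000)
        for k in range(1000):
            out = resect(state, 10**4, rng)
            assert out.total == 10**4
            fracs[k] = out.counts[3, 1] / 10**4
        se = fracs.std(ddof=1) / np.sqrt(len(fracs))
        assert abs(fracs.mean() - 0.10) < 3 * se


@pytest.mark.parametrize("n, s, expected", [(5, 0.004, 0.024), (0, 0.004, 0.004), (9, 0.004, 0.04)])
def test_critical_intensity(n, s, expected):
    p = ModelParams(max_extra_drivers=n, driver_advantage=s)
    assert critical_intensity(p) == pytest.approx(expected)


class TestPolicy:
    def test_metronomic_trigger(self, params5):
        pol = TreatmentPolicy.metronomic(0.01)
        mostly_sensitive = PopulationState.uniform_lesion(params5, 1000, 10)
        mostly_resistant = PopulationState.uniform_lesion(params5, 1000, 990)
        assert pol.sigma_at(mostly_sensitive) == 0.01
        assert pol.sigma_at(mostly_resistant) == 0.0

    def test_none_is_zero_constant(self, params5):
        state = PopulationState.uniform_lesion(params5, 10)
        assert TreatmentPolicy.none().sigma_at(state) == 0.0
        with pytest.raises(ValueError):
            TreatmentPolicy("none", 0.01)
        with pytest.raises(ValueError):
            TreatmentPolicy.constant(-0.1)


class TestState:
    def test_validation(self):
        with pytest.raises(ValueError):
            PopulationState(np.array([[1, -1]]))
        with pytest.raises(ValueError):
            PopulationState(np.zeros((3, 3)))

    def test_mean_drivers_weighted(self, params5):
        state = PopulationState.empty(params5)
        state.counts[1, 0] = 100
        state.counts[3, 1] = 300
        assert state.mean_drivers() == pytest.approx(2.5)
        assert state.resistant_fraction == pytest.approx(0.75)

    def test_snapshot_dataframe_schema(self, params5):
        df = PopulationState.uniform_lesion(params5, 10, 1).to_dataframe()
        assert list(df.columns) == ["step", "i", "j", "count"]
        assert df["count"].sum() == 10


@settings(derandomize=True, max_examples=30)
@given(
    counts=st.lists(st.integers(0, 10**6), min_size=12, max_size=12),
    residual_frac=st.floats(0.0, 1.0),
    seed=st.integers(0, 2**31 - 1),
)
def test_resect_total_exact_property(counts, residual_frac, seed):
    """Resection returns exactly the requested residual for any
    composition and any residual size up to the total."""
    p = ModelParams(max_extra_drivers=5)
    state = PopulationState(np.array(counts, dtype=np.int64).reshape(6, 2))
    total = state.total
    if total == 0:
        return
    residual = int(residual_frac * total)
    out = resect(state, residual, np.random.default_rng(seed))
    assert out.total == residual
    assert (out.counts <= state.counts + residual).all()
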
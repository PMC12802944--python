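import numpy as np
import pytest
from scipy import stats

from ecdsb.dsb import SimulationConfig, simulate_population, window_hit_probability
from ecdsb.population import (
    expand_table_to_cells,
    generate_pseudo_experiment,
    generate_untreated_population,
    make_frequency_table,
)
from ecdsb.survival import (
    CleavageSelectionModel,
    apply_survival,
    expected_condition_summary,
    expected_survivor_weights,
    fit_threshold_and_frequency,
    summarize_population,
    survival_probability,
)


@pytest.fixture(scope="module")
def midpoint_pop():
    """Midpoint-quantized initial population (the histogram-defined start)."""
    raw = generate_untreated_population(2000, seed=31)
    return expand_table_to_cells(make_frequency_table(raw, scale_factor=1))


class TestSurvivalProbability:
    @pytest.mark.parametrize(
        "cp1,Mt,expected",
        [(0, 33, 1.0), (33, 33, 0.0), (50, 33, 0.0), (11, 33, 2 / 3), (1, 1, 0.0)],
    )
    def test_linear_decline_values(self, cp1, Mt, expected):
        assert survival_probability(cp1, Mt) == pytest.approx(expected)

    def test_monotone_in_dsb_count_and_threshold(self):
        cp = np.arange(0, 120)
        p33 = survival_probability(cp, 33)
        p50 = survival_probability(cp, 50)
        assert (np.diff(p33) <= 0).all()
        assert (p50 >= p33).all()
        assert ((p33 >= 0) & (p33 <= 1)).all()

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            survival_probability(-1, 33)
        with pytest.raises(ValueError):
            survival_probability(5, 0)


class TestApplySurvival:
    def test_lethal_everyone(self):
        recs = simulate_population(
            [200] * 50, SimulationConfig(binding_frequency=10_000, seed=1)
        )
        surv = apply_survival(recs, 33, "bernoulli", np.random.default_rng(1))
        assert len(surv.records) == 0

    def test_threshold_far_above_damage_spares_everyone(self):
        recs = simulate_population(
            [20] * 200, SimulationConfig(binding_frequency=40, seed=2)
        )
        bern = apply_survival(recs, 10_000, "bernoulli", np.random.default_rng(2))
        assert len(bern.records) == len(recs)
        expw = apply_survival(recs, 10_000, "expected_weight")
        assert (expw.weights > 0.99).all()

    def test_high_activity_depletes_high_copy_cells(self, untreated_4k):
        """At f=770 nearly every copy is cut, so survivors sit below ~Mt copies."""
        recs = simulate_population(
            untreated_4k, SimulationConfig(binding_frequency=770, seed=3)
        )
        surv = apply_survival(recs, 33, "bernoulli", np.random.default_rng(3))
        assert 0 < len(surv.records) < len(recs)
        assert surv.copy_numbers.max() < 45
        assert surv.copy_numbers.mean() < untreated_4k.copy_numbers.mean()


class TestSummaries:
    def test_no_selection_identity(self, untreated_4k):
        recs = simulate_population(
            untreated_4k, SimulationConfig(binding_frequency=3, seed=4)
        )
        surv = apply_survival(recs, 10_000, "bernoulli", np.random.default_rng(4))
        summary = summarize_population(surv, initial_size=len(recs))
        assert summary.surviving_fraction == pytest.approx(1.0)
        original = make_frequency_table(untreated_4k, scale_factor=1)
        np.testing.assert_array_equal(summary.table.counts, original.counts)

    def test_empty_survivors_flagged(self):
        recs = simulate_population(
            [200] * 20, SimulationConfig(binding_frequency=10_000, seed=5)
        )
        surv = apply_survival(recs, 5, "bernoulli", np.random.default_rng(5))
        summary = summarize_population(surv, initial_size=20)
        assert summary.surviving_fraction == 0.0
        assert np.isnan(summary.mean_copy_number)

    def test_expected_and_bernoulli_agree_at_large_n(self, untreated_10k):
        recs = simulate_population(
            untreated_10k, SimulationConfig(binding_frequency=170, seed=6)
        )
        expw = summarize_population(
            apply_survival(recs, 33, "expected_weight"), initial_size=len(recs)
        )
        bern = summarize_population(
            apply_survival(recs, 33, "bernoulli", np.random.default_rng(6)),
            initial_size=len(recs),
        )
        # surviving fraction is a mean of 10^4 Bernoullis: 4 SE tolerance
        se = np.sqrt(expw.surviving_fraction / len(recs))
        assert abs(expw.surviving_fraction - bern.surviving_fraction) < 4 * se
        assert expw.mean_copy_number == pytest.approx(bern.mean_copy_number, rel=0.1)

    def test_mean_survivor_copies_decrease_with_activity(self, midpoint_pop):
        means = [
            expected_condition_summary(midpoint_pop, f, 33).mean_copy_number
            for f in (3, 30, 40, 170, 770)
        ]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_analytic_forward_matches_simulated_expectation(self, midpoint_pop):
        """Dual route: closed-form binomial expectation vs simulate+reweight."""
        f, Mt = 170, 33
        analytic = expected_condition_summary(midpoint_pop, f, Mt)
        recs = simulate_population(
            midpoint_pop, SimulationConfig(binding_frequency=f, seed=7)
        )
        mc = summarize_population(
            apply_survival(recs, Mt, "expected_weight"), initial_size=len(recs)
        )
        assert mc.surviving_fraction == pytest.approx(
            analytic.surviving_fraction, rel=0.05
        )
        assert mc.mean_copy_number == pytest.approx(
            analytic.mean_copy_number, rel=0.05
        )

    def test_expected_weight_matches_binomial_sum(self):
        """Spot-check the closed-form weight against an explicit pmf sum."""
        f, Mt, n = 40, 33, 60
        p = window_hit_probability(f, 100)
        direct = sum(
            stats.binom.pmf(d, n, p) * (1 - d / Mt) for d in range(0, Mt + 1)
        )
        w = expected_survivor_weights(np.array([n]), f, Mt)[0]
        assert w == pytest.approx(direct, abs=1e-12)


class TestGridFit:
    def test_self_consistency_zero_ssr_at_truth(self, midpoint_pop):
        exp = generate_pseudo_experiment(
            midpoint_pop, 33, {"[0C]": 770, "[10C]": 40}, seed=8, mode="analytic"
        )
        res = fit_threshold_and_frequency(exp)
        assert res.ssr_surface.loc[33, 770] == pytest.approx(0.0, abs=1e-18)
        assert res.best_Mt == 33
        assert res.f_by_condition == {"[0C]": 770, "[10C]": 40}

    def test_recovery_from_noisy_observations(self, midpoint_pop):
        exp = generate_pseudo_experiment(
            midpoint_pop, 33, {"[0C]": 770, "[5C]": 170, "[10C]": 40},
            seed=9, mode="bernoulli",
        )
        res = fit_threshold_and_frequency(exp)
        assert abs(res.best_Mt - 33) <= 2
        # high-f likelihood is flat: accept a factor-2 band around 770
        assert 385 <= res.f_by_condition["[0C]"] <= 1540
        assert res.f_by_condition["[10C]"] == 40

    def test_threshold_stable_across_high_activity_truths(self, midpoint_pop):
        """Fitted Mt barely moves while the true f spans the efficient regime."""
        fitted = []
        for f_true in (300, 770, 2000):
            exp = generate_pseudo_experiment(
                midpoint_pop, 33, {"ref": f_true}, seed=10, mode="analytic"
            )
            fitted.append(fit_threshold_and_frequency(exp).best_Mt)
        assert max(fitted) - min(fitted) <= 2

    def test_fitted_f_preserves_condition_ordering(self, midpoint_pop):
        truth = {"c1": 500, "c2": 170, "c3": 40, "c4": 10}
        exp = generate_pseudo_experiment(
            midpoint_pop, 33, truth, seed=12, mode="bernoulli"
        )
        res = fit_threshold_and_frequency(exp)
        fitted = [res.f_by_condition[c] for c in ("c1", "c2", "c3", "c4")]
        assert all(a > b for a, b in zip(fitted, fitted[1:]))

    def test_summary_reports_fit(self, midpoint_pop):
        exp = generate_pseudo_experiment(
            midpoint_pop, 33, {"[0C]": 770}, seed=13, mode="analytic"
        )
        res = fit_threshold_and_frequency(exp)
        text = res.summary()
        assert "lethal threshold" in text and "770" in text

    def test_mismatched_binning_rejected(self, midpoint_pop):
        from ecdsb.population import PopulationFrequencyTable

        t5 = PopulationFrequencyTable(
            bin_width=5, bin_edges=np.array([0, 5, 10]), counts=np.array([1.0, 1.0])
        )
        t10 = PopulationFrequencyTable(
            bin_width=10, bin_edges=np.array([0, 10]), counts=np.array([2.0])
        )
        with pytest.raises(ValueError):
            CleavageSelectionModel({"a": t5, "b": t10}, midpoint_pop)
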
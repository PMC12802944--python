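import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecdsb.dsb import CellDSBRecord
from ecdsb.knockin import (
    DynamicsConfig,
    KnockinCellState,
    KnockinPopulation,
    classify_groups,
    convert_isolated_to_knockin,
    run_dynamics,
    segregate_cell,
    selection_probability_tetO,
    step_generation,
)


def spaced_records(n_cells, copies_per_cell=17, spacing=6, window=100):
    """Cells whose DSB frames are all >=6 frames apart: every cut copy is an
    isolated single under the default 5-frame neighborhood."""
    frames = np.arange(1, window + 1, spacing)[:copies_per_cell]
    return [
        CellDSBRecord(
            copy_number=copies_per_cell,
            dsb_frames=frames.copy(),
            sampling_window=window,
        )
        for _ in range(n_cells)
    ]


class TestSelectionPressure:
    @pytest.mark.parametrize(
        "cp2,expected",
        [(0, 0.45), (6, 0.65), (30, 0.85), (35, 0.85), (100, 0.85), (12, 0.70)],
    )
    def test_piecewise_values(self, cp2, expected):
        assert selection_probability_tetO(cp2) == pytest.approx(expected)

    def test_continuity_at_breakpoints(self):
        for edge in (6.0, 30.0):
            below = selection_probability_tetO(edge - 1e-9)
            above = selection_probability_tetO(edge + 1e-9)
            assert below == pytest.approx(above, abs=1e-6)

    def test_bounded_and_monotone(self):
        cp2 = np.arange(0, 200)
        p = selection_probability_tetO(cp2)
        assert ((p >= 0.45) & (p <= 0.85)).all()
        assert (np.diff(p) >= 0).all()

    def test_alternative_plateau_keeps_shape(self):
        """The robustness variant (plateau 0.80) stays continuous and monotone."""
        cp2 = np.arange(0, 100)
        p = selection_probability_tetO(cp2, plateau=0.80)
        assert ((p >= 0.45) & (p <= 0.80)).all()
        assert (np.diff(p) >= -1e-12).all()
        assert selection_probability_tetO(30, plateau=0.80) == pytest.approx(0.80)

    def test_negative_copy_number_rejected(self):
        with pytest.raises(ValueError):
            selection_probability_tetO(-1)


class TestConversion:
    def test_rate_zero_and_one(self):
        recs = spaced_records(50)
        rng = np.random.default_rng(0)
        zero = convert_isolated_to_knockin(recs, 0.0, rng)
        assert (zero.population.n_ki == 0).all()
        one = convert_isolated_to_knockin(recs, 1.0, rng)
        assert (one.population.n_ki == 17).all()

    def test_total_copies_conserved(self):
        recs = spaced_records(100)
        res = convert_isolated_to_knockin(recs, 0.5, np.random.default_rng(1))
        np.testing.assert_array_equal(res.population.total, 17)

    def test_realized_rate_converges(self):
        """>=10^4 eligible copies realize the 20.6% rate within 3 SE."""
        recs = spaced_records(700)  # 700 x 17 = 11900 eligible
        res = convert_isolated_to_knockin(recs, 0.206, np.random.default_rng(2))
        assert res.n_eligible >= 10_000
        se = np.sqrt(0.206 * (1 - 0.206) / res.n_eligible)
        assert abs(res.realized_rate - 0.206) < 3 * se

    def test_non_isolated_copies_stay_plain(self):
        # all copies co-cut at one frame -> category "multiple" -> no knock-in
        rec = CellDSBRecord(
            copy_number=10, dsb_frames=np.full(10, 20), sampling_window=100
        )
        res = convert_isolated_to_knockin([rec], 1.0, np.random.default_rng(3))
        assert res.n_eligible == 0
        assert (res.population.n_ki == 0).all()


class TestSegregation:
    def test_empty_cell(self):
        d1, d2 = segregate_cell(KnockinCellState(0, 0), np.random.default_rng(0))
        assert d1.total == d2.total == 0

    @given(n_wt=st.integers(0, 200), n_ki=st.integers(0, 200), seed=st.integers(0, 999))
    @settings(max_examples=80, deadline=None)
    def test_per_class_conservation(self, n_wt, n_ki, seed):
        cell = KnockinCellState(n_wt, n_ki)
        d1, d2 = segregate_cell(cell, np.random.default_rng(seed))
        assert d1.n_wt + d2.n_wt == 2 * n_wt
        assert d1.n_ki + d2.n_ki == 2 * n_ki

    def test_binomial_moments(self):
        """Daughter n_ki over 10^4 segregations: mean n, variance 2n/4."""
        rng = np.random.default_rng(4)
        draws = np.array(
            [segregate_cell(KnockinCellState(0, 10), rng)[0].n_ki for _ in range(10_000)]
        )
        assert draws.mean() == pytest.approx(10, abs=0.15)
        assert draws.var() == pytest.approx(5, rel=0.1)


class TestGenerations:
    def test_sample_size_honored(self):
        pop = KnockinPopulation(np.full(100, 40), np.full(100, 5))
        nxt = step_generation(pop, "neutral", 333, np.random.default_rng(5))
        assert len(nxt) == 333

    def test_plateau_survival_rate(self):
        """All cells above cp2=30: daughters survive at the 0.85 plateau."""
        pop = KnockinPopulation(np.zeros(2000, dtype=int), np.full(2000, 80))
        rng = np.random.default_rng(6)
        from ecdsb.knockin import _segregate_all, selection_probability_tetO

        daughters = _segregate_all(pop, rng)
        p = selection_probability_tetO(daughters.n_ki)
        assert p.mean() == pytest.approx(0.85, abs=1e-6)

    def test_extinction_raises_diagnostic(self):
        pop = KnockinPopulation(np.array([5]), np.array([0]))
        seen = False
        for seed in range(200):
            try:
                step_generation(pop, "blasticidin_eq", 10, np.random.default_rng(seed))
            except RuntimeError as err:
                assert "extinct" in str(err)
                seen = True
                break
        assert seen, "no extinction among 200 seeds for a single low-KI cell"

    def test_neutral_drift_preserves_mean_copy_number(self):
        rng = np.random.default_rng(7)
        n_wt = rng.integers(20, 150, size=4000)
        pop = KnockinPopulation(n_wt, np.zeros(4000, dtype=int))
        config = DynamicsConfig(
            sample_size=4000, iterations=10, runs=5, selection="neutral", seed=8
        )
        result = run_dynamics(pop, config)
        traj = result.trajectories.query("scheme == 'four' and group == 1")
        start = traj.query("iteration == 0")["mean_total"].mean()
        end = traj.query("iteration == 10")["mean_total"].mean()
        assert abs(end - start) / start < 0.05


class TestGrouping:
    def test_six_group_examples(self):
        pop = KnockinPopulation(
            np.array([40, 12, 10, 0]), np.array([0, 18, 0, 0])
        )
        labels = classify_groups(pop, "six")
        # (40,0): <10% KI, >=25 copies -> 2; (12,18): 60% KI, 30 copies -> 6
        # (10,0): both low -> 1; empty cell -> 0 (unclassifiable)
        np.testing.assert_array_equal(labels, [2, 6, 1, 0])

    def test_boundaries_go_to_upper_band(self):
        pop = KnockinPopulation(np.array([25, 18, 5]), np.array([0, 2, 5]))
        labels = classify_groups(pop, "six")
        # 25 copies -> high band; 2/20 = 10% KI -> middle band; 5/10 = 50% -> top
        np.testing.assert_array_equal(labels, [2, 3, 5])

    def test_four_group_scheme(self):
        pop = KnockinPopulation(
            np.array([30, 30, 4, 4]), np.array([0, 31, 0, 6])
        )
        labels = classify_groups(pop, "four")
        np.testing.assert_array_equal(labels, [2, 4, 1, 3])

    def test_every_nonempty_cell_labeled_once(self):
        rng = np.random.default_rng(9)
        pop = KnockinPopulation(
            rng.integers(0, 60, 500), rng.integers(0, 60, 500)
        )
        for scheme, n_groups in (("six", 6), ("four", 4)):
            labels = classify_groups(pop, scheme)
            nonempty = pop.total > 0
            assert ((labels[nonempty] >= 1) & (labels[nonempty] <= n_groups)).all()
            assert (labels[~nonempty] == 0).all()


class TestDynamics:
    def test_reproducible_and_distinct_runs(self):
        pop = KnockinPopulation(np.full(500, 30), np.full(500, 3))
        config = DynamicsConfig(sample_size=500, iterations=3, runs=3, seed=10)
        a = run_dynamics(pop, config)
        b = run_dynamics(pop, config)
        assert a.trajectories.equals(b.trajectories)
        finals = [tuple(p.n_ki[:20]) for p in a.final_populations.values()]
        assert len(set(finals)) == 3

    def test_selection_expands_high_ki_high_copy_group(self, survivors_by_f):
        """Blasticidin-like selection grows the group-4 fraction at f=40."""
        conv = convert_isolated_to_knockin(
            survivors_by_f[40].records, rng=np.random.default_rng(11)
        )
        config = DynamicsConfig(sample_size=2000, iterations=8, runs=3, seed=12)
        result = run_dynamics(conv.population, config)
        g4 = result.group_fraction("four", 4).mean(axis=1)
        assert g4.iloc[-1] > g4.iloc[0]
        assert g4.iloc[-1] > 0
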
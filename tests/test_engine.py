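import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermsel import (
    SimulationConfig,
    assign_matings,
    draw_population,
    fertilize,
    preference_weight,
    run_replicate,
)
from spermsel.engine import RetryBudgetError


class TestPreferenceWeight:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            (0.7, 0.7, 1.0),  # perfect fit
            (0.0, 1.0, math.exp(-0.5)),
            (0.0, 2.0, math.exp(-2.0)),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert preference_weight(x, y, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_width_parameter_scales_distance(self):
        # doubling sigma_U at doubled distance leaves the score unchanged
        assert preference_weight(0.0, 1.0, 1.0) == pytest.approx(
            preference_weight(0.0, 2.0, 2.0), rel=1e-12
        )

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValueError):
            preference_weight(0.0, 1.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(
        # keep (x-y)^2 / sigma_U^2 small enough that exp() stays above the
        # smallest normal double; the underflow path is tested separately
        x=st.floats(-3, 3),
        y=st.floats(-3, 3),
        sigma_U=st.floats(0.25, 10),
    )
    def test_bounded_symmetric_maximal_at_match(self, x, y, sigma_U):
        w = preference_weight(x, y, sigma_U)
        assert 0.0 < w <= 1.0
        assert w == preference_weight(y, x, sigma_U)
        if x == y:
            assert w == 1.0
        else:
            # strictly below 1 except where (x-y)^2/sigma_U^2 underflows
            assert w < 1.0 or abs(x - y) < 1e-7 * sigma_U


class TestDrawPopulation:
    def test_shapes_and_moments(self, rng):
        cfg = SimulationConfig(sigma_F=2.0, n_partners=2)
        male = []
        female = []
        for _ in range(50):
            pop = draw_population(cfg, rng)
            male.append(pop.male_trait)
            female.append(pop.female_trait)
        male = np.concatenate(male)
        female = np.concatenate(female)
        assert male.size == 50 * 200 and female.size == 50 * 200
        assert np.isfinite(male).all() and np.isfinite(female).all()
        # 10000 draws: sample SD within ~4 standard errors of the target
        assert male.std(ddof=1) == pytest.approx(1.0, abs=0.05)
        assert female.std(ddof=1) == pytest.approx(2.0, abs=0.1)
        assert abs(male.mean()) < 0.05 and abs(female.mean()) < 0.1

    def test_degenerate_sd_limit(self, rng):
        cfg = SimulationConfig(sigma_F=1.0, n_partners=2, sigma_M=1e-300, mu_M=0.7)
        pop = draw_population(cfg, rng)
        np.testing.assert_allclose(pop.male_trait, 0.7, atol=1e-290)

    def test_fixed_seed_reproduces(self):
        cfg = SimulationConfig(sigma_F=1.0, n_partners=2, seed=5)
        a = run_replicate(cfg)
        b = run_replicate(cfg)
        np.testing.assert_array_equal(a.population.male_trait, b.population.male_trait)
        np.testing.assert_array_equal(a.fertilization.sire, b.fertilization.sire)


class TestAssignMatings:
    @pytest.mark.parametrize("n, k", [(4, 1), (4, 2), (40, 3), (200, 10)])
    def test_symmetric_invariants(self, rng, n, k):
        cfg = SimulationConfig(sigma_F=1.0, n_partners=k, n_females=n, n_males=n)
        table = assign_matings(cfg, rng).partners
        assert table.shape == (n, k)
        # no male twice for any female
        assert all(np.unique(row).size == k for row in table)
        # each male copulates exactly k times
        np.testing.assert_array_equal(np.bincount(table.ravel(), minlength=n), k)

    def test_single_partner_is_perfect_matching(self, rng):
        cfg = SimulationConfig(sigma_F=1.0, n_partners=1, n_females=30, n_males=30)
        table = assign_matings(cfg, rng).partners
        assert sorted(table[:, 0]) == list(range(30))

    def test_retry_budget_surfaces(self, rng):
        # 2 females x 2 males x 2 partners: after round 1 the only valid
        # round-2 permutation is the swap, so a tiny budget can exhaust
        cfg = SimulationConfig(sigma_F=1.0, n_partners=2, n_females=2, n_males=2)
        with pytest.raises(RetryBudgetError):
            # max_retries=0 forbids even the first draw of round 2
            assign_matings(cfg, rng, max_retries=0)

    def test_asymmetric_degrees(self, rng):
        cfg = SimulationConfig(
            sigma_F=1.0,
            n_partners=2,
            n_females=30,
            n_males=60,
            n_partners_female=4,
            n_partners_male=2,
        )
        table = assign_matings(cfg, rng).partners
        assert table.shape == (30, 4)
        assert all(np.unique(row).size == 4 for row in table)
        np.testing.assert_array_equal(np.bincount(table.ravel(), minlength=60), 2)


class TestFertilize:
    def _replicate(self, cfg, rng):
        pop = draw_population(cfg, rng)
        mat = assign_matings(cfg, rng)
        return pop, mat, fertilize(pop, mat, cfg, rng)

    def test_single_partner_sires_all(self, rng):
        cfg = SimulationConfig(sigma_F=1.0, n_partners=1, n_females=20, n_males=20)
        pop, mat, fert = self._replicate(cfg, rng)
        np.testing.assert_array_equal(
            fert.sire, np.repeat(mat.partners, cfg.eggs_per_female, axis=1)
        )
        np.testing.assert_array_equal(fert.offspring_count, cfg.eggs_per_female)

    @pytest.mark.parametrize("variant", ["default", "winner_take_all", "threshold"])
    def test_conservation_and_paternity_within_partners(self, rng, variant):
        kwargs = {}
        if variant == "winner_take_all":
            kwargs["winner_take_all"] = True
        elif variant == "threshold":
            kwargs["storage_threshold"] = 0.6
        cfg = SimulationConfig(
            sigma_F=2.0, n_partners=3, n_females=50, n_males=50, **kwargs
        )
        pop, mat, fert = self._replicate(cfg, rng)
        assert fert.offspring_count.sum() == cfg.n_females * cfg.eggs_per_female
        for i in range(cfg.n_females):
            assert set(fert.sire[i]) <= set(mat.partners[i])

    def test_winner_take_all_one_sire_per_clutch(self, rng):
        cfg = SimulationConfig(
            sigma_F=2.0, n_partners=5, n_females=50, n_males=50, winner_take_all=True
        )
        _, _, fert = self._replicate(cfg, rng)
        assert all(np.unique(row).size == 1 for row in fert.sire)

    def test_threshold_excludes_poorly_fitting_sperm(self, rng):
        # female at 0 with males at 0 and 3: weight e^{-4.5} < 0.5 cutoff,
        # so the distant male can never sire
        cfg = SimulationConfig(
            sigma_F=1.0,
            n_partners=2,
            n_females=2,
            n_males=2,
            storage_threshold=0.5,
        )
        from spermsel.engine import MatingAssignment, Population

        pop = Population(
            male_trait=np.array([0.0, 3.0]), female_trait=np.array([0.0, 0.0])
        )
        mat = MatingAssignment(partners=np.array([[0, 1], [1, 0]]))
        fert = fertilize(pop, mat, cfg, rng)
        assert (fert.sire == 0).all()

    def test_threshold_all_below_falls_back_to_uniform(self, rng):
        # all eggs are still fertilized even when nobody passes the cutoff
        cfg = SimulationConfig(
            sigma_F=1.0,
            n_partners=2,
            n_females=2,
            n_males=2,
            storage_threshold=0.99,
        )
        from spermsel.engine import MatingAssignment, Population

        pop = Population(
            male_trait=np.array([5.0, -5.0]), female_trait=np.array([0.0, 0.0])
        )
        mat = MatingAssignment(partners=np.array([[0, 1], [1, 0]]))
        fert = fertilize(pop, mat, cfg, rng)
        assert fert.offspring_count.sum() == cfg.n_females * cfg.eggs_per_female

    def test_underflow_warns_and_fertilizes(self, rng):
        cfg = SimulationConfig(sigma_F=1.0, n_partners=2, n_females=2, n_males=2)
        from spermsel.engine import MatingAssignment, Population

        pop = Population(
            male_trait=np.array([1e4, -1e4]), female_trait=np.array([0.0, 0.0])
        )
        mat = MatingAssignment(partners=np.array([[0, 1], [1, 0]]))
        with pytest.warns(RuntimeWarning, match="underflow"):
            fert = fertilize(pop, mat, cfg, rng)
        assert fert.offspring_count.sum() == 10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    n=st.integers(4, 30),
    k=st.integers(1, 4),
    eggs=st.integers(1, 6),
    sigma_F=st.floats(0.3, 3.0),
    seed=st.integers(0, 10_000),
)
def test_total_offspring_is_conserved(n, k, eggs, sigma_F, seed):
    """Every egg gets exactly one sire, whatever the condition."""
    cfg = SimulationConfig(
        sigma_F=sigma_F,
        n_partners=min(k, n),
        n_females=n,
        n_males=n,
        eggs_per_female=eggs,
        seed=seed,
    )
    res = run_replicate(cfg)
    assert res.fertilization.offspring_count.sum() == n * eggs
    assert res.fertilization.offspring_count.size == n
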
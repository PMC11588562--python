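"""Redistribution-pool model: survival function, analytic fitness,
pool accounting, invasion condition and the conservative bound."""

import math

import numpy as np
import pytest

from geminicoev import (
    CapacityError,
    DomainError,
    GeminoScenario,
    conservative_alpha,
    expected_fitness_G,
    exponential_survival,
    fitness_A,
    invasion_condition,
    monte_carlo_fitness_G,
    pool,
    survival,
    twinning_maladaptive,
)
from geminicoev.geneculture import logistic_survival, step_survival


class TestSurvival:
    def test_closed_form_values(self):
        assert survival(0.0, 1.0) == 0.0
        assert survival(1.0, 1.0) == pytest.approx(1 - math.exp(-1))

    def test_strictly_increasing_and_bounded(self):
        r = np.linspace(0, 10, 200)
        s = survival(r, 2.0)
        assert np.all(np.diff(s) > 0)
        assert np.all((s >= 0) & (s < 1))

    def test_negative_resources_rejected(self):
        with pytest.raises(DomainError):
            survival(-0.1, 1.0)
        with pytest.raises(DomainError):
            exponential_survival(0.0)

    def test_exponential_never_makes_twinning_maladaptive(self):
        """2S(M/2) > S(M) for the exponential CDF: algebraically
        2(1-e^{-z}) - (1-e^{-2z}) = (1-e^{-z})^2 + (1-e^{-z}) > 0."""
        for M in (0.1, 1.0, 5.0, 50.0):
            for lam in (0.1, 1.0, 10.0):
                assert not twinning_maladaptive(M, lam)

    def test_step_survival_makes_twinning_maladaptive(self):
        S = step_survival(threshold=0.75, level=0.95)
        assert twinning_maladaptive(1.0, survival=S)  # S(1)=0.95 > 2*S(0.5)=0

    def test_concave_survival_keeps_twinning_adaptive(self):
        # concave through the origin: S(M/2) >= S(M)/2
        S = lambda r: np.sqrt(np.asarray(r, dtype=float) / 10.0)
        assert not twinning_maladaptive(1.0, survival=S)


class TestFitnessA:
    def test_never_twinning_reduces_to_singleton_survival(self):
        assert fitness_A(0.0, 1.0, 2.0) == pytest.approx(survival(1.0, 2.0))

    def test_always_twinning_reduces_to_twin_survival(self):
        assert fitness_A(1.0, 1.0, 2.0) == pytest.approx(2 * survival(0.5, 2.0))

    def test_decreasing_in_beta_when_twinning_maladaptive(self):
        S = logistic_survival(midpoint=0.75, steepness=30.0)
        assert twinning_maladaptive(1.0, survival=S)
        betas = np.linspace(0, 1, 11)
        vals = [fitness_A(b, 1.0, survival=S) for b in betas]
        assert np.all(np.diff(vals) < 0)


class TestPool:
    def test_no_contribution_without_share(self):
        scen = GeminoScenario(M=1.0, alpha_share=0.0, N_GQ=10)
        assert pool(scen, 9).kappa == 0.0

    def test_community_of_100_arithmetic(self):
        # 99 singleton producers each give 0.01 * 0.9; one twinner collects it all
        scen = GeminoScenario(M=1.0, gamma_cost=0.1, alpha_share=0.01, N_GQ=100)
        out = pool(scen, 99)
        assert out.kappa == pytest.approx(0.891)
        assert out.T_G == 1
        assert out.per_twinner_payout == pytest.approx(0.891)

    def test_conservation_and_discard(self):
        scen = GeminoScenario(M=1.0, gamma_cost=0.1, alpha_share=0.05, N_GQ=10)
        with_twinners = pool(scen, 7)
        assert with_twinners.distributed == pytest.approx(with_twinners.kappa)
        no_twinners = pool(scen, 10)
        assert no_twinners.per_twinner_payout is None
        assert no_twinners.distributed == 0.0

    def test_count_out_of_range_rejected(self):
        scen = GeminoScenario(M=1.0, N_GQ=5)
        with pytest.raises(DomainError):
            pool(scen, 6)


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(M=1.0, gamma_cost=1.0, N_GQ=2),  # gamma >= M
            dict(M=1.0, alpha_share=1.5, N_GQ=2),
            dict(M=1.0, beta=0.8, delta=0.3, N_GQ=2),  # beta + delta > 1
            dict(M=1.0, lambda_surv=-1.0, N_GQ=2),
            dict(M=1.0),  # empty population
        ],
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeminoScenario(**kwargs)


class TestExpectedFitnessG:
    def test_norm_free_reduction_to_fitness_A(self):
        scen = GeminoScenario(M=1.0, gamma_cost=0.0, alpha_share=0.0, lambda_surv=2.0, beta=0.3, N_GQ=8)
        assert expected_fitness_G(scen, "Q") == pytest.approx(fitness_A(0.3, 1.0, 2.0))

    def test_no_twinning_anywhere_gives_discounted_singleton(self):
        scen = GeminoScenario(M=1.0, gamma_cost=0.1, alpha_share=0.05, lambda_surv=2.0, beta=0.0, N_GQ=8)
        assert expected_fitness_G(scen, "Q") == pytest.approx(survival(0.95 * 0.9, 2.0))

    def test_capacity_error_directs_to_monte_carlo(self):
        scen = GeminoScenario(M=1.0, beta=0.1, N_GQ=30)
        with pytest.raises(CapacityError, match="monte-carlo"):
            expected_fitness_G(scen, "Q")
        # the Monte Carlo path handles the same scenario
        assert 0 < expected_fitness_G(scen, "Q", method="monte-carlo", n_draws=1000, seed=0) <= 2

    def test_exact_matches_monte_carlo(self, mixed_scenario):
        for genotype in ("Q", "Qtilde"):
            exact = expected_fitness_G(mixed_scenario, genotype)
            mc = monte_carlo_fitness_G(mixed_scenario, genotype, n_draws=100_000, seed=11)
            assert abs(exact - mc.value) < 3 * mc.se

    def test_monotone_in_alpha_and_gamma_for_twinner(self):
        """A guaranteed twinner gains from a larger pool share and
        loses from a larger membership cost."""
        def fit(alpha, gamma):
            scen = GeminoScenario(
                M=1.0, gamma_cost=gamma, alpha_share=alpha, lambda_surv=2.0,
                beta=0.0, delta=1.0, N_GQ=9, N_GQt=1,
            )
            return expected_fitness_G(scen, "Qtilde")

        alphas = np.linspace(0, 0.5, 6)
        vals = [fit(a, 0.1) for a in alphas]
        assert np.all(np.diff(vals) >= 0)
        gammas = np.linspace(0, 0.5, 6)
        vals = [fit(0.1, g) for g in gammas]
        assert np.all(np.diff(vals) <= 0)

    def test_missing_focal_rejected(self):
        scen = GeminoScenario(M=1.0, N_GQ=5)
        with pytest.raises(DomainError):
            expected_fitness_G(scen, "Qtilde")


class TestInvasion:
    def test_direct_evaluation_oracle(self):
        N, M, gamma, alpha, lam = 100, 1.0, 0.1, 0.01, 2.0
        S = exponential_survival(lam)
        left = 2 * S((M - gamma) * (1 + alpha * (N - 1)) / 2)
        right = S((1 - alpha) * (M - gamma))
        assert invasion_condition(N, M, gamma, alpha, lam) == (left > right)

    def test_no_pool_no_invasion_when_twinning_maladaptive(self):
        S = logistic_survival(midpoint=0.75, steepness=30.0)
        assert twinning_maladaptive(1.0, survival=S)
        assert not invasion_condition(100, 1.0, 0.0, 0.0, survival=S)

    def test_alpha_above_tie_point_invades_for_any_increasing_S(self):
        # alpha >= 1/(N+1) makes the twin's share weakly exceed the
        # singleton's; the factor two breaks the tie
        for N in (2, 10, 100):
            alpha = 1.0 / (N + 1)
            for S in (
                exponential_survival(0.5),
                exponential_survival(10.0),
                logistic_survival(0.4, 8.0),
                lambda r: np.sqrt(np.asarray(r) / 100.0),
            ):
                assert invasion_condition(N, 1.0, 0.1, alpha, survival=S)

    def test_conservative_alpha_closed_form(self):
        assert conservative_alpha(99) == pytest.approx(0.01)
        assert conservative_alpha(99) < 1 / 99  # the "give about 1/N" norm is more generous
        assert conservative_alpha(10**6) < 1e-5  # vanishing per-capita cost

    def test_boundary_sharpness(self):
        """1/(N+1) - epsilon fails for some strictly increasing S."""
        N, M, gamma = 100, 1.0, 0.1
        alpha = conservative_alpha(N) - 1e-9
        base = M - gamma
        left_arg = base * (1 + alpha * (N - 1)) / 2
        right_arg = (1 - alpha) * base
        assert left_arg < right_arg
        S = logistic_survival(midpoint=0.5 * (left_arg + right_arg), steepness=1e10)
        assert not invasion_condition(N, M, gamma, alpha, survival=S)
        # while the conservative value itself still passes for that same S
        assert invasion_condition(N, M, gamma, conservative_alpha(N), survival=S)
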
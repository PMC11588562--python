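"""Culture-led selection on twinning propensity via a redistribution pool.

Two haploid genotypes — a low-twinning resident ``Q`` (twin-birth
probability ``beta``) and a higher-twinning mutant ``Qtilde``
(probability ``beta + delta``) — are crossed with two cultural
types: ``A`` (no support institutions) and ``G`` (geminophilous:
members maintain a community pool that insures mothers of twins).

Every individual holds ``M`` resource units and produces one birth
per generation.  Offspring survive independently with probability
``S(r)`` where ``r`` is the per-offspring resource share and ``S``
is a smooth, monotonically increasing map to [0, 1]; the default
parameterisation is the exponential CDF ``S(r) = 1 - exp(-lambda *
r)``.  A singleton receives all of its parent's disposable
resources; twins split them.

``A``-types: a singleton gets ``M``; each twin gets ``M/2``.
Twinning is *maladaptive* when ``S(M) > 2 S(M/2)`` — note that the
pure exponential CDF never satisfies this (it is concave through
the origin), so scenarios exploring maladaptive twinning must plug
in a survival function with an accelerating region (e.g.
:func:`logistic_survival` or :func:`step_survival`).

``G``-types pay a fixed membership cost ``gamma_cost``; members who
do NOT twin additionally contribute a fraction ``alpha_share`` of
their disposable ``M - gamma_cost`` to the pool ``kappa``, which is
split equally among the ``T_G`` members who DO twin.  Per-offspring
shares are then ``(1 - alpha_share)(M - gamma_cost)`` for a
singleton and ``(M - gamma_cost + kappa / T_G) / 2`` for each twin.

The analytic invasion condition asks whether a lone always-twinning
mutant in an otherwise non-twinning ``G`` community of size ``N``
out-reproduces the residents; it reduces to comparing the
arguments of ``S``, giving the conservative sufficient contribution
rate ``alpha* = 1/(N + 1)`` — of the same order as the simple
cultural norm "everyone gives about 1/N of their wealth".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import binom

from ._errors import CapacityError, DomainError

__all__ = [
    "SurvivalFn",
    "GeminoScenario",
    "PoolOutcome",
    "MonteCarloEstimate",
    "survival",
    "exponential_survival",
    "logistic_survival",
    "step_survival",
    "twinning_maladaptive",
    "fitness_A",
    "pool",
    "expected_fitness_G",
    "monte_carlo_fitness_G",
    "invasion_condition",
    "conservative_alpha",
]

SurvivalFn = Callable[[np.ndarray], np.ndarray]

Genotype = Literal["Q", "Qtilde"]

#: default cap on the G-type count for exact enumeration
EXACT_ENUMERATION_CAP = 20


def _check_resources(resources) -> np.ndarray:
    r = np.asarray(resources, dtype=float)
    if np.any(r < 0.0):
        raise DomainError("resources must be non-negative")
    return r


def exponential_survival(lambda_surv: float) -> SurvivalFn:
    """Exponential-CDF survival ``S(r) = 1 - exp(-lambda_surv * r)``."""
    if not lambda_surv > 0:
        raise DomainError("lambda_surv must be positive")

    def S(resources):
        r = _check_resources(resources)
        out = 1.0 - np.exp(-lambda_surv * r)
        return out if out.ndim else float(out)

    return S


def logistic_survival(midpoint: float, steepness: float) -> SurvivalFn:
    """Sigmoidal survival with an accelerating region below ``midpoint``.

    Strictly increasing; with large ``steepness`` it approaches a step
    at ``midpoint`` and can make twinning maladaptive (offspring below
    the midpoint essentially never survive).
    """
    if not steepness > 0:
        raise DomainError("steepness must be positive")

    def S(resources):
        r = _check_resources(resources)
        out = 1.0 / (1.0 + np.exp(-steepness * (r - midpoint)))
        return out if out.ndim else float(out)

    return S


def step_survival(threshold: float, level: float = 0.95) -> SurvivalFn:
    """Threshold survival: 0 below ``threshold``, ``level`` at or above.

    Not strictly increasing — a deliberately extreme illustration of a
    survival function under which twinning is maladaptive.
    """
    if not 0.0 < level <= 1.0:
        raise DomainError("level must lie in (0, 1]")

    def S(resources):
        r = _check_resources(resources)
        out = np.where(r >= threshold, level, 0.0)
        return out if out.ndim else float(out)

    return S


def survival(resources, lambda_surv: float):
    """Offspring survival probability under the exponential default."""
    return exponential_survival(lambda_surv)(resources)


class GeminoScenario(BaseModel):
    """Parameters of the geminophilous redistribution model.

    Fields
    ------
    M : per-individual resource endowment (resource units), > 0
    gamma_cost : fixed cost of support-network membership, in [0, M)
    alpha_share : fraction of (M - gamma_cost) contributed by non-twinning
        G-types, in [0, 1]
    lambda_surv : rate of the default exponential survival CDF, > 0
    beta : twin-birth probability of genotype Q
    delta : increment of the mutant, so Qtilde twins with beta + delta <= 1
    N_AQ, N_AQt, N_GQ, N_GQt : counts of the four culture x genotype types
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    M: float
    gamma_cost: float = 0.0
    alpha_share: float = 0.0
    lambda_surv: float = 1.0
    beta: float = 0.0
    delta: float = 0.0
    N_AQ: int = 0
    N_AQt: int = 0
    N_GQ: int = 0
    N_GQt: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeminoScenario":
        if not self.M > 0:
            raise ValueError("M must be positive")
        if not 0.0 <= self.gamma_cost < self.M:
            raise ValueError("gamma_cost must satisfy 0 <= gamma_cost < M")
        if not 0.0 <= self.alpha_share <= 1.0:
            raise ValueError("alpha_share must lie in [0, 1]")
        if not self.lambda_surv > 0:
            raise ValueError("lambda_surv must be positive")
        if not (0.0 <= self.beta and self.delta >= 0.0 and self.beta + self.delta <= 1.0):
            raise ValueError("probabilities must satisfy 0 <= beta <= beta + delta <= 1")
        if min(self.N_AQ, self.N_AQt, self.N_GQ, self.N_GQt) < 0:
            raise ValueError("type counts must be non-negative")
        if self.N < 1:
            raise ValueError("total population N must be at least 1")
        return self

    @property
    def N(self) -> int:
        return self.N_AQ + self.N_AQt + self.N_GQ + self.N_GQt

    @property
    def N_G(self) -> int:
        """Number of geminophilous (pool-member) individuals."""
        return self.N_GQ + self.N_GQt

    @property
    def beta_tilde(self) -> float:
        return self.beta + self.delta

    def survival_fn(self) -> SurvivalFn:
        return exponential_survival(self.lambda_surv)


@dataclass(frozen=True)
class PoolOutcome:
    """Realised redistribution-pool accounting for one generation."""

    kappa: float
    T_G: int
    per_twinner_payout: float | None

    @property
    def distributed(self) -> float:
        """Total paid out; equals kappa when any twinner exists, else 0."""
        return self.kappa if self.T_G > 0 else 0.0


def pool(scenario: GeminoScenario, n_G_singleton_producers: int) -> PoolOutcome:
    """Pool size and payout given the realised G-type singleton count.

    ``kappa = alpha_share * (M - gamma_cost) * n_singletons``; the
    ``T_G = N_G - n_singletons`` twinners split it equally.  With no
    twinners the contributions are collected and discarded (the
    non-twinner share ``(1 - alpha)(M - gamma)`` is unconditional).
    """
    if not 0 <= n_G_singleton_producers <= scenario.N_G:
        raise DomainError("singleton-producer count must lie between 0 and N_G")
    kappa = scenario.alpha_share * (scenario.M - scenario.gamma_cost) * n_G_singleton_producers
    T_G = scenario.N_G - n_G_singleton_producers
    payout = kappa / T_G if T_G > 0 else None
    return PoolOutcome(kappa=kappa, T_G=T_G, per_twinner_payout=payout)


def twinning_maladaptive(M: float, lambda_surv: float | None = None, survival: SurvivalFn | None = None) -> bool:
    """Whether a singleton beats a twin birth: ``S(M) > 2 S(M/2)``.

    Uses the exponential default when only ``lambda_surv`` is given
    (for which the condition is provably never satisfied); pass a
    custom ``survival`` to explore functions with accelerating regions.
    """
    if not M > 0:
        raise DomainError("M must be positive")
    S = _resolve_survival(lambda_surv, survival)
    return float(S(M)) > 2.0 * float(S(M / 2.0))


def _resolve_survival(lambda_surv: float | None, survival: SurvivalFn | None) -> SurvivalFn:
    if survival is not None:
        return survival
    if lambda_surv is None:
        raise DomainError("provide lambda_surv or a survival function")
    return exponential_survival(lambda_surv)


def fitness_A(genotype_beta: float, M: float, lambda_surv: float | None = None, survival: SurvivalFn | None = None) -> float:
    """Expected surviving offspring of a norm-free (A-type) individual.

    ``(1 - beta) S(M) + beta * 2 S(M/2)`` with ``beta`` the genotype's
    twin-birth probability (use ``beta + delta`` for the mutant).
    """
    if not 0.0 <= genotype_beta <= 1.0:
        raise DomainError("genotype_beta must lie in [0, 1]")
    S = _resolve_survival(lambda_surv, survival)
    return (1.0 - genotype_beta) * float(S(M)) + genotype_beta * 2.0 * float(S(M / 2.0))


def _focal_setup(scenario: GeminoScenario, genotype: Genotype):
    if genotype == "Q":
        if scenario.N_GQ < 1:
            raise DomainError("no GQ individual to serve as focal")
        return scenario.beta, scenario.N_GQ - 1, scenario.N_GQt
    if genotype == "Qtilde":
        if scenario.N_GQt < 1:
            raise DomainError("no GQtilde individual to serve as focal")
        return scenario.beta_tilde, scenario.N_GQ, scenario.N_GQt - 1
    raise DomainError(f"unknown genotype {genotype!r}")


def _g_payoffs(scenario: GeminoScenario, S: SurvivalFn, others_twinning, focal_twins: bool):
    """Payoff of a focal G-type given the others' realised twin counts.

    ``kappa`` and ``T_G`` count the realised outcomes of ALL pool
    members, the focal individual included.
    """
    base = scenario.M - scenario.gamma_cost
    others = np.asarray(others_twinning)
    if focal_twins:
        T_G = others + 1
        n_singletons = scenario.N_G - T_G
        kappa = scenario.alpha_share * base * n_singletons
        return 2.0 * np.asarray(S((base + kappa / T_G) / 2.0))
    return np.full(others.shape, float(S((1.0 - scenario.alpha_share) * base)))


def expected_fitness_G(
    scenario: GeminoScenario,
    genotype: Genotype = "Q",
    method: Literal["exact", "monte-carlo"] = "exact",
    n_draws: int = 100_000,
    seed: int | None = None,
    survival: SurvivalFn | None = None,
    exact_cap: int = EXACT_ENUMERATION_CAP,
) -> float:
    """Expected surviving offspring of a focal pool member.

    The expectation runs over the focal individual's own Bernoulli
    twin draw and the binomial twin counts of the other pool members,
    which jointly determine the pool ``kappa`` and twinner count
    ``T_G``.  The exact method enumerates the two binomials (allowed
    up to ``exact_cap`` pool members); the Monte Carlo method averages
    ``n_draws`` independent replicates.
    """
    if method == "monte-carlo":
        return monte_carlo_fitness_G(scenario, genotype, n_draws=n_draws, seed=seed, survival=survival).value
    if method != "exact":
        raise DomainError(f"unknown method {method!r}")
    if scenario.N_G > exact_cap:
        raise CapacityError(
            f"exact enumeration supports at most {exact_cap} pool members "
            f"(got {scenario.N_G}); use method='monte-carlo'"
        )
    S = survival if survival is not None else scenario.survival_fn()
    beta_f, n_Q_others, n_Qt_others = _focal_setup(scenario, genotype)

    k_Q = np.arange(n_Q_others + 1)
    k_T = np.arange(n_Qt_others + 1)
    w = np.outer(binom.pmf(k_Q, n_Q_others, scenario.beta), binom.pmf(k_T, n_Qt_others, scenario.beta_tilde))
    others = k_Q[:, None] + k_T[None, :]

    f_singleton = float(S((1.0 - scenario.alpha_share) * (scenario.M - scenario.gamma_cost)))
    f_twin = float(np.sum(w * _g_payoffs(scenario, S, others, focal_twins=True)))
    return (1.0 - beta_f) * f_singleton + beta_f * f_twin


@dataclass(frozen=True)
class MonteCarloEstimate:
    value: float
    se: float
    n_draws: int


def monte_carlo_fitness_G(
    scenario: GeminoScenario,
    genotype: Genotype = "Q",
    n_draws: int = 100_000,
    seed: int | None = None,
    survival: SurvivalFn | None = None,
) -> MonteCarloEstimate:
    """Monte Carlo estimate (with standard error) of :func:`expected_fitness_G`."""
    if n_draws < 2:
        raise DomainError("n_draws must be at least 2")
    S = survival if survival is not None else scenario.survival_fn()
    beta_f, n_Q_others, n_Qt_others = _focal_setup(scenario, genotype)
    rng = np.random.default_rng(seed)

    focal = rng.random(n_draws) < beta_f
    others = rng.binomial(n_Q_others, scenario.beta, n_draws) + rng.binomial(
        n_Qt_others, scenario.beta_tilde, n_draws
    )
    payoff = _g_payoffs(scenario, S, others, focal_twins=False)
    if np.any(focal):
        payoff = np.where(focal, 0.0, payoff)
        # twin payoffs only where the focal twinned (T_G >= 1 there)
        twin_vals = _g_payoffs(scenario, S, others[focal], focal_twins=True)
        payoff[focal] = twin_vals
    value = float(payoff.mean())
    se = float(payoff.std(ddof=1) / math.sqrt(n_draws))
    return MonteCarloEstimate(value=value, se=se, n_draws=n_draws)


def invasion_condition(
    N: int,
    M: float,
    gamma_cost: float,
    alpha_share: float,
    lambda_surv: float | None = None,
    survival: SurvivalFn | None = None,
) -> bool:
    """Can a lone always-twinning mutant beat non-twinning pool members?

    With ``N - 1`` residents who all produce singletons and one mutant
    who twins, the pool is ``kappa = alpha (M - gamma)(N - 1)`` and the
    mutant is its sole recipient.  Invasion requires

        2 S( (M - gamma)(1 + alpha (N - 1)) / 2 )  >  S( (1 - alpha)(M - gamma) )
    """
    if N < 2:
        raise DomainError("invasion condition needs a community of at least 2")
    if not 0.0 <= gamma_cost < M:
        raise DomainError("gamma_cost must satisfy 0 <= gamma_cost < M")
    if not 0.0 <= alpha_share <= 1.0:
        raise DomainError("alpha_share must lie in [0, 1]")
    S = _resolve_survival(lambda_surv, survival)
    base = M - gamma_cost
    left = 2.0 * float(S(base * (1.0 + alpha_share * (N - 1)) / 2.0))
    right = float(S((1.0 - alpha_share) * base))
    return left > right


def conservative_alpha(N: int) -> float:
    """Smallest contribution rate that guarantees invasion for any
    strictly increasing survival function: ``1/(N + 1)``.

    At this rate the mutant twin's per-offspring share equals the
    resident singleton's share, and the factor two in offspring number
    breaks the tie; the community norm "give about 1/N" is slightly
    more generous than this bound.
    """
    if N < 2:
        raise DomainError("conservative alpha needs a community of at least 2")
    return 1.0 / (N + 1)
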
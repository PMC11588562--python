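"""Generation-by-generation stochastic simulation of the four-type model.

Each generation: every individual draws its twin/singleton outcome
(Bernoulli with its genotype's twin probability); the redistribution
pool is filled by the realised G-type singleton producers and split
among the realised G-type twinners; every offspring survives
independently with probability ``S`` of its resource share (the same
accounting as the analytic fitness expressions); and the next
generation of constant size ``N`` is formed by multinomial sampling
of parents weighted by their realised surviving-offspring counts
(Wright–Fisher regulation), offspring inheriting genotype and
cultural type clonally.

Fixed-``N`` regulation makes the neutral baseline exact: a selectively
neutral mutant lineage fixes with probability equal to its initial
frequency (``1/N`` for a single copy).  If no offspring at all
survive a generation the population is extinct and the trajectory
truncates with an explicit flag.

All randomness flows from a single root seed through
``numpy.random.SeedSequence`` spawning, so identical seed + scenario
reproduce a trajectory byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DomainError
from .geneculture import GeminoScenario, SurvivalFn

__all__ = [
    "TYPE_ORDER",
    "PopulationTrajectory",
    "step_generation",
    "GenerationStep",
    "simulate",
    "simulate_replicates",
    "replicate_generation_means",
    "run_to_absorption",
]

#: column order of the four culture x genotype types everywhere
TYPE_ORDER = ("AQ", "AQt", "GQ", "GQt")

_TRAJ_COLUMNS = (
    ["generation"]
    + [f"n_{t}" for t in TYPE_ORDER]
    + [f"twins_{t}" for t in TYPE_ORDER]
    + ["kappa"]
    + [f"surv_{t}" for t in TYPE_ORDER]
    + ["extinct"]
)


def _generation_draws(counts, scenario: GeminoScenario, S: SurvivalFn, rng: np.random.Generator, size=None):
    """Twin draws, pool accounting and offspring-survival draws.

    ``counts`` is the (AQ, AQt, GQ, GQt) vector; with ``size`` given,
    all draws carry an independent-replicate axis.  Returns
    ``(twins, survivors, kappa)`` where the first two stack the four
    types along axis 0.
    """
    n_AQ, n_AQt, n_GQ, n_GQt = (int(c) for c in counts)
    b, bt = scenario.beta, scenario.beta_tilde
    t_AQ = rng.binomial(n_AQ, b, size)
    t_AQt = rng.binomial(n_AQt, bt, size)
    t_GQ = rng.binomial(n_GQ, b, size)
    t_GQt = rng.binomial(n_GQt, bt, size)

    base = scenario.M - scenario.gamma_cost
    T_G = t_GQ + t_GQt
    n_singleton_G = (n_GQ - t_GQ) + (n_GQt - t_GQt)
    kappa = scenario.alpha_share * base * n_singleton_G
    payout = np.where(T_G > 0, kappa / np.maximum(T_G, 1), 0.0)

    p_A_single = float(S(scenario.M))
    p_A_twin = float(S(scenario.M / 2.0))
    p_G_single = float(S((1.0 - scenario.alpha_share) * base))
    p_G_twin = np.asarray(S((base + payout) / 2.0))

    s_AQ = rng.binomial(n_AQ - t_AQ, p_A_single) + rng.binomial(2 * t_AQ, p_A_twin)
    s_AQt = rng.binomial(n_AQt - t_AQt, p_A_single) + rng.binomial(2 * t_AQt, p_A_twin)
    s_GQ = rng.binomial(n_GQ - t_GQ, p_G_single) + rng.binomial(2 * t_GQ, p_G_twin)
    s_GQt = rng.binomial(n_GQt - t_GQt, p_G_single) + rng.binomial(2 * t_GQt, p_G_twin)

    twins = np.stack([t_AQ, t_AQt, t_GQ, t_GQt])
    survivors = np.stack([s_AQ, s_AQt, s_GQ, s_GQt])
    return twins, survivors, kappa


@dataclass(frozen=True)
class GenerationStep:
    """Realised accounting of a single generation."""

    twins: np.ndarray  # per-type twin-birth counts
    survivors: np.ndarray  # per-type surviving-offspring counts
    kappa: float
    next_counts: np.ndarray | None  # None on extinction
    extinct: bool


def step_generation(
    counts,
    scenario: GeminoScenario,
    rng: np.random.Generator,
    survival: SurvivalFn | None = None,
) -> GenerationStep:
    """Advance one generation from the given type-count vector."""
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (4,) or counts.min() < 0:
        raise DomainError("counts must be four non-negative integers (AQ, AQt, GQ, GQt)")
    N = int(counts.sum())
    if N < 1:
        raise DomainError("population must contain at least one individual")
    S = survival if survival is not None else scenario.survival_fn()
    twins, survivors, kappa = _generation_draws(counts, scenario, S, rng)
    total = int(survivors.sum())
    if total == 0:
        return GenerationStep(twins=twins, survivors=survivors, kappa=float(kappa), next_counts=None, extinct=True)
    next_counts = rng.multinomial(N, survivors / total)
    return GenerationStep(twins=twins, survivors=survivors, kappa=float(kappa), next_counts=next_counts, extinct=False)


@dataclass
class PopulationTrajectory:
    """Per-generation records of one simulation run."""

    frame: pd.DataFrame
    seed: int
    extinct: bool
    scenario: GeminoScenario = field(repr=False, default=None)  # type: ignore[assignment]

    def final_counts(self) -> np.ndarray:
        last = self.frame.iloc[-1]
        return np.array([last[f"n_{t}"] for t in TYPE_ORDER], dtype=int)


def simulate(
    scenario: GeminoScenario,
    generations: int,
    seed: int,
    survival: SurvivalFn | None = None,
) -> PopulationTrajectory:
    """Run the full stochastic model for a fixed number of generations.

    Each row of the trajectory records the type counts entering the
    generation together with the realised twin counts, pool size and
    surviving-offspring counts produced during it.  The run truncates
    early (with ``extinct=True`` on the last row) if no offspring
    survive a generation.
    """
    if generations < 1:
        raise DomainError("generations must be at least 1")
    rng = np.random.default_rng(seed)
    S = survival if survival is not None else scenario.survival_fn()
    counts = np.array([scenario.N_AQ, scenario.N_AQt, scenario.N_GQ, scenario.N_GQt], dtype=int)

    rows = []
    extinct = False
    for g in range(generations):
        step = step_generation(counts, scenario, rng, survival=S)
        rows.append(
            [g, *counts.tolist(), *step.twins.tolist(), step.kappa, *step.survivors.tolist(), step.extinct]
        )
        if step.extinct:
            extinct = True
            break
        counts = step.next_counts
    frame = pd.DataFrame(rows, columns=_TRAJ_COLUMNS)
    return PopulationTrajectory(frame=frame, seed=seed, extinct=extinct, scenario=scenario)


def simulate_replicates(
    scenario: GeminoScenario,
    generations: int,
    replicates: int,
    seed: int,
    survival: SurvivalFn | None = None,
) -> pd.DataFrame:
    """Independent replicate runs with per-replicate child seeds.

    Child seeds derive deterministically from the root seed via
    ``SeedSequence.spawn``; the output stacks the per-run trajectories
    with a leading ``replicate`` column.
    """
    if replicates < 1:
        raise DomainError("replicates must be at least 1")
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(replicates)]
    frames = []
    for r, child in enumerate(child_seeds):
        traj = simulate(scenario, generations, child, survival=survival)
        f = traj.frame.copy()
        f.insert(0, "replicate", r)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def replicate_generation_means(
    scenario: GeminoScenario,
    replicates: int,
    seed: int,
    survival: SurvivalFn | None = None,
) -> dict[str, tuple[float, float]]:
    """Mean realised surviving offspring per parent, by type.

    Runs the one-generation kernel over many independent replicates
    from the scenario's initial counts and returns, for each type with
    at least one parent, the mean and standard error (across
    replicates) of survivors-per-parent — directly comparable to the
    analytic ``fitness_A`` / ``expected_fitness_G`` expectations.
    """
    if replicates < 2:
        raise DomainError("replicates must be at least 2")
    rng = np.random.default_rng(seed)
    S = survival if survival is not None else scenario.survival_fn()
    counts = np.array([scenario.N_AQ, scenario.N_AQt, scenario.N_GQ, scenario.N_GQt], dtype=int)
    _, survivors, _ = _generation_draws(counts, scenario, S, rng, size=replicates)
    out: dict[str, tuple[float, float]] = {}
    for i, t in enumerate(TYPE_ORDER):
        if counts[i] == 0:
            continue
        per_parent = survivors[i] / counts[i]
        out[t] = (float(per_parent.mean()), float(per_parent.std(ddof=1) / np.sqrt(replicates)))
    return out


def run_to_absorption(
    scenario: GeminoScenario,
    seed: int,
    max_generations: int = 10_000,
    survival: SurvivalFn | None = None,
) -> tuple[str, int]:
    """Track the mutant genotype until fixation, loss or timeout.

    Returns ``(status, generation)`` with status one of ``"fixed"``
    (all ``N`` individuals carry Qtilde), ``"lost"``, ``"extinct"``
    or ``"timeout"``.
    """
    rng = np.random.default_rng(seed)
    S = survival if survival is not None else scenario.survival_fn()
    counts = np.array([scenario.N_AQ, scenario.N_AQt, scenario.N_GQ, scenario.N_GQt], dtype=int)
    N = int(counts.sum())
    for g in range(max_generations):
        mutants = int(counts[1] + counts[3])
        if mutants == 0:
            return "lost", g
        if mutants == N:
            return "fixed", g
        step = step_generation(counts, scenario, rng, survival=S)
        if step.extinct:
            return "extinct", g
        counts = step.next_counts
    return "timeout", max_generations
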
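"""Selection on ovulation strategies along a resource gradient.

Two fixed genotypes compete: a double-ovulation genotype ``P`` and a
mono-ovulation genotype ``S``.  A mother with resource endowment
``E`` in the open unit interval loses each fertilised embryo
independently with probability ``m(E) = d - c*E`` (embryo/foetal
mortality falls linearly as resources rise).  A singleton birth is
worth a constant reproductive value ``R_s``; a twin birth is worth
``R_t(E) = a*E + b``, increasing in resources.  The genotype
fitnesses are

    W_P(E) = R_t(E) * (1 - m)^2  +  R_s * 2 m (1 - m)
    W_S(E) = R_s * (1 - m)

i.e. the double-ovulator produces twins when both embryos survive,
a singleton when exactly one does, and nothing when both die; the
mono-ovulator's single embryo survives with probability ``1 - m``.

The sign of ``W_P - W_S`` on the costly-twinning interval
``(0, E*)``, with ``E* = (R_s - b)/a`` the point where twinning
stops being costly, is governed by a concave quadratic in ``E``
with coefficients

    alpha_q = -a c
    beta_q  = a (d - 1) + c (2 R_s - b)
    gamma_q = R_s (1 - 2 d) + b (d - 1)

Algebraically ``W_P - W_S = -(1 - m) * (alpha_q E^2 + beta_q E +
gamma_q)``, so double-ovulation is favoured exactly where the
quadratic is *negative* (outside its roots, since it is concave).
The resource axis is thereby partitioned into up to four regions by
the roots ``E_1 <= E_2`` and the threshold ``E*``: double-ovulation
can be favoured at both low and high resource levels even where
twinning itself is costly, which is the model's central
non-monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from ._errors import DomainError

__all__ = [
    "OvulationEcology",
    "QuadraticSelectionForm",
    "ResourceRegion",
    "embryo_mortality",
    "twin_reproductive_value",
    "fitness_double_ovulation",
    "fitness_mono_ovulation",
    "selection_quadratic",
    "partition_resource_space",
    "ecology_curve",
    "sample_random_ecology",
]

#: margin by which evaluation grids stay inside the open interval (0, 1)
GRID_MARGIN = 1e-6


class OvulationEcology(BaseModel):
    """Coefficients of the resource-dependent fitness landscape.

    Parameters
    ----------
    a : slope of twin reproductive value vs resources (fitness per resource unit), > 0
    b : intercept of twin reproductive value (fitness units)
    c : slope magnitude of embryo mortality vs resources (probability per resource unit), > 0
    d : intercept of embryo mortality (probability); requires ``c <= d <= 1`` so
        that ``m(E) = d - c E`` stays within [0, 1] on the open unit interval
        (``d = c`` is the boundary where mortality vanishes at maximal resources)
    R_s : reproductive value of a singleton birth (fitness units), > b so that
        the costly-twinning threshold ``E* = (R_s - b)/a`` is positive
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    a: float
    b: float
    c: float
    d: float
    R_s: float

    @model_validator(mode="after")
    def _check_invariants(self) -> "OvulationEcology":
        if not self.a > 0:
            raise ValueError("a must be positive (twin value increasing in resources)")
        if not self.c > 0:
            raise ValueError("c must be positive (mortality decreasing in resources)")
        if not self.d >= self.c:
            raise ValueError("d must be at least c so that m(E) = d - cE stays non-negative on (0, 1)")
        if not self.d <= 1:
            raise ValueError("d must not exceed 1 so that m(E) is a probability")
        if not self.R_s > self.b:
            raise ValueError("R_s must exceed b so that the threshold E* = (R_s - b)/a is positive")
        return self

    @property
    def E_star(self) -> float:
        """Resource threshold above which a twin birth outvalues a singleton."""
        return (self.R_s - self.b) / self.a


def _check_resource_level(E) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0.0) or np.any(E >= 1.0):
        raise DomainError("resource endowment E must lie in the open interval (0, 1)")
    return E


def embryo_mortality(E, eco: OvulationEcology):
    """Embryo/foetal mortality ``m(E) = d - c E``, linear and decreasing."""
    E = _check_resource_level(E)
    m = eco.d - eco.c * E
    return m if m.ndim else float(m)


def twin_reproductive_value(E, eco: OvulationEcology):
    """Reproductive value of a twin birth, ``R_t(E) = a E + b``."""
    E = _check_resource_level(E)
    rt = eco.a * E + eco.b
    return rt if rt.ndim else float(rt)


def fitness_double_ovulation(E, eco: OvulationEcology):
    """Fitness of the double-ovulation genotype ``P``.

    Both ova are fertilised; each embryo dies independently with
    probability ``m(E)``, so twins arrive with probability
    ``(1 - m)^2`` and a singleton with probability ``2 m (1 - m)``.
    """
    E = _check_resource_level(E)
    m = eco.d - eco.c * E
    rt = eco.a * E + eco.b
    w = rt * (1.0 - m) ** 2 + eco.R_s * 2.0 * m * (1.0 - m)
    return w if w.ndim else float(w)


def fitness_mono_ovulation(E, eco: OvulationEcology):
    """Fitness of the mono-ovulation genotype ``S``: one embryo, value ``R_s``."""
    E = _check_resource_level(E)
    w = eco.R_s * (1.0 - (eco.d - eco.c * E))
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class QuadraticSelectionForm:
    """The concave quadratic whose sign decides mono vs double ovulation.

    ``evaluate(E) < 0`` means double-ovulation is favoured at ``E``
    (whenever ``m(E) < 1``; at total mortality both fitnesses vanish).
    """

    alpha_q: float
    beta_q: float
    gamma_q: float
    roots: tuple[float, ...]

    def evaluate(self, E):
        E = np.asarray(E, dtype=float)
        q = self.alpha_q * E**2 + self.beta_q * E + self.gamma_q
        return q if q.ndim else float(q)

    def favours_double_ovulation(self, E):
        """True where the quadratic is negative, i.e. ``W_P > W_S``."""
        fav = np.asarray(self.evaluate(E)) < 0.0
        return fav if fav.ndim else bool(fav)


def selection_quadratic(eco: OvulationEcology, root_tol: float = 1e-12) -> QuadraticSelectionForm:
    """Coefficients and real roots of the selection quadratic.

    A discriminant within ``root_tol`` of zero is treated as a double
    root (a single tangency point with no sign change either side).
    """
    alpha_q = -eco.a * eco.c
    beta_q = eco.a * (eco.d - 1.0) + eco.c * (2.0 * eco.R_s - eco.b)
    gamma_q = eco.R_s * (1.0 - 2.0 * eco.d) + eco.b * (eco.d - 1.0)
    disc = beta_q**2 - 4.0 * alpha_q * gamma_q
    if disc < -root_tol:
        roots: tuple[float, ...] = ()
    elif disc <= root_tol:
        roots = (-beta_q / (2.0 * alpha_q),)
    else:
        sq = float(np.sqrt(disc))
        r1 = (-beta_q + sq) / (2.0 * alpha_q)
        r2 = (-beta_q - sq) / (2.0 * alpha_q)
        roots = tuple(sorted((r1, r2)))
    return QuadraticSelectionForm(alpha_q=alpha_q, beta_q=beta_q, gamma_q=gamma_q, roots=roots)


@dataclass(frozen=True)
class ResourceRegion:
    """A maximal interval of resource space with homogeneous selection labels."""

    lower: float
    upper: float
    twinning_adaptive: bool  # R_t(E) >= R_s on the interval
    double_ov_favoured: bool  # W_P > W_S on the interval

    @property
    def width(self) -> float:
        return self.upper - self.lower


def partition_resource_space(eco: OvulationEcology, tol: float = 1e-9) -> list[ResourceRegion]:
    """Partition (0, 1) into regions by twinning- and ovulation-adaptiveness.

    Boundaries are drawn from the quadratic's real roots and the
    threshold ``E*``, restricted to (0, 1); all root configurations
    are handled (0, 1 or 2 roots, roots outside the costly interval,
    ``E*`` at or beyond 1).  Zero-width slivers below ``tol`` are
    dropped and nearby boundaries merged.  Labels come from midpoint
    evaluation, so they agree with pointwise fitness comparison by
    construction.
    """
    quad = selection_quadratic(eco)
    candidates = [r for r in quad.roots] + [eco.E_star]
    bounds = [0.0]
    for x in sorted(c for c in candidates if tol < c < 1.0 - tol):
        if x - bounds[-1] > tol:
            bounds.append(x)
    if 1.0 - bounds[-1] > tol:
        bounds.append(1.0)
    else:
        bounds[-1] = 1.0

    regions: list[ResourceRegion] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (lo + hi)
        rt = eco.a * mid + eco.b
        regions.append(
            ResourceRegion(
                lower=lo,
                upper=hi,
                twinning_adaptive=bool(rt >= eco.R_s),
                double_ov_favoured=bool(quad.evaluate(mid) < 0.0),
            )
        )
    return regions


def ecology_curve(eco: OvulationEcology, n_grid: int = 201) -> pd.DataFrame:
    """Tabulate the landscape on a uniform open-interval grid.

    Columns: ``E, m, R_t, W_P, W_S, favoured`` where ``favoured`` is the
    double-ovulation flag from the selection quadratic.
    """
    if n_grid < 2:
        raise DomainError("n_grid must be at least 2")
    E = np.linspace(GRID_MARGIN, 1.0 - GRID_MARGIN, n_grid)
    quad = selection_quadratic(eco)
    return pd.DataFrame(
        {
            "E": E,
            "m": embryo_mortality(E, eco),
            "R_t": twin_reproductive_value(E, eco),
            "W_P": fitness_double_ovulation(E, eco),
            "W_S": fitness_mono_ovulation(E, eco),
            "favoured": quad.favours_double_ovulation(E),
        }
    )


def sample_random_ecology(rng: np.random.Generator) -> OvulationEcology:
    """Draw a random valid ecology covering the full admissible space.

    Used by property suites: ``d`` uniform on (0.05, 1), ``c`` a uniform
    fraction of ``d`` (so ``0 < c < d``), slope ``a`` on (0.1, 5),
    intercept ``b`` on [0, 1.5) and ``R_s`` a positive offset above it.
    """
    d = rng.uniform(0.05, 1.0)
    c = d * rng.uniform(0.05, 0.95)
    a = rng.uniform(0.1, 5.0)
    b = rng.uniform(0.0, 1.5)
    R_s = b + rng.uniform(0.05, 2.0)
    return OvulationEcology(a=a, b=b, c=c, d=d, R_s=R_s)
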
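"""Prevalence of mothers-of-twins under different fertility regimes.

With a constant per-pregnancy twinning probability ``x`` and ``P``
successful pregnancies (independent of twinning outcomes), the
probability of ever becoming a mother of twins is the complement of
never twinning:

    T = 1 - (1 - x)^P

Under a high-fertility "natural fertility" regime this cumulative
probability is surprisingly large — e.g. a 4.5% twinning rate over
ten pregnancies makes more than a third of women mothers of twins —
which is the demographic backdrop against which community-level
twin-support institutions become plausible.
"""

from __future__ import annotations

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from ._errors import DomainError

__all__ = ["PrevalenceQuery", "mother_of_twins_probability", "prevalence_curves"]


class PrevalenceQuery(BaseModel):
    """A (per-pregnancy twinning probability, pregnancy count) pair."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    x: float
    P: int

    @model_validator(mode="after")
    def _check(self) -> "PrevalenceQuery":
        if not 0.0 <= self.x <= 1.0:
            raise ValueError("twinning probability x must lie in [0, 1]")
        if self.P < 0:
            raise ValueError("pregnancy count P must be a non-negative integer")
        return self


def mother_of_twins_probability(query: PrevalenceQuery | None = None, *, x: float | None = None, P: int | None = None) -> float:
    """Probability of at least one twin birth in ``P`` pregnancies.

    Accepts either a validated :class:`PrevalenceQuery` or keyword
    ``x``/``P`` (validated on the fly).  Monotone non-decreasing in
    both arguments.
    """
    if query is None:
        if x is None or P is None:
            raise DomainError("provide either a PrevalenceQuery or both x and P")
        try:
            query = PrevalenceQuery(x=x, P=P)
        except ValueError as err:
            raise DomainError(str(err)) from err
    return 1.0 - (1.0 - query.x) ** query.P


def prevalence_curves(x_values: list[float], P_max: int) -> pd.DataFrame:
    """Long-format table of cumulative twin-maternity probability.

    One row per ``(x, P)`` with ``P = 0..P_max``; columns ``x, P, T``.
    Each fixed-``x`` column of ``T`` is monotone in ``P``.
    """
    if P_max < 1:
        raise DomainError("P_max must be at least 1")
    rows = [
        {"x": x, "P": P, "T": mother_of_twins_probability(x=x, P=P)}
        for x in x_values
        for P in range(P_max + 1)
    ]
    return pd.DataFrame(rows, columns=["x", "P", "T"])
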
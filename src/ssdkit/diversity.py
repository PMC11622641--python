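"""Specificity diversity: Renyi entropy of specificity in Hill-number form.

Where classical Hill numbers summarise a species-abundance distribution,
specificity diversity (SD) applies the same family of indices to the
distribution of specificity values across a species assemblage.  With
relative specificities p_i = S_i / sum_j S_j over the species with S > 0:

    SD(q) = (sum_i p_i ** q) ** (1 / (1 - q))     for q != 1
    SD(1) = exp(-sum_i p_i * ln p_i)

SD(q) is an equivalent number of species: SD(0) is the richness of the
assemblage's positive-specificity members, SD(1) weighs species in
proportion to their relative specificity, and q > 1 increasingly favours
high-specificity species.  SD(q) is non-increasing in q and equals the
richness at every order when specificities are uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .specificity import SpecificityTable

__all__ = ["EmptyAssemblageError", "SDProfile", "sd_hill", "sd_profile"]

DEFAULT_ORDERS = (0, 1, 2, 3, 4)


class EmptyAssemblageError(ValueError):
    """No positive-specificity species to take a diversity of."""


def sd_hill(specificities: Sequence[float] | np.ndarray, q: float) -> float:
    """Hill-number specificity diversity of one assemblage at order ``q``.

    Zeros are dropped before normalisation; at least one positive value is
    required.  ``q`` may be any real >= 0 even though pipelines use the
    grid {0, 1, 2, 3, 4}.
    """
    s = np.asarray(specificities, dtype=float)
    if np.any(s < 0):
        raise ValueError("specificities must be non-negative")
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    s = s[s > 0]
    if s.size == 0:
        raise EmptyAssemblageError("all specificities are zero")
    if q == 0:
        return float(s.size)
    p = s / s.sum()
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


@dataclass
class SDProfile:
    """SD(q) over a grid of orders for one assemblage in one habitat.

    ``sd[q]`` is NaN for orders flagged in ``undefined`` (assemblage with no
    positive-specificity member in the habitat: SD(0) = 0 is recorded, the
    higher orders are undefined).
    """

    assemblage: str
    habitat: str
    orders: tuple[float, ...]
    sd: dict[float, float]
    undefined: set[float] = field(default_factory=set)


def sd_profile(
    spec: SpecificityTable,
    assemblage: Sequence[str],
    habitat: str,
    orders: Sequence[float] = DEFAULT_ORDERS,
    name: str = "assemblage",
) -> SDProfile:
    """Profile SD(q) for a species set using one habitat's specificity column."""
    if habitat not in spec.S.columns:
        raise LookupError(f"unknown habitat: {habitat!r}")
    members = list(assemblage)
    unknown = set(members) - set(spec.S.index)
    if unknown:
        raise LookupError(f"assemblage members not in table: {sorted(unknown)[:5]}")
    values = spec.S.loc[members, habitat].to_numpy() if members else np.array([])
    sd: dict[float, float] = {}
    undefined: set[float] = set()
    positive = values[values > 0]
    for q in orders:
        if positive.size == 0:
            if q == 0:
                sd[q] = 0.0
            else:
                sd[q] = float("nan")
                undefined.add(q)
        else:
            sd[q] = sd_hill(values, q)
    return SDProfile(
        assemblage=name,
        habitat=habitat,
        orders=tuple(orders),
        sd=sd,
        undefined=undefined,
    )
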
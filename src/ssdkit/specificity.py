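"""Species specificity: position on the generalist-specialist continuum.

Specificity S(i, h) of species *i* in habitat *h* is the product of two
habitat-local quantities computed on the landscape:

* prevalence ``P(i, h)``: the fraction of habitat *h*'s samples in which the
  species was observed (count > 0), and
* abundance share ``A(i, h)``: the habitat's share of the species'
  landscape-wide abundance, computed from habitat-mean relative abundances
  so that unequal cohort sizes do not bias the share.

``S = P * A`` lies in [0, 1]; it is 0 exactly when the species is absent
from the habitat and 1 only for a perfect indicator — a species present in
every sample of the habitat and nowhere else in the landscape.  The product
form is isolated in :func:`specificity_from_groups` so an alternative
definition can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import Landscape, ValidationError

__all__ = [
    "SpecificityTable",
    "specificity_from_groups",
    "species_specificity",
    "specificity_histogram",
    "shared_species_fraction",
    "write_specificity_table",
]


@dataclass
class SpecificityTable:
    """Per-species, per-habitat specificity with its two components.

    All three frames are species x habitats with identical index/columns:
    ``S`` (specificity), ``P`` (prevalence) and ``A`` (abundance share).
    For every species with any abundance in the landscape the shares sum to
    one across habitats.
    """

    S: pd.DataFrame
    P: pd.DataFrame
    A: pd.DataFrame

    @property
    def species_ids(self) -> list[str]:
        return list(self.S.index)

    @property
    def habitats(self) -> list[str]:
        return list(self.S.columns)


def specificity_from_groups(
    counts: np.ndarray,
    groups: Mapping[str, np.ndarray],
    species_ids: Sequence[str],
) -> SpecificityTable:
    """Compute S = P * A over an arbitrary number of habitats.

    ``groups`` maps habitat name -> column indices into ``counts``.  This is
    the one place the specificity formula lives; the two-habitat landscape
    path and the multi-site (sites-as-habitats) network path both call it.
    """
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValidationError("samples with zero total counts are not allowed")
    relab = counts / totals  # per-sample relative abundances
    names = list(groups)
    P = np.empty((counts.shape[0], len(names)))
    M = np.empty_like(P)  # habitat-mean relative abundance
    for k, name in enumerate(names):
        idx = np.asarray(groups[name], dtype=np.intp)
        if idx.size == 0:
            raise ValidationError(f"habitat {name!r} has zero samples")
        P[:, k] = (counts[:, idx] > 0).mean(axis=1)
        M[:, k] = relab[:, idx].mean(axis=1)
    tot = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(tot > 0, M / np.where(tot > 0, tot, 1.0), 0.0)
    S = P * A
    index = pd.Index(list(species_ids), name="species_id")
    return SpecificityTable(
        S=pd.DataFrame(S, index=index, columns=names),
        P=pd.DataFrame(P, index=index, columns=names),
        A=pd.DataFrame(A, index=index, columns=names),
    )


def species_specificity(landscape: Landscape) -> SpecificityTable:
    """Specificity table for the two habitats of a landscape."""
    if landscape.table.n_species < 1:
        raise ValidationError("landscape has no species")
    return specificity_from_groups(
        landscape.table.counts,
        {landscape.habitat_a: landscape.idx_a, landscape.habitat_b: landscape.idx_b},
        landscape.table.species_ids,
    )


def specificity_histogram(
    spec: SpecificityTable, habitat: str, bins: int = 20
) -> pd.DataFrame:
    """Histogram of positive specificity values for one habitat.

    Zero-specificity (absent) species are excluded; bin edges cover (0, 1]
    uniformly and the counts sum to the number of species with S > 0.
    Specificity distributions of real communities are typically highly
    skewed and long-tailed, which this summary makes visible.
    """
    if habitat not in spec.S.columns:
        raise LookupError(f"unknown habitat: {habitat!r}")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    values = spec.S[habitat].to_numpy()
    values = values[values > 0]
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def shared_species_fraction(landscape: Landscape) -> float:
    """Percentage of present species shared by the two habitats.

    Defined as 100 * |present(A) & present(B)| / |present(A) | present(B)|;
    the union denominator keeps the measure symmetric in the habitats.
    """
    counts = landscape.table.counts
    in_a = counts[:, landscape.idx_a].sum(axis=1) > 0
    in_b = counts[:, landscape.idx_b].sum(axis=1) > 0
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        raise ValidationError("no species present in either habitat")
    return 100.0 * np.count_nonzero(in_a & in_b) / union


def write_specificity_table(
    spec: SpecificityTable, path, provenance: str | None = None
) -> None:
    """Write a specificity list TSV: S, P and A per habitat, one species per row."""
    out = pd.DataFrame(index=spec.S.index)
    for h in spec.habitats:
        out[f"S_{h}"] = spec.S[h]
    for h in spec.habitats:
        out[f"P_{h}"] = spec.P[h]
    for h in spec.habitats:
        out[f"A_{h}"] = spec.A[h]
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        out.to_csv(fh, sep="\t")
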
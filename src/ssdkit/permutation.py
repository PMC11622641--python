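"""Specificity permutation (SP) and specificity-diversity permutation (SDP) tests.

Both tests share one null model: the sample (column) labels of the two
habitats are randomly reassigned into groups of the original sizes m and n,
and the full specificity table — prevalence and abundance share alike — is
recomputed for every reassignment.  Whole samples are permuted, never
per-species values, so within-sample species correlation is preserved; the
exchangeable unit under the null of "no habitat effect" is the sample.

The SP test screens species one at a time with the statistic
T_i = |S(i, A) - S(i, B)| and classifies the significant ones (after
Benjamini-Hochberg FDR control) into unique species (US, present in one
habitat only) and enriched species (ES, present in both but with higher
specificity on one side).  The SDP test compares whole assemblages through
D(q) = |SD_A(q) - SD_B(q)| on the same permutation null.

P-values use the add-one estimator p = (1 + #{T* >= T}) / (1 + n_perm), so
the minimum attainable p is 1/(1 + n_perm) and p <= 1 always.  An
exhaustive mode enumerates every distinct label assignment instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .diversity import DEFAULT_ORDERS
from .landscape import Landscape, OTUTable, split_landscape
from .specificity import species_specificity

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORIES",
    "SpeciesClassification",
    "SDPResult",
    "NegativeControlReport",
    "classify_species",
    "sp_test",
    "sp_frame",
    "assemblages_from_classifications",
    "sdp_test",
    "sdp_frame",
    "negative_control",
]

CATEGORIES = ("US-A", "US-B", "ES-A", "ES-B", "IDS")

_EXHAUSTIVE_CAP = 500_000


@dataclass
class SpeciesClassification:
    """SP-test record for one species."""

    species_id: str
    s_a: float
    s_b: float
    fold_change: float  # s_a / s_b; inf when s_b == 0
    p_value: float
    q_value: float
    category: str


@dataclass
class SDPResult:
    """SDP-test record for one assemblage over a grid of orders.

    ``sd_a``/``sd_b`` hold the observed SD(q) per habitat and ``p`` the
    permutation p-value per order.  Assemblages with fewer than two members
    of positive specificity anywhere in the landscape are degenerate and
    recorded as not testable (``testable=False`` with a reason) rather than
    raising.  Inside the permutation machinery SD of an assemblage with no
    positive-specificity member is taken as 0, which makes richness shifts
    (e.g. a unique-species assemblage empty on one side) visible to D(q).
    """

    assemblage: str
    habitat_a: str
    habitat_b: str
    orders: tuple[float, ...]
    sd_a: dict[float, float] = field(default_factory=dict)
    sd_b: dict[float, float] = field(default_factory=dict)
    p: dict[float, float] = field(default_factory=dict)
    n_perm: int = 0
    testable: bool = True
    reason: str = ""


def classify_species(s_a: float, s_b: float, q_value: float, alpha: float) -> str:
    """Assign the five-way category from a specificity pair and its q-value.

    Non-significant species are IDS; among significant ones a zero on one
    side makes the species unique (US) to the other, otherwise it is
    enriched (ES) on the larger side.
    """
    if q_value >= alpha:
        return "IDS"
    if s_b == 0 and s_a > 0:
        return "US-A"
    if s_a == 0 and s_b > 0:
        return "US-B"
    if s_a > s_b:
        return "ES-A"
    if s_b > s_a:
        return "ES-B"
    raise RuntimeError(
        "internal inconsistency: species significant with S_A == S_B"
    )


def _presence_relab(table: OTUTable) -> tuple[np.ndarray, np.ndarray]:
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    return (counts > 0).astype(float), counts / totals


def _pair_stats(
    presence: np.ndarray, relab: np.ndarray, za: np.ndarray, m: int, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Specificity columns for many label assignments at once.

    ``za`` is a samples x k 0/1 membership matrix (1 = habitat A); returns
    ``(S_A, S_B)`` of shape species x k.  The product formula is recomputed
    in full — prevalence and habitat-mean abundance share — per assignment.
    """
    zb = 1.0 - za
    p_a = presence @ za / m
    p_b = presence @ zb / n
    mean_a = relab @ za / m
    mean_b = relab @ zb / n
    tot = mean_a + mean_b
    safe = np.where(tot > 0, tot, 1.0)
    share_a = np.where(tot > 0, mean_a / safe, 0.0)
    share_b = np.where(tot > 0, mean_b / safe, 0.0)
    return p_a * share_a, p_b * share_b


def _random_memberships(
    ns: int, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    order = np.argsort(rng.random((n_perm, ns)), axis=1)
    za = np.zeros((ns, n_perm))
    for k in range(n_perm):
        za[order[k, :m], k] = 1.0
    return za


def _exhaustive_memberships(ns: int, m: int) -> np.ndarray:
    total = comb(ns, m)
    if total > _EXHAUSTIVE_CAP:
        raise ValueError(
            f"exhaustive enumeration of {total} assignments exceeds cap"
        )
    za = np.zeros((ns, total))
    for k, idx in enumerate(combinations(range(ns), m)):
        za[list(idx), k] = 1.0
    return za


def _null_memberships(
    landscape: Landscape,
    n_perm: int,
    method: str,
    rng: np.random.Generator,
) -> np.ndarray:
    ns = landscape.m + landscape.n
    if comb(ns, landscape.m) == 1:
        raise ValueError("degenerate design: only one label assignment exists")
    if method == "exhaustive":
        return _exhaustive_memberships(ns, landscape.m)
    if method == "monte_carlo":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        return _random_memberships(ns, landscape.m, n_perm, rng)
    raise ValueError(f"unknown method: {method!r}")


def sp_test(
    landscape: Landscape,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    method: str = "monte_carlo",
) -> list[SpeciesClassification]:
    """Per-species specificity permutation test with FDR control.

    Species absent from both habitats cannot be classified and are excluded.
    With ``method="exhaustive"`` every distinct label assignment is
    enumerated and p is the exact null fraction with T* >= T (the identity
    assignment is among them, so p > 0); the default Monte-Carlo mode uses
    ``n_perm`` random reassignments with the add-one estimator.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    table = landscape.table
    present = table.counts[:, np.concatenate([landscape.idx_a, landscape.idx_b])]
    tested = np.flatnonzero(present.sum(axis=1) > 0)
    if tested.size == 0:
        raise ValueError("no species present in the landscape")

    # columns of the permuted layout: first m are habitat A, next n are B
    cols = np.concatenate([landscape.idx_a, landscape.idx_b])
    sub = OTUTable(
        list(table.species_ids),
        [table.sample_ids[i] for i in cols],
        table.counts[:, cols],
    )
    presence, relab = _presence_relab(sub)
    m, n = landscape.m, landscape.n

    obs = species_specificity(landscape)
    s_a = obs.S[landscape.habitat_a].to_numpy()
    s_b = obs.S[landscape.habitat_b].to_numpy()
    t_obs = np.abs(s_a - s_b)

    rng = np.random.default_rng(seed)
    za = _null_memberships(landscape, n_perm, method, rng)
    sa_perm, sb_perm = _pair_stats(presence[tested], relab[tested], za, m, n)
    t_null = np.abs(sa_perm - sb_perm)

    exceed = (t_null >= t_obs[tested, None] - 1e-12).sum(axis=1)
    if method == "exhaustive":
        p = exceed / za.shape[1]
    else:
        p = (1.0 + exceed) / (1.0 + n_perm)

    _, q, _, _ = multipletests(p, method="fdr_bh")

    out: list[SpeciesClassification] = []
    for k, i in enumerate(tested):
        sa, sb = float(s_a[i]), float(s_b[i])
        fold = float("inf") if sb == 0 else sa / sb
        out.append(
            SpeciesClassification(
                species_id=table.species_ids[i],
                s_a=sa,
                s_b=sb,
                fold_change=fold,
                p_value=float(p[k]),
                q_value=float(q[k]),
                category=classify_species(sa, sb, float(q[k]), alpha),
            )
        )
    n_sig = sum(c.category != "IDS" for c in out)
    logger.info(
        "SP test: %d species tested, %d significant at FDR %g",
        len(out), n_sig, alpha,
    )
    return out


def sp_frame(classifications: Sequence[SpeciesClassification]) -> pd.DataFrame:
    """Tabulate SP records (one species per row)."""
    return pd.DataFrame(
        {
            "species_id": [c.species_id for c in classifications],
            "S_A": [c.s_a for c in classifications],
            "S_B": [c.s_b for c in classifications],
            "fold_change": [c.fold_change for c in classifications],
            "p": [c.p_value for c in classifications],
            "q": [c.q_value for c in classifications],
            "category": [c.category for c in classifications],
        }
    ).set_index("species_id")


def assemblages_from_classifications(
    classifications: Sequence[SpeciesClassification],
) -> dict[str, list[str]]:
    """The six SDP assemblages: the four categories, DS (their union) and ALL."""
    groups: dict[str, list[str]] = {c: [] for c in ("US-A", "US-B", "ES-A", "ES-B")}
    ds: list[str] = []
    everything: list[str] = []
    for c in classifications:
        everything.append(c.species_id)
        if c.category != "IDS":
            ds.append(c.species_id)
            groups[c.category].append(c.species_id)
    groups["DS"] = ds
    groups["ALL"] = everything
    return groups


def _hill_cols(s: np.ndarray, q: float) -> np.ndarray:
    """Hill number per column of a species x k specificity matrix.

    Columns with no positive mass yield 0 (degenerate-assemblage
    convention used inside the permutation null).
    """
    tot = s.sum(axis=0)
    pos = tot > 0
    out = np.zeros(s.shape[1])
    if q == 0:
        out[:] = (s > 0).sum(axis=0)
        return out
    if not np.any(pos):
        return out
    p = s[:, pos] / tot[pos]
    if q == 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        out[pos] = np.exp(-terms.sum(axis=0))
    else:
        out[pos] = (p**q).sum(axis=0) ** (1.0 / (1.0 - q))
    return out


def sdp_test(
    landscape: Landscape,
    assemblages: Mapping[str, Sequence[str]],
    orders: Sequence[float] = DEFAULT_ORDERS,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[SDPResult]:
    """Assemblage-level specificity-diversity permutation test.

    Membership of each assemblage is held fixed (it comes from an already
    run SP test); the null redistributes sample labels at the landscape
    level and recomputes each habitat's specificity column, from which
    D(q) = |SD_A(q) - SD_B(q)| is re-evaluated per permutation.
    """
    table = landscape.table
    cols = np.concatenate([landscape.idx_a, landscape.idx_b])
    sub = OTUTable(
        list(table.species_ids),
        [table.sample_ids[i] for i in cols],
        table.counts[:, cols],
    )
    presence, relab = _presence_relab(sub)
    m, n = landscape.m, landscape.n

    rng = np.random.default_rng(seed)
    za = _random_memberships(m + n, m, n_perm, rng)
    sa_perm, sb_perm = _pair_stats(presence, relab, za, m, n)

    obs = species_specificity(landscape)
    row = {s: i for i, s in enumerate(table.species_ids)}

    results: list[SDPResult] = []
    for name, members in assemblages.items():
        res = SDPResult(
            assemblage=name,
            habitat_a=landscape.habitat_a,
            habitat_b=landscape.habitat_b,
            orders=tuple(orders),
            n_perm=n_perm,
        )
        members = list(members)
        if not members:
            res.testable = False
            res.reason = "empty assemblage"
            results.append(res)
            continue
        idx = np.array([row[s] for s in members])
        sa = obs.S[landscape.habitat_a].to_numpy()[idx]
        sb = obs.S[landscape.habitat_b].to_numpy()[idx]
        if np.count_nonzero((sa > 0) | (sb > 0)) < 2:
            res.testable = False
            res.reason = "fewer than 2 members with positive specificity"
            results.append(res)
            continue
        na, nb = sa_perm[idx], sb_perm[idx]
        for q in orders:
            sd_a = float(_hill_cols(sa[:, None], q)[0])
            sd_b = float(_hill_cols(sb[:, None], q)[0])
            d_obs = abs(sd_a - sd_b)
            d_null = np.abs(_hill_cols(na, q) - _hill_cols(nb, q))
            res.sd_a[q] = sd_a
            res.sd_b[q] = sd_b
            res.p[q] = float(
                (1.0 + (d_null >= d_obs - 1e-9).sum()) / (1.0 + n_perm)
            )
        results.append(res)
    return results


def sdp_frame(results: Sequence[SDPResult]) -> pd.DataFrame:
    """Tabulate SDP records, one row per (assemblage, q)."""
    rows = []
    for r in results:
        for q in r.orders:
            rows.append(
                {
                    "assemblage": r.assemblage,
                    "q": q,
                    "SD_A": r.sd_a.get(q, float("nan")),
                    "SD_B": r.sd_b.get(q, float("nan")),
                    "p": r.p.get(q, float("nan")),
                    "testable": r.testable,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class NegativeControlReport:
    """False-positive inventory of a self-comparison control run."""

    scheme: str
    alpha: float
    n_perm: int
    n_tested: int
    category_counts: dict[str, int]
    n_significant_species: int
    n_sdp_tests: int
    n_sdp_significant: int
    classifications: list[SpeciesClassification]
    sdp_results: list[SDPResult]

    def summary(self) -> dict:
        return {
            "scheme": self.scheme,
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "n_tested": self.n_tested,
            "category_counts": self.category_counts,
            "n_significant_species": self.n_significant_species,
            "n_sdp_tests": self.n_sdp_tests,
            "n_sdp_significant": self.n_sdp_significant,
        }


def negative_control(
    table: OTUTable,
    scheme: str,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    orders: Sequence[float] = DEFAULT_ORDERS,
) -> NegativeControlReport:
    """Self-comparison control: split one cohort against itself, run SP + SDP.

    Under the duplicated scheme the two habitats are identical, so every
    observed statistic is exactly zero and no detection is possible; under
    the half-divided scheme detections are pure false positives, whose count
    measures how well the FDR control holds at halved sample size.
    """
    rng = np.random.default_rng(seed)
    split_seed, sp_seed, sdp_seed = rng.integers(0, 2**31 - 1, size=3)
    landscape = split_landscape(table, scheme, seed=int(split_seed))
    classifications = sp_test(
        landscape, n_perm=n_perm, alpha=alpha, seed=int(sp_seed)
    )
    assemblages = assemblages_from_classifications(classifications)
    sdp_results = sdp_test(
        landscape, assemblages, orders=orders, n_perm=n_perm, seed=int(sdp_seed)
    )
    counts = {c: 0 for c in CATEGORIES}
    for c in classifications:
        counts[c.category] += 1
    n_sdp_tests = sum(len(r.orders) for r in sdp_results if r.testable)
    n_sdp_sig = sum(
        1
        for r in sdp_results
        if r.testable
        for q in r.orders
        if r.p[q] < alpha
    )
    return NegativeControlReport(
        scheme=scheme,
        alpha=alpha,
        n_perm=n_perm,
        n_tested=len(classifications),
        category_counts=counts,
        n_significant_species=sum(
            c.category != "IDS" for c in classifications
        ),
        n_sdp_tests=n_sdp_tests,
        n_sdp_significant=n_sdp_sig,
        classifications=classifications,
        sdp_results=sdp_results,
    )
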
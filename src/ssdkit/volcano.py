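"""Volcano catalogues of SP-test results and per-site category counts.

The volcano table scatters species by x = log10 of the specificity fold
change S_A / S_B against y = -log10 of the permutation p-value.  Microbiome
data routinely put a zero on one side of the fold change, which the log
cannot take; those species get the zero side substituted by a small epsilon
(half the minimum positive specificity observed among tested species) and a
``zero_flag`` that preserves the information losslessly.  The raw
specificity pair is always carried alongside the transformed coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .permutation import CATEGORIES, SpeciesClassification

logger = logging.getLogger(__name__)

__all__ = [
    "VolcanoPoint",
    "volcano_table",
    "volcano_frame",
    "volcano_plot",
    "category_counts",
]


@dataclass
class VolcanoPoint:
    species_id: str
    s_a: float
    s_b: float
    fold_change_raw: float
    x: float
    p: float
    q: float
    y: float
    category: str
    zero_flag: str  # none | zero_numerator | zero_denominator


def volcano_table(
    classifications: Sequence[SpeciesClassification],
    epsilon: float | None = None,
) -> list[VolcanoPoint]:
    """Volcano coordinates for every tested species with any specificity.

    ``epsilon`` overrides the default zero substitute (half the minimum
    positive specificity among the classifications).  Species with both
    specificities zero carry no fold-change information and are skipped
    with a log entry.
    """
    if epsilon is None:
        positives = [
            v
            for c in classifications
            for v in (c.s_a, c.s_b)
            if v > 0
        ]
        if not positives:
            raise ValueError("no positive specificity values to scale epsilon")
        epsilon = min(positives) / 2.0
    points: list[VolcanoPoint] = []
    for c in classifications:
        if c.s_a == 0 and c.s_b == 0:
            logger.info("volcano: skipping %s (S = 0 in both habitats)", c.species_id)
            continue
        flag = "none"
        num, den = c.s_a, c.s_b
        if num == 0:
            num, flag = epsilon, "zero_numerator"
        if den == 0:
            den, flag = epsilon, "zero_denominator"
        points.append(
            VolcanoPoint(
                species_id=c.species_id,
                s_a=c.s_a,
                s_b=c.s_b,
                fold_change_raw=c.fold_change,
                x=math.log10(num / den),
                p=c.p_value,
                q=c.q_value,
                y=-math.log10(c.p_value),
                category=c.category,
                zero_flag=flag,
            )
        )
    return points


def volcano_frame(points: Sequence[VolcanoPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species_id": [p.species_id for p in points],
            "S_A": [p.s_a for p in points],
            "S_B": [p.s_b for p in points],
            "fold_change_raw": [p.fold_change_raw for p in points],
            "x": [p.x for p in points],
            "p": [p.p for p in points],
            "q": [p.q for p in points],
            "y": [p.y for p in points],
            "category": [p.category for p in points],
            "zero_flag": [p.zero_flag for p in points],
        }
    ).set_index("species_id")


_COLORS = {
    "US-A": "red",
    "US-B": "blue",
    "ES-A": "cyan",
    "ES-B": "green",
    "IDS": "grey",
}


def volcano_plot(points: Sequence[VolcanoPoint], path, alpha: float = 0.05) -> None:
    """Render a basic volcano scatter (cosmetic; the TSV is the contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for cat in CATEGORIES:
        xs = [p.x for p in points if p.category == cat]
        ys = [p.y for p in points if p.category == cat]
        if xs:
            ax.scatter(xs, ys, s=8, c=_COLORS[cat], label=cat, alpha=0.7)
    ax.axvline(0.0, ls=":", c="k", lw=0.8)
    ax.axhline(-math.log10(alpha), ls=":", c="k", lw=0.8)
    ax.set_xlabel("log10 fold change  S_A / S_B")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def category_counts(
    per_site: Mapping[str, Sequence[SpeciesClassification]],
) -> pd.DataFrame:
    """Per-site US/ES/IDS counts with B/A ratio columns.

    The four US/ES counts plus IDS partition the tested species of each
    site.  Ratios with a zero denominator are reported as NaN (undefined).
    """
    if not per_site:
        raise ValueError("at least one site required")
    rows = []
    for site, cls in per_site.items():
        counts = {c: 0 for c in CATEGORIES}
        for c in cls:
            counts[c.category] += 1
        rows.append(
            {
                "site": site,
                **counts,
                "n_tested": len(cls),
                "US_ratio_B_over_A": (
                    counts["US-B"] / counts["US-A"] if counts["US-A"] else float("nan")
                ),
                "ES_ratio_B_over_A": (
                    counts["ES-B"] / counts["ES-A"] if counts["ES-A"] else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows).set_index("site")
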
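"""Synthetic two-habitat and multi-site OTU tables with known ground truth.

The generator emulates the features of real amplicon count tables that the
pipeline's statistics rely on: highly skewed, long-tailed species-abundance
distributions (log-normal base abundances), incomplete per-sample occupancy,
fixed sequencing depth (multinomial read sampling), and planted signal —
unique species given zero probability in one habitat, enriched species with
jointly boosted abundance and prevalence (specificity is a product of both,
so both are perturbed).  A multi-site variant adds habitat blocks (oral- /
skin- / airway- / stool-like) whose sites share block-level abundance
preferences, the ground truth for network-recovery tests.

All randomness flows through one seeded generator; outputs are bit
reproducible for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .landscape import OTUTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_landscape",
    "generate_multisite",
    "DEFAULT_BLOCKS",
]

# multi-site default mirrors a human-body layout: one large oral-like block,
# a skin-like block, and two singleton habitats (airway, stool analogues)
DEFAULT_BLOCKS: dict[str, int] = {"oral": 9, "skin": 4, "airway": 1, "stool": 1}


@dataclass
class SimulationConfig:
    """Study conditions for the two-habitat generator.

    Defaults describe a balanced two-cohort 16S-style comparison: 1000
    species, 30 samples per cohort, log-normal base abundances (sigma 1.5
    gives the long right tail typical of species-abundance distributions),
    right-skewed per-species occupancy (a Beta(0.7, 1.7) draw scaled onto
    ``occupancy_range``, emulating the survey pattern of many sparse taxa
    and few near-ubiquitous ones), and 10^4 reads per sample.  Planted
    species get a detectability floor on base abundance
    (``planted_min_base``) so an "occupied" planted species is actually
    observed at the default depth (expected >= ~10 reads); unique species
    are sampled with probability ``us_prevalence`` per own-habitat sample
    and probability zero elsewhere; enriched species have abundance
    multiplied by ``es_effect`` and occupancy raised by
    ``es_prevalence_shift`` in their habitat, on top of a moderate
    baseline-occupancy floor (``es_base_occupancy_min``) — an enriched
    species is by construction observable on both sides, otherwise a
    prevalence shift carries no meaning.
    """

    n_species: int = 1000
    m: int = 30
    n: int = 30
    lognormal_mean: float = 0.0
    lognormal_sigma: float = 1.5
    occupancy_range: tuple[float, float] = (0.05, 1.0)
    occupancy_beta: tuple[float, float] = (0.7, 1.7)
    es_base_occupancy_min: float = 0.5
    n_us_a: int = 0
    n_us_b: int = 0
    n_es_a: int = 0
    n_es_b: int = 0
    us_prevalence: float = 0.9
    es_effect: float = 8.0
    es_prevalence_shift: float = 0.2
    planted_min_base: float = 3.0
    depth: int = 10_000
    habitat_names: tuple[str, str] = ("A", "B")
    seed: int = 0

    def validate(self) -> None:
        planted = self.n_us_a + self.n_us_b + self.n_es_a + self.n_es_b
        if planted > self.n_species:
            raise ValueError("planted counts exceed n_species")
        if self.es_effect <= 1:
            raise ValueError("es_effect must exceed 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 < self.us_prevalence <= 1):
            raise ValueError("us_prevalence must be in (0, 1]")
        lo, hi = self.occupancy_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("occupancy_range must satisfy 0 < lo <= hi <= 1")
        if min(self.m, self.n) < 2:
            raise ValueError("need >= 2 samples per habitat")


@dataclass
class GroundTruth:
    """Planted truth: per-species category and (multi-site) block layout."""

    categories: pd.Series  # species_id -> US-A | US-B | ES-A | ES-B | null
    site_blocks: dict[str, str] | None = None
    species_blocks: pd.Series | None = None  # preferred block per species
    ubiquitous: list[str] | None = None

    def planted(self, category: str) -> list[str]:
        return list(self.categories.index[self.categories == category])


def _species_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"sp{i:0{width}d}" for i in range(1, n + 1)]


def _sample_counts(
    rng: np.random.Generator,
    profile: np.ndarray,
    occupancy: np.ndarray,
    depth: int,
) -> np.ndarray:
    mask = rng.random(profile.size) < occupancy
    w = profile * mask
    if w.sum() == 0:  # pathological thinning; fall back to the raw profile
        w = profile
    return rng.multinomial(depth, w / w.sum())


def generate_landscape(
    config: SimulationConfig,
) -> tuple[OTUTable, pd.DataFrame, GroundTruth]:
    """Draw one two-habitat landscape: counts, metadata, planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    ns = config.n_species
    species = _species_ids(ns)

    base = rng.lognormal(config.lognormal_mean, config.lognormal_sigma, ns)
    lo, hi = config.occupancy_range
    a, b = config.occupancy_beta
    occ = lo + (hi - lo) * rng.beta(a, b, ns)

    order = rng.permutation(ns)
    k = 0
    planted: dict[str, np.ndarray] = {}
    for cat, cnt in (
        ("US-A", config.n_us_a),
        ("US-B", config.n_us_b),
        ("ES-A", config.n_es_a),
        ("ES-B", config.n_es_b),
    ):
        planted[cat] = order[k : k + cnt]
        k += cnt
    categories = pd.Series("null", index=pd.Index(species, name="species_id"))
    for cat, idx in planted.items():
        categories.iloc[idx] = cat
        base[idx] = np.maximum(base[idx], config.planted_min_base)
        if cat.startswith("ES"):
            occ[idx] = np.maximum(occ[idx], config.es_base_occupancy_min)

    prof = {h: base.copy() for h in config.habitat_names}
    occ_h = {h: occ.copy() for h in config.habitat_names}
    ha, hb = config.habitat_names
    for own, other, us, es in ((ha, hb, "US-A", "ES-A"), (hb, ha, "US-B", "ES-B")):
        prof[other][planted[us]] = 0.0
        occ_h[own][planted[us]] = config.us_prevalence
        prof[own][planted[es]] *= config.es_effect
        occ_h[own][planted[es]] = np.minimum(
            1.0, occ[planted[es]] + config.es_prevalence_shift
        )

    columns = []
    sample_ids = []
    habitat_col = []
    for h, n_samples in ((ha, config.m), (hb, config.n)):
        for j in range(n_samples):
            columns.append(
                _sample_counts(rng, prof[h], occ_h[h], config.depth)
            )
            sample_ids.append(f"{h}_s{j + 1:02d}")
            habitat_col.append(h)
    counts = np.column_stack(columns)
    table = OTUTable(species, sample_ids, counts)
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "habitat": habitat_col, "site": "site1"}
    )
    return table, meta, GroundTruth(categories=categories)


def generate_multisite(
    config: SimulationConfig,
    blocks: Mapping[str, int] | None = None,
    n_ubiquitous: int = 40,
    samples_per_site: int = 10,
    block_effect: float = 8.0,
    site_jitter_sigma: float = 0.25,
    habitat: str = "A",
) -> tuple[OTUTable, pd.DataFrame, GroundTruth]:
    """Draw a one-cohort, multi-site landscape with habitat-block structure.

    ``n_ubiquitous`` species are present at every site (they alone survive
    the all-sites inclusion rule of the network path); each is assigned a
    preferred block whose sites get its abundance multiplied by
    ``block_effect`` (with per-site log-normal jitter shared across that
    site's samples).  The remaining species are block specialists with zero
    probability outside their block.  Because abundance shares compete
    across sites, same-block site pairs end up positively associated in
    specificity and different-block pairs negatively — the planted ground
    truth for SHN recovery.  ``block_effect=1`` turns the block structure
    off while keeping everything else.
    """
    config.validate()
    if blocks is None:
        blocks = DEFAULT_BLOCKS
    if len(blocks) < 2:
        raise ValueError("need >= 2 blocks")
    if any(v < 1 for v in blocks.values()):
        raise ValueError("block sizes must be >= 1")
    if n_ubiquitous > config.n_species:
        raise ValueError("n_ubiquitous exceeds n_species")
    if block_effect < 1:
        raise ValueError("block_effect must be >= 1")

    rng = np.random.default_rng(config.seed)
    ns = config.n_species
    species = _species_ids(ns)
    block_names = list(blocks)
    sites: list[str] = []
    site_blocks: dict[str, str] = {}
    for b in block_names:
        for i in range(blocks[b]):
            name = f"{b}{i + 1}" if blocks[b] > 1 else b
            sites.append(name)
            site_blocks[name] = b

    base = rng.lognormal(config.lognormal_mean, config.lognormal_sigma, ns)
    # ubiquitous species get a high floor so detection at every site is
    # effectively certain at the configured depth
    base[:n_ubiquitous] = np.maximum(base[:n_ubiquitous], 20.0)
    pref = rng.choice(len(block_names), size=ns)
    species_blocks = pd.Series(
        [block_names[b] for b in pref], index=pd.Index(species, name="species_id")
    )

    profiles = np.empty((ns, len(sites)))
    for k, site in enumerate(sites):
        jitter = rng.lognormal(0.0, site_jitter_sigma, ns)
        w = base * jitter
        own = pref == block_names.index(site_blocks[site])
        w = np.where(own, w * block_effect, w)
        w[n_ubiquitous:] = np.where(own[n_ubiquitous:], w[n_ubiquitous:], 0.0)
        profiles[:, k] = w

    columns, sample_ids, site_col = [], [], []
    occupancy = np.ones(ns)
    for k, site in enumerate(sites):
        for j in range(samples_per_site):
            columns.append(
                _sample_counts(rng, profiles[:, k], occupancy, config.depth)
            )
            sample_ids.append(f"{site}_s{j + 1:02d}")
            site_col.append(site)
    table = OTUTable(species, sample_ids, np.column_stack(columns))
    meta = pd.DataFrame(
        {"sample_id": sample_ids, "habitat": habitat, "site": site_col}
    )
    truth = GroundTruth(
        categories=pd.Series(
            "null", index=pd.Index(species, name="species_id")
        ),
        site_blocks=site_blocks,
        species_blocks=species_blocks,
        ubiquitous=species[:n_ubiquitous],
    )
    return table, meta, truth


def write_ground_truth(truth: GroundTruth, path, provenance: str | None = None) -> None:
    frame = pd.DataFrame({"category": truth.categories})
    if truth.species_blocks is not None:
        frame["block"] = truth.species_blocks
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        frame.to_csv(fh, sep="\t")


def config_from_dict(payload: Mapping) -> SimulationConfig:
    """Build a config from parsed YAML/JSON, tolerating list-valued tuples."""
    data = dict(payload)
    for key in ("occupancy_range", "habitat_names"):
        if key in data:
            data[key] = tuple(data[key])
    config = SimulationConfig(**data)
    config.validate()
    return config


def config_to_dict(config: SimulationConfig) -> dict:
    data = asdict(config)
    data["occupancy_range"] = list(config.occupancy_range)
    data["habitat_names"] = list(config.habitat_names)
    return data
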
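"""Count-table containers and the two-habitat landscape abstraction.

A *landscape* is the unit on which species specificity is defined: two
disjoint sets of microbiome samples (habitats, e.g. a male and a female
cohort at one body site) over a shared species list.  This module holds the
validated containers (:class:`OTUTable`, :class:`Landscape`), TSV readers and
writers, and the two negative-control split schemes (duplicated and
half-divided cohorts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "InsufficientSamplesError",
    "OTUTable",
    "Landscape",
    "load_otu_table",
    "write_otu_table",
    "load_metadata",
    "validate_metadata",
    "build_landscape",
    "split_landscape",
]


class FormatError(ValueError):
    """Malformed input table (non-numeric, negative, or duplicated ids)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


class InsufficientSamplesError(ValueError):
    """Too few samples for the requested operation."""


@dataclass
class OTUTable:
    """A species-by-sample matrix of non-negative read counts.

    Parameters
    ----------
    species_ids
        Unique, stable species/OTU identifiers (rows).
    sample_ids
        Unique sample identifiers (columns).
    counts
        Integer matrix of shape ``(n_species, n_samples)``; ``counts[i, j]``
        is the number of reads of species ``i`` observed in sample ``j``.
    """

    species_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D species x samples matrix")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise FormatError("counts must be numeric")
        if np.any(~np.isfinite(self.counts.astype(float))):
            raise FormatError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if np.any(self.counts != np.floor(self.counts)):
            raise FormatError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.species_ids = [str(s) for s in self.species_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.species_ids) != self.counts.shape[0]:
            raise FormatError("species_ids length does not match counts rows")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise FormatError("sample_ids length does not match counts columns")
        dup = _duplicates(self.species_ids)
        if dup:
            raise FormatError(f"duplicated species ids: {sorted(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise FormatError(f"duplicated sample ids: {sorted(dup)}")
        empty = np.asarray(self.sample_ids)[self.counts.sum(axis=0) == 0]
        if empty.size:
            raise ValidationError(
                f"samples with zero total counts: {empty.tolist()}"
            )

    @property
    def n_species(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.species_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OTUTable":
        return cls(
            species_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            counts=frame.to_numpy(),
        )


@dataclass
class Landscape:
    """Two disjoint habitats (sample groups) over one :class:`OTUTable`.

    ``idx_a`` / ``idx_b`` are column indices into ``table.counts``.  The
    species list is the full table's list: species absent from both habitats
    are retained so row indices stay comparable across landscapes.
    """

    table: OTUTable
    habitat_a: str
    habitat_b: str
    idx_a: np.ndarray
    idx_b: np.ndarray

    def __post_init__(self) -> None:
        self.idx_a = np.asarray(self.idx_a, dtype=np.intp)
        self.idx_b = np.asarray(self.idx_b, dtype=np.intp)
        if self.idx_a.size == 0 or self.idx_b.size == 0:
            raise InsufficientSamplesError("both habitats must be non-empty")
        if set(self.idx_a.tolist()) & set(self.idx_b.tolist()):
            raise ValidationError("habitat sample sets must be disjoint")
        n = self.table.n_samples
        if self.idx_a.max() >= n or self.idx_b.max() >= n:
            raise ValidationError("sample index out of range")

    @property
    def m(self) -> int:
        """Number of samples in habitat A."""
        return int(self.idx_a.size)

    @property
    def n(self) -> int:
        """Number of samples in habitat B."""
        return int(self.idx_b.size)

    @property
    def habitats(self) -> tuple[str, str]:
        return (self.habitat_a, self.habitat_b)

    def samples_a(self) -> list[str]:
        return [self.table.sample_ids[i] for i in self.idx_a]

    def samples_b(self) -> list[str]:
        return [self.table.sample_ids[i] for i in self.idx_b]


def _duplicates(items: list[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def load_otu_table(path, rows_are_species: bool = True) -> OTUTable:
    """Read a TSV OTU table (first column = row ids, header = column ids).

    Lines starting with ``#`` are treated as provenance comments and skipped.
    Set ``rows_are_species=False`` for tables with samples as rows.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if frame.empty:
        raise FormatError(f"empty table: {path}")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric counts in {path}: {exc}") from exc
    if not rows_are_species:
        frame = frame.T
    dup = _duplicates(list(map(str, frame.index)))
    if dup:
        raise FormatError(f"duplicated species ids in {path}: {sorted(dup)}")
    table = OTUTable.from_frame(frame)
    logger.info(
        "loaded OTU table %s: %d species x %d samples",
        path, table.n_species, table.n_samples,
    )
    return table


def write_otu_table(table: OTUTable, path, provenance: str | None = None) -> None:
    """Write a TSV OTU table (species as rows, UTF-8, no quoting)."""
    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        table.to_frame().to_csv(fh, sep="\t", index_label="species_id")


METADATA_COLUMNS = ("sample_id", "habitat", "site")


def load_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV with columns sample_id, habitat, site."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    dup = _duplicates(list(meta["sample_id"]))
    if dup:
        raise FormatError(f"duplicated sample ids in metadata: {sorted(dup)}")
    return meta


def validate_metadata(meta: pd.DataFrame, table: OTUTable) -> None:
    """Require exactly one metadata row per analyzed sample."""
    missing = set(table.sample_ids) - set(meta["sample_id"])
    if missing:
        raise ValidationError(
            f"samples without metadata: {sorted(missing)[:10]}"
        )


def build_landscape(
    table: OTUTable,
    meta: pd.DataFrame,
    site: str,
    habitats: tuple[str, str],
) -> Landscape:
    """Restrict a table to one body site and split it into a habitat pair.

    The returned landscape contains only that site's samples from the two
    requested habitat labels (samples with other labels at the site are
    ignored); the species list is kept whole, including all-zero rows.
    """
    validate_metadata(meta, table)
    site_meta = meta[meta["site"] == site]
    if site_meta.empty:
        raise LookupError(f"site not found in metadata: {site!r}")
    ha, hb = habitats
    col = {s: j for j, s in enumerate(table.sample_ids)}
    sub = []
    for label in (ha, hb):
        ids = [
            s for s in site_meta.loc[site_meta["habitat"] == label, "sample_id"]
            if s in col
        ]
        if len(ids) < 2:
            raise InsufficientSamplesError(
                f"habitat {label!r} at site {site!r} has {len(ids)} samples; "
                "need >= 2"
            )
        sub.append(ids)
    keep = sub[0] + sub[1]
    counts = table.counts[:, [col[s] for s in keep]]
    sub_table = OTUTable(list(table.species_ids), keep, counts)
    m = len(sub[0])
    return Landscape(
        table=sub_table,
        habitat_a=ha,
        habitat_b=hb,
        idx_a=np.arange(m),
        idx_b=np.arange(m, m + len(sub[1])),
    )


def split_landscape(table: OTUTable, scheme: str, seed: int | None = None) -> Landscape:
    """Build a negative-control landscape from a single cohort's table.

    ``"duplicated"`` compares the cohort against an identical copy of itself
    (copied sample ids get a ``_dup`` suffix); ``"half_divided"`` compares a
    seeded uniform random partition of the cohort into ceil(n/2) and
    floor(n/2) samples.  Either way no real signal exists between the two
    habitats, so a well-behaved test should detect nothing.
    """
    n = table.n_samples
    if scheme == "duplicated":
        if n < 2:
            raise InsufficientSamplesError("duplicated scheme needs >= 2 samples")
        ids = table.sample_ids + [f"{s}_dup" for s in table.sample_ids]
        counts = np.concatenate([table.counts, table.counts], axis=1)
        big = OTUTable(list(table.species_ids), ids, counts)
        return Landscape(
            table=big,
            habitat_a="original",
            habitat_b="duplicate",
            idx_a=np.arange(n),
            idx_b=np.arange(n, 2 * n),
        )
    if scheme == "half_divided":
        if n < 4:
            raise InsufficientSamplesError(
                f"half_divided scheme needs >= 4 samples, got {n}"
            )
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        m = int(np.ceil(n / 2))
        return Landscape(
            table=table,
            habitat_a="half_1",
            habitat_b="half_2",
            idx_a=np.sort(perm[:m]),
            idx_b=np.sort(perm[m:]),
        )
    raise ValueError(f"unknown split scheme: {scheme!r}")
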
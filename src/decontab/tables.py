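"""Core in-memory containers: taxon-by-sample count tables and exclusion lists.

The central object is :class:`TaxaCountTable`, a validated wrapper around a
pandas DataFrame of non-negative integer read counts (taxa as rows, samples as
columns) with one :class:`~decontab.taxonomy.TaxonomyLineage` per taxon and
optional per-sample cohort labels.  All pipeline stages consume and return
these tables; transforms (rank aggregation, relative abundance) live here.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .taxonomy import RANKS, TaxonomyLineage


class TableValidationError(ValueError):
    """An input table violates the container's invariants."""


def _find_duplicates(labels: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dupes: list[str] = []
    for item in labels:
        if item in seen and item not in dupes:
            dupes.append(item)
        seen.add(item)
    return dupes


@dataclass
class TaxaCountTable:
    """Taxon x sample read counts with lineage metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon_id with sample_id columns; values must be
        non-negative and integral (a float representation like ``7.0`` is
        accepted and coerced; ``7.5`` is an error).
    lineages
        taxon_id -> TaxonomyLineage.  Taxa without an entry get a lineage
        parsed from their id (bare-name dialect).
    cohorts
        Optional sample_id -> cohort label (e.g. ``FNA`` / ``surgical``).
    marker
        Which amplicon the table profiles, ``16S`` or ``ITS``.
    """

    counts: pd.DataFrame
    lineages: dict[str, TaxonomyLineage] = field(default_factory=dict)
    cohorts: dict[str, str] | None = None
    marker: str = "16S"

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise TableValidationError("counts must be a pandas DataFrame")
        dup_taxa = _find_duplicates(self.counts.index)
        if dup_taxa:
            raise TableValidationError(f"duplicate taxon ids: {dup_taxa}")
        dup_samples = _find_duplicates(self.counts.columns)
        if dup_samples:
            raise TableValidationError(f"duplicate sample ids: {dup_samples}")
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                bad = self._first_bad_cell(lambda v: not _is_number(v))
                raise TableValidationError(f"non-numeric count at {bad}")
            if np.isnan(values.astype(float)).any():
                bad = self._first_bad_cell(lambda v: pd.isna(v))
                raise TableValidationError(f"missing count at {bad}")
            floats = values.astype(float)
            if (floats < 0).any():
                bad = self._first_bad_cell(lambda v: float(v) < 0)
                raise TableValidationError(f"negative count at {bad}")
            if not np.array_equal(floats, np.round(floats)):
                bad = self._first_bad_cell(
                    lambda v: float(v) != round(float(v))
                )
                raise TableValidationError(f"non-integral count at {bad}")
        self.counts = self.counts.astype(np.int64)
        missing = [t for t in self.counts.index if t not in self.lineages]
        for taxon_id in missing:
            self.lineages[taxon_id] = TaxonomyLineage.from_string(taxon_id)
        if self.cohorts is not None:
            unknown = set(self.cohorts) - set(self.counts.columns)
            if unknown:
                raise TableValidationError(
                    f"cohort labels for unknown samples: {sorted(unknown)}"
                )

    def _first_bad_cell(self, predicate) -> str:
        for taxon in self.counts.index:
            for sample in self.counts.columns:
                if predicate(self.counts.at[taxon, sample]):
                    return f"(taxon={taxon!r}, sample={sample!r})"
        return "(unknown cell)"

    # -- basic views -----------------------------------------------------

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_depths(self) -> pd.Series:
        """Total read count per sample."""
        return self.counts.sum(axis=0)

    def name_at_rank(self, taxon_id: str, rank: str = "genus") -> str:
        """Display label of a taxon at ``rank`` (``unclassified_*`` fallback)."""
        return self.lineages[taxon_id].label_at(rank)

    def subset_taxa(self, keep: Iterable[str]) -> "TaxaCountTable":
        """A new table restricted to ``keep`` (in current row order)."""
        keep = set(keep)
        idx = [t for t in self.counts.index if t in keep]
        return TaxaCountTable(
            counts=self.counts.loc[idx].copy(),
            lineages={t: self.lineages[t] for t in idx},
            cohorts=dict(self.cohorts) if self.cohorts else None,
            marker=self.marker,
        )

    def subset_samples(self, keep: Iterable[str]) -> "TaxaCountTable":
        keep = set(keep)
        cols = [s for s in self.counts.columns if s in keep]
        cohorts = (
            {s: c for s, c in self.cohorts.items() if s in keep}
            if self.cohorts
            else None
        )
        return TaxaCountTable(
            counts=self.counts[cols].copy(),
            lineages={t: self.lineages[t] for t in self.counts.index},
            cohorts=cohorts,
            marker=self.marker,
        )

    def equals(self, other: "TaxaCountTable") -> bool:
        """Equality on ids, counts and lineage raw strings (order-sensitive)."""
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts.to_numpy(), other.counts.to_numpy())
            and all(
                self.lineages[t].names == other.lineages[t].names
                for t in self.taxon_ids
            )
        )


@dataclass
class RelAbundanceTable:
    """Per-sample proportions on the same axes as a count table.

    Every sample column sums to 1 (within 1e-9); values lie in [0, 1].
    """

    proportions: pd.DataFrame
    lineages: dict[str, TaxonomyLineage] = field(default_factory=dict)
    cohorts: dict[str, str] | None = None
    marker: str = "16S"

    def __post_init__(self) -> None:
        values = self.proportions.to_numpy(dtype=float)
        if values.size:
            if (values < -1e-12).any() or (values > 1 + 1e-12).any():
                raise TableValidationError("proportions outside [0, 1]")
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.proportions.columns[np.argmax(np.abs(sums - 1))]
                raise TableValidationError(
                    f"sample {bad!r} proportions sum to {sums.max():.6f}, not 1"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass(frozen=True)
class ExclusionList:
    """A named set of taxa to remove a priori.

    Names are stored as given but matched case-insensitively; ``source``
    records provenance (``published-curated`` or ``manual``) and ``label`` is
    a free-text citation shown in filter reports.
    """

    names: frozenset[str]
    rank: str = "genus"
    source: str = "published-curated"
    label: str = ""

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if any(not n or not n.strip() for n in self.names):
            raise ValueError("exclusion list contains empty names")

    @classmethod
    def from_names(
        cls,
        names: Iterable[str],
        rank: str = "genus",
        source: str = "published-curated",
        label: str = "",
    ) -> "ExclusionList":
        return cls(
            names=frozenset(n.strip() for n in names if n.strip()),
            rank=rank,
            source=source,
            label=label,
        )

    def normalized(self) -> frozenset[str]:
        """Case-normalized name set used for matching."""
        return frozenset(n.lower() for n in self.names)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self.normalized()


def _is_number(value) -> bool:
    try:
        float(value)
        return True
    except (TypeError, ValueError):
        return False


def aggregate_to_rank(table: TaxaCountTable, rank: str = "genus") -> TaxaCountTable:
    """Sum taxa sharing an identical lineage prefix up to ``rank``.

    Taxa unclassified at ``rank`` are grouped under ``unclassified_<parent>``
    where the parent is their deepest classified ancestor, so reads are never
    dropped: per-sample totals are conserved exactly.  Applying the operation
    to a table already at ``rank`` is the identity (up to row grouping).
    """
    if rank not in RANKS:
        raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}")
    groups: dict[tuple, list[str]] = {}
    labels: dict[tuple, str] = {}
    for taxon_id in table.taxon_ids:
        lineage = table.lineages[taxon_id]
        key = lineage.key_up_to(rank)
        if lineage.name_at(rank) is None:
            # distinct unclassified parents stay distinct rows
            key = key + (lineage.label_at(rank),)
        groups.setdefault(key, []).append(taxon_id)
        labels[key] = lineage.label_at(rank)

    rows = []
    ids: list[str] = []
    lineages: dict[str, TaxonomyLineage] = {}
    used: set[str] = set()
    for key, members in groups.items():
        label = labels[key]
        new_id = label
        suffix = 1
        while new_id in used:  # two clades may share a display label
            suffix += 1
            new_id = f"{label}__{suffix}"
        used.add(new_id)
        ids.append(new_id)
        rows.append(table.counts.loc[members].sum(axis=0))
        first = table.lineages[members[0]]
        limit = RANKS.index(rank)
        names = {r: first.names.get(r) for r in RANKS[: limit + 1]}
        lineages[new_id] = TaxonomyLineage(names=names, raw=first.raw)
    counts = pd.DataFrame(rows, index=ids, columns=table.sample_ids, dtype=np.int64)
    return TaxaCountTable(
        counts=counts,
        lineages=lineages,
        cohorts=dict(table.cohorts) if table.cohorts else None,
        marker=table.marker,
    )


def to_relative_abundance(table: TaxaCountTable) -> RelAbundanceTable:
    """Divide each sample column by its total read count.

    Raises
    ------
    TableValidationError
        If any sample has zero total reads (a proportion is undefined there);
        the error names the offending sample.
    """
    depths = table.sample_depths()
    zero = depths[depths == 0]
    if len(zero):
        raise TableValidationError(
            f"zero-depth samples (cannot normalize): {list(zero.index)}"
        )
    props = table.counts.astype(float).div(depths.astype(float), axis=1)
    return RelAbundanceTable(
        proportions=props,
        lineages=dict(table.lineages),
        cohorts=dict(table.cohorts) if table.cohorts else None,
        marker=table.marker,
    )
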
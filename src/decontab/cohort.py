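"""Cohort-level summaries of decontaminated tables.

Prevalence / core-taxon calls, the most-abundant taxon, percentage rounding
as printed in study reports, cross-cohort Venn overlap, GI-site annotation
and per-sample composition rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import pandas as pd

from .tables import TaxaCountTable, to_relative_abundance


@dataclass
class PrevalenceSummary:
    """Per-taxon prevalence and mean relative abundance.

    ``table`` has columns ``prevalence_fraction`` (share of samples in which
    the taxon was detected) and ``mean_relative_abundance`` (averaged over
    *all* samples, zeros included), indexed by taxon_id.
    """

    table: pd.DataFrame
    n_samples: int = 0

    def prevalence(self, taxon_id: str) -> float:
        return float(self.table.at[taxon_id, "prevalence_fraction"])


@dataclass
class OverlapResult:
    """Venn partition of two cohorts' taxon sets."""

    only_a: frozenset[str]
    shared: frozenset[str]
    only_b: frozenset[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "shared": len(self.shared),
            "only_b": len(self.only_b),
        }

    def to_dict(self) -> dict:
        return {
            "only_a": sorted(self.only_a),
            "shared": sorted(self.shared),
            "only_b": sorted(self.only_b),
            "counts": self.counts,
        }


def prevalence_table(
    table: TaxaCountTable, min_rel_abundance: float = 0.0
) -> PrevalenceSummary:
    """Prevalence and mean relative abundance for every taxon.

    Presence means count > 0; an optional relative-abundance floor
    (``min_rel_abundance``) tightens detection, but defaults off because most
    study designs state no threshold.
    """
    if table.n_taxa == 0 or table.n_samples == 0:
        raise ValueError("prevalence is undefined on an empty table")
    rel = to_relative_abundance(table).proportions
    present = table.counts.gt(0)
    if min_rel_abundance > 0:
        present = present & rel.ge(min_rel_abundance)
    frame = pd.DataFrame(
        {
            "prevalence_fraction": present.mean(axis=1),
            "mean_relative_abundance": rel.where(present, 0.0).mean(axis=1),
        }
    )
    return PrevalenceSummary(table=frame, n_samples=table.n_samples)


def core_taxa(
    table: TaxaCountTable,
    min_prevalence: float = 1.0,
    min_rel_abundance: float = 0.0,
) -> frozenset[str]:
    """Taxa present in at least ``min_prevalence`` of samples (default all)."""
    if not 0.0 < min_prevalence <= 1.0:
        raise ValueError("min_prevalence must be in (0, 1]")
    summary = prevalence_table(table, min_rel_abundance=min_rel_abundance)
    mask = summary.table["prevalence_fraction"] >= min_prevalence
    return frozenset(summary.table.index[mask])


def most_abundant(table: TaxaCountTable) -> str:
    """The taxon with the largest mean relative abundance across samples.

    Mean of per-sample proportions (not pooled counts), so a single deep
    sample cannot dominate.  Exact ties break to the lexicographically
    smaller taxon_id.
    """
    if table.n_taxa == 0:
        raise ValueError("most_abundant is undefined on an empty table")
    means = to_relative_abundance(table).proportions.mean(axis=1)
    best = means.max()
    candidates = sorted(means.index[means == best])
    return candidates[0]


def percent_of_total(part: int, whole: int) -> int:
    """Integer percentage, rounded to nearest with halves away from zero.

    This is the rounding convention of printed cohort reports (e.g. 7 of 65
    -> 11%, 35 of 65 -> 54%), not banker's rounding.
    """
    if whole <= 0:
        raise ValueError("whole must be positive")
    if not 0 <= part <= whole:
        raise ValueError("part must satisfy 0 <= part <= whole")
    q = Fraction(100 * part, whole)
    return int(q + Fraction(1, 2)) if q >= 0 else -int(-q + Fraction(1, 2))


def cohort_overlap(
    taxa_a: Iterable[str],
    taxa_b: Iterable[str],
    synonyms: Mapping[str, str] | None = None,
) -> OverlapResult:
    """Venn partition of two taxon-name sets.

    Names are case-normalized before comparison; spelling variants are *not*
    auto-corrected, but a user-supplied ``synonyms`` map (variant ->
    canonical) is applied first.  The three returned sets are pairwise
    disjoint and use the canonical capitalization seen in cohort A (then B).
    """
    syn = {k.lower(): v for k, v in (synonyms or {}).items()}

    def canon(name: str) -> str:
        return syn.get(name.lower(), name).lower()

    spelling: dict[str, str] = {}
    a_keys: set[str] = set()
    for name in taxa_a:
        key = canon(name)
        a_keys.add(key)
        spelling.setdefault(key, syn.get(name.lower(), name))
    b_keys: set[str] = set()
    for name in taxa_b:
        key = canon(name)
        b_keys.add(key)
        spelling.setdefault(key, syn.get(name.lower(), name))
    return OverlapResult(
        only_a=frozenset(spelling[k] for k in a_keys - b_keys),
        shared=frozenset(spelling[k] for k in a_keys & b_keys),
        only_b=frozenset(spelling[k] for k in b_keys - a_keys),
    )


def annotate_gi_overlap(
    taxa: Iterable[str], gi_site_lists: Mapping[str, Iterable[str]]
) -> dict[str, list[str]]:
    """Tag each taxon with the GI-site lists that contain it.

    ``gi_site_lists`` maps a site label (e.g. ``duodenum``, ``stomach``) to
    the genera reported there; matching is case-insensitive exact.  A pure
    lookup -- no inference, taxa found in no list get an empty tag list.
    """
    normalized = {
        site: {n.lower() for n in names} for site, names in gi_site_lists.items()
    }
    out: dict[str, list[str]] = {}
    for taxon in taxa:
        out[taxon] = sorted(
            site for site, names in normalized.items() if taxon.lower() in names
        )
    return out


def composition_summary(table: TaxaCountTable) -> pd.DataFrame:
    """Per-sample taxa ranked by descending relative abundance.

    Long-format frame with columns ``sample``, ``taxon_id``, ``proportion``,
    ``rank`` (1 = most abundant in that sample; ties rank by taxon_id).
    Per-sample proportions sum to 1.
    """
    rel = to_relative_abundance(table).proportions
    rows = []
    for sample in rel.columns:
        ordered = rel[sample].sort_values(ascending=False, kind="mergesort")
        ordered = ordered.loc[
            sorted(ordered.index, key=lambda t: (-ordered.loc[t], t))
        ]
        for rank, (taxon_id, prop) in enumerate(ordered.items(), start=1):
            rows.append(
                {"sample": sample, "taxon_id": taxon_id, "proportion": float(prop), "rank": rank}
            )
    return pd.DataFrame(rows, columns=["sample", "taxon_id", "proportion", "rank"])
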
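"""Contaminant removal for low-biomass amplicon profiles.

Biopsies taken through the upper GI tract (and any low-biomass specimen)
carry abundant non-resident DNA: reagent and laboratory contaminants plus
taxa picked up along the sampling route.  This module removes them in two
complementary ways:

1. **Exclusion lists** -- curated catalogues of genera known as reagent/lab
   contaminants are dropped a priori by case-insensitive exact name match at
   the list's rank.
2. **Co-occurrence screening** -- contamination tends to enter all samples
   through a shared vehicle, so contaminant taxa co-vary with each other
   across samples.  Given a set of *indicator* taxa designated as known
   contaminants, every taxon whose Spearman rank correlation against any
   indicator strictly exceeds a threshold (default 0.3) is also removed.

Every removal is recorded in a :class:`FilterReport` with its stage and
evidence (matched list, or the maximal correlation and the indicator that
produced it), so the whole filtering pass is auditable after the fact.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import ExclusionList, TableValidationError, TaxaCountTable, to_relative_abundance

logger = logging.getLogger(__name__)

DISPOSITIONS = (
    "retained",
    "removed_list",
    "removed_correlation",
    "removed_manual",
    "removed_indicator",
)


@dataclass(frozen=True)
class DecontamParams:
    """Knobs of the correlation filter.

    Attributes
    ----------
    rho_threshold
        Spearman cutoff; a taxon is removed when its maximal correlation
        against any indicator is *strictly greater* than this (default 0.3).
    min_samples_for_correlation
        Smallest sample count at which the correlation screen runs at all
        (default 4).  With two samples Spearman is always +/-1 and the screen
        degenerates, so below the floor the stage is skipped with a warning.
    transform
        Abundance scale on which correlations are computed:
        ``relative_abundance`` (default; per-sample proportions, so depth
        differences between samples do not masquerade as co-occurrence) or
        ``raw_counts``.
    constant_vector_rho
        Correlation assigned when either vector has zero variance (default
        0.0): a flat profile carries no co-occurrence evidence.
    """

    rho_threshold: float = 0.3
    min_samples_for_correlation: int = 4
    transform: str = "relative_abundance"
    constant_vector_rho: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_threshold <= 1.0:
            raise ValueError("rho_threshold must be in [0, 1]")
        if self.min_samples_for_correlation < 2:
            raise ValueError("min_samples_for_correlation must be >= 2")
        if self.transform not in ("relative_abundance", "raw_counts"):
            raise ValueError(
                "transform must be 'relative_abundance' or 'raw_counts'"
            )


@dataclass(frozen=True)
class IndicatorSet:
    """Taxa designated as known contamination indicators."""

    taxon_ids: frozenset[str]

    @classmethod
    def from_ids(cls, ids: Iterable[str]) -> "IndicatorSet":
        return cls(taxon_ids=frozenset(ids))

    def validate_against(self, table: TaxaCountTable) -> None:
        missing = self.taxon_ids - set(table.taxon_ids)
        if missing:
            raise TableValidationError(
                f"indicator taxa absent from table: {sorted(missing)}"
            )
        if not self.taxon_ids:
            raise TableValidationError("indicator set is empty")

    def __len__(self) -> int:
        return len(self.taxon_ids)


@dataclass
class TaxonRecord:
    """Disposition and evidence for one input taxon."""

    taxon_id: str
    disposition: str
    evidence: dict = field(default_factory=dict)


@dataclass
class FilterReport:
    """Auditable account of a decontamination run.

    Every input taxon appears exactly once; retained plus removed records
    partition the input set, so taxon counts are conserved by construction.
    """

    records: list[TaxonRecord] = field(default_factory=list)
    params: DecontamParams | None = None
    n_input: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return sum(1 for r in self.records if r.disposition == "retained")

    @property
    def n_removed(self) -> int:
        return sum(1 for r in self.records if r.disposition != "retained")

    def by_disposition(self, disposition: str) -> list[str]:
        return [r.taxon_id for r in self.records if r.disposition == disposition]

    def validate(self) -> None:
        ids = [r.taxon_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("a taxon appears more than once in the report")
        if len(ids) != self.n_input:
            raise ValueError(
                f"report covers {len(ids)} taxa but input had {self.n_input}"
            )
        for r in self.records:
            if r.disposition not in DISPOSITIONS:
                raise ValueError(f"unknown disposition {r.disposition!r}")
            if r.disposition == "removed_correlation":
                if self.params and not (
                    r.evidence.get("max_rho", -math.inf) > self.params.rho_threshold
                ):
                    raise ValueError(
                        f"{r.taxon_id}: removed_correlation without max_rho "
                        f"exceeding the threshold"
                    )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "taxon_id": r.taxon_id,
                    "disposition": r.disposition,
                    "matched_list": r.evidence.get("matched_list", ""),
                    "max_rho": r.evidence.get("max_rho", ""),
                    "partner_indicator": r.evidence.get("partner_indicator", ""),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["taxon_id", "disposition", "matched_list", "max_rho", "partner_indicator"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "params": {
                "rho_threshold": self.params.rho_threshold,
                "min_samples_for_correlation": self.params.min_samples_for_correlation,
                "transform": self.params.transform,
                "constant_vector_rho": self.params.constant_vector_rho,
            }
            if self.params
            else None,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_removed": self.n_removed,
            "warnings": self.warnings,
            "taxa": [
                {"taxon_id": r.taxon_id, "disposition": r.disposition, "evidence": r.evidence}
                for r in self.records
            ],
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(doc, handle, indent=2)


def spearman_rho(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    constant_vector_rho: float = 0.0,
) -> float:
    """Spearman rank correlation with midranks for ties.

    The statistic is the Pearson correlation of the two rank vectors, where
    tied observations receive the average of the ranks they span.  If either
    vector is constant the correlation is undefined; ``constant_vector_rho``
    (default 0) is returned instead so the filter stays total.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return constant_vector_rho
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _rank_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Midrank each row; return (centered ranks, row sums of squares, constant mask).

    The correlation of rows i, j is then ``(c_i @ c_j) / sqrt(ss_i * ss_j)``,
    taking the square root of the *product* -- the same expression as the
    scalar path -- so constructed boundary cases (e.g. an exact 0.3) evaluate
    bit-identically in both.
    """
    ranks = stats.rankdata(matrix, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    sumsq = (centered**2).sum(axis=1)
    constant = sumsq == 0
    return centered, np.where(constant, 1.0, sumsq), constant


def _rho_block(
    centered: np.ndarray, sumsq: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    return centered[rows] @ centered[cols].T / np.sqrt(
        np.outer(sumsq[rows], sumsq[cols])
    )


def pairwise_spearman(
    table: TaxaCountTable,
    params: DecontamParams = DecontamParams(),
) -> pd.DataFrame:
    """All-pairs taxon-taxon Spearman matrix on the configured transform."""
    matrix = _transformed_matrix(table, params)
    centered, sumsq, constant = _rank_rows(matrix)
    everything = np.arange(len(sumsq))
    rho = _rho_block(centered, sumsq, everything, everything)
    rho[constant, :] = params.constant_vector_rho
    rho[:, constant] = params.constant_vector_rho
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=table.taxon_ids, columns=table.taxon_ids)


def _transformed_matrix(table: TaxaCountTable, params: DecontamParams) -> np.ndarray:
    if params.transform == "relative_abundance":
        return to_relative_abundance(table).proportions.to_numpy(dtype=float)
    return table.counts.to_numpy(dtype=float)


def apply_exclusion_list(
    table: TaxaCountTable, exclusion: ExclusionList
) -> tuple[TaxaCountTable, list[TaxonRecord], list[str]]:
    """Drop taxa whose name at the list's rank matches a list entry.

    Matching is case-insensitive and exact at ``exclusion.rank``.  Returns
    the filtered table, one record per *removed* taxon, and the list entries
    that matched nothing (reported as warnings, never errors: a curated list
    is expected to mention taxa a given dataset lacks).
    """
    wanted = exclusion.normalized()
    disposition = "removed_manual" if exclusion.source == "manual" else "removed_list"
    removed: list[TaxonRecord] = []
    kept: list[str] = []
    hit: set[str] = set()
    for taxon_id in table.taxon_ids:
        name = table.lineages[taxon_id].name_at(exclusion.rank)
        key = name.lower() if name else None
        if key is not None and key in wanted:
            hit.add(key)
            removed.append(
                TaxonRecord(
                    taxon_id=taxon_id,
                    disposition=disposition,
                    evidence={"matched_list": exclusion.label, "matched_name": name},
                )
            )
        else:
            kept.append(taxon_id)
    unused = sorted(n for n in exclusion.names if n.lower() not in hit)
    for name in unused:
        logger.warning(
            "exclusion list %r entry %r matched no taxon", exclusion.label, name
        )
    if not kept:
        logger.warning(
            "exclusion list %r removed every taxon; table is now empty",
            exclusion.label,
        )
    return table.subset_taxa(kept), removed, unused


def correlation_filter(
    table: TaxaCountTable,
    indicators: IndicatorSet,
    params: DecontamParams = DecontamParams(),
) -> tuple[TaxaCountTable, list[TaxonRecord], pd.DataFrame]:
    """Remove taxa co-varying with indicator contaminants.

    Abundances are transformed per ``params.transform`` on the table exactly
    as passed in (a single pass; correlations are never recomputed after
    removals).  For every non-indicator taxon the maximum Spearman
    correlation over all indicators is computed; taxa with
    ``max_rho > params.rho_threshold`` (strictly) are removed with the
    best-correlated indicator recorded as evidence.  Indicator taxa
    themselves are removed as ``removed_indicator`` -- they are contaminants
    by designation.

    If the table has fewer than ``params.min_samples_for_correlation``
    samples the stage is skipped with a warning and the table is returned
    unchanged (no removals at all, indicators included).

    Returns the filtered table, the removal records, and the full
    (non-indicator x indicator) correlation matrix for reporting.
    """
    indicators.validate_against(table)
    empty = pd.DataFrame(index=[], columns=sorted(indicators.taxon_ids))
    if table.n_samples < params.min_samples_for_correlation:
        logger.warning(
            "correlation filter skipped: %d samples < min_samples_for_correlation=%d",
            table.n_samples,
            params.min_samples_for_correlation,
        )
        return table, [], empty

    matrix = _transformed_matrix(table, params)
    centered, sumsq, constant = _rank_rows(matrix)
    ids = table.taxon_ids
    ind_ids = [t for t in ids if t in indicators.taxon_ids]
    other_ids = [t for t in ids if t not in indicators.taxon_ids]
    pos = {t: i for i, t in enumerate(ids)}
    ind_idx = np.array([pos[t] for t in ind_ids], dtype=int)
    oth_idx = np.array([pos[t] for t in other_ids], dtype=int)

    rho = _rho_block(centered, sumsq, oth_idx, ind_idx)  # (n_other, n_indicator)
    rho[constant[oth_idx], :] = params.constant_vector_rho
    rho[:, constant[ind_idx]] = params.constant_vector_rho
    rho_frame = pd.DataFrame(rho, index=other_ids, columns=ind_ids)

    removed: list[TaxonRecord] = []
    kept: list[str] = []
    for taxon_id in other_ids:
        row = rho_frame.loc[taxon_id]
        best = row.idxmax()
        max_rho = float(row.loc[best])
        if max_rho > params.rho_threshold:
            removed.append(
                TaxonRecord(
                    taxon_id=taxon_id,
                    disposition="removed_correlation",
                    evidence={"max_rho": max_rho, "partner_indicator": best},
                )
            )
            logger.info(
                "removed %s (correlation): max_rho=%.3f vs indicator %s",
                taxon_id,
                max_rho,
                best,
            )
        else:
            kept.append(taxon_id)
    for taxon_id in ind_ids:
        removed.append(
            TaxonRecord(taxon_id=taxon_id, disposition="removed_indicator", evidence={})
        )
        logger.info("removed %s (designated indicator contaminant)", taxon_id)
    return table.subset_taxa(kept), removed, rho_frame


def decontaminate(
    table: TaxaCountTable,
    published_lists: Sequence[ExclusionList] = (),
    manual_list: ExclusionList | None = None,
    indicators: IndicatorSet | None = None,
    params: DecontamParams = DecontamParams(),
) -> tuple[TaxaCountTable, FilterReport]:
    """Run the full decontamination pipeline and account for every taxon.

    Stage order: published exclusion lists, then the correlation screen
    (when indicators are given and the sample count allows), then the manual
    list.  Correlations are computed once, on the post-list table's
    transformed abundances.  The returned :class:`FilterReport` covers every
    input taxon exactly once, so retained + removed always equals the input
    taxon count.
    """
    report = FilterReport(params=params, n_input=table.n_taxa)
    current = table

    for exclusion in published_lists:
        current, removed, unused = apply_exclusion_list(current, exclusion)
        report.records.extend(removed)
        report.warnings.extend(
            f"list {exclusion.label!r}: unused entry {name!r}" for name in unused
        )

    if indicators is not None and len(indicators):
        present = IndicatorSet.from_ids(
            indicators.taxon_ids & set(current.taxon_ids)
        )
        gone = indicators.taxon_ids - set(current.taxon_ids)
        if gone & set(table.taxon_ids):
            # an earlier list already removed them; fine, note it
            report.warnings.append(
                f"indicators already removed by lists: {sorted(gone & set(table.taxon_ids))}"
            )
        if len(present):
            if current.n_samples >= params.min_samples_for_correlation:
                current, removed, _rho = correlation_filter(current, present, params)
                report.records.extend(removed)
            else:
                report.warnings.append(
                    f"correlation filter skipped: {current.n_samples} samples < "
                    f"min_samples_for_correlation={params.min_samples_for_correlation}"
                )
                logger.warning(report.warnings[-1])

    if manual_list is not None:
        current, removed, unused = apply_exclusion_list(current, manual_list)
        report.records.extend(removed)
        report.warnings.extend(
            f"list {manual_list.label!r}: unused entry {name!r}" for name in unused
        )

    for taxon_id in current.taxon_ids:
        report.records.append(TaxonRecord(taxon_id=taxon_id, disposition="retained"))
    report.validate()
    return current, report
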
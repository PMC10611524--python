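"""Synthetic contaminated low-biomass amplicon tables with ground truth.

The generator produces genus-level count tables that mimic a small biopsy
cohort profiled at >= 10,000 reads per sample, contaminated the way a shared
sampling route or reagent lot contaminates real specimens:

* **Residents** -- the genuine community.  Taxon ``i`` in sample ``s`` has
  expected abundance ``a_i * eps_is`` with ``a_i ~ LogNormal(mu_r, sigma_r)``
  (a skewed, few-dominants genus profile) and multiplicative noise
  ``eps ~ LogNormal(0, taxon_noise_sigma)``.
* **Correlation contaminants** -- enter through a single per-sample
  contamination load ``lambda_s ~ LogNormal(mu_l, sigma_l)``; taxon ``j``
  contributes ``w_j * lambda_s * eps_js`` with ``w_j`` lognormal.  Because
  every such taxon shares ``lambda_s``, their profiles co-vary across
  samples -- exactly the structure a Spearman screen against indicator taxa
  detects.  A designated subset of them is flagged as the indicator set.
* **List contaminants** -- drawn like residents (no shared load) but named
  after genera from an exclusion list, so the list stage removes them by name.

Expected abundances are normalized to per-sample proportions and counts are
drawn multinomially at depth ``depth_min`` plus a Poisson offset.  All
randomness flows from the explicit seed; the same params give bit-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from ._contaminants import CONTAMINANT_GENERA
from .decontam import IndicatorSet, pairwise_spearman, DecontamParams
from .tables import ExclusionList, TaxaCountTable
from .taxonomy import TaxonomyLineage


@dataclass(frozen=True)
class SimParams:
    """Generator settings.

    Cohort sizes default to 5 biopsy (A) and 10 surgical (B) samples, the
    shape of a small unmatched feasibility cohort; ``depth_min`` defaults to
    10,000 reads, a typical per-sample sequencing floor.  Lognormal
    parameters are (mu, sigma) of the underlying normal.
    """

    n_samples_a: int = 5
    n_samples_b: int = 10
    n_resident: int = 70
    n_list_contaminant: int = 10
    n_corr_contaminant: int = 20
    n_indicator: int = 5
    depth_min: int = 10_000
    depth_extra_mean: float = 2_000.0
    resident_lognormal: tuple[float, float] = (0.0, 1.0)
    contaminant_weight_lognormal: tuple[float, float] = (0.0, 0.5)
    load_lognormal: tuple[float, float] = (0.0, 1.0)
    taxon_noise_sigma: float = 0.3
    shared_resident_fraction: float = 0.54
    marker: str = "16S"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_samples_a",
            "n_samples_b",
            "n_resident",
            "n_list_contaminant",
            "n_corr_contaminant",
            "n_indicator",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_min < 1:
            raise ValueError("depth_min must be >= 1")
        if not 0.0 <= self.shared_resident_fraction <= 1.0:
            raise ValueError("shared_resident_fraction must be in [0, 1]")
        if self.n_indicator > self.n_corr_contaminant:
            raise ValueError("n_indicator cannot exceed n_corr_contaminant")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError(
                "SimParams.seed is required; the generator draws no implicit entropy"
            )
        return self.seed


#: Named presets: ``paper_scale`` mirrors a 5-biopsy / 10-surgical cohort with
#: 65 resident genera; ``test_scale`` uses 24 samples, where a rank-correlation
#: screen is statistically stable, for recovery testing.
PRESETS: dict[str, SimParams] = {
    "paper_scale": SimParams(
        n_samples_a=5, n_samples_b=10, n_resident=65,
        n_list_contaminant=10, n_corr_contaminant=20,
    ),
    "test_scale": SimParams(
        n_samples_a=24, n_samples_b=0, n_resident=70,
        n_list_contaminant=10, n_corr_contaminant=20,
    ),
}


def preset(name: str, seed: int | None = None, **overrides) -> SimParams:
    """A preset by name, optionally with a seed and field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = PRESETS[name]
    if seed is not None:
        overrides["seed"] = seed
    return replace(params, **overrides) if overrides else params


@dataclass
class SyntheticTruth:
    """Ground truth for a generated table.

    ``labels`` maps every taxon_id to ``resident``, ``list_contaminant``,
    ``corr_contaminant`` or ``indicator`` (indicators are the designated
    subset of correlation contaminants).  ``loads`` is the per-sample
    contamination load lambda_s; ``indicator_rho`` the realized Spearman
    (on relative abundances) between each non-indicator correlation
    contaminant and each indicator.
    """

    labels: dict[str, str]
    loads: pd.Series
    params: SimParams
    indicator_rho: pd.DataFrame = field(default_factory=pd.DataFrame)

    def taxa_with_label(self, label: str) -> frozenset[str]:
        return frozenset(t for t, lab in self.labels.items() if lab == label)

    @property
    def indicators(self) -> IndicatorSet:
        return IndicatorSet.from_ids(self.taxa_with_label("indicator"))

    def validate(self, table: TaxaCountTable) -> None:
        if set(self.labels) != set(table.taxon_ids):
            raise ValueError("truth labels do not partition the table's taxa")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon_id": list(self.labels), "label": list(self.labels.values())}
        )


def _lineage_for(genus: str, kingdom: str) -> TaxonomyLineage:
    prefix = "k__{k};p__{p};c__{c};o__{o};f__{f};g__{g}"
    raw = prefix.format(
        k=kingdom, p=f"{genus}_phylum", c=f"{genus}_class",
        o=f"{genus}_order", f=f"{genus}_family", g=genus,
    )
    return TaxonomyLineage.from_string(raw)


def _draw_block(
    rng: np.random.Generator,
    base: np.ndarray,
    per_sample: np.ndarray,
    noise_sigma: float,
) -> np.ndarray:
    """Expected abundances base_i * per_sample_s * noise, shape (taxa, samples)."""
    n_taxa, n_samples = base.size, per_sample.size
    noise = np.exp(rng.normal(0.0, noise_sigma, size=(n_taxa, n_samples)))
    return base[:, None] * per_sample[None, :] * noise


def _sample_counts(
    rng: np.random.Generator, expected: np.ndarray, params: SimParams
) -> np.ndarray:
    """Multinomial read sampling per sample at depth >= depth_min."""
    n_taxa, n_samples = expected.shape
    counts = np.zeros((n_taxa, n_samples), dtype=np.int64)
    for s in range(n_samples):
        depth = params.depth_min + int(rng.poisson(params.depth_extra_mean))
        col = expected[:, s]
        total = col.sum()
        if total <= 0:
            raise ValueError("all expected abundances are zero in a sample")
        counts[:, s] = rng.multinomial(depth, col / total)
    return counts


def _contaminant_names(
    params: SimParams, rng: np.random.Generator, name_source: Iterable[str] | None
) -> list[str]:
    pool = list(name_source) if name_source is not None else list(CONTAMINANT_GENERA)
    if params.n_list_contaminant > len(pool):
        raise ValueError(
            f"need {params.n_list_contaminant} list-contaminant names, "
            f"name source has {len(pool)}"
        )
    picked = rng.choice(len(pool), size=params.n_list_contaminant, replace=False)
    return [pool[int(i)] for i in sorted(picked)]


def generate_table(
    params: SimParams,
    list_name_source: Iterable[str] | None = None,
    sample_prefix: str = "fna",
    cohort: str = "FNA",
    _rng: np.random.Generator | None = None,
    _resident_names: list[str] | None = None,
    _contaminated: bool = True,
) -> tuple[TaxaCountTable, SyntheticTruth]:
    """Generate one contaminated table (cohort A geometry) with truth labels.

    Uses ``params.n_samples_a`` samples.  ``list_name_source`` supplies the
    genus names given to list-type contaminants (defaults to the bundled
    contaminant-genus list, so a matching exclusion list removes them).
    """
    n_total = params.n_resident + params.n_list_contaminant + params.n_corr_contaminant
    if n_total == 0:
        raise ValueError("cannot generate a table with zero taxa")
    rng = _rng if _rng is not None else np.random.default_rng(params.require_seed())
    n_samples = params.n_samples_a
    if n_samples < 1:
        raise ValueError("need at least one sample")

    kingdom = "Fungi" if params.marker.upper() == "ITS" else "Bacteria"
    resident_names = _resident_names or [
        f"Resident{i:03d}" for i in range(1, params.n_resident + 1)
    ]
    list_names = _contaminant_names(params, rng, list_name_source)
    corr_names = [f"Contam{i:03d}" for i in range(1, params.n_corr_contaminant + 1)]

    mu_r, sg_r = params.resident_lognormal
    mu_w, sg_w = params.contaminant_weight_lognormal
    mu_l, sg_l = params.load_lognormal

    a = np.exp(rng.normal(mu_r, sg_r, size=params.n_resident))
    a_list = np.exp(rng.normal(mu_r, sg_r, size=params.n_list_contaminant))
    w = np.exp(rng.normal(mu_w, sg_w, size=params.n_corr_contaminant))
    loads = np.exp(rng.normal(mu_l, sg_l, size=n_samples))
    ones = np.ones(n_samples)

    blocks, names, labels = [], [], {}
    if params.n_resident:
        blocks.append(_draw_block(rng, a, ones, params.taxon_noise_sigma))
        names += resident_names
        labels.update({n: "resident" for n in resident_names})
    if _contaminated and params.n_list_contaminant:
        blocks.append(_draw_block(rng, a_list, ones, params.taxon_noise_sigma))
        names += list_names
        labels.update({n: "list_contaminant" for n in list_names})
    if _contaminated and params.n_corr_contaminant:
        blocks.append(_draw_block(rng, w, loads, params.taxon_noise_sigma))
        names += corr_names
        for i, n in enumerate(corr_names):
            labels[n] = "indicator" if i < params.n_indicator else "corr_contaminant"

    expected = np.vstack(blocks)
    counts = _sample_counts(rng, expected, params)
    sample_ids = [f"{sample_prefix}{s:02d}" for s in range(1, n_samples + 1)]
    table = TaxaCountTable(
        counts=pd.DataFrame(counts, index=names, columns=sample_ids),
        lineages={n: _lineage_for(n, kingdom) for n in names},
        cohorts={s: cohort for s in sample_ids},
        marker=params.marker,
    )
    truth = SyntheticTruth(
        labels=labels,
        loads=pd.Series(loads, index=sample_ids, name="lambda"),
        params=params,
    )
    truth.indicator_rho = _realized_indicator_rho(table, truth)
    truth.validate(table)
    return table, truth


def _realized_indicator_rho(
    table: TaxaCountTable, truth: SyntheticTruth
) -> pd.DataFrame:
    indicators = sorted(truth.taxa_with_label("indicator"))
    targets = sorted(truth.taxa_with_label("corr_contaminant"))
    if not indicators or not targets or table.n_samples < 2:
        return pd.DataFrame(index=targets, columns=indicators, dtype=float)
    rho = pairwise_spearman(table, DecontamParams())
    return rho.loc[targets, indicators]


def generate_cohort_pair(
    params: SimParams,
    list_name_source: Iterable[str] | None = None,
) -> tuple[TaxaCountTable, TaxaCountTable, SyntheticTruth]:
    """Generate an unmatched cohort pair: contaminated A, clean B.

    The two cohorts share ``shared_resident_fraction`` of A's resident taxa
    (each cohort also carries private residents, keeping ``n_resident``
    residents per cohort); contamination -- list and correlation type -- is
    applied to cohort A only, the arm sampled through a contaminating route.
    Truth labels cover the union of both tables' taxa; cohort-B-only
    residents are labelled ``resident``.
    """
    seed = params.require_seed()
    rng = np.random.default_rng(seed)
    n_shared = round(params.shared_resident_fraction * params.n_resident)
    n_private = params.n_resident - n_shared
    shared = [f"Shared{i:03d}" for i in range(1, n_shared + 1)]
    private_a = [f"PrivateA{i:03d}" for i in range(1, n_private + 1)]
    private_b = [f"PrivateB{i:03d}" for i in range(1, n_private + 1)]

    table_a, truth_a = generate_table(
        params,
        list_name_source=list_name_source,
        sample_prefix="fna",
        cohort="FNA",
        _rng=rng,
        _resident_names=shared + private_a,
    )
    params_b = replace(params, n_samples_a=params.n_samples_b)
    table_b, truth_b = generate_table(
        params_b,
        sample_prefix="surg",
        cohort="surgical",
        _rng=rng,
        _resident_names=shared + private_b,
        _contaminated=False,
    )
    labels = dict(truth_b.labels)
    labels.update(truth_a.labels)
    truth = SyntheticTruth(
        labels=labels,
        loads=truth_a.loads,
        params=params,
        indicator_rho=truth_a.indicator_rho,
    )
    return table_a, table_b, truth
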
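"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from decontab import TaxaCountTable
from decontab.taxonomy import TaxonomyLineage


def oracle_midranks(values) -> list[float]:
    """Textbook average ranks: tied observations share the mean of the
    positions they would occupy, written without library rank routines."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # positions are 1-based
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman(x, y, constant=0.0) -> float:
    """Brute-force Spearman: midrank both vectors, then the textbook Pearson
    formula on the ranks.  Independent of the package implementation."""
    rx, ry = oracle_midranks(x), oracle_midranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    sxx = sum((a - mx) ** 2 for a in rx)
    syy = sum((b - my) ** 2 for b in ry)
    if sxx == 0 or syy == 0:
        return constant
    sxy = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    return sxy / math.sqrt(sxx * syy)


def make_table(
    counts: dict[str, list[int]],
    samples: list[str] | None = None,
    lineages: dict[str, str] | None = None,
    **kwargs,
) -> TaxaCountTable:
    """Build a small table from {taxon_id: [counts per sample]}."""
    n = len(next(iter(counts.values())))
    samples = samples or [f"s{i+1}" for i in range(n)]
    frame = pd.DataFrame.from_dict(counts, orient="index", columns=samples)
    parsed = {
        t: TaxonomyLineage.from_string(s) for t, s in (lineages or {}).items()
    }
    return TaxaCountTable(counts=frame, lineages=parsed, **kwargs)


def random_table(rng: np.random.Generator, n_taxa=8, n_samples=5) -> TaxaCountTable:
    counts = rng.integers(0, 500, size=(n_taxa, n_samples))
    # avoid all-zero samples so relative abundance is defined
    counts[0, :] += 1
    frame = pd.DataFrame(
        counts,
        index=[f"Taxon{i:02d}" for i in range(n_taxa)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    return TaxaCountTable(counts=frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230919)
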
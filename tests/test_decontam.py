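"""Exclusion-list and Spearman co-occurrence filtering.

The rank-correlation oracle here (``oracle_spearman``) is a textbook
midrank-then-Pearson implementation written independently of the package;
boundary cases are permutations constructed so that rho is *exactly* on or
just above the removal threshold.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from decontab import (
    DecontamParams,
    ExclusionList,
    IndicatorSet,
    TableValidationError,
    apply_exclusion_list,
    correlation_filter,
    decontaminate,
    generate_table,
    pairwise_spearman,
    preset,
    spearman_rho,
)

from conftest import make_table, oracle_spearman, random_table


class TestSpearmanRho:
    def test_perfect_monotone_agreement(self):
        assert spearman_rho([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_vectors_match_textbook_oracle(self):
        x, y = [1, 1, 2, 3], [4, 5, 5, 6]
        assert spearman_rho(x, y) == pytest.approx(oracle_spearman(x, y), abs=1e-12)

    def test_constant_vector_returns_configured_value(self):
        assert spearman_rho([1, 1, 1], [1, 2, 3]) == 0.0
        assert spearman_rho([1, 1, 1], [1, 2, 3], constant_vector_rho=0.5) == 0.5

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_rho([1], [2])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(0, 5), min_size=2, max_size=8),
        st.data(),
    )
    def test_matches_oracle_and_is_symmetric(self, x, data):
        y = data.draw(
            st.lists(st.integers(0, 5), min_size=len(x), max_size=len(x))
        )
        got = spearman_rho(x, y)
        assert got == pytest.approx(oracle_spearman(x, y), abs=1e-12)
        assert got == pytest.approx(spearman_rho(y, x), abs=1e-12)

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, 3 * y + 10) == pytest.approx(base, abs=1e-12)


class TestApplyExclusionList:
    def test_fungal_manual_list_removes_only_matches(self):
        table = make_table(
            {"Malassezia": [5, 1], "Saccharomyces": [9, 9], "Trichosporon": [2, 3]}
        )
        manual = ExclusionList.from_names(
            ["Malassezia", "Cystidiodontia", "Cladosporum"],
            source="manual",
            label="manual-fungal",
        )
        out, removed, unused = apply_exclusion_list(table, manual)
        assert sorted(out.taxon_ids) == ["Saccharomyces", "Trichosporon"]
        assert [r.taxon_id for r in removed] == ["Malassezia"]
        assert removed[0].disposition == "removed_manual"
        assert sorted(unused) == ["Cladosporum", "Cystidiodontia"]

    def test_empty_intersection_is_identity(self):
        table = make_table({"A": [1, 2], "B": [3, 4]})
        out, removed, unused = apply_exclusion_list(
            table, ExclusionList.from_names(["Zzz"], label="none")
        )
        assert out.equals(table)
        assert removed == []

    def test_list_matching_everything_empties_table(self):
        table = make_table({"A": [1], "B": [2]})
        out, removed, _ = apply_exclusion_list(
            table, ExclusionList.from_names(["a", "b"], label="all")
        )
        assert out.n_taxa == 0
        assert len(removed) == 2

    def test_published_list_disposition_is_removed_list(self):
        table = make_table({"Pseudomonas": [1, 1]})
        _, removed, _ = apply_exclusion_list(
            table, ExclusionList.from_names(["Pseudomonas"], source="published-curated")
        )
        assert removed[0].disposition == "removed_list"


def boundary_table_rho_030():
    """Indicator ranks 1..5 vs target permutation (1,5,2,4,3): rho = 0.30."""
    return make_table({"ind": [1, 2, 3, 4, 5], "target": [1, 5, 2, 4, 3]})


def boundary_table_rho_031():
    """n=25 permutation with sum(d^2) = 1794, giving rho = 0.31 exactly."""
    y = list(range(17, 0, -1)) + [25, 23, 24, 21, 22, 19, 20, 18]
    d2 = sum((i + 1 - v) ** 2 for i, v in enumerate(y))
    assert d2 == 1794 and sorted(y) == list(range(1, 26))
    return make_table({"ind": list(range(1, 26)), "target": y})


class TestCorrelationFilter:
    RAW = DecontamParams(transform="raw_counts")

    def test_rho_exactly_030_is_retained(self):
        table = boundary_table_rho_030()
        assert oracle_spearman(table.counts.loc["ind"], table.counts.loc["target"]) == pytest.approx(0.30, abs=1e-15)
        out, removed, rho = correlation_filter(
            table, IndicatorSet.from_ids(["ind"]), self.RAW
        )
        assert out.taxon_ids == ["target"]  # strict "exceeding": 0.30 stays
        assert rho.at["target", "ind"] == pytest.approx(0.30, abs=1e-12)

    def test_rho_031_is_removed(self):
        table = boundary_table_rho_031()
        assert oracle_spearman(table.counts.loc["ind"], table.counts.loc["target"]) == pytest.approx(0.31, abs=1e-15)
        out, removed, _ = correlation_filter(
            table, IndicatorSet.from_ids(["ind"]), self.RAW
        )
        assert out.n_taxa == 0
        by_id = {r.taxon_id: r for r in removed}
        assert by_id["target"].disposition == "removed_correlation"
        assert by_id["target"].evidence["max_rho"] == pytest.approx(0.31, abs=1e-12)
        assert by_id["target"].evidence["partner_indicator"] == "ind"
        assert by_id["ind"].disposition == "removed_indicator"

    def test_zero_variance_indicator_removes_nothing_else(self):
        table = make_table({"ind": [5, 5, 5, 5], "A": [1, 2, 3, 4], "B": [4, 1, 3, 2]})
        out, removed, _ = correlation_filter(
            table, IndicatorSet.from_ids(["ind"]), self.RAW
        )
        assert sorted(out.taxon_ids) == ["A", "B"]
        assert {r.disposition for r in removed} == {"removed_indicator"}

    def test_skipped_below_min_samples(self):
        table = make_table({"ind": [1, 2], "A": [1, 2]})  # rho would be 1
        out, removed, _ = correlation_filter(
            table, IndicatorSet.from_ids(["ind"]), DecontamParams()
        )
        assert out.equals(table)
        assert removed == []

    def test_missing_indicator_is_an_error(self):
        table = make_table({"A": [1, 2, 3, 4]})
        with pytest.raises(TableValidationError):
            correlation_filter(table, IndicatorSet.from_ids(["ghost"]))

    def test_planted_contaminants_match_exhaustive_oracle(self):
        """Every removal decision agrees with brute-force rho on the same
        relative-abundance matrix, recomputed outside the pipeline."""
        table, truth = generate_table(preset("test_scale", seed=17))
        indicators = truth.indicators
        params = DecontamParams()
        out, removed, _ = correlation_filter(table, indicators, params)
        rel = table.counts / table.counts.sum(axis=0)
        expected_removed = set()
        for taxon in table.taxon_ids:
            if taxon in indicators.taxon_ids:
                continue
            max_rho = max(
                oracle_spearman(rel.loc[taxon], rel.loc[ind])
                for ind in indicators.taxon_ids
            )
            if max_rho > params.rho_threshold:
                expected_removed.add(taxon)
        got = {r.taxon_id for r in removed if r.disposition == "removed_correlation"}
        assert got == expected_removed

    def test_threshold_monotonicity(self):
        table, truth = generate_table(preset("test_scale", seed=3))
        previous = None
        for rho in (0.1, 0.3, 0.5, 0.9):
            _, removed, _ = correlation_filter(
                table, truth.indicators, DecontamParams(rho_threshold=rho)
            )
            n = sum(1 for r in removed if r.disposition == "removed_correlation")
            if previous is not None:
                assert n <= previous
            previous = n

    def test_threshold_one_removes_indicators_only(self):
        table, truth = generate_table(preset("test_scale", seed=3))
        _, removed, _ = correlation_filter(
            table, truth.indicators, DecontamParams(rho_threshold=1.0)
        )
        assert {r.disposition for r in removed} == {"removed_indicator"}


class TestPairwiseSpearman:
    def test_matrix_matches_scipy(self):
        from scipy import stats

        table = random_table(np.random.default_rng(5), n_taxa=6, n_samples=8)
        ours = pairwise_spearman(table, DecontamParams(transform="raw_counts"))
        ref, _ = stats.spearmanr(table.counts.to_numpy(), axis=1)
        mask = ~np.eye(6, dtype=bool)
        assert np.allclose(ours.to_numpy()[mask], ref[mask], atol=1e-12)


class TestDecontaminate:
    def test_identity_pipeline(self):
        table = make_table({"A": [1, 2], "B": [3, 4]})
        out, report = decontaminate(table)
        assert out.equals(table)
        assert {r.disposition for r in report.records} == {"retained"}

    def test_report_partitions_all_taxa(self):
        table, truth = generate_table(preset("test_scale", seed=17))
        lists = [ExclusionList.from_names(
            truth.taxa_with_label("list_contaminant"), label="curated"
        )]
        out, report = decontaminate(table, published_lists=lists, indicators=truth.indicators)
        assert report.n_input == 100
        assert report.n_retained + report.n_removed == 100
        ids = [r.taxon_id for r in report.records]
        assert sorted(ids) == sorted(table.taxon_ids)
        assert report.n_retained == out.n_taxa

    def test_fungal_mode_stage_provenance(self):
        """No published list: removals may only come from the correlation and
        manual stages (de-novo OTU workflow)."""
        table = make_table(
            {
                "otu1": [10, 20, 30, 40],     # tracks the indicator
                "otu2": [40, 9, 21, 5],
                "Malassezia": [3, 3, 4, 3],
                "ind": [1, 2, 3, 4],
            },
            marker="ITS",
        )
        manual = ExclusionList.from_names(["Malassezia"], source="manual", label="manual")
        out, report = decontaminate(
            table,
            manual_list=manual,
            indicators=IndicatorSet.from_ids(["ind"]),
            params=DecontamParams(transform="raw_counts"),
        )
        dispositions = {r.taxon_id: r.disposition for r in report.records}
        assert dispositions["otu1"] == "removed_correlation"
        assert dispositions["ind"] == "removed_indicator"
        assert dispositions["Malassezia"] == "removed_manual"
        assert dispositions["otu2"] == "retained"
        assert "removed_list" not in dispositions.values()

    def test_correlation_evidence_matches_direct_post_list_run(self):
        """The orchestrator computes correlations on the post-list table; the
        reported max_rho must equal a direct correlation_filter run on it."""
        table, truth = generate_table(preset("test_scale", seed=5))
        lists = [ExclusionList.from_names(
            truth.taxa_with_label("list_contaminant"), label="curated"
        )]
        _, report = decontaminate(table, published_lists=lists, indicators=truth.indicators)
        post_list, _, _ = apply_exclusion_list(table, lists[0])
        _, removed_direct, _ = correlation_filter(post_list, truth.indicators, DecontamParams())
        direct = {
            r.taxon_id: r.evidence["max_rho"]
            for r in removed_direct
            if r.disposition == "removed_correlation"
        }
        via_pipeline = {
            r.taxon_id: r.evidence["max_rho"]
            for r in report.records
            if r.disposition == "removed_correlation"
        }
        assert via_pipeline.keys() == direct.keys()
        for taxon, rho in direct.items():
            assert via_pipeline[taxon] == pytest.approx(rho, abs=1e-12)

    def test_correlation_skipped_with_too_few_samples(self):
        table = make_table({"ind": [1, 2], "A": [1, 2]})
        out, report = decontaminate(table, indicators=IndicatorSet.from_ids(["ind"]))
        assert sorted(out.taxon_ids) == ["A", "ind"]
        assert any("skipped" in w for w in report.warnings)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        table = random_table(rng, n_taxa=int(rng.integers(2, 15)), n_samples=5)
        names = list(table.taxon_ids)
        listed = [n for n in names if rng.random() < 0.3]
        indicators = [n for n in names if n not in listed and rng.random() < 0.2]
        out, report = decontaminate(
            table,
            published_lists=[ExclusionList.from_names(listed, label="rand")] if listed else [],
            indicators=IndicatorSet.from_ids(indicators) if indicators else None,
        )
        assert report.n_retained + report.n_removed == table.n_taxa
        assert sorted(r.taxon_id for r in report.records) == sorted(names)
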
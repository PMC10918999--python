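"""Pathway coverage, abundance weighting, and KO-set comparisons."""

import numpy as np
import pandas as pd
import pytest

from proteotyper import (
    annotation_rate,
    compare_taxa_pathways,
    compute_pathway_coverage,
    generate_ko_fixture,
    pathway_abundance,
    taxon_function_matrix,
    Taxonomy,
)

from conftest import make_lineage
from oracles import coverage_by_set_arithmetic


def annotations_from(rows):
    return pd.DataFrame(rows, columns=["protein_group", "ko", "taxon", "abundance"])


def pathways_from(rows):
    return pd.DataFrame(rows, columns=["pathway", "category", "ko"])


class TestCoverage:
    def test_partial_coverage_fraction(self):
        pathways = pathways_from(
            [("p1", "metabolism", f"K{i}") for i in range(10)]
        )
        annotations = annotations_from(
            [(f"pg{i}", f"K{i}", "t1", 1.0) for i in range(4)]
        )
        report = compute_pathway_coverage(annotations, pathways)
        assert report.coverage("p1") == 40.0

    def test_full_and_zero_coverage(self):
        pathways = pathways_from([("p1", "metabolism", "K1"),
                                  ("p2", "metabolism", "K2")])
        annotations = annotations_from([("pg1", "K1", "t1", 1.0)])
        report = compute_pathway_coverage(annotations, pathways)
        assert report.coverage("p1") == 100.0
        assert report.coverage("p2") == 0.0

    def test_unannotated_counted_and_unmapped_reported(self):
        pathways = pathways_from([("p1", "metabolism", "K1")])
        annotations = annotations_from(
            [("pg1", "K1", "t1", 1.0), ("pg2", None, "t1", 1.0),
             ("pg3", "K999", "t1", 1.0)]
        )
        report = compute_pathway_coverage(annotations, pathways)
        assert report.n_unannotated == 1
        assert report.unmapped_kos == ["K999"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_arithmetic_oracle(self, seed):
        annotations, pathways, _ = generate_ko_fixture(
            n_pathways=30, seed=seed
        )
        report = compute_pathway_coverage(annotations, pathways)
        expected = coverage_by_set_arithmetic(annotations, pathways)
        for row in report.frame.itertuples(index=False):
            assert row.coverage_pct == pytest.approx(expected[row.pathway])

    def test_coverage_bounds_and_saturation(self):
        annotations, pathways, _ = generate_ko_fixture(seed=9)
        report = compute_pathway_coverage(annotations, pathways)
        assert ((report.frame["coverage_pct"] >= 0)
                & (report.frame["coverage_pct"] <= 100)).all()
        full = report.frame["coverage_pct"] == 100.0
        assert (full == (report.frame["n_observed"]
                         == report.frame["n_total"])).all()


class TestAbundance:
    def test_weights_sum_within_pathway(self):
        pathways = pathways_from([("p1", "metabolism", "K1")])
        annotations = annotations_from(
            [("pg1", "K1", "t1", 1.0), ("pg2", "K1", "t1", 3.0)]
        )
        weights = pathway_abundance(annotations, pathways)
        assert weights.loc[0, "weight"] == 4.0

    def test_multi_pathway_ko_counts_fully_in_each(self):
        pathways = pathways_from(
            [("p1", "metabolism", "K1"), ("p2", "cellular processes", "K1")]
        )
        annotations = annotations_from([("pg1", "K1", "t1", 2.5)])
        weights = pathway_abundance(annotations, pathways).set_index("pathway")
        assert weights.loc["p1", "weight"] == 2.5
        assert weights.loc["p2", "weight"] == 2.5

    def test_uniqueness_weighting_splits_abundance(self):
        pathways = pathways_from(
            [("p1", "metabolism", "K1"), ("p2", "cellular processes", "K1")]
        )
        annotations = annotations_from([("pg1", "K1", "t1", 2.0)])
        weights = pathway_abundance(
            annotations, pathways, uniqueness_weighted=True
        ).set_index("pathway")
        assert weights.loc["p1", "weight"] == 1.0
        assert weights.loc["p2", "weight"] == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_join_and_sum_oracle(self, seed):
        annotations, pathways, _ = generate_ko_fixture(seed=100 + seed)
        weights = pathway_abundance(annotations, pathways)
        # brute-force recount: loop over proteins x pathway rows
        expected: dict[tuple, float] = {}
        pathway_kos = pathways.groupby("pathway")["ko"].apply(set)
        for protein in annotations.dropna(subset=["ko"]).itertuples(index=False):
            for pathway, kos in pathway_kos.items():
                if protein.ko in kos:
                    key = (pathway, protein.taxon)
                    expected[key] = expected.get(key, 0.0) + protein.abundance
        got = {
            (r.pathway, r.group): r.weight
            for r in weights.itertuples(index=False)
        }
        assert got.keys() == expected.keys()
        for key in expected:
            assert got[key] == pytest.approx(expected[key])

    def test_group_sums_equal_pooled_weights(self):
        """Abundance conservation: per-group weights sum to the pooled
        weight for every pathway."""
        annotations, pathways, _ = generate_ko_fixture(seed=5)
        pooled = pathway_abundance(
            annotations, pathways, groups={}
        )  # every taxon -> "unclassified"
        per_taxon = pathway_abundance(annotations, pathways)
        summed = per_taxon.groupby("pathway")["weight"].sum()
        pooled = pooled.set_index("pathway")["weight"]
        pd.testing.assert_series_equal(
            summed.sort_index(), pooled.sort_index(), check_names=False
        )


class TestTaxonFunctionMatrix:
    @pytest.fixture()
    def taxonomy(self):
        return Taxonomy(
            {"sp1": make_lineage("sp1", genus="G1"),
             "sp2": make_lineage("sp2", genus="G2")}
        )

    def test_single_genus_single_category(self, taxonomy):
        pathways = pathways_from([("p1", "metabolism", "K1")])
        annotations = annotations_from([("pg1", "K1", "sp1", 4.0)])
        matrix = taxon_function_matrix(annotations, pathways, taxonomy)
        assert matrix.shape == (1, 1)
        assert matrix.loc["G1", "metabolism"] == 4.0

    def test_disjoint_categories_block_diagonal(self, taxonomy):
        pathways = pathways_from(
            [("p1", "metabolism", "K1"), ("p2", "cellular processes", "K2")]
        )
        annotations = annotations_from(
            [("pg1", "K1", "sp1", 1.0), ("pg2", "K2", "sp2", 2.0)]
        )
        matrix = taxon_function_matrix(annotations, pathways, taxonomy)
        assert matrix.loc["G1", "metabolism"] == 1.0
        assert matrix.loc["G2", "cellular processes"] == 2.0
        assert matrix.loc["G1", "cellular processes"] == 0.0
        assert matrix.loc["G2", "metabolism"] == 0.0

    def test_unresolvable_taxon_lands_in_unclassified(self, taxonomy):
        pathways = pathways_from([("p1", "metabolism", "K1")])
        annotations = annotations_from([("pg1", "K1", "mystery", 1.0)])
        matrix = taxon_function_matrix(annotations, pathways, taxonomy)
        assert matrix.loc["unclassified", "metabolism"] == 1.0

    def test_matrix_total_matches_pathway_abundance(self, taxonomy):
        annotations, pathways, _ = generate_ko_fixture(
            taxa=("sp1", "sp2"), seed=8
        )
        matrix = taxon_function_matrix(annotations, pathways, taxonomy)
        weights = pathway_abundance(annotations, pathways)
        assert matrix.to_numpy().sum() == pytest.approx(
            weights["weight"].sum()
        )


class TestCompareTaxa:
    def test_identical_sets_all_shared(self):
        annotations = annotations_from(
            [("pg1", "K1", "A", 1.0), ("pg2", "K1", "B", 1.0),
             ("pg3", "K2", "A", 1.0), ("pg4", "K2", "B", 1.0)]
        )
        cmp = compare_taxa_pathways(annotations, "A", "B")
        assert cmp.shared == {"K1", "K2"}
        assert cmp.a_only == set() and cmp.b_only == set()

    def test_disjoint_sets_no_shared(self):
        annotations = annotations_from(
            [("pg1", "K1", "A", 1.0), ("pg2", "K2", "B", 1.0)]
        )
        cmp = compare_taxa_pathways(annotations, "A", "B")
        assert cmp.shared == set()
        assert cmp.a_only == {"K1"} and cmp.b_only == {"K2"}

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_is_disjoint_exhaustive_and_oracle_exact(self, seed):
        rng = np.random.default_rng(seed)
        universe = [f"K{i}" for i in range(40)]
        rows = []
        for i, ko in enumerate(universe):
            for taxon in ("A", "B"):
                if rng.random() < 0.4:
                    rows.append((f"pg{taxon}{i}", ko, taxon, 1.0))
        annotations = annotations_from(rows)
        cmp = compare_taxa_pathways(annotations, "A", "B")
        set_a = {r[1] for r in rows if r[2] == "A"}
        set_b = {r[1] for r in rows if r[2] == "B"}
        assert cmp.shared == set_a & set_b
        assert cmp.a_only == set_a - set_b
        assert cmp.b_only == set_b - set_a
        assert cmp.shared | cmp.a_only | cmp.b_only == set_a | set_b
        assert not (cmp.shared & cmp.a_only)
        assert not (cmp.shared & cmp.b_only)
        assert not (cmp.a_only & cmp.b_only)

    def test_pathway_labels(self):
        pathways = pathways_from(
            [("pshared", "metabolism", "K1"),
             ("pa", "metabolism", "K2"),
             ("pmix", "metabolism", "K1"), ("pmix", "metabolism", "K3")]
        )
        annotations = annotations_from(
            [("pg1", "K1", "A", 1.0), ("pg2", "K1", "B", 1.0),
             ("pg3", "K2", "A", 1.0), ("pg4", "K3", "B", 1.0)]
        )
        cmp = compare_taxa_pathways(annotations, "A", "B", pathways)
        labels = cmp.pathway_labels.set_index("pathway")["label"]
        assert labels["pshared"] == "shared"
        assert labels["pa"] == "a_only"
        assert labels["pmix"] == "mixed"


class TestAnnotationRate:
    def test_simple_fraction(self):
        annotations = annotations_from(
            [("pg1", "K1", "t", 1.0), ("pg2", "K2", "t", 1.0),
             ("pg3", "K3", "t", 1.0), ("pg4", "K4", "t", 1.0),
             ("pg5", None, "t", 1.0)]
        )
        rates = annotation_rate(annotations).set_index("group")
        assert rates.loc["t", "pct"] == 80.0

    def test_grouped_rates(self):
        annotations = annotations_from(
            [("pg1", "K1", "human", 1.0), ("pg2", None, "microbe", 1.0)]
        )
        groups = {"human": "host", "microbe": "microbiota"}
        rates = annotation_rate(annotations, groups).set_index("group")
        assert rates.loc["host", "pct"] == 100.0
        assert rates.loc["microbiota", "pct"] == 0.0

    def test_empty_table_no_division_error(self):
        rates = annotation_rate(annotations_from([]))
        assert rates.empty

    def test_matches_recount_on_fixture(self):
        annotations, _, truth = generate_ko_fixture(seed=4)
        rates = annotation_rate(
            annotations, groups={t: "all" for t in annotations["taxon"]}
        )
        assert int(rates.set_index("group").loc["all", "annotated"]) == (
            truth["annotated_count"]
        )
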
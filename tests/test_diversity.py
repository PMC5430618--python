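"""Shannon entropy, population profiles, regrouping and heatmap orderings."""

import math

import numpy as np
import pytest
from scipy.stats import entropy as scipy_entropy

from viroquant.diversity import (
    diversity_report,
    heatmap_order,
    population_profile,
    regroup,
    shannon,
)
from viroquant.quantify import AbundanceTable, abundance_table, assign_read
from viroquant.records import Lineage, LineageTable

import pandas as pd


def table_from(values, samples, taxa, lineage=None, groups=None):
    df = pd.DataFrame(values, index=pd.Index(taxa, name="accession"),
                      columns=samples)
    return AbundanceTable(values=df, lineage=lineage, groups=groups or {})


@pytest.fixture()
def lineage4():
    lin = LineageTable()
    for i, acc in enumerate(["a", "b", "c", "d"]):
        lin.add(acc, Lineage("dsDNA", "F", f"G{i // 2}", f"Sp{i}"))
    return lin


class TestShannon:
    def test_uniform_over_four_is_ln4(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(math.log(4))

    def test_single_taxon_zero(self):
        assert shannon([5.0]) == 0.0

    def test_half_quarter_quarter(self):
        assert shannon([0.5, 0.25, 0.25]) == pytest.approx(1.5 * math.log(2))

    def test_zeros_ignored(self):
        assert shannon([2, 0, 2, 0]) == pytest.approx(math.log(2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_matches_independent_implementation(self, rng):
        for _ in range(20):
            x = rng.random(int(rng.integers(2, 10))) + 1e-6
            assert shannon(x) == pytest.approx(float(scipy_entropy(x)))

    def test_bounds_over_random_profiles(self, rng):
        """0 <= H <= ln(richness); maximal at uniform, zero at degenerate."""
        for _ in range(50):
            k = int(rng.integers(1, 12))
            x = rng.dirichlet(np.ones(k))
            h = shannon(x)
            richness = int((x > 0).sum())
            assert -1e-12 <= h <= math.log(richness) + 1e-12
        assert shannon(np.ones(7)) == pytest.approx(math.log(7))


class TestDiversityReport:
    def test_species_rank_entropy(self, lineage4):
        table = table_from([[4.0], [4.0], [4.0], [4.0]], ["S1"],
                           ["a", "b", "c", "d"], lineage=lineage4)
        (row,) = diversity_report(table, rank="species")
        assert row.shannon == pytest.approx(math.log(4))
        assert row.richness == 4

    def test_empty_sample_zero_entropy(self, lineage4):
        table = table_from([[1.0, 0.0]], ["S1", "S2"], ["a"], lineage=lineage4)
        rows = {r.sample_id: r for r in diversity_report(table, rank="species")}
        assert rows["S2"].shannon == 0.0 and rows["S2"].richness == 0


class TestPopulationProfile:
    def test_single_sample_normalized(self, lineage4):
        table = table_from([[3.0], [1.0]], ["S1"], ["a", "b"], lineage=lineage4)
        profiles = population_profile(table, "species", {"S1": "g"})
        assert profiles["g"]["proportions"] == pytest.approx(
            {"Sp0": 0.75, "Sp1": 0.25}
        )
        assert profiles["g"]["total"] == 4.0

    def test_duplicate_samples_scale_invariant(self, lineage4):
        one = table_from([[3.0], [1.0]], ["S1"], ["a", "b"], lineage=lineage4)
        two = table_from([[3.0, 3.0], [1.0, 1.0]], ["S1", "S2"], ["a", "b"],
                         lineage=lineage4)
        p1 = population_profile(one, "species", {"S1": "g"})
        p2 = population_profile(two, "species", {"S1": "g", "S2": "g"})
        assert p1["g"]["proportions"] == pytest.approx(p2["g"]["proportions"])

    def test_proportions_sum_to_one_per_group(self, lineage4, rng):
        values = rng.random((4, 5)) * 10
        table = table_from(values, [f"S{i}" for i in range(5)],
                           ["a", "b", "c", "d"], lineage=lineage4)
        grouping = {"S0": "x", "S1": "x", "S2": "y"}  # S3, S4 -> ungrouped
        for rank in ("group", "family", "genus", "species"):
            profiles = population_profile(table, rank, grouping)
            assert set(profiles) == {"x", "y", "ungrouped"}
            for group in profiles.values():
                assert sum(group["proportions"].values()) == pytest.approx(
                    1.0, abs=1e-12
                )


class TestRegroup:
    def test_idempotent_on_same_grouping(self, lineage4):
        table = table_from([[3.0, 1.0], [1.0, 5.0]], ["S1", "S2"], ["a", "b"],
                           lineage=lineage4)
        grouping = {"S1": "x", "S2": "y"}
        assert regroup(table, "species", grouping) == population_profile(
            table, "species", grouping
        )

    def test_merged_group_is_weighted_combination(self, lineage4):
        table = table_from([[3.0, 1.0], [1.0, 5.0]], ["S1", "S2"], ["a", "b"],
                           lineage=lineage4)
        separate = population_profile(table, "species", {"S1": "x", "S2": "y"})
        merged = regroup(table, "species", {"S1": "xy", "S2": "xy"})
        wx, wy = separate["x"]["total"], separate["y"]["total"]
        for label in ("Sp0", "Sp1"):
            expected = (
                separate["x"]["proportions"][label] * wx
                + separate["y"]["proportions"][label] * wy
            ) / (wx + wy)
            assert merged["xy"]["proportions"][label] == pytest.approx(expected)

    def test_values_never_touched(self, lineage4):
        table = table_from([[3.0, 1.0], [1.0, 5.0]], ["S1", "S2"], ["a", "b"],
                           lineage=lineage4)
        before = table.values.copy(deep=True)
        regroup(table, "genus", {"S1": "z", "S2": "z"})
        pd.testing.assert_frame_equal(table.values, before)

    def test_unknown_sample_listed_in_error(self, lineage4):
        table = table_from([[1.0]], ["S1"], ["a"], lineage=lineage4)
        with pytest.raises(ValueError, match="S9"):
            regroup(table, "species", {"S9": "x"})


class TestHeatmapOrder:
    def test_duplicate_samples_adjacent(self, rng):
        base = rng.random(6) * 5
        distinct = rng.random(6) * 50
        values = np.column_stack([base, base, distinct])
        table = table_from(values, ["dupA", "dupB", "other"],
                           [f"t{i}" for i in range(6)])
        sample_order, _, _, _ = heatmap_order(table)
        ia, ib = sample_order.index("dupA"), sample_order.index("dupB")
        assert abs(ia - ib) == 1

    def test_two_by_two_returns_both_orderings(self):
        table = table_from([[1.0, 2.0], [3.0, 4.0]], ["S1", "S2"], ["a", "b"])
        sample_order, taxon_order, s_link, t_link = heatmap_order(table)
        assert sorted(sample_order) == ["S1", "S2"]
        assert sorted(taxon_order) == ["a", "b"]
        assert s_link is not None and t_link is not None

    def test_degenerate_sizes_identity_order(self):
        table = table_from([[1.0, 2.0]], ["S1", "S2"], ["a"])
        sample_order, taxon_order, s_link, t_link = heatmap_order(table)
        assert taxon_order == ["a"] and t_link is None
        assert len(sample_order) == 2

    @staticmethod
    def tree_partitions(link, labels):
        """Set of label-sets formed by each merge: the tree's topology."""
        clusters = {i: frozenset([label]) for i, label in enumerate(labels)}
        n = len(labels)
        out = set()
        for i, (a, b, _, _) in enumerate(link):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + i] = merged
            out.add(merged)
        return out

    def test_permutation_invariant_topology(self, rng):
        values = rng.random((5, 4)) * 20
        samples = ["S1", "S2", "S3", "S4"]
        taxa = [f"t{i}" for i in range(5)]
        table = table_from(values, samples, taxa)
        perm = [2, 0, 3, 1]
        permuted = table_from(values[:, perm], [samples[i] for i in perm], taxa)
        _, _, link_a, _ = heatmap_order(table)
        _, _, link_b, _ = heatmap_order(permuted)
        assert self.tree_partitions(link_a, samples) == self.tree_partitions(
            link_b, [samples[i] for i in perm]
        )
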
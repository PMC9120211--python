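import numpy as np
import pandas as pd
import pytest

from conftest import matrix_from_sets, random_fixture
from oracles import brute_branch_ranges, brute_pd, brute_pe, brute_we

from riverdiv import (
    InvalidInputError,
    Phylogeny,
    branch_ranges,
    faith_pd,
    make_catalog,
    phylogenetic_endemism,
    richness,
    weighted_endemism,
)

STAR3 = "(A:1,B:1,C:1);"
CATERPILLAR = "((A:1,B:1):1,C:2);"


class TestPhylogeny:
    def test_rejects_nonpositive_branch_length(self):
        with pytest.raises(InvalidInputError):
            Phylogeny.from_newick("(A:1,B:0);")

    def test_rejects_duplicate_tips(self):
        with pytest.raises(InvalidInputError):
            Phylogeny.from_newick("(A:1,A:1);")

    def test_total_branch_length(self):
        assert Phylogeny.from_newick(CATERPILLAR).total_branch_length() == 5.0


class TestFaithPD:
    def test_star_tree_two_of_three_tips(self, unit_grid):
        m = matrix_from_sets({0: {"A", "B"}}, unit_grid)
        t = Phylogeny.from_newick(STAR3)
        assert faith_pd(m, t)[0] == 2.0

    def test_cell_with_all_tips_equals_total_length(self, unit_grid):
        m = matrix_from_sets({0: {"A", "B", "C"}, 1: {"A"}}, unit_grid)
        t = Phylogeny.from_newick(CATERPILLAR)
        assert faith_pd(m, t)[0] == t.total_branch_length()

    def test_root_inclusive_single_tip_scores_root_path(self, unit_grid):
        m = matrix_from_sets({0: {"C"}}, unit_grid)
        t = Phylogeny.from_newick(CATERPILLAR)
        assert faith_pd(m, t, include_root=True)[0] == 2.0
        assert faith_pd(m, t, include_root=False)[0] == 0.0

    def test_root_exclusive_drops_shared_root_path(self, unit_grid):
        m = matrix_from_sets({0: {"A", "B"}}, unit_grid)
        t = Phylogeny.from_newick(CATERPILLAR)
        # minimal subtree connecting A,B excludes the stem below their MRCA
        assert faith_pd(m, t, include_root=False)[0] == 2.0
        assert faith_pd(m, t, include_root=True)[0] == 3.0

    def test_no_tip_overlap_rejected(self, unit_grid):
        m = matrix_from_sets({0: {"X"}}, unit_grid)
        with pytest.raises(InvalidInputError):
            faith_pd(m, Phylogeny.from_newick(STAR3))

    def test_species_missing_from_tree_excluded(self, unit_grid):
        m = matrix_from_sets({0: {"A", "X"}}, unit_grid)
        t = Phylogeny.from_newick(STAR3)
        assert faith_pd(m, t)[0] == 1.0  # only A's branch counts


class TestBranchRanges:
    def test_tip_branch_range_counts_occupied_cells(self, unit_grid):
        m = matrix_from_sets({0: {"A"}, 1: {"A"}, 2: {"A", "B"}}, unit_grid)
        r = branch_ranges(m, Phylogeny.from_newick(STAR3))
        assert r[frozenset({"A"})] == 3
        assert r[frozenset({"B"})] == 1
        assert frozenset({"C"}) not in r

    def test_matches_brute_force_descendant_union(self, unit_grid):
        rng = np.random.default_rng(11)
        for _ in range(20):
            newick, cs = random_fixture(rng)
            m = matrix_from_sets(cs, unit_grid)
            got = branch_ranges(m, Phylogeny.from_newick(newick))
            assert got == brute_branch_ranges(newick, cs)


class TestPhylogeneticEndemism:
    def test_single_cell_world_pe_equals_pd(self, unit_grid):
        m = matrix_from_sets({0: {"A", "B", "C"}}, unit_grid)
        t = Phylogeny.from_newick(CATERPILLAR)
        assert phylogenetic_endemism(m, t)[0] == faith_pd(m, t)[0]

    def test_identical_composition_divides_by_cell_count(self, unit_grid):
        k = 4
        m = matrix_from_sets({c: {"A", "B", "C"} for c in range(k)}, unit_grid)
        t = Phylogeny.from_newick(CATERPILLAR)
        pd_t = faith_pd(m, t)
        pe_t = phylogenetic_endemism(m, t)
        for c in range(k):
            assert pe_t[c] == pytest.approx(pd_t[c] / k, rel=1e-12)

    def test_pe_sums_to_pooled_pd(self, unit_grid):
        rng = np.random.default_rng(5)
        for _ in range(20):
            newick, cs = random_fixture(rng)
            m = matrix_from_sets(cs, unit_grid)
            t = Phylogeny.from_newick(newick)
            pe_total = sum(phylogenetic_endemism(m, t).values.values())
            pooled = brute_pd(newick, set().union(*cs.values()))
            assert pe_total == pytest.approx(pooled, rel=1e-9)

    def test_pe_never_exceeds_pd(self, unit_grid):
        rng = np.random.default_rng(6)
        for _ in range(20):
            newick, cs = random_fixture(rng)
            m = matrix_from_sets(cs, unit_grid)
            t = Phylogeny.from_newick(newick)
            pd_t, pe_t = faith_pd(m, t), phylogenetic_endemism(m, t)
            for c in cs:
                assert pe_t[c] <= pd_t[c] + 1e-12


class TestWeightedEndemism:
    def test_single_cell_endemic_contributes_one(self, unit_grid):
        m = matrix_from_sets({0: {"A", "B"}, 1: {"B"}}, unit_grid)
        we = weighted_endemism(m)
        assert we[0] == pytest.approx(1.0 + 0.5)
        assert we[1] == pytest.approx(0.5)

    def test_ubiquitous_species_contributes_reciprocal(self, unit_grid):
        k = 5
        m = matrix_from_sets({c: {"A"} for c in range(k)}, unit_grid)
        we = weighted_endemism(m)
        for c in range(k):
            assert we[c] == pytest.approx(1 / k)

    def test_sums_to_species_count(self, unit_grid):
        rng = np.random.default_rng(9)
        for _ in range(20):
            _, cs = random_fixture(rng)
            m = matrix_from_sets(cs, unit_grid)
            total = sum(weighted_endemism(m).values.values())
            assert total == pytest.approx(m.n_species, rel=1e-9)

    def test_bounded_by_richness(self, unit_grid):
        rng = np.random.default_rng(10)
        _, cs = random_fixture(rng)
        m = matrix_from_sets(cs, unit_grid)
        cat = make_catalog(pd.DataFrame({"species": m.species}))
        rich = richness(m, "all", cat)
        we = weighted_endemism(m)
        for c in cs:
            assert we[c] <= rich[c] + 1e-12


class TestRichness:
    def test_counts_flagged_species(self, unit_grid):
        m = matrix_from_sets({0: {"A", "B"}, 1: {"C"}}, unit_grid)
        cat = make_catalog(
            pd.DataFrame(
                {
                    "species": ["A", "B", "C"],
                    "endemic": [True, False, True],
                    "threatened": [False, False, False],
                }
            )
        )
        assert richness(m, "all", cat)[0] == 2
        assert richness(m, "endemic", cat).values == {0: 1.0, 1: 1.0}
        assert richness(m, "threatened", cat).values == {0: 0.0, 1: 0.0}

    def test_unknown_group_rejected(self, unit_grid):
        m = matrix_from_sets({0: {"A"}, 1: {"B"}}, unit_grid)
        cat = make_catalog(pd.DataFrame({"species": ["A", "B"]}))
        with pytest.raises(InvalidInputError):
            richness(m, "rare", cat)

    def test_matches_brute_force_flag_count(self, unit_grid):
        rng = np.random.default_rng(13)
        for _ in range(10):
            _, cs = random_fixture(rng)
            m = matrix_from_sets(cs, unit_grid)
            flags = {s: bool(rng.random() < 0.4) for s in m.species}
            cat = make_catalog(
                pd.DataFrame(
                    {
                        "species": list(flags),
                        "endemic": list(flags.values()),
                    }
                )
            )
            table = richness(m, "endemic", cat)
            flagged = {s for s, f in flags.items() if f}
            for c in cs:
                assert table[c] == len(cs[c] & flagged)


class TestMonotonicity:
    def test_adding_a_species_never_decreases_metrics(self, unit_grid):
        newick = "((A:1,B:2):1,(C:1,D:3):2);"
        base = {0: {"A"}, 1: {"B", "C"}, 2: {"D"}}
        grown = {0: {"A", "C"}, 1: {"B", "C"}, 2: {"D"}}
        t = Phylogeny.from_newick(newick)
        m0, m1 = matrix_from_sets(base, unit_grid), matrix_from_sets(grown, unit_grid)
        cat = make_catalog(pd.DataFrame({"species": list("ABCD")}))
        assert faith_pd(m1, t)[0] >= faith_pd(m0, t)[0]
        assert phylogenetic_endemism(m1, t)[0] >= phylogenetic_endemism(m0, t)[0]
        assert weighted_endemism(m1)[0] >= weighted_endemism(m0)[0]
        assert richness(m1, "all", cat)[0] >= richness(m0, "all", cat)[0]


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force(self, unit_grid):
        rng = np.random.default_rng(2024)
        for _ in range(30):
            newick, cs = random_fixture(rng)
            m = matrix_from_sets(cs, unit_grid)
            t = Phylogeny.from_newick(newick)
            pd_t = faith_pd(m, t)
            pe_t = phylogenetic_endemism(m, t)
            we_t = weighted_endemism(m)
            for c in cs:
                assert pd_t[c] == pytest.approx(brute_pd(newick, cs[c]), abs=1e-9)
                assert pe_t[c] == pytest.approx(brute_pe(newick, cs, c), abs=1e-9)
                assert we_t[c] == pytest.approx(brute_we(cs, c), abs=1e-9)
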
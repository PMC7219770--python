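import math

import dendropy
import numpy as np
import pytest

from codonpairing.parsimony_matrix import MISSING, CharacterMatrix
from codonpairing.profiles_af import DistanceMatrix
from codonpairing.simulate import random_tree
from codonpairing.tree_metrics import (
    edge_overlap,
    average_edge_overlap,
    fitch_length,
    retention_index,
    ri_permutation_test,
    saturation_profile,
    tree_from_newick,
)

from oracles import brute_force_fitch


class TestEdgeOverlap:
    def test_identical_trees_full_overlap(self):
        t = random_tree(8, 1)
        ov = edge_overlap(t, t.clone(depth=1))
        assert ov.pct_source_in_ref == 100.0
        assert ov.pct_ref_in_source == 100.0
        assert ov.mean_pct == 100.0

    def test_star_source_undefined_direction(self):
        star = tree_from_newick("(A,B,C,D,E);")
        ref = tree_from_newick("((A,B),(C,D),E);")
        ov = edge_overlap(star, ref)
        assert ov.n_source == 0
        assert math.isnan(ov.pct_source_in_ref)
        assert ov.pct_ref_in_source == 0.0

    def test_single_nni_against_hand_enumeration(self):
        # ((A,B),(C,D),(E,F)) vs NNI swap of C and B
        t1 = tree_from_newick("((A,B),(C,D),(E,F));")
        t2 = tree_from_newick("((A,C),(B,D),(E,F));")
        # t1 splits: {A,B}, {C,D}, {E,F}; t2: {A,C}, {B,D}, {E,F} -> share 1
        ov = edge_overlap(t1, t2)
        assert ov.shared_bipartitions == 1
        assert ov.n_source == ov.n_reference == 3
        assert ov.mean_pct == pytest.approx(100 / 3)

    def test_prunes_to_shared_leaves(self):
        t1 = tree_from_newick("((A,B),(C,D),(E,X));")
        t2 = tree_from_newick("((A,B),(C,D),(E,Y));")
        ov = edge_overlap(t1, t2)
        # on {A..E}: both reduce to splits {A,B} and {C,D}
        assert ov.shared_bipartitions == 2
        assert ov.mean_pct == 100.0

    def test_rooted_and_unrooted_representations_agree(self):
        rooted = tree_from_newick("(((A,B),C),((D,E),F));")
        unrooted = tree_from_newick("((A,B),C,((D,E),F));")
        assert edge_overlap(rooted, unrooted).mean_pct == 100.0

    def test_too_few_shared_leaves(self):
        t1 = tree_from_newick("((A,B),(C,X));")
        t2 = tree_from_newick("((A,B),(Y,Z));")
        with pytest.raises(ValueError):
            edge_overlap(t1, t2)

    def test_average_over_equally_parsimonious_trees(self):
        ref = tree_from_newick("((A,B),(C,D),(E,F));")
        sources = [
            tree_from_newick("((A,B),(C,D),(E,F));"),
            tree_from_newick("((A,C),(B,D),(E,F));"),
        ]
        avg = average_edge_overlap(sources, ref)
        assert avg == pytest.approx((100 + 100 / 3) / 2)


class TestFitch:
    def test_clean_synapomorphy_single_step(self):
        t = tree_from_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        column = {s: 1 for s in "ABCD"} | {s: 0 for s in "EFGH"}
        assert fitch_length(t, column) == 1

    def test_constant_and_all_missing(self):
        t = tree_from_newick("((A,B),(C,D));")
        assert fitch_length(t, {s: 1 for s in "ABCD"}) == 0
        assert fitch_length(t, {s: MISSING for s in "ABCD"}) == 0

    def test_alternating_character(self):
        t = tree_from_newick("((A,B),(C,D),(E,F));")
        assert fitch_length(t, {"A": 1, "B": 0, "C": 1, "D": 0, "E": 1, "F": 0}) == 3

    def test_matches_brute_force_on_random_characters(self):
        rng = np.random.default_rng(17)
        t = random_tree(8, 4)
        labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
        for _ in range(30):
            column = {
                lab: int(s) if s != 2 else MISSING
                for lab, s in zip(labels, rng.integers(0, 3, size=8))
            }
            assert fitch_length(t, column) == brute_force_fitch(t, column)

    def test_polytomy_exactness(self):
        t = tree_from_newick("((A,B,C),(D,E,F),(G,H));")
        rng = np.random.default_rng(23)
        labels = list("ABCDEFGH")
        for _ in range(20):
            column = {lab: int(s) for lab, s in zip(labels, rng.integers(0, 2, size=8))}
            assert fitch_length(t, column) == brute_force_fitch(t, column)


def _matrix_from_columns(species, columns):
    cells = np.array(columns, dtype=np.int8).T
    chars = [(f"og{j}", "AAA") for j in range(len(columns))]
    return CharacterMatrix(species_ids=species, characters=chars, cells=cells)


class TestRetentionIndex:
    def test_clean_synapomorphy_ri_one(self):
        t = tree_from_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        m = _matrix_from_columns(list("ABCDEFGH"), [[1, 1, 1, 1, 0, 0, 0, 0]])
        rep = retention_index(t, m)
        assert rep.per_character[0] == pytest.approx(1.0)

    def test_maximal_homoplasy_ri_zero(self):
        t = tree_from_newick("((A,B),(C,D),(E,F));")
        m = _matrix_from_columns(list("ABCDEF"), [[1, 0, 1, 0, 1, 0]])
        rep = retention_index(t, m)
        assert rep.per_character[0] == pytest.approx(0.0)

    def test_autapomorphy_skipped(self):
        t = tree_from_newick("((A,B),(C,D));")
        m = _matrix_from_columns(list("ABCD"), [[1, 0, 0, 0]])
        rep = retention_index(t, m)
        assert rep.n_skipped == 1
        assert math.isnan(rep.per_character[0])

    def test_ri_bounds_and_oracle_on_random_characters(self):
        rng = np.random.default_rng(31)
        t = random_tree(10, 8)
        labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
        columns = rng.integers(0, 2, size=(50, 10))
        m = _matrix_from_columns(labels, columns.tolist())
        rep = retention_index(t, m)
        for j in range(50):
            col = {lab: int(columns[j, i]) for i, lab in enumerate(labels)}
            s = brute_force_fitch(t, col)
            ones = int(columns[j].sum())
            g = min(ones, 10 - ones)
            m_min = 1 if 0 < ones < 10 else 0
            if g > m_min:
                assert rep.per_character[j] == pytest.approx((g - s) / (g - m_min))
                assert 0.0 <= rep.per_character[j] <= 1.0
            else:
                assert math.isnan(rep.per_character[j])

    def test_empty_matrix_rejected(self):
        t = tree_from_newick("((A,B),(C,D));")
        m = CharacterMatrix(list("ABCD"), [], np.zeros((4, 0), dtype=np.int8))
        with pytest.raises(ValueError):
            retention_index(t, m)


class TestPermutationTest:
    def _clean_matrix(self, tree, n_chars):
        # every character a clean synapomorphy of some internal edge
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        sides = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = {lf.taxon.label for lf in node.leaf_iter()}
            if 2 <= len(side) <= len(labels) - 2:
                sides.append(side)
        columns = []
        for j in range(n_chars):
            side = sides[j % len(sides)]
            columns.append([1 if lab in side else 0 for lab in labels])
        return _matrix_from_columns(labels, columns)

    def test_clean_signal_minimal_p(self):
        t = random_tree(12, 2)
        m = self._clean_matrix(t, 40)
        res = ri_permutation_test(t, m, n_perm=200, seed=7)
        assert res.observed_mean_ri == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 201)
        assert (res.null_mean_ri < 1.0).all()

    def test_seed_reproducibility(self):
        t = random_tree(8, 3)
        rng = np.random.default_rng(12)
        m = _matrix_from_columns(
            sorted(lf.taxon.label for lf in t.leaf_node_iter()),
            rng.integers(0, 2, size=(20, 8)).tolist(),
        )
        r1 = ri_permutation_test(t, m, n_perm=50, seed=99)
        r2 = ri_permutation_test(t, m, n_perm=50, seed=99)
        assert np.array_equal(r1.null_mean_ri, r2.null_mean_ri)
        assert r1.p_value == r2.p_value

    def test_random_characters_not_significant(self):
        t = random_tree(10, 5)
        rng = np.random.default_rng(41)
        m = _matrix_from_columns(
            sorted(lf.taxon.label for lf in t.leaf_node_iter()),
            rng.integers(0, 2, size=(60, 10)).tolist(),
        )
        res = ri_permutation_test(t, m, n_perm=100, seed=13)
        assert res.p_value > 0.05  # i.i.d. characters carry no tree signal

    def test_zero_perms_rejected(self):
        t = random_tree(8, 3)
        m = _matrix_from_columns(
            sorted(lf.taxon.label for lf in t.leaf_node_iter()),
            [[1, 1, 1, 1, 0, 0, 0, 0]],
        )
        with pytest.raises(ValueError):
            ri_permutation_test(t, m, n_perm=0, seed=1)


class TestSaturation:
    def _dm(self, values):
        n = len(values)
        ids = [f"sp{i:02d}" for i in range(1, n + 1)]
        return DistanceMatrix(ids=ids, values=np.array(values, dtype=float))

    def test_all_zero_distances(self):
        t = random_tree(4, 1)
        dm = self._dm(np.zeros((4, 4)))
        res = saturation_profile(dm, t)
        assert res.saturation_fraction == 0.0

    def test_all_ones_fully_saturated(self):
        t = random_tree(4, 1)
        v = np.ones((4, 4)) - np.eye(4)
        res = saturation_profile(self._dm(v), t)
        assert res.saturation_fraction == 1.0

    def test_taxonomic_distance_is_edge_count(self):
        tree = tree_from_newick("((sp01:1,sp02:1):1,(sp03:1,sp04:1):1);")
        dm = self._dm(np.zeros((4, 4)))
        res = saturation_profile(dm, tree)
        t = res.table.set_index(["species_a", "species_b"])["taxonomic_distance"]
        assert t["sp01", "sp02"] == 2
        # unrooted: path sp01-sp03 crosses one internal edge -> 3 edges
        assert t["sp01", "sp03"] == 3

    def test_missing_species_excluded_with_warning(self):
        tree = tree_from_newick("((sp01,sp02),(sp03,spXX));")
        dm = self._dm(np.zeros((4, 4)))
        with pytest.warns(UserWarning):
            res = saturation_profile(dm, tree)
        assert res.excluded_species == ["sp04"]
        assert len(res.table) == 3
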
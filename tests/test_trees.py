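"""Neighbor joining, bipartitions, RF rate, newick I/O."""

import itertools

import dendropy
import numpy as np
import pytest

from distimpute.matrix import MaskedDistanceMatrix
from distimpute.missingness import delete_random_entries
from distimpute.synthetic import SimConfig, random_tree
from distimpute.trees import (
    additive_matrix,
    bipartitions,
    leaf_labels,
    nj_tree,
    parse_newick,
    rf_rate,
    write_newick,
)

from conftest import random_masked_matrix


def five_leaf_topologies():
    """All 15 unrooted binary topologies on leaves A..E as
    (newick, split-set) pairs; splits computed by construction, not by the
    tree code under test: each topology is two cherries plus a middle
    leaf, so its non-trivial splits are exactly the two cherries."""
    leaves = "ABCDE"
    seen = {}
    for middle in leaves:
        rest = [c for c in leaves if c != middle]
        for partner in rest[1:]:
            cherry1 = frozenset({rest[0], partner})
            cherry2 = frozenset(set(rest) - cherry1)
            key = frozenset({cherry1, cherry2})
            if key in seen:
                continue
            a, b = sorted(cherry1)
            c, d = sorted(cherry2)
            nwk = f"(({a}:1,{b}:1):1,{middle}:1,({c}:1,{d}:1):1);"
            seen[key] = (nwk, {cherry1, cherry2})
    assert len(seen) == 15
    return list(seen.values())


def oracle_rf_rate(splits1, splits2):
    # canonicalize each split as the side not containing "A"
    full = set("ABCDE")
    def canon(splits):
        return {s if "A" not in s else frozenset(full - s) for s in splits}
    b1, b2 = canon(splits1), canon(splits2)
    return len(b1 ^ b2) / (len(b1) + len(b2))


class TestNJ:
    def test_quartet_topology(self, quartet_matrix):
        tree = nj_tree(quartet_matrix)
        assert bipartitions(tree) == frozenset({frozenset({"C", "D"})})

    def test_three_taxon_branch_lengths(self):
        m = MaskedDistanceMatrix(
            ("A", "B", "C"),
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = nj_tree(m)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_two_taxa_single_edge(self):
        m = MaskedDistanceMatrix(
            ("A", "B"), np.array([[0.0, 1.7], [1.7, 0.0]])
        )
        tree = nj_tree(m)
        d = additive_matrix(tree)
        assert d.values[0, 1] == pytest.approx(1.7)

    def test_rejects_incomplete_matrix(self, rng):
        m = random_masked_matrix(rng, 6, 2)
        with pytest.raises(ValueError, match="missing"):
            nj_tree(m)

    def test_recovers_random_additive_trees(self):
        for seed in range(10):
            tree = random_tree(SimConfig(n_taxa=4 + 2 * seed, seed=seed))
            assert rf_rate(tree, nj_tree(additive_matrix(tree))) == 0.0

    def test_agrees_with_dendropy_nj(self):
        # independent cross-check: dendropy's NJ on the same matrix must
        # give a topologically identical tree on additive input
        tree = random_tree(SimConfig(n_taxa=12, seed=77))
        m = additive_matrix(tree)
        ours = nj_tree(m)
        csv = "," + ",".join(m.labels) + "\n" + "\n".join(
            lab + "," + ",".join(str(v) for v in m.values[i])
            for i, lab in enumerate(m.labels)
        )
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        theirs = parse_newick(pdm.nj_tree().as_string(schema="newick"))
        assert rf_rate(ours, theirs) == 0.0


class TestBipartitions:
    def test_quartet_single_split(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert bipartitions(t) == frozenset({frozenset({"C", "D"})})

    def test_star_tree_has_no_splits(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1);")
        assert bipartitions(t) == frozenset()

    def test_caterpillar_split_count(self):
        for n in (5, 8, 12):
            nwk = "(L1:1,L2:1)"
            for i in range(3, n + 1):
                nwk = f"({nwk}:1,L{i}:1)"
            t = parse_newick(nwk + ";")
            assert len(bipartitions(t)) == n - 3


class TestRFRate:
    def test_identity_is_zero(self):
        tree = random_tree(SimConfig(n_taxa=15, seed=2))
        assert rf_rate(tree, tree) == 0.0

    def test_hand_enumerated_five_leaf_case(self):
        t1 = parse_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        t2 = parse_newick("((A:1,C:1):1,B:1,(D:1,E:1):1);")
        # shared split DE, differing splits AB vs AC: RF = 2 of max 4
        assert rf_rate(t1, t2) == pytest.approx(0.5)

    def test_disjoint_caterpillars_rate_one(self):
        t1 = parse_newick("(((((A:1,B:1):1,C:1):1,D:1):1,E:1):1,F:1);")
        t2 = parse_newick("(((((A:1,D:1):1,F:1):1,B:1):1,E:1):1,C:1);")
        assert rf_rate(t1, t2) == 1.0

    def test_leaf_set_mismatch_rejected(self):
        t1 = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(ValueError, match="leaf sets"):
            rf_rate(t1, t2)

    def test_small_trees_rate_zero(self):
        t1 = parse_newick("(A:1,B:1,C:1);")
        t2 = parse_newick("(A:2,C:1,B:5);")
        assert rf_rate(t1, t2) == 0.0

    def test_matches_bruteforce_oracle_on_all_five_leaf_topologies(self):
        topos = five_leaf_topologies()
        trees = [(parse_newick(nwk), splits) for nwk, splits in topos]
        for (ta, sa), (tb, sb) in itertools.combinations_with_replacement(trees, 2):
            assert rf_rate(ta, tb) == pytest.approx(oracle_rf_rate(sa, sb))

    def test_symmetry_and_bounds(self):
        trees = [
            random_tree(SimConfig(n_taxa=9, seed=s)) for s in range(4)
        ]
        for ta, tb in itertools.combinations(trees, 2):
            r1, r2 = rf_rate(ta, tb), rf_rate(tb, ta)
            assert r1 == r2
            assert 0.0 <= r1 <= 1.0


class TestNewick:
    def test_round_trip_topology_and_lengths(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        back = parse_newick(write_newick(t))
        assert rf_rate(t, back) == 0.0
        assert np.allclose(
            additive_matrix(t).values, additive_matrix(back).values, atol=1e-9
        )

    def test_two_leaf_path_length(self):
        t = parse_newick("(A:1,B:2);")
        assert additive_matrix(t).values[0, 1] == pytest.approx(3.0)

    def test_write_read_idempotent_on_random_trees(self):
        for seed in range(8):
            t = random_tree(SimConfig(n_taxa=10, seed=seed))
            s1 = write_newick(t)
            s2 = write_newick(parse_newick(s1))
            assert s1 == s2

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("((A:1,A:1):1,(C:1,D:1):1);")


class TestAdditiveMatrix:
    def test_quartet_path_sums(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = additive_matrix(t)
        idx = {lab: i for i, lab in enumerate(m.labels)}
        assert m.values[idx["A"], idx["B"]] == pytest.approx(2.0)
        assert m.values[idx["A"], idx["C"]] == pytest.approx(4.0)

    def test_nj_consistency_property(self):
        # NJ provably recovers the tree from its own additive matrix
        for seed in range(20):
            n = 5 + (seed % 12)
            tree = random_tree(SimConfig(n_taxa=n, seed=1000 + seed))
            assert rf_rate(tree, nj_tree(additive_matrix(tree))) == 0.0

    def test_binary_tree_split_count(self):
        for n in (5, 9, 14):
            tree = random_tree(SimConfig(n_taxa=n, seed=n))
            assert len(bipartitions(tree)) == n - 3
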
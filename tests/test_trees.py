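"""Tree I/O, neighbor joining, bootstrap, and midpoint rooting."""

import numpy as np
import pytest

from lgtscreen.trees import (
    AnnotatedGeneTree,
    DistanceMatrix,
    NewickParseError,
    annotate,
    bootstrap_support,
    build_nj_tree,
    hamming_distance_matrix,
    max_root_to_leaf_depth,
    midpoint_root,
    nj_from_characters,
    parse_newick,
    read_taxonomy,
    split_set,
    tree_distance_matrix,
    write_newick,
    write_taxonomy,
)

from conftest import annotated_tree, taxon


class TestNewickIO:
    def test_supports_parsed_from_internal_labels(self):
        gtree = parse_newick("((A:1,B:1)90:1,C:2);")
        supports = [
            nd.support for nd in gtree.tree.preorder_internal_node_iter()
            if nd.support is not None
        ]
        assert supports == [90]
        assert sorted(gtree.leaf_ids) == ["A", "B", "C"]

    @pytest.mark.parametrize(
        "bad",
        ["(A:1);", "((A:1,B:1):1,A:2);", "((A:1,B:1:1,C:2);", "((A,B)150,C);"],
        ids=["too_few_leaves", "duplicate_leaf", "unbalanced", "support_range"],
    )
    def test_malformed_input_rejected(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_round_trip_preserves_topology_lengths_and_supports(self):
        rng = np.random.default_rng(7)
        # random 50-leaf tree built by leaf insertion
        gtree = parse_newick(_random_newick(50, rng))
        text = write_newick(gtree)
        back = parse_newick(text)
        assert split_set(back) == split_set(gtree)
        d1, d2 = tree_distance_matrix(gtree), tree_distance_matrix(back)
        assert d1.taxon_ids == d2.taxon_ids
        np.testing.assert_allclose(d1.d, d2.d, atol=1e-9)
        sup1 = sorted(n.support for n in gtree.tree.preorder_internal_node_iter()
                      if n.support is not None)
        sup2 = sorted(n.support for n in back.tree.preorder_internal_node_iter()
                      if n.support is not None)
        assert sup1 == sup2


def _random_newick(n_leaves, rng):
    parts = [f"L{i:02d}:{rng.uniform(0.1, 1):.4f}" for i in range(n_leaves)]
    while len(parts) > 3:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        sup = rng.integers(0, 101)
        parts.append(f"({a},{b}){sup}:{rng.uniform(0.1, 1):.4f}")
    return f"({parts[0]},{parts[1]},{parts[2]});"


class TestAnnotate:
    def test_strict_complete_table(self):
        records = [taxon(x, "Bacteria") for x in "ABCDE"]
        gtree = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        gtree, dropped = annotate(gtree, {r.leaf_id: r for r in records})
        assert dropped == 0
        assert gtree.is_fully_annotated()

    def test_strict_missing_leaf_errors(self):
        records = {r.leaf_id: r for r in [taxon(x, "Bacteria") for x in "ABCD"]}
        gtree = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        with pytest.raises(KeyError, match="E"):
            annotate(gtree, records, strict=True)

    def test_lenient_drops_unknown_leaves(self):
        records = {r.leaf_id: r for r in [taxon(x, "Bacteria") for x in "ABCD"]}
        gtree = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        gtree, dropped = annotate(gtree, records, strict=False)
        assert dropped == 1
        assert sorted(gtree.leaf_ids) == ["A", "B", "C", "D"]

    def test_lenient_below_three_leaves_errors(self):
        records = {"A": taxon("A", "Bacteria"), "B": taxon("B", "Bacteria")}
        gtree = parse_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        with pytest.raises(ValueError, match="< 3"):
            annotate(gtree, records, strict=False)

    def test_taxonomy_tsv_round_trip(self, tmp_path):
        records = {r.leaf_id: r for r in [taxon(x, "Bacteria") for x in "ABC"]}
        path = tmp_path / "tax.tsv"
        write_taxonomy(records, path)
        assert read_taxonomy(path) == records


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"], np.array(
            [[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float))
        nj = build_nj_tree(dm)
        back = tree_distance_matrix(nj)
        np.testing.assert_allclose(back.d, dm.d, atol=1e-9)

    def test_additive_matrix_recovers_planted_six_leaf_tree(self):
        planted = parse_newick(
            "(((A:0.3,B:0.2):0.25,(C:0.1,D:0.4):0.15):0.2,(E:0.3,F:0.2):0.1);"
        )
        dm = tree_distance_matrix(planted)
        nj = build_nj_tree(dm)
        assert split_set(nj) == split_set(planted)
        np.testing.assert_allclose(tree_distance_matrix(nj).d, dm.d, atol=1e-9)

    def test_caterpillar_recovery(self):
        planted = parse_newick(
            "((((A:0.2,B:0.3):0.15,C:0.2):0.12,D:0.3):0.2,E:0.4);"
        )
        dm = tree_distance_matrix(planted)
        assert split_set(build_nj_tree(dm)) == split_set(planted)

    def test_non_symmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B", "C"], np.array(
                [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))

    def test_matches_skbio_reference_implementation(self):
        # independent cross-check on a non-additive (noisy) matrix
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(11)
        n = 7
        base = rng.uniform(0.5, 2.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0)
        ids = [f"T{i}" for i in range(n)]
        mine = build_nj_tree(DistanceMatrix(ids, d))
        ref = sk_nj(SkDM(d, ids))
        assert split_set(mine) == split_set(parse_newick(str(ref)))


class TestBootstrap:
    taxa = ["A", "B", "C", "D", "E"]
    chars = np.array(
        [[0, 0, 1, 1, 1],
         [0, 0, 1, 1, 0],
         [1, 1, 0, 0, 0],
         [1, 1, 0, 0, 1],
         [1, 0, 1, 0, 1]])

    def test_no_conflict_columns_give_full_support(self):
        wide = np.repeat(self.chars, 30, axis=1)
        sup = bootstrap_support(wide, self.taxa, nj_from_characters, 50, seed=0)
        assert sup and all(v == 100.0 for v in sup.values())

    def test_single_replicate_forces_zero_or_hundred(self):
        sup = bootstrap_support(self.chars, self.taxa, nj_from_characters, 1, seed=3)
        assert set(sup.values()) <= {0.0, 100.0}

    def test_nonpositive_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.chars, self.taxa, nj_from_characters, 0, seed=0)

    def test_two_seeds_agree_within_binomial_envelope(self):
        wide = np.repeat(self.chars, 20, axis=1)
        s1 = bootstrap_support(wide, self.taxa, nj_from_characters, 100, seed=1)
        s2 = bootstrap_support(wide, self.taxa, nj_from_characters, 100, seed=2)
        for split in s1:
            p = max(s1[split], s2[split]) / 100
            envelope = 100 * 2 * 1.96 * np.sqrt(max(p * (1 - p), 1e-4) / 100)
            assert abs(s1[split] - s2[split]) <= max(envelope, 5.0)

    def test_invariant_to_taxon_input_order(self):
        order = [3, 1, 4, 0, 2]
        s1 = bootstrap_support(self.chars, self.taxa, nj_from_characters, 30, seed=9)
        s2 = bootstrap_support(
            self.chars[order], [self.taxa[i] for i in order],
            nj_from_characters, 30, seed=9,
        )
        assert s1 == s2


class TestMidpointRoot:
    def test_bisects_longest_path(self):
        gtree = parse_newick("((A:1,B:1):1,C:3);")
        midpoint_root(gtree)
        # A<->C path has length 5; deepest leaf ends 2.5 from the root
        assert max_root_to_leaf_depth(gtree) == pytest.approx(2.5)

    def test_symmetric_quartet_roots_on_central_edge(self):
        gtree = parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        midpoint_root(gtree)
        sides = {frozenset(lf.taxon.label for lf in ch.leaf_iter())
                 for ch in gtree.tree.seed_node.child_nodes()}
        assert sides == {frozenset("AB"), frozenset("CD")}

    def test_depth_equals_half_diameter_on_random_tree(self):
        rng = np.random.default_rng(5)
        gtree = parse_newick(_random_newick(20, rng))
        diameter = tree_distance_matrix(gtree).d.max()
        midpoint_root(gtree)
        assert max_root_to_leaf_depth(gtree) == pytest.approx(diameter / 2, abs=1e-9)

    def test_all_zero_lengths_fall_back_to_centroid(self, caplog):
        gtree = parse_newick("((A:0,B:0):0,(C:0,D:0):0,E:0);")
        import logging

        with caplog.at_level(logging.WARNING):
            midpoint_root(gtree)
        assert gtree.tree.is_rooted
        assert any("centroid" in r.message for r in caplog.records)

    def test_supports_follow_their_splits_across_rerooting(self):
        gtree = parse_newick("(((A:1,B:1)80:0.2,C:2)60:0.3,(D:1,E:1)95:2.5);")
        before = _support_splits(gtree)
        midpoint_root(gtree)
        assert _support_splits(gtree) == before


def _support_splits(gtree):
    labels = sorted(gtree.leaf_ids)
    anchor, all_leaves = labels[0], frozenset(labels)
    out = {}
    for nd in gtree.tree.preorder_internal_node_iter():
        if getattr(nd, "support", None) is None:
            continue
        below = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if anchor in below:
            below = all_leaves - below
        if 1 < len(below) < len(all_leaves) - 1:
            out[below] = nd.support
    return out
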
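"""Newick parsing, patristic distances, and nearest-relative annotation."""

import itertools

import dendropy
import numpy as np
import pytest

from tfcat.tree_annotation import (
    AnnotationRecord,
    LeafMetadata,
    NewickParseError,
    all_pairs_patristic,
    annotate_query,
    annotate_trees,
    parse_newick,
    patristic_distance,
    read_leaf_metadata,
    to_newick,
)
from tests.conftest import naive_patristic, random_tree


class TestParseNewick:
    def test_two_leaf_tree(self):
        tree = parse_newick("(A:1,B:2);")
        assert tree.leaf_labels == ["A", "B"]
        assert [l.length for l in tree.leaves] == [1.0, 2.0]

    def test_internal_label_stored_not_a_leaf(self):
        tree = parse_newick("((A:1,B:2)0.95:3,C:4);")
        assert tree.leaf_labels == ["A", "B", "C"]
        internal = tree.root.children[0]
        assert internal.label == "0.95" and not internal.is_leaf
        assert internal.length == 3.0

    def test_duplicate_leaf_label_errors(self):
        with pytest.raises(ValueError, match="duplicate leaf label"):
            parse_newick("(A:1,A:2);")

    def test_unbalanced_parentheses_error_carries_position(self):
        with pytest.raises(NewickParseError, match="position"):
            parse_newick("((A:1,B:2:3,C:4);")
        with pytest.raises(NewickParseError):
            parse_newick("(A:1,B:2));")

    def test_empty_string_errors(self):
        with pytest.raises(NewickParseError, match="empty"):
            parse_newick("   ")

    def test_quoted_labels_with_escapes_and_spaces(self):
        tree = parse_newick("('leaf one':1,'it''s':2);")
        assert tree.leaf_labels == ["leaf one", "it's"]

    def test_underscores_kept_literal(self):
        assert parse_newick("(gene_1:1,gene_2:2);").leaf_labels == ["gene_1", "gene_2"]

    def test_scientific_notation_branch_lengths(self):
        tree = parse_newick("(A:1.5e-3,B:2E2);")
        assert [l.length for l in tree.leaves] == [0.0015, 200.0]

    def test_negative_branch_length_rejected(self):
        with pytest.raises(NewickParseError, match="negative"):
            parse_newick("(A:-1,B:2);")

    def test_missing_lengths_error_unless_unit_fill(self):
        tree = parse_newick("((A,B):1,C:2);")
        with pytest.raises(ValueError, match="unit branch"):
            patristic_distance(tree, "A", "B")
        tree.resolve_branch_lengths(fill=1.0)
        assert patristic_distance(tree, "A", "B") == 2.0

    def test_serialize_parse_round_trip(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            tree = random_tree(int(rng.integers(2, 30)), rng)
            back = parse_newick(to_newick(tree))
            assert back.leaf_labels == tree.leaf_labels
            labels, m1 = all_pairs_patristic(tree)
            _, m2 = all_pairs_patristic(back)
            np.testing.assert_allclose(m1, m2, rtol=0, atol=0)

    def test_quoted_label_round_trip(self):
        text = "('a b':1,'c''d':2);"
        assert parse_newick(to_newick(parse_newick(text))).leaf_labels == ["a b", "c'd"]


class TestPatristicDistance:
    def test_self_distance_zero(self):
        tree = parse_newick("((A:1,B:2):3,C:4);")
        assert patristic_distance(tree, "A", "A") == 0.0

    def test_hand_checked_three_leaf_tree(self):
        tree = parse_newick("((A:1,B:2):3,C:4);")
        assert patristic_distance(tree, "A", "B") == 3.0
        assert patristic_distance(tree, "A", "C") == 8.0
        assert patristic_distance(tree, "B", "C") == 9.0

    def test_zero_length_edge_contributes_zero(self):
        tree = parse_newick("((A:1,B:2):0,C:4);")
        assert patristic_distance(tree, "A", "C") == 5.0

    def test_unknown_leaf_named_in_error(self):
        tree = parse_newick("(A:1,B:2);")
        with pytest.raises(KeyError, match="ghost"):
            patristic_distance(tree, "A", "ghost")

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        tree = random_tree(10, rng)
        for a, b in itertools.combinations(tree.leaf_labels, 2):
            # summation order differs by direction, so exact only up to float error
            assert patristic_distance(tree, a, b) == pytest.approx(
                patristic_distance(tree, b, a), rel=1e-12
            )


class TestAllPairsPatristic:
    def test_single_leaf_tree(self):
        labels, mat = all_pairs_patristic(parse_newick("A:1;"))
        assert labels == ["A"] and mat.shape == (1, 1) and mat[0, 0] == 0.0

    def test_matches_naive_oracle_on_random_trees(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            tree = random_tree(int(rng.integers(2, 40)), rng)
            labels, mat = all_pairs_patristic(tree)
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    assert mat[i, j] == pytest.approx(
                        naive_patristic(tree, a, b), rel=1e-12, abs=1e-12
                    )

    def test_matches_pairwise_operation_on_12_leaves(self):
        rng = np.random.default_rng(66)
        tree = random_tree(12, rng)
        labels, mat = all_pairs_patristic(tree)
        for i, j in itertools.combinations(range(12), 2):
            assert mat[i, j] == pytest.approx(
                patristic_distance(tree, labels[i], labels[j]), rel=1e-12
            )

    def test_metric_axioms(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = int(rng.integers(3, 25))
            _, mat = all_pairs_patristic(random_tree(n, rng))
            assert np.allclose(np.diag(mat), 0.0)
            assert (mat >= 0).all()
            np.testing.assert_allclose(mat, mat.T)
            for i, j, k in itertools.combinations(range(n), 3):
                assert mat[i, j] <= mat[i, k] + mat[k, j] + 1e-9

    def test_four_point_condition(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 16))
            _, mat = all_pairs_patristic(random_tree(n, rng))
            for i, j, k, l in itertools.combinations(range(n), 4):
                sums = sorted([mat[i, j] + mat[k, l], mat[i, k] + mat[j, l], mat[i, l] + mat[j, k]])
                assert sums[1] == pytest.approx(sums[2], rel=1e-9, abs=1e-9)

    def test_agrees_with_dendropy(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            tree = random_tree(int(rng.integers(3, 30)), rng)
            newick = to_newick(tree)
            dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
            pdm = dtree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in dtree.taxon_namespace}
            labels, mat = all_pairs_patristic(tree)
            for i, a in enumerate(labels):
                for j, b in enumerate(labels):
                    assert mat[i, j] == pytest.approx(
                        pdm.patristic_distance(taxa[a], taxa[b]), rel=1e-9, abs=1e-12
                    )

    def test_invariant_under_rerooting(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            tree = random_tree(int(rng.integers(4, 25)), rng)
            labels, mat = all_pairs_patristic(tree)
            order = np.argsort(labels)
            dtree = dendropy.Tree.get(
                data=to_newick(tree), schema="newick", preserve_underscores=True
            )
            edges = [e for e in dtree.preorder_edge_iter() if e.length and e.head_node.parent_node]
            edge = edges[int(rng.integers(0, len(edges)))]
            dtree.reroot_at_edge(edge, update_bipartitions=False, length1=edge.length / 2,
                                 length2=edge.length / 2)
            rerooted = parse_newick(dtree.as_string(schema="newick", suppress_rooting=True).strip())
            labels2, mat2 = all_pairs_patristic(rerooted)
            order2 = np.argsort(labels2)
            assert sorted(labels) == sorted(labels2)
            np.testing.assert_allclose(
                mat[np.ix_(order, order)], mat2[np.ix_(order2, order2)], rtol=1e-9, atol=1e-12
            )


class TestLeafMetadata:
    def test_three_row_file(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("seq_id\tgene_symbol\tsource\nL1\thoxA\tfly\nL2\tpax\tfly\nL3\tubx\t\n")
        meta = read_leaf_metadata(path)
        assert len(meta) == 3
        assert meta.symbol("L1") == "hoxA"
        assert meta.source_tag("L3") is None

    def test_headerless_file_autodetected(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("ENSP1\thoxA\nENSP2\tpax\n")
        assert len(read_leaf_metadata(path)) == 2

    def test_duplicate_id_errors(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("L1\thoxA\nL1\tpax\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_leaf_metadata(path)

    def test_empty_symbol_rows_dropped_with_warning(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("L1\thoxA\nL2\t\n")
        with pytest.warns(UserWarning, match="empty gene symbol"):
            meta = read_leaf_metadata(path)
        assert len(meta) == 1

    def test_single_column_errors(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("L1\nL2\n")
        with pytest.raises(ValueError, match="fewer than 2"):
            read_leaf_metadata(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "meta.tsv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert len(read_leaf_metadata(path)) == 0


class TestAnnotateQuery:
    def meta(self, **mapping):
        return LeafMetadata({k: (v, None) for k, v in mapping.items()})

    def test_closest_annotated_leaf_donates_symbol(self):
        tree = parse_newick("((Q:1,B:2):3,C:4);")
        rec = annotate_query(tree, "Q", self.meta(B="hoxA", C="pax"))
        assert rec.assigned_symbol == "hoxA"
        assert rec.donor_leaf == "B"
        assert rec.patristic_distance == 3.0
        assert rec.n_ties == 1

    def test_empty_metadata_gives_none_record(self):
        tree = parse_newick("((Q:1,B:2):3,C:4);")
        rec = annotate_query(tree, "Q", LeafMetadata())
        assert rec.assigned_symbol is None
        assert rec.donor_leaf is None
        assert rec.patristic_distance is None
        assert rec.n_ties == 0

    def test_exact_tie_breaks_lexicographically_on_symbol(self):
        tree = parse_newick("(Q:1,B:2,C:2);")  # B and C exactly equidistant from Q
        rec = annotate_query(tree, "Q", self.meta(B="Ubx", C="abd-A"))
        assert rec.assigned_symbol == "abd-A"
        assert rec.n_ties == 2

    def test_excluded_source_tags_never_donate(self):
        tree = parse_newick("((Q:1,B:2):3,C:4);")
        meta = LeafMetadata({"B": ("hoxA", "same_species"), "C": ("pax", "other")})
        rec = annotate_query(tree, "Q", meta, exclude_tags={"same_species"})
        assert rec.assigned_symbol == "pax"

    def test_query_not_a_leaf_errors(self):
        tree = parse_newick("(A:1,B:2);")
        with pytest.raises(KeyError, match="Q"):
            annotate_query(tree, "Q", LeafMetadata())


class TestAnnotateTrees:
    def write_trees(self, tmp_path, texts):
        d = tmp_path / "trees"
        d.mkdir()
        for i, t in enumerate(texts):
            (d / f"tree_{i}.nwk").write_text(t)
        return d

    def test_queries_resolved_across_files(self, tmp_path):
        d = self.write_trees(
            tmp_path, ["((Q1:1,B:2):3,C:4);", "((Q2:1,D:1):2,(E:1,F:5):1);"]
        )
        meta = LeafMetadata(
            {k: (f"sym_{k}", None) for k in ["B", "C", "D", "E", "F"]}
        )
        records = annotate_trees(d, ["Q1", "Q2", "Q3"], meta)
        by_query = {r.query_id: r for r in records}
        assert by_query["Q1"].assigned_symbol == "sym_B"
        assert by_query["Q2"].assigned_symbol == "sym_D"
        assert by_query["Q3"].assigned_symbol is None
        assert by_query["Q3"].tree_source is None

    def test_malformed_tree_skipped_not_fatal(self, tmp_path):
        d = self.write_trees(tmp_path, ["((Q1:1,B:2):3,C:4);", "((broken:1;"])
        meta = LeafMetadata({"B": ("hoxA", None), "C": ("pax", None)})
        with pytest.warns(UserWarning, match="skipping unparseable"):
            records = annotate_trees(d, ["Q1"], meta)
        assert records[0].assigned_symbol == "hoxA"

    def test_query_in_two_trees_reported_first_wins(self, tmp_path):
        d = self.write_trees(tmp_path, ["(Q1:1,B:2);", "(Q1:1,C:2);"])
        meta = LeafMetadata({"B": ("hoxA", None), "C": ("pax", None)})
        with pytest.warns(UserWarning, match="appears in 2 trees"):
            records = annotate_trees(d, ["Q1"], meta)
        assert records[0].tree_source == "tree_0.nwk"

    def test_missing_directory_errors(self, tmp_path):
        with pytest.raises(NotADirectoryError):
            annotate_trees(tmp_path / "nope", [], LeafMetadata())

    def test_unit_branch_length_flag(self, tmp_path):
        d = self.write_trees(tmp_path, ["((Q1,B),C);"])
        meta = LeafMetadata({"B": ("hoxA", None), "C": ("pax", None)})
        records = annotate_trees(d, ["Q1"], meta, unit_branch_lengths=True)
        assert records[0].assigned_symbol == "hoxA"
        assert records[0].patristic_distance == 2.0
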
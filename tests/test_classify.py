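"""Gene-tree classification: clade discovery, nesting, the decision cascade."""

import itertools

import numpy as np
import pytest

from cyanihgt import (
    Nesting,
    Pattern,
    Status,
    Thresholds,
    classify_tree,
    focal_clades,
    nesting_context,
    presence_matrix,
    read_newick_with_supports,
)

from conftest import taxonomy_for


def parse(nwk):
    return read_newick_with_supports(nwk, taxonomy_for(nwk))


def leafset(node):
    return frozenset(l.taxon.label for l in node.leaf_iter())


class TestFocalClades:
    def test_single_monophyletic_group(self):
        tree = parse("((E_gal1,E_gal2),(B_x,B_y));")
        assert [leafset(c) for c in focal_clades(tree)] == [
            frozenset({"E_gal1", "E_gal2"})
        ]

    def test_scattered_focal_leaves_give_singleton_clades(self):
        tree = parse("((E_gal1,B_x),(E_gal2,B_y));")
        assert {leafset(c) for c in focal_clades(tree)} == {
            frozenset({"E_gal1"}), frozenset({"E_gal2"})
        }

    def test_matches_brute_force_on_random_trees(self):
        # maximal all-focal clades found by enumerating every node
        rng = np.random.default_rng(11)
        for _ in range(10):
            labels = [
                (f"E_gal{i}" if rng.random() < 0.3 else
                 f"B_b{i}" if rng.random() < 0.5 else f"E_o{i}")
                for i in range(50)
            ]
            nwk = _random_newick(labels, rng)
            tree = parse(nwk)
            found = {leafset(c) for c in focal_clades(tree)}
            # oracle: all-focal nodes whose parent is not all-focal
            def all_focal(n):
                return all(tree.info(l).is_focal for l in n.leaf_iter())
            oracle = {
                leafset(n)
                for n in tree.tree.preorder_node_iter()
                if all_focal(n)
                and (n.parent_node is None or not all_focal(n.parent_node))
            }
            assert found == oracle


def _random_newick(labels, rng):
    parts = [l for l in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), 2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}){rng.integers(50, 101)}")
    inner = parts[0]
    # strip the support that would sit on the root label
    return inner[: inner.rfind(")") + 1] + ";"


class TestNestingContext:
    def test_prokaryotic_with_donor_set(self):
        tree = parse("(((E_gal1,E_gal2)95,(B_x,(B_y,B_z))90)98,(E_o1,E_o2));")
        ctx = nesting_context(tree, focal_clades(tree)[0])
        assert ctx.nesting is Nesting.PROKARYOTIC
        assert ctx.donor_taxa == {"x", "y", "z"}

    def test_eukaryotic(self):
        tree = parse("((E_gal1,E_gal2)95,(E_o1,E_o2)90);")
        ctx = nesting_context(tree, focal_clades(tree)[0])
        assert ctx.nesting is Nesting.EUKARYOTIC

    def test_mixed(self):
        tree = parse("((E_gal1,E_gal2)95,(B_x,E_o1)90);")
        ctx = nesting_context(tree, focal_clades(tree)[0])
        assert ctx.nesting is Nesting.MIXED

    def test_whole_tree_clade_is_an_error(self):
        tree = parse("(E_gal1,(E_gal2,E_gal3));")
        with pytest.raises(ValueError, match="whole tree"):
            nesting_context(tree, focal_clades(tree)[0])

    def test_depth_two_extends_donor_set_inside_tree(self):
        # donors one level further out are collected when not across the root
        nwk = "((((E_gal1,E_gal2)95,(B_x,B_y)90)97,(B_z,B_w)92)98,(E_o1,E_o2));"
        tree = parse(nwk)
        ctx = nesting_context(tree, focal_clades(tree)[0])
        assert ctx.donor_taxa == {"x", "y", "z", "w"}
        ctx1 = nesting_context(
            tree, focal_clades(tree)[0], Thresholds(donor_neighborhood_depth=1)
        )
        assert ctx1.donor_taxa == {"x", "y"}


HGT_NWK = "(((E_gal1,E_gal2)95,((B_s1,B_s2)91,B_s3)90)98,(E_o1,E_o2));"


class TestClassifyCascade:
    def test_clean_hgt(self):
        call = classify_tree(parse(HGT_NWK))
        assert call.status is Status.HGT
        assert call.donor_taxa == {"s1", "s2", "s3"}
        assert call.pattern is Pattern.GALDIERIA_EXCLUSIVE

    def test_too_few_donors(self):
        nwk = "(((E_gal1,E_gal2)95,(B_s1,B_s2)91)98,(E_o1,E_o2));"
        call = classify_tree(parse(nwk))
        assert call.status is Status.REJECTED_FEW_DONORS

    def test_consecutive_weak_supports_reject(self):
        nwk = "(((E_gal1,E_gal2)60,(B_s1,(B_s2,B_s3))55)58,(E_o1,E_o2));"
        call = classify_tree(parse(nwk))
        assert call.status is Status.REJECTED_LOW_SUPPORT

    def test_single_weak_node_does_not_reject(self):
        nwk = "(((E_gal1,E_gal2)60,((B_s1,B_s2)91,B_s3)90)98,(E_o1,E_o2));"
        call = classify_tree(parse(nwk))
        assert call.status is Status.HGT
        # but the weak discriminating context keeps the pattern honest
        assert call.pattern in {Pattern.GALDIERIA_EXCLUSIVE, Pattern.UNCERTAIN}

    def test_egt_excluded_with_photosynthetic_annotation(self):
        nwk = "(((E_gal1,E_gal2)95,((B_cyano1,B_cyano2)95,B_cyano3)96)98,(E_o1,E_o2));"
        call = classify_tree(parse(nwk), photosynthetic_annotation=True)
        assert call.status is Status.EGT_EXCLUDED

    def test_egt_excluded_via_photosynthetic_homologs_in_tree(self):
        nwk = (
            "(((E_gal1,E_gal2)95,((B_cyano1,B_cyano2)95,B_cyano3)96)98,"
            "(E_photo1,E_photo2));"
        )
        call = classify_tree(parse(nwk))
        assert call.status is Status.EGT_EXCLUDED

    def test_non_cyano_donors_are_not_egt(self):
        call = classify_tree(parse(HGT_NWK), photosynthetic_annotation=True)
        assert call.status is Status.HGT

    def test_singleton(self):
        nwk = "((E_gal1,((B_s1,B_s2)91,B_s3)90)98,(E_o1,E_o2));"
        call = classify_tree(parse(nwk))
        assert call.status is Status.SINGLETON

    def test_native(self):
        nwk = "(((E_gal1,E_gal2)95,(E_o1,E_o2)90)97,(B_x,B_y));"
        call = classify_tree(parse(nwk))
        assert call.status is Status.NATIVE

    def test_shared_ancient_pattern(self):
        nwk = "((((E_gal1,E_gal2)95,(E_cya1,E_cya2)96)97,(B_s1,(B_s2,B_s3))90)98,(E_o1,E_o2));"
        call = classify_tree(parse(nwk))
        assert call.status is Status.HGT
        assert call.pattern is Pattern.SHARED_ANCIENT

    def test_replacement_flag(self):
        # Galdieria nested in bacteria; Cyanidioschyzon clusters with eukaryotes
        nwk = (
            "(((E_gal1,E_gal2)95,(B_s1,(B_s2,B_s3))90)98,"
            "((E_cya1,E_cya2)94,(E_o1,E_o2))96);"
        )
        call = classify_tree(parse(nwk))
        assert call.status is Status.HGT
        assert call.pattern is Pattern.GALDIERIA_EXCLUSIVE
        assert call.replacement is Pattern.REPLACEMENT_GALDIERIA

    def test_multiple_hgt_disjoint_donor_phyla(self):
        nwk = (
            "((((E_gal1,E_gal2)95,(B_p1,(B_p2,B_p3))92)96,"
            "((E_cya1,E_cya2)95,(B_f1@Firmicutes,(B_f2@Firmicutes,B_f3@Firmicutes))93)97)98,"
            "(E_o1,E_o2));"
        )
        call = classify_tree(parse(nwk))
        assert call.status is Status.HGT
        assert call.pattern is Pattern.MULTIPLE_HGT
        assert call.donor_phyla == {"Proteobacteria", "Firmicutes"}

    def test_leaf_order_permutation_invariance(self):
        base = classify_tree(parse(HGT_NWK))
        variant = "((((B_s1,B_s2)91,B_s3)90,(E_gal2,E_gal1)95)98,(E_o2,E_o1));"
        call = classify_tree(parse(variant))
        assert call.status is base.status
        assert call.donor_taxa == base.donor_taxa

    def test_min_donor_monotonicity(self):
        # raising min_donor_taxa never converts a non-hgt call into hgt
        trees = [HGT_NWK, "(((E_gal1,E_gal2)95,(B_s1,B_s2)91)98,(E_o1,E_o2));"]
        for nwk in trees:
            previous_hgt = True
            for k in (1, 2, 3, 4, 5):
                call = classify_tree(parse(nwk), Thresholds(min_donor_taxa=k))
                is_hgt = call.status is Status.HGT
                assert is_hgt <= previous_hgt  # once lost, never regained
                previous_hgt = is_hgt


class TestPresenceMatrix:
    def test_row_sums_equal_strain_counts(self):
        nwk = "((((E_gal1,E_gal2)95,(E_cya1,E_cya2)96)97,(B_s1,(B_s2,B_s3))90)98,(E_o1,E_o2));"
        tree = parse(nwk)
        call = classify_tree(tree)
        strains = ["gal1", "gal2", "gal3", "cya1", "cya2"]
        m = presence_matrix([call], strains, tree.taxonomy)
        assert m.loc[call.og_id].sum() == 4
        assert m.loc[call.og_id, "gal3"] == 0
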
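"""Subtree extraction, tip-name filtering, polytomy resolution, matching."""

import dendropy
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltrait.phylo import TreeIndex, tree_from_newick
from saltrait.treeprep import (
    extract_family_subtree,
    filter_tip_names,
    match_halophytes,
    normalize_name,
    resolve_polytomies,
)


@pytest.mark.parametrize(
    "name,kept",
    [
        ("Atriplex_halimus", True),
        ("Limonium_sp", False),
        ("Atriplex_sp.", False),
        ("Limonium_cf_vulgare", False),
        ("Limonium_aff_vulgare", False),
        ("Limonium_af_vulgare", False),
        ("Spartina_alterniflora", True),       # 'sp' prefix but not the token
        ("Sporobolus_virginicus", True),
        ("Tamarix_chinensis_x_ramosissima", False),
        ("Atriplex_halimus_x_canescens", False),
        ("Atriplex_halimus_hybrid", False),
        ("Puccinellia_distans_subsp_limosa", True),  # infraspecific, kept
        ("Xanthium_strumarium", True),         # genus starting with X
    ],
)
def test_filter_tip_names_rules(name, kept):
    kept_names, dropped = filter_tip_names([name])
    assert (name in kept_names) is kept
    if not kept:
        assert dropped[0].reason in ("epithet", "hybrid")


def test_filter_reports_reasons():
    _, dropped = filter_tip_names(["Limonium_sp", "A_b_x_c"])
    assert {d.reason for d in dropped} == {"epithet", "hybrid"}


@given(st.lists(st.sampled_from([
    "Atriplex_halimus", "Limonium_sp", "Tamarix_a_x_b", "Suaeda_maritima",
    "Salicornia_cf_europaea", "Avicennia_marina_hybrid",
]), max_size=12))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_filter_idempotent(names):
    kept, _ = filter_tip_names(names)
    kept2, dropped2 = filter_tip_names(kept)
    assert kept2 == kept and dropped2 == []


def test_extract_monophyletic_family():
    tree = tree_from_newick("(((A,B),(C,D)),(E,F));")
    fam = {"A": "X", "B": "X", "C": "X", "D": "X", "E": "Y", "F": "Y"}
    sub, log = extract_family_subtree(tree, fam, "X")
    assert sorted(l.taxon.label for l in sub.leaf_node_iter()) == ["A", "B", "C", "D"]
    assert log.removed_intruders == []


def test_extract_prunes_and_logs_intruders():
    tree = tree_from_newick("(((A,B),(Z,D)),(E,F));")
    fam = {"A": "X", "B": "X", "Z": "Y", "D": "X", "E": "Y", "F": "Y"}
    sub, log = extract_family_subtree(tree, fam, "X")
    tips = sorted(l.taxon.label for l in sub.leaf_node_iter())
    assert tips == ["A", "B", "D"]
    assert log.removed_intruders == ["Z"]
    # pruning left no unifurcations
    assert all(len(n.child_nodes()) == 2 for n in sub.preorder_internal_node_iter())


def test_extract_family_spanning_root():
    tree = tree_from_newick("((A,B),(C,(D,E)));")
    fam = {"A": "X", "B": "Y", "C": "X", "D": "X", "E": "Y"}
    sub, log = extract_family_subtree(tree, fam, "X")
    assert sorted(l.taxon.label for l in sub.leaf_node_iter()) == ["A", "C", "D"]
    assert log.removed_intruders == ["B", "E"]


def test_extract_errors():
    tree = tree_from_newick("((A,B),(C,D));")
    fam = {"A": "X", "B": "Y", "C": "Y", "D": "Y"}
    with pytest.raises(KeyError):
        extract_family_subtree(tree, fam, "Nope")
    with pytest.raises(ValueError, match=">= 2"):
        extract_family_subtree(tree, fam, "X")


def test_resolve_polytomies_binary_tree_unchanged():
    tree = tree_from_newick("((A,B),(C,D));")
    resolved = resolve_polytomies(tree, seed=1)
    assert resolved.as_string(schema="newick", suppress_edge_lengths=True) == \
        tree.as_string(schema="newick", suppress_edge_lengths=True)


def test_resolve_polytomies_star_tree():
    star = tree_from_newick("(A,B,C,D);")
    r1 = resolve_polytomies(star, seed=7)
    r2 = resolve_polytomies(star, seed=7)
    assert r1.as_string(schema="newick") == r2.as_string(schema="newick")
    idx = TreeIndex.from_dendropy(r1)  # raises if not binary
    assert idx.n_tips == 4 and idx.n_nodes == 7
    assert sorted(idx.labels) == ["A", "B", "C", "D"]
    assert all(e.length == 1.0 for e in r1.preorder_edge_iter())
    # original untouched
    assert max(len(n.child_nodes()) for n in star.preorder_node_iter()) == 4


def test_resolution_never_shortens_tip_paths():
    nwk = "((A,B,C,(D,E,F)),G);"
    tree = tree_from_newick(nwk)
    resolved = resolve_polytomies(tree, seed=3)

    def path_lengths(t):
        # edge counts between tip pairs, via root paths
        import itertools
        paths = {}
        for leaf in t.leaf_node_iter():
            anc, n = [], leaf
            while n is not None:
                anc.append(id(n))
                n = n.parent_node
            paths[leaf.taxon.label] = anc
        out = {}
        for a, b in itertools.combinations(sorted(paths), 2):
            pa, pb = paths[a], paths[b]
            sb = set(pb)
            i = next(i for i, x in enumerate(pa) if x in sb)
            out[(a, b)] = i + pb.index(pa[i])
        return out

    before, after = path_lengths(tree), path_lengths(resolved)
    assert all(after[p] >= before[p] for p in before)


def test_match_halophytes_normalisation():
    states = match_halophytes(
        ["Atriplex_halimus", "Suaeda maritima", "Puccinellia_distans_subsp_limosa"],
        ["Atriplex halimus", "SUAEDA_MARITIMA", "Puccinellia distans"],
    )
    assert states == {
        "Atriplex_halimus": 1,
        "Suaeda maritima": 1,
        "Puccinellia_distans_subsp_limosa": 0,  # no collapsing to species
    }


def test_match_halophytes_zero_matches_ok():
    assert match_halophytes(["A_b"], ["C_d"]) == {"A_b": 0}
    with pytest.raises(ValueError):
        match_halophytes(["A_b"], [])


def test_normalize_name():
    assert normalize_name(" Atriplex  halimus ") == "atriplex halimus"
    assert normalize_name("Atriplex_halimus") == "atriplex halimus"
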
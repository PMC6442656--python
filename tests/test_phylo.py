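"""Parsimony search vs brute-force oracle, bootstrap behaviour, matrix rules."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from residualphylo.absence import AbsenceTestResult, DetectionRule
from residualphylo.io_formats import Assay, RegionClass, write_newick
from residualphylo.phylo import (
    PhyloTree,
    PresenceMatrix,
    PresenceState,
    TreeNode,
    bootstrap_support,
    build_presence_matrix,
    fitch_score,
    parsimony_tree,
)

from conftest import make_sample, make_variant

A, P, U = PresenceState.ABSENT, PresenceState.PRESENT, PresenceState.UNKNOWN


def matrix_from_rows(rows, blood="BLOOD", m_samples=()):
    """rows: dict sample -> list of states."""
    df = pd.DataFrame(
        {f"chr1:{i}:A>T": [states[i] for states in rows.values()]
         for i in range(len(next(iter(rows.values()))))},
        index=list(rows),
        dtype=np.int8,
    )
    regions = {
        s: (RegionClass.BLOOD if s == blood
            else RegionClass.M if s in m_samples else RegionClass.T)
        for s in rows
    }
    return PresenceMatrix(df, blood, regions)


# ---------------------------------------------------------------------------
# independent oracle: naive set-based Fitch over exhaustively enumerated trees
# ---------------------------------------------------------------------------

def all_rooted_topologies(leaves):
    """All rooted binary topologies over the leaves (nested tuples)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for sub in all_rooted_topologies(rest):
        yield from _insert_everywhere(sub, first)


def _insert_everywhere(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        for i in (0, 1):
            for new_sub in _insert_everywhere(tree[i], leaf):
                yield (new_sub, tree[1]) if i == 0 else (tree[0], new_sub)


def naive_fitch(tree, char):
    """Classic set-based Fitch; char maps leaf -> state set."""
    def down(node):
        if not isinstance(node, tuple):
            return char[node], 0
        (ls, lc), (rs, rc) = down(node[0]), down(node[1])
        inter = ls & rs
        if inter:
            return inter, lc + rc
        return ls | rs, lc + rc + 1

    _, changes = down(tree)
    return changes


def oracle_min_score(matrix: PresenceMatrix):
    samples = matrix.sample_ids
    chars = []
    for vid in matrix.variant_ids:
        col = {}
        for s in samples:
            state = matrix.data.loc[s, vid]
            col[s] = frozenset({0, 1}) if state == U else frozenset({int(state)})
        chars.append(col)
    best = None
    for topo in all_rooted_topologies(tuple(samples)):
        score = sum(naive_fitch(topo, c) for c in chars)
        best = score if best is None else min(best, score)
    return best


def random_matrix(rng, n_taxa=5, n_chars=20, unknown_in=()):
    rows = {}
    names = ["BLOOD"] + [f"S{i}" for i in range(1, n_taxa)]
    for name in names:
        if name == "BLOOD":
            rows[name] = [A] * n_chars
        else:
            states = rng.integers(0, 2, n_chars).tolist()
            if name in unknown_in:
                for j in rng.choice(n_chars, size=3, replace=False):
                    states[j] = U
            rows[name] = states
    return matrix_from_rows(rows, m_samples=set(unknown_in))


def test_parsimony_matches_exhaustive_oracle(rng):
    for rep in range(8):
        matrix = random_matrix(rng, unknown_in=("S4",) if rep % 2 else ())
        tree = parsimony_tree(matrix)
        assert tree.score == oracle_min_score(matrix)
        # the returned tree itself achieves the reported score
        assert fitch_score(tree, matrix) == tree.score


def test_perfect_nesting_gives_caterpillar():
    # S1 c S2 c S3 private mutation sets: chain topology, score = #mutations
    rows = {
        "BLOOD": [A] * 6,
        "S1": [P, P, P, P, P, P],
        "S2": [A, A, P, P, P, P],
        "S3": [A, A, A, A, P, P],
    }
    tree = parsimony_tree(matrix_from_rows(rows))
    assert tree.score == 6
    clades = set(tree.clades())
    assert frozenset({"S1", "S2"}) in clades or frozenset({"S1", "S2", "S3"}) in clades
    # nesting: S3 splits first from the root
    assert tree.root_path_mutations("S3") < tree.root_path_mutations("S1")


def test_identical_samples_collapse_to_star():
    rows = {
        "BLOOD": [A] * 5,
        "S1": [P] * 5,
        "S2": [P] * 5,
        "S3": [P] * 5,
        "S4": [P] * 5,
    }
    tree = parsimony_tree(matrix_from_rows(rows))
    assert tree.score == 5  # one trunk gain per mutation
    trunk = [c for c in tree.root.children if not c.is_leaf]
    assert len(trunk) == 1 and len(trunk[0].children) == 4
    assert trunk[0].length == 5
    assert all(child.length == 0 for child in trunk[0].children)


def test_star_tree_fitch_examples():
    # hand-built multifurcating star: k private mutations cost k
    k = 4
    rows = {"BLOOD": [A] * k}
    for i in range(k):
        rows[f"S{i + 1}"] = [P if j == i else A for j in range(k)]
    matrix = matrix_from_rows(rows)
    star = TreeNode(children=[TreeNode(name=s) for s in rows])
    assert fitch_score(star, matrix) == k

    # all-PRESENT column costs exactly one trunk gain on any tree
    rows_trunk = {s: ([A] if s == "BLOOD" else [P]) for s in rows}
    assert fitch_score(star, matrix_from_rows(rows_trunk)) == 1


def test_fitch_score_leaf_mismatch_errors():
    rows = {"BLOOD": [A], "S1": [P], "S2": [P]}
    matrix = matrix_from_rows(rows)
    tree = TreeNode(children=[TreeNode(name="BLOOD"), TreeNode(name="SX")])
    with pytest.raises(ValueError, match="do not match"):
        fitch_score(tree, matrix)


def test_unknown_cells_carry_no_cost():
    rows_known = {"BLOOD": [A], "S1": [P], "S2": [A], "S3": [P]}
    rows_unknown = {"BLOOD": [A], "S1": [P], "S2": [U], "S3": [P]}
    t_known = parsimony_tree(matrix_from_rows(rows_known, m_samples={"S2"}))
    t_unknown = parsimony_tree(matrix_from_rows(rows_unknown, m_samples={"S2"}))
    assert t_unknown.score <= t_known.score


def test_too_many_taxa_error(rng):
    n = 14
    rows = {"BLOOD": [A] * 4}
    for i in range(n - 1):
        rows[f"S{i:02d}"] = rng.integers(0, 2, 4).tolist()
    with pytest.raises(ValueError, match="exact-search limit"):
        parsimony_tree(matrix_from_rows(rows))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _supported_matrix(chars_per_branch=20):
    rows = {
        "BLOOD": [],
        "S1": [], "S2": [], "S3": [], "S4": [],
    }
    blocks = {
        ("S1", "S2", "S3", "S4"): chars_per_branch,   # trunk
        ("S1", "S2"): chars_per_branch,
        ("S3", "S4"): chars_per_branch,
        ("S1",): chars_per_branch, ("S2",): chars_per_branch,
        ("S3",): chars_per_branch, ("S4",): chars_per_branch,
    }
    for members, count in blocks.items():
        for s in rows:
            rows[s].extend(
                [P if s in members else A] * count if s != "BLOOD" else [A] * count
            )
    return matrix_from_rows(rows)


def test_bootstrap_compatible_matrix_high_support_and_determinism():
    matrix = _supported_matrix(20)
    t1 = bootstrap_support(matrix, n_replicates=200, seed=11)
    t2 = bootstrap_support(matrix, n_replicates=200, seed=11)
    supports1 = sorted(n.support for n in t1.root.walk() if n.support is not None)
    supports2 = sorted(n.support for n in t2.root.walk() if n.support is not None)
    assert supports1 == supports2
    assert min(supports1) >= 99
    assert t1.to_newick() == t2.to_newick()


def test_bootstrap_conflicting_characters_split_support(rng):
    # two incompatible splits with equal weight plus one private character per
    # leaf: expected supports computed by exhaustively enumerating resamples
    rows = {
        "BLOOD": [A] * 6,
        "S1": [P, P, P, A, A, A],
        "S2": [P, A, A, P, A, A],
        "S3": [A, P, A, A, P, A],
        "S4": [A, A, A, A, A, P],
    }
    matrix = matrix_from_rows(rows)
    tree = parsimony_tree(matrix)
    boot = bootstrap_support(matrix, n_replicates=1000, seed=5, tree=tree)

    # oracle: enumerate multinomial resamples of the 6 columns; each replicate
    # contributes its minimal trees' clades uniformly
    samples = matrix.sample_ids
    ingroup = tuple(s for s in samples if s != "BLOOD")
    topos = list(all_rooted_topologies(ingroup))
    expected: dict[frozenset, float] = {}
    cols = [
        {s: frozenset({int(matrix.data.loc[s, vid])}) for s in samples}
        for vid in matrix.variant_ids
    ]
    m = len(cols)
    from math import comb, factorial
    from itertools import product as iproduct

    def clades_of(topo):
        out = set()

        def walk(node):
            if not isinstance(node, tuple):
                return frozenset([node])
            leaves = walk(node[0]) | walk(node[1])
            if len(leaves) >= 2:
                out.add(leaves)
            return leaves

        walk(topo)
        return out

    for counts in iproduct(*[range(m + 1)] * (m - 1)):
        if sum(counts) > m:
            continue
        counts = counts + (m - sum(counts),)
        prob = factorial(m)
        for c in counts:
            prob //= factorial(c)
        prob = prob / m ** m
        scores = [
            sum(c * naive_fitch(("BLOOD", t), col) for c, col in zip(counts, cols))
            for t in topos
        ]
        best = min(scores)
        min_trees = [t for t, s in zip(topos, scores) if s == best]
        for t in min_trees:
            for clade in clades_of(t):
                expected[clade] = expected.get(clade, 0.0) + prob / len(min_trees)

    for node in boot.root.walk():
        if node.support is None:
            continue
        clade = frozenset(node.leaf_names())
        want = 100.0 * expected.get(clade, 0.0)
        if clade == frozenset(ingroup):
            want = 100.0  # fixed by rooting on the germline
        assert node.support == pytest.approx(want, abs=5)


def test_bootstrap_requires_replicates():
    with pytest.raises(ValueError, match="n_replicates"):
        bootstrap_support(_supported_matrix(5), n_replicates=0)


# ---------------------------------------------------------------------------
# presence matrix construction
# ---------------------------------------------------------------------------

def _matrix_inputs():
    samples = {
        "T1": make_sample("T1", RegionClass.T, 0.6, (Assay.WES,)),
        "T2": make_sample("T2", RegionClass.T, 0.5, (Assay.WES,)),
        "M1": make_sample("M1", RegionClass.M, 0.07, (Assay.WES, Assay.TES1)),
        "BLOOD": make_sample("BLOOD", RegionClass.BLOOD, 0.0),
    }
    shared = make_variant("chr1:1:A>T", {
        ("T1", Assay.WES): (100, 40), ("T2", Assay.WES): (100, 35),
        ("M1", Assay.WES): (150, 0), ("M1", Assay.TES1): (4000, 90),
    })
    t_only = make_variant("chr1:2:A>T", {
        ("T1", Assay.WES): (100, 40), ("T2", Assay.WES): (100, 35),
        ("M1", Assay.WES): (150, 0), ("M1", Assay.TES1): (4000, 0),
    })
    undet = make_variant("chr1:3:A>T", {
        ("T1", Assay.WES): (100, 40), ("T2", Assay.WES): (100, 0),
        ("M1", Assay.WES): (150, 0),
    })
    return samples, [shared, t_only, undet]


def test_presence_matrix_states_from_counts_and_decisions():
    samples, variants = _matrix_inputs()
    results = [AbsenceTestResult(
        "chr1:2:A>T", "M1", Assay.TES1, 4000, 0, 0.005, 0.01,
        1e-9, 5e-8, 1, True, "ABSENT",
    )]
    matrix = build_presence_matrix(variants, samples, results)
    df = matrix.data
    assert df.loc["BLOOD"].tolist() == [A, A, A]
    assert df.loc["T1"].tolist() == [P, P, P]
    assert df.loc["T2"].tolist() == [P, P, A]
    # margin: detected by deep assay / tested absent / untested -> unknown
    assert df.loc["M1"].tolist() == [P, A, U]


def test_presence_matrix_rejects_uncovered_sample():
    samples, variants = _matrix_inputs()
    for v in variants:
        for key in [k for k in v.observations if k[0] == "M1"]:
            del v.observations[key]
    with pytest.raises(ValueError, match="zero covered"):
        build_presence_matrix(variants, samples, [])


def test_unknown_only_allowed_in_margin_rows():
    rows = {"BLOOD": [A], "S1": [U], "S2": [P]}
    with pytest.raises(ValueError, match="UNKNOWN"):
        matrix_from_rows(rows)  # S1 is a T sample here


# ---------------------------------------------------------------------------
# rootward-margin behaviour and Newick output
# ---------------------------------------------------------------------------

def test_tested_absences_pull_margin_rootward():
    # margin carries the early trunk but lacks the late trunk (tested ABSENT)
    # and has unknown status for T-private mutations
    rows = {
        "BLOOD": [A] * 12,
        "T1": [P] * 10 + [P, A],
        "T2": [P] * 10 + [A, P],
        "T3": [P] * 10 + [A, A],
        "M1": [P] * 4 + [A] * 6 + [U, U],
    }
    tree = parsimony_tree(matrix_from_rows(rows, m_samples={"M1"}))
    m_depth = tree.root_path_mutations("M1")
    t_depths = [tree.root_path_mutations(s) for s in ("T1", "T2", "T3")]
    assert m_depth < min(t_depths)


def test_newick_round_trips_through_dendropy(tmp_path):
    matrix = _supported_matrix(20)
    tree = bootstrap_support(matrix, n_replicates=100, seed=3)
    path = tmp_path / "tree.nwk"
    write_newick(tree, path)
    parsed = dendropy.Tree.get(path=str(path), schema="newick")
    assert sorted(t.label for t in parsed.taxon_namespace) == sorted(matrix.sample_ids)
    # supports serialised as integer internal labels
    internal_labels = [
        int(n.label) for n in parsed.preorder_internal_node_iter() if n.label
    ]
    assert internal_labels and all(0 <= s <= 100 for s in internal_labels)
    # branch lengths preserved
    leaf_edges = {l.taxon.label: int(l.edge.length) for l in parsed.leaf_node_iter()}
    for leaf in matrix.sample_ids:
        assert leaf_edges[leaf] == tree.find_leaf(leaf).length


def test_write_newick_requires_rooted(tmp_path):
    matrix = _supported_matrix(5)
    tree = parsimony_tree(matrix)
    tree.rooted = False
    with pytest.raises(ValueError, match="rooted"):
        write_newick(tree, tmp_path / "t.nwk")
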
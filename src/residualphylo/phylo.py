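"""Sample-level parsimony phylogenies from mutation presence/absence.

Characters are binary (mutation present/absent) with UNKNOWN treated as
missing data. Trees are rooted on the germline (BLOOD) sample, scored by
minimum-change (Fitch/Sankoff) parsimony, and searched exactly by
branch-and-bound over all rooted topologies with the germline as outgroup —
affordable because multi-region designs have few samples per patient. A
partial tree's score never decreases when more taxa are added, which gives
the bound. Branch lengths count the mutations assigned to each edge by a
minimum-change traceback with ties placed rootward; bootstrap supports are
percentages of column-resampled replicates recovering each clade of the
full-data tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .absence import AbsenceTestResult, DetectionRule
from .io_formats import Assay, RegionClass, SampleMeta, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceState",
    "PresenceMatrix",
    "TreeNode",
    "PhyloTree",
    "build_presence_matrix",
    "parsimony_tree",
    "bootstrap_support",
    "fitch_score",
]

MAX_NONBLOOD_TAXA = 12
_INF = np.float64(1e18)


class PresenceState(IntEnum):
    ABSENT = 0
    PRESENT = 1
    UNKNOWN = 2


@dataclass
class PresenceMatrix:
    """Samples x mutations matrix over {PRESENT, ABSENT, UNKNOWN}.

    ``data`` holds int8 :class:`PresenceState` codes with samples as the index
    and variant ids as columns; the BLOOD row is all ABSENT and UNKNOWN is
    allowed only in M/SVZ rows.
    """

    data: pd.DataFrame
    blood_sample: str
    region_by_sample: dict[str, RegionClass]

    def __post_init__(self) -> None:
        if self.blood_sample not in self.data.index:
            raise ValueError(f"blood sample {self.blood_sample} not in matrix")
        if (self.data.loc[self.blood_sample] != PresenceState.ABSENT).any():
            raise ValueError("BLOOD row must be all ABSENT")
        for sid in self.data.index:
            region = self.region_by_sample[sid]
            if region in (RegionClass.M, RegionClass.SVZ):
                continue
            if (self.data.loc[sid] == PresenceState.UNKNOWN).any():
                raise ValueError(f"UNKNOWN state outside M/SVZ rows (sample {sid})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_frame(self) -> pd.DataFrame:
        """Human-readable copy with state names."""
        return self.data.map(lambda v: PresenceState(v).name)


_REGION_ORDER = {RegionClass.BLOOD: 0, RegionClass.T: 1, RegionClass.SVZ: 2, RegionClass.M: 3}


def build_presence_matrix(
    variants: Sequence[VariantRecord],
    samples: Mapping[str, SampleMeta],
    absence_results: Sequence[AbsenceTestResult] = (),
    detection_rule: DetectionRule = DetectionRule(),
    tumour_assay: Assay = Assay.WES,
) -> PresenceMatrix:
    """Combine read counts and absence-test decisions into character states.

    BLOOD is all ABSENT by construction. T cells apply the detection rule to
    the whole-exome counts. M/SVZ cells are PRESENT when detected by any
    assay; otherwise they take the absence-test decision for that (variant,
    sample): ABSENT when the test rejected, UNKNOWN when it was undetermined
    or the variant was never tested.
    """
    sample_ids = sorted(
        samples, key=lambda s: (_REGION_ORDER[samples[s].region_class], s)
    )
    blood = [s for s in sample_ids if samples[s].region_class is RegionClass.BLOOD]
    if len(blood) != 1:
        raise ValueError(f"need exactly one BLOOD sample, got {len(blood)}")
    decisions = {
        (r.variant_id, r.target_sample_id): r.decision for r in absence_results
    }
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt))
    mat = np.full((len(sample_ids), len(variants)), PresenceState.ABSENT, dtype=np.int8)
    for j, v in enumerate(variants):
        for i, sid in enumerate(sample_ids):
            region = samples[sid].region_class
            if region is RegionClass.BLOOD:
                continue
            if region is RegionClass.T:
                obs = v.observation(sid, tumour_assay)
                present = obs is not None and detection_rule.is_detected(
                    obs.alt_count, obs.depth
                )
                mat[i, j] = PresenceState.PRESENT if present else PresenceState.ABSENT
                continue
            # M / SVZ
            observed = [
                o for (s, _a), o in v.observations.items() if s == sid and o.depth > 0
            ]
            if any(detection_rule.is_detected(o.alt_count, o.depth) for o in observed):
                mat[i, j] = PresenceState.PRESENT
            elif decisions.get((v.variant_id, sid)) == "ABSENT":
                mat[i, j] = PresenceState.ABSENT
            else:
                mat[i, j] = PresenceState.UNKNOWN
    df = pd.DataFrame(mat, index=sample_ids, columns=[v.variant_id for v in variants])
    for sid in sample_ids:
        if samples[sid].region_class is RegionClass.BLOOD:
            continue
        if (df.loc[sid] == PresenceState.UNKNOWN).all():
            raise ValueError(f"sample {sid} has zero covered SNVs")
    return PresenceMatrix(
        data=df,
        blood_sample=blood[0],
        region_by_sample={s: samples[s].region_class for s in sample_ids},
    )


# ---------------------------------------------------------------------------
# Tree containers
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    length: int = 0                 # mutations on the edge above this node
    support: int | None = None      # bootstrap percentage, internal nodes only
    mutations: list[tuple[str, str]] = field(default_factory=list)  # (variant_id, gain|loss)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]


@dataclass
class PhyloTree:
    """Rooted sample tree; the root edge carries the germline (BLOOD) leaf."""

    root: TreeNode
    score: int
    rooted: bool = True

    def leaves(self) -> list[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> TreeNode:
        for n in self.root.walk():
            if n.is_leaf and n.name == name:
                return n
        raise KeyError(name)

    def clades(self, include_trivial: bool = False) -> list[frozenset[str]]:
        """Leaf sets of internal nodes below the root (rooted bipartitions)."""
        out = []
        for n in self.root.walk():
            if n is self.root or n.is_leaf:
                continue
            names = frozenset(n.leaf_names())
            if include_trivial or len(names) >= 2:
                out.append(names)
        return out

    def root_path_mutations(self, leaf_name: str) -> int:
        """Mutations on the path from the root to the leaf's parent edge.

        A rootward attachment point means a small value: the leaf branched off
        early in the mutation history.
        """
        path = self._path_to(self.root, leaf_name)
        if path is None:
            raise KeyError(leaf_name)
        return sum(n.length for n in path[1:-1])  # exclude root and the leaf itself

    def _path_to(self, node: TreeNode, leaf_name: str):
        if node.is_leaf:
            return [node] if node.name == leaf_name else None
        for c in node.children:
            sub = self._path_to(c, leaf_name)
            if sub is not None:
                return [node] + sub
        return None

    def to_newick(self) -> str:
        return self._newick(self.root) + ";"

    def _newick(self, node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length}"
        inner = ",".join(self._newick(c) for c in node.children)
        label = "" if node.support is None else str(int(node.support))
        if node is self.root:
            return f"({inner}){label}"
        return f"({inner}){label}:{node.length}"


# ---------------------------------------------------------------------------
# Scoring (binary-state Sankoff, vectorised over characters)
# ---------------------------------------------------------------------------

def _leaf_cost_arrays(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-leaf cost arrays (c_absent, c_present); UNKNOWN costs 0 for both."""
    c0 = np.where(states == PresenceState.PRESENT, _INF, 0.0)
    c1 = np.where(states == PresenceState.ABSENT, _INF, 0.0)
    return c0, c1


def _subtree_cost(node, c0s, c1s):
    if isinstance(node, (int, np.integer)):
        return c0s[node], c1s[node]
    a0 = None
    for child in node:
        l0, l1 = _subtree_cost(child, c0s, c1s)
        k0 = np.minimum(l0, l1 + 1.0)
        k1 = np.minimum(l1, l0 + 1.0)
        if a0 is None:
            a0, a1 = k0, k1
        else:
            a0 = a0 + k0
            a1 = a1 + k1
    return a0, a1


def _score_with_blood(subtree, c0s, c1s, weights) -> float:
    """Parsimony score of (blood, subtree) with the germline all-ABSENT."""
    t0, t1 = _subtree_cost(subtree, c0s, c1s)
    per_char = np.minimum(t0, t1 + 1.0)
    return float(np.dot(np.minimum(per_char, _INF), weights))


def _insertions(tree, leaf):
    """All trees obtained by attaching ``leaf`` on an edge of ``tree``."""
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for sub in _insertions(left, leaf):
            yield (sub, right)
        for sub in _insertions(right, leaf):
            yield (left, sub)


def _canonical_key(node, names) -> str:
    if isinstance(node, (int, np.integer)):
        return names[node]
    parts = sorted(_canonical_key(c, names) for c in node)
    return "(" + ",".join(parts) + ")"


class _TieChooser:
    """Keeps one tree among equally parsimonious ones.

    ``canonical`` keeps the lexicographically smallest canonical form
    (deterministic); ``random`` reservoir-samples uniformly with the supplied
    RNG (used by bootstrap replicates).
    """

    def __init__(self, mode: str, names: Sequence[str], rng=None):
        self.mode = mode
        self.names = names
        self.rng = rng
        self.best_score = np.inf
        self.tree = None
        self._key = None
        self._count = 0

    def offer(self, tree, score: float) -> None:
        if score < self.best_score - 1e-9:
            self.best_score = score
            self.tree = tree
            self._count = 1
            self._key = _canonical_key(tree, self.names) if self.mode == "canonical" else None
            return
        if abs(score - self.best_score) > 1e-9:
            return
        self._count += 1
        if self.mode == "canonical":
            key = _canonical_key(tree, self.names)
            if key < self._key:
                self.tree = tree
                self._key = key
        else:
            if self.rng.random() < 1.0 / self._count:
                self.tree = tree


def _branch_and_bound(
    leaf_states: np.ndarray,
    weights: np.ndarray,
    names: Sequence[str],
    chooser: _TieChooser,
) -> tuple[float, object]:
    """Exact search over ingroup topologies rooted on the germline.

    ``leaf_states`` has one row per ingroup leaf; the germline contributes an
    implicit all-ABSENT leaf at the root.
    """
    k = leaf_states.shape[0]
    c0s, c1s = [], []
    for i in range(k):
        c0, c1 = _leaf_cost_arrays(leaf_states[i])
        c0s.append(c0)
        c1s.append(c1)
    if k == 1:
        chooser.offer(0, _score_with_blood(0, c0s, c1s, weights))
        return chooser.best_score, chooser.tree

    order = list(range(k))  # names are pre-sorted

    def recurse(tree, remaining):
        score = _score_with_blood(tree, c0s, c1s, weights)
        if score > chooser.best_score + 1e-9:
            return
        if not remaining:
            chooser.offer(tree, score)
            return
        nxt, rest = remaining[0], remaining[1:]
        for candidate in _insertions(tree, nxt):
            recurse(candidate, rest)

    recurse(order[0], order[1:])
    return chooser.best_score, chooser.tree


def _states_matrix(matrix: PresenceMatrix) -> tuple[np.ndarray, list[str], list[str]]:
    ingroup = [s for s in matrix.sample_ids if s != matrix.blood_sample]
    ingroup.sort()
    states = matrix.data.loc[ingroup].to_numpy(dtype=np.int8)
    return states, ingroup, matrix.variant_ids


def _collapse_columns(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique column patterns and their multiplicities."""
    patterns, counts = np.unique(states, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def parsimony_tree(matrix: PresenceMatrix) -> PhyloTree:
    """Minimum-change rooted tree for a presence matrix, found exactly.

    Ties between equally parsimonious topologies are broken by the
    lexicographically smallest canonical Newick form. Internal edges to which
    the traceback assigns zero mutations are collapsed, so uninformative
    resolutions do not masquerade as structure.
    """
    states, ingroup, variant_ids = _states_matrix(matrix)
    if len(ingroup) > MAX_NONBLOOD_TAXA:
        raise ValueError(
            f"{len(ingroup)} non-blood samples exceed the exact-search limit "
            f"({MAX_NONBLOOD_TAXA}); a heuristic search is out of scope"
        )
    if len(ingroup) == 0:
        raise ValueError("no non-blood samples to place on a tree")
    patterns, wts = _collapse_columns(states)
    chooser = _TieChooser("canonical", ingroup)
    score, nested = _branch_and_bound(patterns, wts, ingroup, chooser)
    root = _materialise(nested, ingroup, matrix.blood_sample)
    _assign_mutations(root, states, variant_ids, ingroup)
    _collapse_zero_internal_edges(root)
    return PhyloTree(root=root, score=int(round(score)))


def _materialise(nested, names: Sequence[str], blood: str) -> TreeNode:
    def build(node) -> TreeNode:
        if isinstance(node, (int, np.integer)):
            return TreeNode(name=names[node])
        return TreeNode(children=[build(c) for c in node])

    return TreeNode(children=[TreeNode(name=blood), build(nested)])


def _assign_mutations(
    root: TreeNode,
    states: np.ndarray,
    variant_ids: Sequence[str],
    ingroup: Sequence[str],
) -> None:
    """Minimum-change state assignment with gains placed rootward on ties.

    The root is the germline and is ABSENT for every character. Each edge
    receives the characters whose state changes along it; branch length is the
    number of such mutations (gains and losses).
    """
    index = {name: i for i, name in enumerate(ingroup)}
    n_chars = states.shape[1]

    costs: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def down(node: TreeNode) -> tuple[np.ndarray, np.ndarray]:
        if node.is_leaf:
            if node.name in index:
                c = _leaf_cost_arrays(states[index[node.name]])
            else:  # germline leaf: all ABSENT
                c = (np.zeros(n_chars), np.full(n_chars, _INF))
            costs[id(node)] = c
            return c
        a0 = np.zeros(n_chars)
        a1 = np.zeros(n_chars)
        for child in node.children:
            l0, l1 = down(child)
            a0 += np.minimum(l0, l1 + 1.0)
            a1 += np.minimum(l1, l0 + 1.0)
        costs[id(node)] = (a0, a1)
        return a0, a1

    down(root)

    def up(node: TreeNode, parent_state: np.ndarray) -> None:
        node.mutations = []
        if node.is_leaf and node.name not in index:
            node.length = 0
            return
        c0, c1 = costs[id(node)]
        stay = np.where(parent_state == 0, c0, c1)
        move = np.where(parent_state == 0, c1, c0) + 1.0
        # ties go to the changed state: mutations as close to the root as possible
        state = np.where(move <= stay, 1 - parent_state, parent_state)
        changed = np.nonzero(state != parent_state)[0]
        node.mutations = [
            (variant_ids[j], "gain" if state[j] == 1 else "loss") for j in changed
        ]
        node.length = len(changed)
        for child in node.children:
            up(child, state)

    germline_state = np.zeros(n_chars, dtype=np.int8)
    for child in root.children:
        up(child, germline_state)


def _collapse_zero_internal_edges(root: TreeNode) -> None:
    def collapse(node: TreeNode) -> None:
        new_children: list[TreeNode] = []
        for child in node.children:
            collapse(child)
            if not child.is_leaf and child.length == 0:
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    collapse(root)


def fitch_score(tree: PhyloTree | TreeNode, matrix: PresenceMatrix) -> int:
    """Parsimony score of a given (possibly multifurcating) tree.

    Exact for binary characters at any node arity via the two-state
    minimum-change recursion; UNKNOWN cells are missing data.
    """
    root = tree.root if isinstance(tree, PhyloTree) else tree
    leaves = sorted(root.leaf_names())
    rows = sorted(matrix.sample_ids)
    if leaves != rows:
        raise ValueError(
            f"tree leaves {leaves} do not match matrix samples {rows}"
        )
    data = matrix.data
    n_chars = data.shape[1]

    def down(node: TreeNode) -> tuple[np.ndarray, np.ndarray]:
        if node.is_leaf:
            return _leaf_cost_arrays(data.loc[node.name].to_numpy(dtype=np.int8))
        a0 = np.zeros(n_chars)
        a1 = np.zeros(n_chars)
        for child in node.children:
            l0, l1 = down(child)
            a0 += np.minimum(l0, l1 + 1.0)
            a1 += np.minimum(l1, l0 + 1.0)
        return a0, a1

    c0, c1 = down(root)
    return int(np.minimum(c0, c1).sum())


def bootstrap_support(
    matrix: PresenceMatrix,
    n_replicates: int = 1000,
    seed: int | None = None,
    tree: PhyloTree | None = None,
) -> PhyloTree:
    """Column-resampling bootstrap supports on the full-data parsimony tree.

    Each replicate resamples the matrix columns with replacement and rebuilds
    an exact parsimony tree; a clade's support is the percentage of replicates
    whose tree contains it. Replicate-level ties between equally parsimonious
    trees are resolved uniformly at random from the seeded generator, so the
    whole procedure is reproducible bit-for-bit given ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if tree is None:
        tree = parsimony_tree(matrix)
    states, ingroup, _ = _states_matrix(matrix)
    patterns, counts = _collapse_columns(states)
    m = int(counts.sum())
    probs = counts / m
    rng = np.random.default_rng(seed)

    clade_counts: dict[frozenset[str], int] = {c: 0 for c in tree.clades()}
    ingroup_set = frozenset(ingroup)
    for _ in range(n_replicates):
        weights = rng.multinomial(m, probs).astype(float)
        chooser = _TieChooser("random", ingroup, rng=rng)
        _, nested = _branch_and_bound(patterns, weights, ingroup, chooser)
        rep_clades = _nested_clades(nested, ingroup)
        rep_clades.add(ingroup_set)  # rooting on the germline is fixed
        for clade in clade_counts:
            if clade in rep_clades:
                clade_counts[clade] += 1

    out = _copy_tree(tree)
    for node in out.root.walk():
        if node is out.root or node.is_leaf:
            continue
        names = frozenset(node.leaf_names())
        if len(names) >= 2:
            node.support = int(round(100.0 * clade_counts.get(names, 0) / n_replicates))
    return out


def _nested_clades(nested, names: Sequence[str]) -> set[frozenset[str]]:
    clades: set[frozenset[str]] = set()

    def walk(node) -> frozenset[str]:
        if isinstance(node, (int, np.integer)):
            return frozenset([names[node]])
        leaves = frozenset().union(*(walk(c) for c in node))
        if len(leaves) >= 2:
            clades.add(leaves)
        return leaves

    walk(nested)
    return clades


def _copy_tree(tree: PhyloTree) -> PhyloTree:
    def copy_node(n: TreeNode) -> TreeNode:
        return TreeNode(
            name=n.name,
            children=[copy_node(c) for c in n.children],
            length=n.length,
            support=n.support,
            mutations=list(n.mutations),
        )

    return PhyloTree(root=copy_node(tree.root), score=tree.score, rooted=tree.rooted)
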
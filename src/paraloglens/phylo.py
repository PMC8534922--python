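"""Minimum-evolution phylogenetics on protein alignments.

The tree engine behind the paralog-family comparisons: evolutionary
distances with pairwise deletion, neighbor joining as a starting topology,
a balanced minimum-evolution (BME) criterion evaluated with Pauplin's
weighting ``L = sum_{i<j} d_ij * 2^(-p_ij)`` (``p_ij`` = number of edges
between leaves i and j), nearest-neighbor-interchange hill climbing on that
criterion, ordinary-least-squares branch lengths, outgroup rooting and
Robinson-Foulds topology comparison.

All branch lengths are in expected substitutions per site; a length of 0.01
corresponds to 1 substitution per 100 residues.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

import dendropy
import numpy as np

from .records import GAP, UNKNOWN, Alignment


class Correction(enum.Enum):
    """Distance correction applied to the raw proportion of differing sites."""

    P = "p"            # uncorrected p-distance (fraction of mismatches)
    POISSON = "poisson"  # d = -ln(1 - p), Poisson-corrected substitutions/site


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

class Node:
    """One tree node; ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]


class PhyloTree:
    """Rooted or unrooted tree with branch lengths in substitutions/site.

    Unrooted trees are stored with a trifurcation at the top-level node; the
    ``rooted`` flag records the intended semantics.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = [leaf.name for leaf in root.leaves()]
        if None in names or len(set(names)) != len(names):
            raise ValueError("leaves must carry unique non-empty labels")

    # -- basic queries ------------------------------------------------------

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"no leaf named {name!r}")

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            for ch in node.children:
                new.add(clone(ch))
            return new

        return PhyloTree(clone(self.root), rooted=self.rooted)

    # -- bipartitions -------------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side leaf-name set
        canonicalized against the full leaf set."""
        all_leaves = frozenset(self.leaf_names())
        n = len(all_leaves)
        parts: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            clade = frozenset(leaf.name for leaf in node.leaves())
            if 2 <= len(clade) <= n - 2:
                other = all_leaves - clade
                parts.add(min(clade, other, key=lambda s: (len(s), sorted(s))))
        return parts

    # -- Newick -------------------------------------------------------------

    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: Node, top: bool = False) -> str:
            if node.is_leaf:
                core = node.name
            else:
                inner = ",".join(fmt(ch) for ch in node.children)
                core = f"({inner})" + (node.name or "")
            if top:
                return core
            return f"{core}:{node.length:.{decimals}f}"

        return fmt(self.root, top=True) + ";"

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               suppress_internal_node_taxa=True,
                               preserve_underscores=True)

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label, dnode.edge.length or 0.0)
            for ch in dnode.child_nodes():
                node.add(convert(ch))
            return node

        root = convert(dt.seed_node)
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted=rooted)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances over an ordered taxon list."""

    taxa: list[str]
    d: np.ndarray
    units: Correction = Correction.P

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.taxa)

    def to_phylip(self) -> str:
        lines = [f" {len(self.taxa)}"]
        for name, row in zip(self.taxa, self.d):
            lines.append(name + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def distance_matrix(aln: Alignment, correction: Correction = Correction.POISSON) -> DistanceMatrix:
    """Pairwise evolutionary distances with pairwise deletion of gaps/'X'.

    Pairwise deletion keeps taxa comparable even when one family lacks an
    entire domain (an aligned deletion block would otherwise wipe out the
    comparable columns under complete deletion).
    """
    if len(aln) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    ids = aln.ids
    rows = np.array([list(aln.row(sid)) for sid in ids])
    valid = (rows != GAP) & (rows != UNKNOWN)
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        both = valid[i] & valid[j]
        compared = int(both.sum())
        if compared == 0:
            raise ValueError(
                f"no comparable columns between {ids[i]!r} and {ids[j]!r}"
            )
        p = float((rows[i][both] != rows[j][both]).sum()) / compared
        if correction is Correction.POISSON:
            if p >= 1.0:
                raise ValueError(
                    f"saturated pair {ids[i]!r} vs {ids[j]!r}: p = {p}"
                )
            dist = -math.log(1.0 - p)
        else:
            dist = p
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa=list(ids), d=d, units=correction)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with the Studier-Keppler Q criterion.

    Returns an unrooted tree (trifurcation at the top).  Ties in Q are
    broken by the lowest index pair; negative branch-length estimates are
    clamped to zero.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[Node] = [Node(t) for t in dm.taxa]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie break: argmin of flattened row-major array
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = Node()
        nodes[i].length = max(0.0, li)
        nodes[j].length = max(0.0, lj)
        parent.add(nodes[i])
        parent.add(nodes[j])
        # new distances to remaining taxa
        new_row = np.zeros(d.shape[0] + 1)
        for ak in active:
            if ak in (i, j):
                continue
            new_row[ak] = 0.5 * (d[i, ak] + d[j, ak] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    root = Node()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(0.0, ln)
        root.add(nodes[idx])
    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# Balanced minimum evolution
# ---------------------------------------------------------------------------

def _topological_leaf_paths(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Edge-count path lengths between all leaf pairs (tree as undirected graph)."""
    nodes = list(tree.root.walk())
    index = {id(n): i for i, n in enumerate(nodes)}
    adj: list[list[int]] = [[] for _ in nodes]
    for node in nodes:
        for ch in node.children:
            adj[index[id(node)]].append(index[id(ch)])
            adj[index[id(ch)]].append(index[id(node)])
    leaf_idx = [index[id(n)] for n in nodes if n.is_leaf]
    leaf_names = [nodes[i].name for i in leaf_idx]
    paths = np.zeros((len(leaf_idx), len(leaf_idx)), dtype=int)
    for a, start in enumerate(leaf_idx):
        dist = np.full(len(nodes), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        while queue:
            cur = queue.pop()
            for nb in adj[cur]:
                if dist[nb] < 0:
                    dist[nb] = dist[cur] + 1
                    queue.append(nb)
        for b, other in enumerate(leaf_idx):
            paths[a, b] = dist[other]
    return leaf_names, paths


def bme_tree_length(tree: PhyloTree, dm: DistanceMatrix) -> float:
    """Balanced minimum-evolution tree length via Pauplin's weights."""
    names, paths = _topological_leaf_paths(tree)
    if set(names) != set(dm.taxa):
        raise ValueError("tree leaves do not match distance-matrix taxa")
    order = [dm.taxa.index(nm) for nm in names]
    d = dm.d[np.ix_(order, order)]
    k = len(names)
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            total += d[i, j] * 2.0 ** (-paths[i, j])
    return total


def _internal_edges(tree: PhyloTree) -> list[Node]:
    """Internal edges, each identified by its child node (a non-leaf non-root)."""
    return [
        n for n in tree.root.walk()
        if n is not tree.root and not n.is_leaf
    ]


def _swap_subtrees(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _nni_neighbors(tree: PhyloTree) -> Iterator[PhyloTree]:
    """The two NNI rearrangements across every internal edge, as copies."""
    edges = _internal_edges(tree)
    for e_idx in range(len(edges)):
        for side in (0, 1):
            cand = tree.copy()
            child = _internal_edges(cand)[e_idx]
            parent = child.parent
            # one concrete subtree on the parent side of the edge
            other = next(ch for ch in parent.children if ch is not child)
            _swap_subtrees(child.children[side], other)
            yield cand


def me_tree(dm: DistanceMatrix, max_sweeps: int = 200) -> PhyloTree:
    """Minimum-evolution tree: NJ start, NNI hill climb on the BME length.

    Taxa are canonicalized to lexicographic order first so the result does
    not depend on input order.  Each sweep evaluates every NNI neighbor and
    accepts the best strictly-improving one; OLS branch lengths are fitted on
    the final topology (negative estimates clamped to zero).
    """
    order = sorted(range(len(dm)), key=lambda i: dm.taxa[i])
    dm = DistanceMatrix(
        taxa=[dm.taxa[i] for i in order],
        d=dm.d[np.ix_(order, order)],
        units=dm.units,
    )
    tree = nj_tree(dm)
    if len(dm) <= 3:
        return tree
    best_len = bme_tree_length(tree, dm)
    for _ in range(max_sweeps):
        best_cand, best_cand_len = None, best_len
        for cand in _nni_neighbors(tree):
            cl = bme_tree_length(cand, dm)
            if cl < best_cand_len - 1e-12:
                best_cand, best_cand_len = cand, cl
        if best_cand is None:
            break
        tree, best_len = best_cand, best_cand_len
    else:
        warnings.warn("NNI search hit the sweep limit; returning best so far",
                      stacklevel=2)
    fit_branch_lengths_ols(tree, dm)
    return tree


def fit_branch_lengths_ols(tree: PhyloTree, dm: DistanceMatrix) -> None:
    """Ordinary-least-squares branch lengths on a fixed topology, in place.

    Solves ``min || A x - d ||`` where A indicates which edges lie on each
    leaf-pair path; negative estimates are clamped to zero.
    """
    nodes = list(tree.root.walk())
    edges = [n for n in nodes if n is not tree.root]
    edge_idx = {id(n): i for i, n in enumerate(edges)}
    leaves = tree.leaves()
    name_to_leaf = {lf.name: lf for lf in leaves}
    if set(name_to_leaf) != set(dm.taxa):
        raise ValueError("tree leaves do not match distance-matrix taxa")

    def path_edges(a: Node, b: Node) -> list[int]:
        anc_a = []
        cur = a
        while cur is not None:
            anc_a.append(cur)
            cur = cur.parent
        aset = {id(n): k for k, n in enumerate(anc_a)}
        cur = b
        path_b = []
        while id(cur) not in aset:
            path_b.append(cur)
            cur = cur.parent
        lca_pos = aset[id(cur)]
        return [edge_idx[id(n)] for n in anc_a[:lca_pos]] + [
            edge_idx[id(n)] for n in path_b
        ]

    pairs = list(combinations(dm.taxa, 2))
    A = np.zeros((len(pairs), len(edges)))
    b = np.zeros(len(pairs))
    for row, (ta, tb) in enumerate(pairs):
        for e in path_edges(name_to_leaf[ta], name_to_leaf[tb]):
            A[row, e] = 1.0
        b[row] = dm.d[dm.taxa.index(ta), dm.taxa.index(tb)]
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    for node, length in zip(edges, x):
        node.length = max(0.0, float(length))


# ---------------------------------------------------------------------------
# Rooting
# ---------------------------------------------------------------------------

def root_tree(tree: PhyloTree, outgroup: set[str]) -> PhyloTree:
    """Root on the edge separating the outgroup clade from everything else.

    The chosen edge's length is split equally between the two root children.
    Raises if the outgroup is not monophyletic in the unrooted tree.
    """
    outgroup = set(outgroup)
    names = set(tree.leaf_names())
    missing = outgroup - names
    if missing:
        raise ValueError(f"outgroup taxa not in tree: {sorted(missing)}")
    if not outgroup or outgroup == names:
        raise ValueError("outgroup must be a proper non-empty subset of leaves")
    work = tree.copy()
    target = None
    for node in work.root.walk():
        if node is work.root:
            continue
        clade = {leaf.name for leaf in node.leaves()}
        if clade == outgroup or clade == names - outgroup:
            target = node
            break
    if target is None:
        best = _closest_clade(work, outgroup)
        raise ValueError(
            f"outgroup {sorted(outgroup)} is not monophyletic; "
            f"closest clade found: {sorted(best)}"
        )
    edge_len = target.length
    p = target.parent
    p.children.remove(target)
    target.parent = None
    _make_top(p)
    rest: Node = p
    if len(rest.children) == 1:  # degree-2 top left by a rooted input
        only = rest.children[0]
        only.parent = None
        rest = only
        rest.length += 0.0
    new_root = Node()
    target.length = edge_len / 2.0
    rest.length = edge_len / 2.0
    # put the outgroup side first for readability
    out_side, in_side = (target, rest) if (
        {leaf.name for leaf in target.leaves()} == outgroup
    ) else (rest, target)
    new_root.add(out_side)
    new_root.add(in_side)
    return PhyloTree(new_root, rooted=True)


def _closest_clade(tree: PhyloTree, outgroup: set[str]) -> set[str]:
    best, best_score = set(), -1.0
    for node in tree.root.walk():
        clade = {leaf.name for leaf in node.leaves()}
        inter = len(clade & outgroup)
        union = len(clade | outgroup)
        score = inter / union if union else 0.0
        if score > best_score:
            best, best_score = clade, score
    return best


def _make_top(node: Node) -> None:
    """Reverse parent links so ``node`` becomes the parentless top of its tree."""
    chain: list[Node] = []
    cur: Node | None = node
    while cur is not None:
        chain.append(cur)
        cur = cur.parent
    lengths = [n.length for n in chain]
    for lower, upper in zip(chain, chain[1:]):
        upper.children.remove(lower)
    for i in range(len(chain) - 1):
        lower, upper = chain[i], chain[i + 1]
        lower.add(upper)
        upper.length = lengths[i]
    node.parent = None
    node.length = 0.0
    for n in chain[1:]:
        _splice_if_unary(n)


def _splice_if_unary(node: Node) -> None:
    """Remove a degree-2 passthrough node created by rerooting."""
    if node.parent is not None and len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        parent = node.parent
        parent.children[parent.children.index(node)] = child
        child.parent = parent
        node.children = []
        node.parent = None


def unroot(tree: PhyloTree) -> PhyloTree:
    """Collapse the root bifurcation into a trifurcation."""
    work = tree.copy()
    root = work.root
    if len(root.children) != 2:
        return PhyloTree(work.root, rooted=False)
    a, b = root.children
    keep, merge = (a, b) if not a.is_leaf else (b, a)
    if keep.is_leaf:
        raise ValueError("cannot unroot a 2-leaf tree")
    root.children = []
    merge.length += keep.length
    new_root = Node()
    for ch in keep.children:
        new_root.add(ch)
        ch.length = ch.length
    new_root.add(merge)
    return PhyloTree(new_root, rooted=False)


# ---------------------------------------------------------------------------
# Topology comparison and utilities
# ---------------------------------------------------------------------------

def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric-difference count of non-trivial bipartitions."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees have different leaf sets")
    u1 = unroot(t1) if t1.rooted else t1
    u2 = unroot(t2) if t2.rooted else t2
    return len(u1.bipartitions() ^ u2.bipartitions())


def root_to_tip_lengths(tree: PhyloTree) -> dict[str, float]:
    """Path length (substitutions/site) from the root to every leaf."""
    out: dict[str, float] = {}

    def descend(node: Node, acc: float) -> None:
        if node.is_leaf:
            out[node.name] = acc
        for ch in node.children:
            descend(ch, acc + ch.length)

    descend(tree.root, 0.0)
    return out


def mrca(tree: PhyloTree, leaf_names: set[str]) -> Node:
    """Most recent common ancestor of the named leaves (rooted tree)."""
    target = set(leaf_names)
    best = None
    for node in tree.root.walk():
        clade = {leaf.name for leaf in node.leaves()}
        if target <= clade:
            if best is None or len(clade) < len({l.name for l in best.leaves()}):
                best = node
    if best is None:
        raise ValueError(f"leaves {sorted(target)} not all present")
    return best


def all_topologies(taxa: list[str]) -> Iterator[PhyloTree]:
    """Every unrooted binary topology over the taxa ((2n-5)!! of them).

    Built by sequential leaf insertion into every edge; used as the
    exhaustive enumeration oracle for minimum-evolution search.
    """
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def build(current: PhyloTree, remaining: list[str]) -> Iterator[PhyloTree]:
        if not remaining:
            yield current
            return
        nxt, rest = remaining[0], remaining[1:]
        edges = [n for n in current.root.walk() if n is not current.root]
        for k in range(len(edges)):
            cand = current.copy()
            edge_child = [n for n in cand.root.walk() if n is not cand.root][k]
            parent = edge_child.parent
            idx = parent.children.index(edge_child)
            mid = Node()
            parent.children[idx] = mid
            mid.parent = parent
            mid.add(edge_child)
            mid.add(Node(nxt))
            yield from build(cand, rest)

    root = Node()
    for t in taxa[:3]:
        root.add(Node(t))
    yield from build(PhyloTree(root, rooted=False), list(taxa[3:]))
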
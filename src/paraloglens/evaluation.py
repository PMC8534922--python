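"""Desk-scale benchmark routines with known ground truth.

Each function here measures one property of the pipeline against an
independent oracle (exhaustive enumeration, closed form, or simulator
truth) at problem sizes that run in seconds to a couple of minutes on one
CPU.  They are shared by the test suite and the reproduction script so
both report identical quantities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from . import phylo
from .ancestral import SubstitutionModel, marginal_posteriors
from .conservation import conservation_profile
from .motifs import call_motifs
from .phylo import (
    Correction,
    DistanceMatrix,
    PhyloTree,
    all_topologies,
    bme_tree_length,
    distance_matrix,
    me_tree,
    mrca,
    robinson_foulds,
    root_tree,
)
from .records import AMINO_ACIDS, Alignment
from .synthetic import SimulationConfig, simulate


# ---------------------------------------------------------------------------
# Random additive matrices and exhaustive balanced-ME search
# ---------------------------------------------------------------------------

def random_additive_matrix(
    n_taxa: int, rng: np.random.Generator
) -> tuple[DistanceMatrix, PhyloTree]:
    """A random binary unrooted tree plus its exact leaf-path distances."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    # build by random sequential insertion
    root = phylo.Node()
    for t in taxa[:3]:
        root.add(phylo.Node(t))
    tree = PhyloTree(root, rooted=False)
    for t in taxa[3:]:
        edges = [n for n in tree.root.walk() if n is not tree.root]
        target = edges[int(rng.integers(len(edges)))]
        parent = target.parent
        idx = parent.children.index(target)
        mid = phylo.Node()
        parent.children[idx] = mid
        mid.parent = parent
        mid.add(target)
        mid.add(phylo.Node(t))
    for node in tree.root.walk():
        if node is not tree.root:
            node.length = float(rng.uniform(0.05, 0.5))
    # exact additive distances
    d = np.zeros((n_taxa, n_taxa))
    leaves = {lf.name: lf for lf in tree.leaves()}

    def depth_to(node, anc_set):
        total = 0.0
        while id(node) not in anc_set:
            total += node.length
            node = node.parent
        return total, node

    for i, j in itertools.combinations(range(n_taxa), 2):
        a, b = leaves[taxa[i]], leaves[taxa[j]]
        anc = {}
        cur, acc = a, 0.0
        while cur is not None:
            anc[id(cur)] = acc
            acc += cur.length
            cur = cur.parent
        cur, acc = b, 0.0
        while id(cur) not in anc:
            acc += cur.length
            cur = cur.parent
        d[i, j] = d[j, i] = acc + anc[id(cur)]
    return DistanceMatrix(taxa=taxa, d=d), tree


def exhaustive_bme_optimum(dm: DistanceMatrix) -> tuple[PhyloTree, float]:
    """Minimum balanced-ME length over every unrooted binary topology."""
    best_tree, best_len = None, math.inf
    for cand in all_topologies(dm.taxa):
        length = bme_tree_length(cand, dm)
        if length < best_len:
            best_tree, best_len = cand, length
    return best_tree, best_len


@dataclass
class BmeBenchmark:
    n_matrices: int
    n_optimal: int
    max_length_gap: float

    @property
    def optimal_pct(self) -> float:
        return 100.0 * self.n_optimal / self.n_matrices


def bme_vs_exhaustive(n_matrices: int = 100, seed: int = 0) -> BmeBenchmark:
    """Hill-climbing minimum-evolution search vs exhaustive enumeration on
    random additive 5- and 6-taxon matrices."""
    rng = np.random.default_rng(seed)
    n_opt = 0
    max_gap = 0.0
    for k in range(n_matrices):
        n_taxa = 5 if k % 2 == 0 else 6
        dm, _ = random_additive_matrix(n_taxa, rng)
        found = me_tree(dm)
        _, best_len = exhaustive_bme_optimum(dm)
        found_len = bme_tree_length(found, dm)
        gap = abs(found_len - best_len)
        max_gap = max(max_gap, gap)
        if gap <= 1e-9:
            n_opt += 1
    return BmeBenchmark(n_matrices=n_matrices, n_optimal=n_opt, max_length_gap=max_gap)


# ---------------------------------------------------------------------------
# Topology recovery from simulated alignments
# ---------------------------------------------------------------------------

def single_family_config(seed: int, seq_length: int = 2000) -> SimulationConfig:
    """One family, homogeneous site rates: the topology-recovery condition."""
    return SimulationConfig(
        duplication_node=None,
        site_classes=[],
        motif_blocks=[],
        iso1_deletion=None,
        seq_length=seq_length,
        seed=seed,
    )


def tree_recovery_rate(n_seeds: int = 40, seed: int = 0) -> float:
    """Fraction of simulated datasets whose minimum-evolution tree matches
    the true topology (Robinson-Foulds distance 0)."""
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_seeds)
    hits = 0
    for s in base:
        records, aln, truth = simulate(single_family_config(int(s)))
        dm = distance_matrix(aln, Correction.POISSON)
        est = me_tree(dm)
        if robinson_foulds(est, truth.gene_tree) == 0:
            hits += 1
    return hits / n_seeds


# ---------------------------------------------------------------------------
# Ancestral reconstruction vs brute-force enumeration
# ---------------------------------------------------------------------------

def brute_force_column(
    tree: PhyloTree, column: dict[str, str], model: SubstitutionModel
) -> tuple[float, dict[frozenset, np.ndarray]]:
    """Exhaustive sum over all internal-state assignments for one column.

    Returns (log-likelihood, posteriors keyed by the clade leaf-set of each
    internal node) so results can be matched across re-rootings.
    """
    internals = [n for n in tree.root.walk() if not n.is_leaf]
    k = len(internals)
    idx_of = {id(n): i for i, n in enumerate(internals)}
    grids = np.indices((20,) * k)
    like = model.pi[grids[idx_of[id(tree.root)]]].astype(float)
    for node in tree.root.walk():
        for ch in node.children:
            P = model.transition_matrix(ch.length)
            if ch.is_leaf:
                res = column[ch.name]
                if res in AMINO_ACIDS:
                    like = like * P[grids[idx_of[id(node)]], AMINO_ACIDS.index(res)]
                # missing data contributes a factor of 1
            else:
                like = like * P[grids[idx_of[id(node)]], grids[idx_of[id(ch)]]]
    total = like.sum()
    posteriors: dict[frozenset, np.ndarray] = {}
    for node in internals:
        axis = tuple(a for a in range(k) if a != idx_of[id(node)])
        marg = like.sum(axis=axis)
        posteriors[frozenset(lf.name for lf in node.leaves())] = marg / total
    return float(np.log(total)), posteriors


@dataclass
class AncestralBenchmark:
    max_posterior_dev: float
    max_loglik_dev: float
    rerooting_loglik_spread: float


def ancestral_vs_brute_force(seed: int = 0) -> AncestralBenchmark:
    """Marginal posteriors and site likelihoods vs exhaustive enumeration,
    across every rooting of 4- and 5-leaf trees."""
    rng = np.random.default_rng(seed)
    model = SubstitutionModel.uniform()
    newicks = [
        "((A:0.12,B:0.30):0.08,(C:0.25,D:0.10):0.15);",
        "(((A:0.10,B:0.20):0.05,C:0.30):0.10,(D:0.15,E:0.25):0.08);",
    ]
    max_post = 0.0
    max_ll = 0.0
    max_spread = 0.0
    for nwk in newicks:
        base = PhyloTree.from_newick(nwk, rooted=True)
        leaves = base.leaf_names()
        n_sites = 4
        cols = [
            "".join(AMINO_ACIDS[int(rng.integers(20))] for _ in leaves)
            for _ in range(n_sites)
        ]
        aln = Alignment(leaves, ["".join(c[i] for c in cols) for i in range(len(leaves))])
        unrooted = phylo.unroot(base)
        # one rooting per edge
        rooting_lls: list[float] = []
        for edge_child in [n for n in unrooted.root.walk() if n is not unrooted.root]:
            clade = {lf.name for lf in edge_child.leaves()}
            if clade == set(leaves):
                continue
            rooted = root_tree(unrooted, clade)
            recon = marginal_posteriors(rooted, aln, model)
            rooting_lls.append(recon.total_log_likelihood)
            # brute force per site on this rooting
            for site in range(n_sites):
                column = {name: aln.row(name)[site] for name in leaves}
                ll, post = brute_force_column(rooted, column, model)
                max_ll = max(max_ll, abs(ll - recon.site_log_likelihoods[site]))
                # match posteriors to brute force by clade leaf-set
                named = _clades_by_name(rooted)
                for node_name, clade_set in named.items():
                    dev = np.abs(
                        recon.posteriors[node_name][site] - post[clade_set]
                    ).max()
                    max_post = max(max_post, dev)
        max_spread = max(max_spread, max(rooting_lls) - min(rooting_lls))
    return AncestralBenchmark(
        max_posterior_dev=max_post,
        max_loglik_dev=max_ll,
        rerooting_loglik_spread=max_spread,
    )


def _clades_by_name(rooted: PhyloTree) -> dict[str, frozenset]:
    from .ancestral import label_internal_nodes

    labeled = label_internal_nodes(rooted)
    return {
        n.name: frozenset(lf.name for lf in n.leaves())
        for n in labeled.root.walk()
        if not n.is_leaf
    }


# ---------------------------------------------------------------------------
# Planted-motif recovery
# ---------------------------------------------------------------------------

@dataclass
class MotifBenchmark:
    n_seeds: int
    n_recovered: int
    n_clean: int

    @property
    def recovery_pct(self) -> float:
        return 100.0 * self.n_recovered / self.n_seeds

    @property
    def clean_pct(self) -> float:
        return 100.0 * self.n_clean / self.n_seeds


def motif_recovery(n_seeds: int = 50, seed: int = 0) -> MotifBenchmark:
    """Planted-motif recovery at default thresholds over simulator seeds.

    A seed counts as recovered when every planted block is called with both
    ends within one residue on each reference; as clean when no call lies
    outside the planted columns.
    """
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_seeds)
    n_recovered = 0
    n_clean = 0
    for s in base:
        config = SimulationConfig(seed=int(s))
        records, aln, truth = simulate(config)
        profile = conservation_profile(
            aln, truth.isoform_map, ref1="human_ISO1", ref2="human_ISO2"
        )
        calls = call_motifs(profile)
        ok = True
        for m in truth.motifs:
            got1 = any(
                c.isoform.value == "ISO1"
                and abs(c.ref_start - m.iso1_start) <= 1
                and abs(c.ref_end - m.iso1_end) <= 1
                for c in calls
            )
            got2 = any(
                c.isoform.value == "ISO2"
                and abs(c.ref_start - m.iso2_start) <= 1
                and abs(c.ref_end - m.iso2_end) <= 1
                for c in calls
            )
            ok = ok and got1 and got2
        if ok:
            n_recovered += 1
        true_cols = [(m.col_start, m.col_end) for m in truth.motifs]
        spurious = any(
            not any(lo <= c.columns[1] and c.columns[0] <= hi for lo, hi in true_cols)
            for c in calls
        )
        if not spurious:
            n_clean += 1
    return MotifBenchmark(n_seeds=n_seeds, n_recovered=n_recovered, n_clean=n_clean)


# ---------------------------------------------------------------------------
# Rate-multiplier recovery
# ---------------------------------------------------------------------------

def rate_ratio_config(seed: int, rate_multiplier: float = 2.0) -> SimulationConfig:
    """Duplication with a faster young clade, homogeneous site rates: the
    condition isolating the clade rate multiplier."""
    return SimulationConfig(
        duplication_node="chordates",
        rate_multiplier=rate_multiplier,
        site_classes=[],
        motif_blocks=[],
        iso1_deletion=None,
        seq_length=1500,
        seed=seed,
    )


def estimate_rate_ratio(n_seeds: int = 20, seed: int = 0,
                        rate_multiplier: float = 2.0) -> float:
    """Mean estimated ISO1/ISO2 root-to-tip ratio from reconstructed trees."""
    base = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_seeds)
    ratios = []
    for s in base:
        records, aln, truth = simulate(rate_ratio_config(int(s), rate_multiplier))
        dm = distance_matrix(aln, Correction.POISSON)
        est = me_tree(dm)
        iso1 = {r.id for r in records if r.isoform.value == "ISO1"}
        clade_species = {r.id.rsplit("_", 1)[0] for r in records if r.id in iso1}
        iso2_clade = {f"{sp}_ISO2" for sp in clade_species}
        outgroup = set(aln.ids) - iso1 - iso2_clade
        rooted = root_tree(est, outgroup)
        ratios.append(_clade_depth(rooted, iso1) / _clade_depth(rooted, iso2_clade))
    return float(np.mean(ratios))


def _clade_depth(rooted: PhyloTree, leaf_set: set[str]) -> float:
    """Mean path length from the MRCA of ``leaf_set`` down to its leaves."""
    node = mrca(rooted, leaf_set)
    depths: list[float] = []

    def descend(n, acc):
        if n.is_leaf:
            depths.append(acc)
        for ch in n.children:
            descend(ch, acc + ch.length)

    descend(node, 0.0)
    return float(np.mean(depths))
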
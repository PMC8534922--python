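"""Marginal maximum-likelihood ancestral sequence reconstruction.

Works on a fixed rooted tree with branch lengths in substitutions per site,
under the equal-input (F81-type) amino-acid model: with stationary
frequencies pi and normalization ``beta = 1 / (1 - sum_a pi_a^2)`` the
transition probabilities are closed-form,

    P_ij(t) = exp(-beta*t) * delta_ij + (1 - exp(-beta*t)) * pi_j ,

so one expected substitution per site happens per unit branch length at
stationarity.  Site likelihoods come from the pruning (sum-product) pass
over the tree; per-node marginal posteriors from the complementary
top-down pass.  Gaps and unknown residues are treated as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import AA_INDEX, AMINO_ACIDS, GAP, UNKNOWN, Alignment
from .phylo import Node, PhyloTree

_N_STATES = 20


class SubstitutionModel:
    """Equal-input amino-acid substitution model with closed-form P(t)."""

    def __init__(self, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (_N_STATES,):
            raise ValueError(f"pi must have {_N_STATES} entries")
        if np.any(pi <= 0) or not np.isclose(pi.sum(), 1.0):
            raise ValueError("pi must be strictly positive and sum to 1")
        self.pi = pi / pi.sum()
        self.beta = 1.0 / (1.0 - float(np.sum(self.pi**2)))

    @classmethod
    def uniform(cls) -> "SubstitutionModel":
        return cls(np.full(_N_STATES, 1.0 / _N_STATES))

    @classmethod
    def empirical(cls, aln: Alignment, pseudocount: float = 1.0) -> "SubstitutionModel":
        counts = np.full(_N_STATES, float(pseudocount))
        for sid in aln.ids:
            for ch in aln.row(sid):
                if ch in AA_INDEX:
                    counts[AA_INDEX[ch]] += 1.0
        return cls(counts / counts.sum())

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t); rows sum to 1, P(0) = I, rows tend to pi as t grows."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        e = np.exp(-self.beta * t)
        return e * np.eye(_N_STATES) + (1.0 - e) * np.tile(self.pi, (_N_STATES, 1))

    def expected_p_distance(self, t: float) -> float:
        """Expected fraction of differing sites between two ends of a path t."""
        return (1.0 - float(np.sum(self.pi**2))) * (1.0 - np.exp(-self.beta * t))


@dataclass
class AncestralReconstruction:
    """Per internal node: marginal posteriors, MAP sequences, site likelihoods."""

    node_names: list[str]
    posteriors: dict[str, np.ndarray]  # node -> (n_sites, 20)
    map_sequences: dict[str, str]
    site_log_likelihoods: np.ndarray  # (n_sites,)

    @property
    def total_log_likelihood(self) -> float:
        return float(self.site_log_likelihoods.sum())


def _leaf_partials(residues: str) -> np.ndarray:
    """(n_sites, 20) indicator partial likelihoods; missing data = all ones."""
    n = len(residues)
    out = np.zeros((n, _N_STATES))
    for i, ch in enumerate(residues):
        if ch == GAP or ch == UNKNOWN:
            out[i, :] = 1.0
        elif ch in AA_INDEX:
            out[i, AA_INDEX[ch]] = 1.0
        else:
            raise ValueError(f"unknown residue {ch!r}")
    return out


def label_internal_nodes(tree: PhyloTree, prefix: str = "N") -> PhyloTree:
    """Return a copy with unnamed internal nodes labeled prefix1, prefix2, ...
    in preorder; existing labels are kept."""
    out = tree.copy()
    counter = 0
    for node in out.root.walk():
        if not node.is_leaf and not node.name:
            counter += 1
            node.name = f"{prefix}{counter}"
    return out


def _check_rooted(tree: PhyloTree) -> None:
    if not tree.rooted:
        raise ValueError("ancestral reconstruction requires a rooted tree")


def _upward_pass(tree: PhyloTree, seqs: dict[str, str], model: SubstitutionModel):
    """Pruning pass. Returns (partials, scale_logs, nodes_postorder).

    ``partials[id(node)]`` is (n_sites, 20), rescaled per node/site; the
    dropped factors accumulate in ``scale_logs`` (n_sites,) so downstream
    likelihoods can be corrected exactly.
    """
    leaves = tree.leaves()
    missing = [lf.name for lf in leaves if lf.name not in seqs]
    if missing:
        raise ValueError(f"no sequence data for leaves: {missing}")
    n_sites = len(next(iter(seqs.values())))
    partials: dict[int, np.ndarray] = {}
    scale_logs = np.zeros(n_sites)
    postorder: list[Node] = []

    def visit(node: Node) -> None:
        for ch in node.children:
            visit(ch)
        if node.is_leaf:
            partials[id(node)] = _leaf_partials(seqs[node.name])
        else:
            acc = np.ones((n_sites, _N_STATES))
            for ch in node.children:
                P = model.transition_matrix(ch.length)
                acc *= partials[id(ch)] @ P.T
            scale = acc.max(axis=1)
            scale[scale == 0] = 1.0
            nonlocal scale_logs
            scale_logs += np.log(scale)
            partials[id(node)] = acc / scale[:, None]
        postorder.append(node)

    visit(tree.root)
    return partials, scale_logs, postorder


def site_log_likelihood(
    tree: PhyloTree, column: dict[str, str], model: SubstitutionModel
) -> float:
    """Log-likelihood of a single alignment column on a rooted tree."""
    _check_rooted(tree)
    seqs = {name: res for name, res in column.items()}
    partials, scale_logs, _ = _upward_pass(tree, seqs, model)
    root_like = partials[id(tree.root)] @ model.pi
    return float(np.log(root_like[0]) + scale_logs[0])


def marginal_posteriors(
    tree: PhyloTree, aln: Alignment, model: SubstitutionModel
) -> AncestralReconstruction:
    """Marginal posterior state distributions at every internal node.

    The posterior at node v integrates over all other internal states:
    an upward (pruning) pass collects subtree likelihoods, a downward pass
    propagates the likelihood of everything outside each subtree, and the
    product normalized per site gives the posterior.  MAP residues break
    ties alphabetically.
    """
    _check_rooted(tree)
    tree = label_internal_nodes(tree)
    tree_leaves = set(tree.leaf_names())
    if tree_leaves != set(aln.ids):
        raise ValueError(
            f"alignment ids do not match tree leaves; "
            f"only in tree: {sorted(tree_leaves - set(aln.ids))}, "
            f"only in alignment: {sorted(set(aln.ids) - tree_leaves)}"
        )
    seqs = {sid: aln.row(sid) for sid in aln.ids}
    n_sites = aln.n_cols
    partials, scale_logs, _ = _upward_pass(tree, seqs, model)

    root_like = partials[id(tree.root)] @ model.pi
    site_ll = np.log(root_like) + scale_logs

    # downward ("outside") messages
    outside: dict[int, np.ndarray] = {id(tree.root): np.tile(model.pi, (n_sites, 1))}

    def descend(node: Node) -> None:
        if node.is_leaf:
            return
        up = outside[id(node)]
        child_msgs = {}
        for ch in node.children:
            P = model.transition_matrix(ch.length)
            child_msgs[id(ch)] = partials[id(ch)] @ P.T  # (sites, parent-state)
        for ch in node.children:
            sib = np.ones((n_sites, _N_STATES))
            for other in node.children:
                if other is not ch:
                    sib *= child_msgs[id(other)]
            P = model.transition_matrix(ch.length)
            msg = (up * sib) @ P  # (sites, child-state)
            scale = msg.max(axis=1)
            scale[scale == 0] = 1.0
            outside[id(ch)] = msg / scale[:, None]
            descend(ch)

    descend(tree.root)

    node_names: list[str] = []
    posteriors: dict[str, np.ndarray] = {}
    map_sequences: dict[str, str] = {}
    for node in tree.root.walk():
        if node.is_leaf:
            continue
        joint = partials[id(node)] * outside[id(node)]
        norm = joint.sum(axis=1, keepdims=True)
        post = joint / norm
        node_names.append(node.name)
        posteriors[node.name] = post
        # AMINO_ACIDS is alphabetical, so argmax ties resolve alphabetically
        map_sequences[node.name] = "".join(
            AMINO_ACIDS[i] for i in post.argmax(axis=1)
        )
    return AncestralReconstruction(
        node_names=node_names,
        posteriors=posteriors,
        map_sequences=map_sequences,
        site_log_likelihoods=site_ll,
    )


def write_ancestral_fasta(
    recon: AncestralReconstruction, fasta_path, tsv_path=None
) -> None:
    """MAP ancestor sequences as FASTA plus a per-site posterior TSV."""
    with open(fasta_path, "w") as fh:
        for name in recon.node_names:
            fh.write(f">{name}\n")
            seq = recon.map_sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("node\tsite\tmap_residue\tposterior\n")
            for name in recon.node_names:
                post = recon.posteriors[name]
                seq = recon.map_sequences[name]
                for site in range(post.shape[0]):
                    fh.write(
                        f"{name}\t{site + 1}\t{seq[site]}\t"
                        f"{post[site].max():.6f}\n"
                    )


def read_ancestral_tsv(path) -> dict[str, list[tuple[int, str, float]]]:
    out: dict[str, list[tuple[int, str, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("node\t") or line.startswith("#"):
                continue
            name, site, res, post = line.rstrip("\n").split("\t")
            out.setdefault(name, []).append((int(site), res, float(post)))
    return out
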
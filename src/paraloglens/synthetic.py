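"""Synthetic paralog-family generator with full ground truth.

Emulates the data structure of a two-paralog protein family study without
any database access: a rooted species tree; a gene duplication at a chosen
internal node, after which the younger copy (ISO1) exists only in that
clade and evolves faster by a per-branch rate multiplier; per-site rate
classes mimicking conserved domain blocks and drifting termini; planted
isoform-specific motif blocks that are frozen within each family but
different between families (with shared frozen flank columns anchoring
them); and an N-terminal span deleted in every ISO1 sequence, standing in
for a domain lost after duplication.

Sites evolve under the equal-input model, which has an exact simulation
rule per branch: each site keeps its state with probability
``exp(-beta * rate * t)`` and otherwise redraws from the stationary
frequencies.  Because the only indel event is the one known deletion, the
generator can emit the by-construction true alignment, so downstream
stages are testable without a multiple-alignment program in the loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ancestral import SubstitutionModel
from .phylo import Node, PhyloTree
from .records import AMINO_ACIDS, GAP, Alignment, Isoform, SequenceRecord


@dataclass(frozen=True)
class SiteClass:
    """Inclusive 1-based span with a relative substitution rate."""

    start: int
    end: int
    relative_rate: float

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid site-class span [{self.start},{self.end}]")
        if self.relative_rate < 0:
            raise ValueError("relative rate must be >= 0")


@dataclass(frozen=True)
class MotifBlock:
    """A planted isoform-specific block, in root (ISO2) coordinates.

    The block itself is frozen to a family-specific residue string that
    differs between families at every position; ``flank`` extra columns on
    each side are frozen to the shared ancestral residues, anchoring the
    motif in conserved context.
    """

    start: int
    end: int
    flank: int = 4

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid motif span [{self.start},{self.end}]")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def default_species_tree() -> PhyloTree:
    """A 12-species rooted tree with chordate-like and invertebrate-like
    clades; branch lengths in substitutions per site at relative rate 1."""
    newick = (
        "((((((human:0.03,mouse:0.03)n_mam:0.03,chicken:0.05)n_amn:0.03,"
        "frog:0.07)n_tet:0.03,(zebrafish:0.06,shark:0.08)n_fish:0.04)"
        "chordates:0.06,(lancelet:0.10,seaurchin:0.12)n_ambu:0.05)"
        "n_deut:0.04,((worm:0.15,fly:0.14)n_prot:0.05,"
        "(hydra:0.12,sponge:0.16)n_basal:0.04)n_nonchord:0.04)root;"
    )
    return PhyloTree.from_newick(newick, rooted=True)


def default_site_classes() -> list[SiteClass]:
    """Domain-like rate layout over 900 sites: a drifting N-terminal region
    (lost in ISO1), two strongly conserved domain blocks, moderately
    conserved linkers, a moderately drifting motif-hosting region, and a
    fast C-terminus."""
    return [
        SiteClass(1, 110, 2.5),    # N-terminal region, deleted in ISO1
        SiteClass(111, 330, 0.25),  # conserved regulatory domain block
        SiteClass(331, 420, 0.50),  # linker
        SiteClass(421, 520, 0.35),  # exchange-motif block
        SiteClass(521, 700, 0.45),  # association-domain region (hosts motif)
        SiteClass(701, 860, 0.30),  # conserved catalytic domain block
        SiteClass(861, 900, 2.50),  # fast C-terminus
    ]


@dataclass
class SimulationConfig:
    species_tree: PhyloTree = field(default_factory=default_species_tree)
    duplication_node: str | None = "chordates"
    rate_multiplier: float = 2.0
    duplication_stem: float = 0.05
    site_classes: list[SiteClass] = field(default_factory=default_site_classes)
    motif_blocks: list[MotifBlock] = field(
        default_factory=lambda: [MotifBlock(633, 649)]
    )
    iso1_deletion: tuple[int, int] | None = (1, 110)
    seq_length: int = 900
    seed: int = 0
    pi: np.ndarray | None = None

    def __post_init__(self):
        if self.rate_multiplier < 1.0:
            raise ValueError("rate_multiplier must be >= 1")
        spans = [(sc.start, sc.end) for sc in self.site_classes]
        for s, e in spans:
            if e > self.seq_length:
                raise ValueError(f"site class [{s},{e}] exceeds seq_length")
        for (s1, e1), (s2, e2) in zip(sorted(spans), sorted(spans)[1:]):
            if s2 <= e1:
                raise ValueError("site-class spans must be disjoint")
        for mb in self.motif_blocks:
            if mb.end > self.seq_length:
                raise ValueError(f"motif block [{mb.start},{mb.end}] exceeds seq_length")
            if self.iso1_deletion is not None:
                ds, de = self.iso1_deletion
                if not (mb.end < ds or mb.start - mb.flank > de):
                    raise ValueError("motif block may not overlap the deletion span")
        if self.iso1_deletion is not None:
            ds, de = self.iso1_deletion
            if not (1 <= ds <= de <= self.seq_length):
                raise ValueError("invalid deletion span")


@dataclass
class MotifTruth:
    """Planted motif coordinates on each family's ungapped reference frame."""

    iso1_start: int
    iso1_end: int
    iso2_start: int
    iso2_end: int
    col_start: int
    col_end: int
    iso1_seq: str
    iso2_seq: str


@dataclass
class SyntheticTruth:
    gene_tree: PhyloTree
    isoform_map: dict[str, Isoform]
    ancestors: dict[str, str]
    motifs: list[MotifTruth]
    expected_substitutions: dict[str, float]
    site_rates: np.ndarray
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Gene-tree construction
# ---------------------------------------------------------------------------

def build_gene_tree(config: SimulationConfig) -> tuple[PhyloTree, set[str]]:
    """Species tree -> gene tree with the duplication applied.

    Returns the gene tree (leaves ``<species>_ISO1`` / ``<species>_ISO2``)
    and the set of node names belonging to the ISO1 copy (whose branch
    lengths are scaled by the rate multiplier).
    """
    tree = config.species_tree.copy()
    for leaf in tree.leaves():
        leaf.name = f"{leaf.name}_ISO2"
    if config.duplication_node is None:
        return PhyloTree(tree.root, rooted=True), set()
    dup = None
    for node in tree.root.walk():
        if not node.is_leaf and node.name == config.duplication_node:
            dup = node
            break
    if dup is None:
        raise ValueError(
            f"no internal node named {config.duplication_node!r} in species tree"
        )

    def clone(node: Node, scale: float, rename) -> Node:
        new = Node(rename(node.name) if node.name else None, node.length * scale)
        for ch in node.children:
            new.add(clone(ch, scale, rename))
        return new

    r = config.rate_multiplier
    iso2_copy = Node(None, config.duplication_stem)
    iso1_copy = Node(None, config.duplication_stem * r)
    for ch in list(dup.children):
        iso2_copy.add(clone(ch, 1.0, lambda n: n))
        iso1_copy.add(clone(ch, r, lambda n: n.replace("_ISO2", "_ISO1")))
    dup.children = []
    dup.add(iso2_copy)
    dup.add(iso1_copy)
    gene_tree = PhyloTree(tree.root, rooted=True)
    iso1_names = {leaf.name for leaf in iso1_copy.leaves()}
    return gene_tree, iso1_names


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _site_rate_vector(config: SimulationConfig) -> np.ndarray:
    rates = np.ones(config.seq_length)
    for sc in config.site_classes:
        rates[sc.start - 1 : sc.end] = sc.relative_rate
    for mb in config.motif_blocks:
        lo = max(1, mb.start - mb.flank)
        hi = min(config.seq_length, mb.end + mb.flank)
        rates[lo - 1 : hi] = 0.0
    return rates


def simulate(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], Alignment, SyntheticTruth]:
    """Evolve the family down the gene tree; return records, the true
    alignment, and the full ground truth.  Byte-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    pi = (
        np.full(20, 1.0 / 20.0)
        if config.pi is None
        else np.asarray(config.pi, dtype=float)
    )
    model = SubstitutionModel(pi)
    L = config.seq_length
    rates = _site_rate_vector(config)

    gene_tree, _ = build_gene_tree(config)
    from .ancestral import label_internal_nodes

    gene_tree = label_internal_nodes(gene_tree)

    # identify the ISO1 copy subtree (node named dup child with ISO1 leaves)
    iso1_nodes: set[int] = set()
    if config.duplication_node is not None:
        for node in gene_tree.root.walk():
            if not node.is_leaf:
                leaves = {lf.name for lf in node.leaves()}
                if leaves and all(n.endswith("_ISO1") for n in leaves):
                    iso1_nodes.add(id(node))
                    break
        if iso1_nodes:
            top = next(
                n for n in gene_tree.root.walk() if id(n) in iso1_nodes
            )
            for n in top.walk():
                iso1_nodes.add(id(n))

    # frozen motif strings: ISO2 string drawn from pi, ISO1 differing at
    # every position
    motif_strings: list[tuple[np.ndarray, np.ndarray]] = []
    for mb in config.motif_blocks:
        iso2_states = rng.choice(20, size=mb.length, p=pi)
        iso1_states = np.empty(mb.length, dtype=int)
        for k, s2 in enumerate(iso2_states):
            q = pi.copy()
            q[s2] = 0.0
            q /= q.sum()
            iso1_states[k] = rng.choice(20, p=q)
        motif_strings.append((iso1_states, iso2_states))

    root_states = rng.choice(20, size=L, p=pi)
    for mb, (_, iso2_states) in zip(config.motif_blocks, motif_strings):
        root_states[mb.start - 1 : mb.end] = iso2_states

    states: dict[int, np.ndarray] = {}
    expected_subs: dict[str, float] = {}
    mean_rate = float(rates.mean())

    def evolve(node: Node, parent_states: np.ndarray | None) -> None:
        if parent_states is None:
            seq = root_states.copy()
        else:
            seq = parent_states.copy()
            p_change = 1.0 - np.exp(-model.beta * rates * node.length)
            mask = rng.random(L) < p_change
            n_new = int(mask.sum())
            if n_new:
                seq[mask] = rng.choice(20, size=n_new, p=pi)
        if id(node) in iso1_nodes:
            for mb, (iso1_states, _) in zip(config.motif_blocks, motif_strings):
                seq[mb.start - 1 : mb.end] = iso1_states
        states[id(node)] = seq
        if node.name:
            expected_subs[node.name] = node.length * mean_rate
        for ch in node.children:
            evolve(ch, seq)

    evolve(gene_tree.root, None)

    # assemble records and the true alignment
    isoform_map: dict[str, Isoform] = {}
    ids: list[str] = []
    rows: list[str] = []
    records: list[SequenceRecord] = []
    del_span = config.iso1_deletion
    for leaf in gene_tree.leaves():
        seq = "".join(AMINO_ACIDS[s] for s in states[id(leaf)])
        iso = Isoform.ISO1 if leaf.name.endswith("_ISO1") else Isoform.ISO2
        species = leaf.name.rsplit("_", 1)[0]
        if iso is Isoform.ISO1 and del_span is not None:
            ds, de = del_span
            row = seq[: ds - 1] + GAP * (de - ds + 1) + seq[de:]
            ungapped = seq[: ds - 1] + seq[de:]
        else:
            row = seq
            ungapped = seq
        isoform_map[leaf.name] = iso
        ids.append(leaf.name)
        rows.append(row)
        records.append(
            SequenceRecord(id=leaf.name, residues=ungapped, species=species, isoform=iso)
        )
    aln = Alignment(ids, rows)

    ancestors = {
        node.name: "".join(AMINO_ACIDS[s] for s in states[id(node)])
        for node in gene_tree.root.walk()
        if not node.is_leaf
    }

    del_len = (del_span[1] - del_span[0] + 1) if del_span is not None else 0
    motif_truths = []
    for mb, (iso1_states, iso2_states) in zip(config.motif_blocks, motif_strings):
        offset = del_len if (del_span is not None and mb.start > del_span[1]) else 0
        motif_truths.append(
            MotifTruth(
                iso1_start=mb.start - offset,
                iso1_end=mb.end - offset,
                iso2_start=mb.start,
                iso2_end=mb.end,
                col_start=mb.start,
                col_end=mb.end,
                iso1_seq="".join(AMINO_ACIDS[s] for s in iso1_states),
                iso2_seq="".join(AMINO_ACIDS[s] for s in iso2_states),
            )
        )

    truth = SyntheticTruth(
        gene_tree=gene_tree,
        isoform_map=isoform_map,
        ancestors=ancestors,
        motifs=motif_truths,
        expected_substitutions=expected_subs,
        site_rates=rates,
        config=config,
    )
    return records, aln, truth


# ---------------------------------------------------------------------------
# Truth tables
# ---------------------------------------------------------------------------

def truth_tables(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the ground truth (tree, ancestors, motif coordinates) as
    plain-text files for downstream comparison."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tree_path = out_dir / "true_tree.nwk"
    tree_path.write_text(truth.gene_tree.to_newick() + "\n")
    paths["tree"] = tree_path

    anc_path = out_dir / "true_ancestors.fasta"
    with open(anc_path, "w") as fh:
        for name in sorted(truth.ancestors):
            fh.write(f">{name}\n")
            seq = truth.ancestors[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["ancestors"] = anc_path

    motif_path = out_dir / "true_motifs.tsv"
    with open(motif_path, "w") as fh:
        fh.write(
            "iso1_start\tiso1_end\tiso2_start\tiso2_end\tcol_start\tcol_end\t"
            "iso1_seq\tiso2_seq\n"
        )
        for m in truth.motifs:
            fh.write(
                f"{m.iso1_start}\t{m.iso1_end}\t{m.iso2_start}\t{m.iso2_end}\t"
                f"{m.col_start}\t{m.col_end}\t{m.iso1_seq}\t{m.iso2_seq}\n"
            )
    paths["motifs"] = motif_path

    map_path = out_dir / "isoform_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("seq_id\tspecies\tisoform\n")
        for sid, iso in sorted(truth.isoform_map.items()):
            species = sid.rsplit("_", 1)[0]
            fh.write(f"{sid}\t{species}\t{iso.value}\n")
    paths["isoform_map"] = map_path
    return paths
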
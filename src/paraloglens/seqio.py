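"""Sequence and alignment I/O plus pairwise global alignment.

Standard-format parsing (FASTA, Clustal) is delegated to Biopython; this
module adds the validation, labeling and coordinate bookkeeping the rest of
the pipeline relies on, and wraps Needleman-Wunsch global alignment with the
identity convention used for all between-species percent-identity figures.

Identity convention
-------------------
``identity_pct = 100 * identities / compared columns`` where a compared
column is any alignment column in which at least one sequence has a residue
(terminal and internal gap-vs-residue columns count in the denominator) and
neither symbol is the unknown residue 'X'.  Columns involving 'X' are
excluded from numerator and denominator alike.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment, PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import (
    GAP,
    UNKNOWN,
    Alignment,
    Domain,
    DomainAnnotation,
    Isoform,
    PairwiseAlignmentResult,
    SequenceRecord,
)

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


# ---------------------------------------------------------------------------
# FASTA / Clustal reading and writing
# ---------------------------------------------------------------------------

def read_isoform_map(path: str | Path) -> dict[str, tuple[str, Isoform]]:
    """Read a tab-separated (seq_id, species, isoform) side-car map.

    A header row whose first field is ``seq_id`` is tolerated and skipped.
    """
    mapping: dict[str, tuple[str, Isoform]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "seq_id":
                continue
            if len(row) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(row)}"
                )
            seq_id, species, iso = row[0].strip(), row[1].strip(), row[2].strip()
            try:
                isoform = Isoform(iso.upper())
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: unknown isoform label {iso!r} "
                    f"(expected ISO1, ISO2 or OTHER)"
                ) from None
            mapping[seq_id] = (species, isoform)
    return mapping


def read_fasta(
    path: str | Path, isoform_map: str | Path | dict | None = None
) -> list[SequenceRecord]:
    """Read ungapped protein sequences from a FASTA file.

    Species and isoform labels are filled from ``isoform_map`` (a path to the
    side-car TSV or a pre-parsed dict) when supplied, else left as
    ``OTHER``/``""``.  Duplicate ids raise; an empty file returns an empty
    list with a warning.
    """
    if isoform_map is not None and not isinstance(isoform_map, dict):
        isoform_map = read_isoform_map(isoform_map)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTA: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        species, isoform = "", Isoform.OTHER
        if isoform_map and rec.id in isoform_map:
            species, isoform = isoform_map[rec.id]
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq).upper(),
                species=species,
                isoform=isoform,
                description=desc,
            )
        )
    if not records:
        warnings.warn(f"{path}: no sequences found", stacklevel=2)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a multiple sequence alignment in FASTA or Clustal format.

    Validation (equal gapped lengths, no all-gap column, unique ids) happens
    in the :class:`Alignment` constructor; ragged inputs raise a ValueError
    naming the offending sequences.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format {format!r}")
    if fmt == "fasta":
        # read leniently so our own validator reports ragged ids
        entries = list(SeqIO.parse(str(path), "fasta"))
        ids = [e.id for e in entries]
        rows = [str(e.seq).upper() for e in entries]
    else:
        msa = AlignIO.read(str(path), "clustal")
        ids = [r.id for r in msa]
        rows = [str(r.seq).upper() for r in msa]
    if not ids:
        raise ValueError(f"{path}: no sequences found")
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    fmt = format.lower()
    if fmt == "fasta":
        with open(path, "w") as fh:
            for sid in aln.ids:
                fh.write(f">{sid}\n")
                row = aln.row(sid)
                for i in range(0, len(row), 60):
                    fh.write(row[i : i + 60] + "\n")
    elif fmt == "clustal":
        msa = MultipleSeqAlignment(
            [BioSeqRecord(Seq(aln.row(sid)), id=sid, description="") for sid in aln.ids]
        )
        AlignIO.write(msa, str(path), "clustal")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


def read_domain_annotations(path: str | Path) -> list[DomainAnnotation]:
    """Read domain annotations from TSV columns (seq_id, domain, start, end)."""
    out: list[DomainAnnotation] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if lineno == 1 and row[0].strip().lower() == "seq_id":
                continue
            if len(row) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected 4 fields, got {len(row)}"
                )
            out.append(
                DomainAnnotation(
                    sequence_id=row[0].strip(),
                    domain=Domain(row[1].strip().upper()),
                    start=int(row[2]),
                    end=int(row[3]),
                )
            )
    _check_domain_overlaps(out)
    return out


def _check_domain_overlaps(annotations: list[DomainAnnotation]) -> None:
    by_seq: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        by_seq.setdefault(ann.sequence_id, []).append(ann)
    for sid, anns in by_seq.items():
        anns = sorted(anns, key=lambda a: a.start)
        for prev, nxt in zip(anns, anns[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"overlapping domains on {sid!r}: "
                    f"{prev.domain.value} [{prev.start},{prev.end}] and "
                    f"{nxt.domain.value} [{nxt.start},{nxt.end}]"
                )


# ---------------------------------------------------------------------------
# Domain extraction
# ---------------------------------------------------------------------------

def extract_domain(record: SequenceRecord, annotation: DomainAnnotation) -> SequenceRecord:
    """Cut the annotated span out of a sequence; id gets a domain suffix."""
    if annotation.end > len(record):
        raise IndexError(
            f"domain [{annotation.start},{annotation.end}] exceeds length "
            f"{len(record)} of {record.id!r}"
        )
    sub = record.residues[annotation.start - 1 : annotation.end]
    return SequenceRecord(
        id=f"{record.id}_{annotation.domain.value}",
        residues=sub,
        species=record.species,
        isoform=record.isoform,
        description=record.description,
    )


# ---------------------------------------------------------------------------
# Global pairwise alignment
# ---------------------------------------------------------------------------

def load_matrix(name: str):
    """Load a substitution matrix with the unknown residue scoring zero."""
    try:
        mat = substitution_matrices.load(name)
    except FileNotFoundError:
        raise ValueError(
            f"unknown substitution matrix {name!r}; available: "
            f"{', '.join(substitution_matrices.load())}"
        ) from None
    mat = mat.copy()
    if UNKNOWN in mat.alphabet:
        xi = mat.alphabet.index(UNKNOWN)
        mat[xi, :] = 0.0
        mat[:, xi] = 0.0
    return mat


def alignment_identity(aligned_a: str, aligned_b: str) -> tuple[int, int, float]:
    """(identities, compared columns, percent identity) for two gapped rows.

    Columns where both symbols are gaps are skipped; columns where either
    symbol is 'X' are excluded from numerator and denominator.
    """
    ident = 0
    compared = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP and y == GAP:
            continue
        if x == UNKNOWN or y == UNKNOWN:
            continue
        compared += 1
        if x == y and x != GAP:
            ident += 1
    pct = 100.0 * ident / compared if compared else 0.0
    return ident, compared, pct


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignmentResult:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment of two sequences.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Among
    co-optimal alignments a fixed deterministic one is returned.
    """
    if not a.residues or not b.residues:
        raise ValueError("both sequences must be non-empty")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = load_matrix(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    alignments = aligner.align(a.residues, b.residues)
    best = alignments[0]
    aligned_a, aligned_b = str(best[0]), str(best[1])
    ident, compared, pct = alignment_identity(aligned_a, aligned_b)
    return PairwiseAlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(best.score),
        identity_pct=pct,
        n_identities=ident,
        n_compared=compared,
    )
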
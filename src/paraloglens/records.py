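"""Core domain types shared across the pipeline.

A paralog-family analysis works with protein sequences carrying two labels:
the species they come from and which of the two paralogous isoforms they
belong to.  Coordinates on ungapped sequences are 1-based and inclusive
throughout, matching the convention of protein databases and of domain
annotations such as "residues 523 to 539".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"

VALID_RESIDUES = frozenset(AMINO_ACIDS + UNKNOWN)


class Isoform(enum.Enum):
    """Which paralog family a sequence belongs to.

    ISO1 is the younger paralog (restricted to a sub-clade, evolving faster);
    ISO2 the ancestral one present in all species.  OTHER covers outgroup or
    unlabeled sequences.
    """

    ISO1 = "ISO1"
    ISO2 = "ISO2"
    OTHER = "OTHER"


class Domain(enum.Enum):
    """Named regions of the multi-domain paralog architecture."""

    CBD_A = "CBD_A"
    DEP = "DEP"
    CBD_B = "CBD_B"
    REM = "REM"
    RA = "RA"
    GEF = "GEF"
    NTERM = "NTERM"
    CTERM = "CTERM"


@dataclass
class SequenceRecord:
    """One ungapped protein sequence with species/isoform labels."""

    id: str
    residues: str
    species: str = ""
    isoform: Isoform = Isoform.OTHER
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        if GAP in self.residues:
            raise ValueError(f"sequence {self.id!r} contains gap characters")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain on one sequence, in 1-based inclusive ungapped coords."""

    sequence_id: str
    domain: Domain
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid domain span [{self.start}, {self.end}] on "
                f"{self.sequence_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PairwiseAlignmentResult:
    """Optimal global alignment of two sequences plus its identity summary."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    n_identities: int = 0
    n_compared: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct must lie in [0, 100]")


class Alignment:
    """Equal-length gapped sequences with column/residue coordinate maps.

    Columns are 1-based alignment positions; residues are 1-based ungapped
    positions on each member sequence.  Both directions of the coordinate
    map are precomputed so the per-column scans stay O(1) per lookup.
    """

    def __init__(self, ids: list[str], rows: list[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows must have the same length")
        if not rows:
            raise ValueError("alignment must contain at least one sequence")
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dupes}")
        n_cols = len(rows[0])
        ragged = [i for i, r in zip(ids, rows) if len(r) != n_cols]
        if ragged:
            raise ValueError(
                f"ragged alignment: sequences {ragged} differ in length "
                f"from {ids[0]!r} ({n_cols} columns)"
            )
        if n_cols == 0:
            raise ValueError("alignment has zero columns")
        for c in range(n_cols):
            if all(r[c] == GAP for r in rows):
                raise ValueError(f"column {c + 1} is all-gap")
        self.ids: list[str] = list(ids)
        self.rows: list[str] = list(rows)
        self.n_cols: int = n_cols
        self._row_of = {sid: i for i, sid in enumerate(ids)}
        # per sequence: column (0-based) -> residue index (1-based) or None
        self._col2res: dict[str, list[int | None]] = {}
        self._res2col: dict[str, list[int]] = {}
        for sid, row in zip(ids, rows):
            c2r: list[int | None] = []
            r2c: list[int] = []
            pos = 0
            for c, ch in enumerate(row):
                if ch == GAP:
                    c2r.append(None)
                else:
                    pos += 1
                    c2r.append(pos)
                    r2c.append(c + 1)
            self._col2res[sid] = c2r
            self._res2col[sid] = r2c

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._row_of

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self._row_of[seq_id]]
        except KeyError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def col_to_residue(self, seq_id: str, col: int) -> int | None:
        """1-based residue index at alignment column ``col``, or None on a gap."""
        if not (1 <= col <= self.n_cols):
            raise IndexError(
                f"column {col} out of range 1..{self.n_cols}"
            )
        if seq_id not in self._row_of:
            raise KeyError(f"sequence {seq_id!r} not in alignment")
        return self._col2res[seq_id][col - 1]

    def residue_to_col(self, seq_id: str, residue: int) -> int:
        """Alignment column holding 1-based ungapped position ``residue``."""
        if seq_id not in self._row_of:
            raise KeyError(f"sequence {seq_id!r} not in alignment")
        r2c = self._res2col[seq_id]
        if not (1 <= residue <= len(r2c)):
            raise IndexError(
                f"residue {residue} out of range 1..{len(r2c)} for {seq_id!r}"
            )
        return r2c[residue - 1]

    def records(self) -> list[SequenceRecord]:
        return [SequenceRecord(id=sid, residues=self.ungapped(sid)) for sid in self.ids]
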
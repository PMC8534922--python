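"""Isoform-specific motif calling and two-sided sequence-logo matrices.

A candidate motif is a run of alignment columns where the two family
references disagree (cross-family divergence) while each family remains
internally conserved above a threshold — the signature of a segment that
is diagnostic for one paralog.  Logo matrices quantify per-position amino
acid enrichment/depletion against a background with the weighted
Kullback-Leibler letter heights ``p_a * log2(p_a / q_a)``, using
position-based (Henikoff) sequence weights so over-represented subfamilies
do not dominate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conservation import ConservationProfile
from .records import AMINO_ACIDS, GAP, UNKNOWN, Alignment, Isoform


@dataclass
class MotifCall:
    """One contiguous isoform-specific segment, in ungapped reference coords."""

    isoform: Isoform
    ref_id: str
    ref_start: int
    ref_end: int
    columns: tuple[int, int]  # inclusive 1-based alignment columns
    mean_cons1: float
    mean_cons2: float
    n_mismatch_cols: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


@dataclass
class LogoMatrix:
    """Signed letter heights (bits) over a column span.

    ``heights`` is positions x 20 (rows indexed by alignment column);
    positive entries mark enrichment over the background, negative ones
    depletion.  Letters absent at a position contribute height 0 so the
    matrix stays bounded.  ``flagged`` lists columns with no usable residue
    mass (or majority gap weight), where heights are undefined.
    """

    columns: list[int]
    heights: pd.DataFrame
    probabilities: pd.DataFrame
    background: np.ndarray
    weights: dict[str, float]
    flagged: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Motif calling
# ---------------------------------------------------------------------------

def call_motifs(
    profile: ConservationProfile,
    min_cons: float = 0.5,
    min_len: int = 10,
    max_violations: int = 2,
) -> list[MotifCall]:
    """Maximal divergent-yet-conserved runs of alignment columns.

    A column passes when the references disagree (``match`` is False) and
    both within-family conservation fractions are >= ``min_cons``.  Runs may
    bridge up to ``max_violations`` interior failing columns, must start and
    end on passing columns, and are kept only when they span at least
    ``min_len`` columns.  Each surviving run yields one call per isoform
    with its boundaries mapped to that reference's ungapped coordinates.
    """
    if not (0.0 < min_cons <= 1.0):
        raise ValueError(f"min_cons must lie in (0, 1], got {min_cons}")
    if min_len < 1 or max_violations < 0:
        raise ValueError("min_len must be >= 1 and max_violations >= 0")

    rows = profile.rows

    def passes(r) -> bool:
        return (
            r.match is False
            and not math.isnan(r.cons1)
            and not math.isnan(r.cons2)
            and r.cons1 >= min_cons
            and r.cons2 >= min_cons
        )

    passing = [i for i, r in enumerate(rows) if passes(r)]
    runs: list[tuple[int, int]] = []
    if passing:
        start = end = passing[0]
        violations = 0
        for idx in passing[1:]:
            interior = idx - end - 1
            if violations + interior <= max_violations:
                violations += interior
                end = idx
            else:
                runs.append((start, end))
                start = end = idx
                violations = 0
        runs.append((start, end))

    calls: list[MotifCall] = []
    for start, end in runs:
        if end - start + 1 < min_len:
            continue
        span_rows = rows[start : end + 1]
        cons1 = [r.cons1 for r in span_rows if not math.isnan(r.cons1)]
        cons2 = [r.cons2 for r in span_rows if not math.isnan(r.cons2)]
        n_bad = sum(1 for r in span_rows if not passes(r))
        for iso, ref_id, pos_of in (
            (Isoform.ISO1, profile.ref1, lambda r: r.pos1),
            (Isoform.ISO2, profile.ref2, lambda r: r.pos2),
        ):
            if pos_of(span_rows[0]) is None or pos_of(span_rows[-1]) is None:
                continue  # reference gapped at a boundary column
            calls.append(
                MotifCall(
                    isoform=iso,
                    ref_id=ref_id,
                    ref_start=pos_of(span_rows[0]),
                    ref_end=pos_of(span_rows[-1]),
                    columns=(span_rows[0].col, span_rows[-1].col),
                    mean_cons1=sum(cons1) / len(cons1) if cons1 else math.nan,
                    mean_cons2=sum(cons2) / len(cons2) if cons2 else math.nan,
                    n_mismatch_cols=n_bad,
                )
            )
    calls.sort(key=lambda c: (c.columns[0], c.isoform.value))
    return calls


# ---------------------------------------------------------------------------
# Sequence weighting and logo matrices
# ---------------------------------------------------------------------------

def henikoff_weights(aln: Alignment) -> dict[str, float]:
    """Position-based sequence weights, normalized to sum to 1.

    At a column with r distinct residue types, a sequence whose residue
    occurs s times contributes 1/(r*s); gaps contribute nothing.  Summed
    over columns this down-weights redundant sequences.
    """
    raw = {sid: 0.0 for sid in aln.ids}
    rows = {sid: aln.row(sid) for sid in aln.ids}
    for c in range(aln.n_cols):
        counts: dict[str, int] = {}
        for sid in aln.ids:
            ch = rows[sid][c]
            if ch != GAP:
                counts[ch] = counts.get(ch, 0) + 1
        r = len(counts)
        if r == 0:
            continue
        for sid in aln.ids:
            ch = rows[sid][c]
            if ch != GAP:
                raw[sid] += 1.0 / (r * counts[ch])
    total = sum(raw.values())
    if total == 0.0:
        n = len(aln.ids)
        return {sid: 1.0 / n for sid in aln.ids}
    return {sid: w / total for sid, w in raw.items()}


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def empirical_background(aln: Alignment) -> np.ndarray:
    """Residue frequencies over the whole alignment (gaps/'X' ignored)."""
    counts = np.zeros(20)
    for sid in aln.ids:
        for ch in aln.row(sid):
            if ch in AMINO_ACIDS:
                counts[AMINO_ACIDS.index(ch)] += 1
    if counts.sum() == 0:
        return uniform_background()
    return counts / counts.sum()


def logo_matrix(
    aln: Alignment,
    columns: tuple[int, int],
    weights: dict[str, float] | None = None,
    background: np.ndarray | None = None,
    pseudocount: float = 0.0,
    members: list[str] | None = None,
    max_gap_fraction: float = 0.5,
) -> LogoMatrix:
    """Two-sided Kullback-Leibler logo matrix over an inclusive column span.

    ``p_a(c) = (weighted count of a at c + alpha*q_a) / (non-gap weight + alpha)``
    and ``height_a(c) = p_a(c) * log2(p_a(c)/q_a)`` — positive when the
    letter is enriched over the background, negative when depleted, zero
    when absent.  Columns whose gap weight exceeds ``max_gap_fraction`` (or
    with no residue mass at all) are flagged and get undefined heights.
    """
    lo, hi = columns
    if not (1 <= lo <= hi <= aln.n_cols):
        raise ValueError(f"column span {columns} outside 1..{aln.n_cols}")
    if members is None:
        members = list(aln.ids)
    if weights is None:
        weights = {sid: 1.0 / len(members) for sid in members}
    q = uniform_background() if background is None else np.asarray(background, float)
    if not math.isclose(q.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    alpha = float(pseudocount)

    cols = list(range(lo, hi + 1))
    heights = np.zeros((len(cols), 20))
    probs = np.zeros((len(cols), 20))
    flagged: list[int] = []
    for k, c in enumerate(cols):
        w = np.zeros(20)
        gap_w = 0.0
        total_member_w = 0.0
        for sid in members:
            wt = weights.get(sid, 0.0)
            total_member_w += wt
            ch = aln.row(sid)[c - 1]
            if ch == GAP:
                gap_w += wt
            elif ch != UNKNOWN and ch in AMINO_ACIDS:
                w[AMINO_ACIDS.index(ch)] += wt
        residue_w = w.sum()
        if residue_w == 0.0 or (
            total_member_w > 0 and gap_w / total_member_w > max_gap_fraction
        ):
            flagged.append(c)
            heights[k, :] = np.nan
            probs[k, :] = np.nan
            continue
        p = (w + alpha * q) / (residue_w + alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / q), 0.0)
        probs[k] = p
        heights[k] = h
    letters = list(AMINO_ACIDS)
    return LogoMatrix(
        columns=cols,
        heights=pd.DataFrame(heights, index=cols, columns=letters),
        probabilities=pd.DataFrame(probs, index=cols, columns=letters),
        background=q,
        weights=dict(weights),
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def motif_report(
    calls: list[MotifCall],
    logos: list[LogoMatrix],
    aln: Alignment,
    out_dir: str | Path,
    params_comment: str = "",
) -> list[Path]:
    """Write motifs.tsv plus one logo_<k>.tsv per call; returns paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    motifs_path = out_dir / "motifs.tsv"
    with open(motifs_path, "w") as fh:
        if params_comment:
            for line in params_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(
            "isoform\tref_id\tref_start\tref_end\tlength\tcol_start\tcol_end\t"
            "mean_cons1\tmean_cons2\tn_mismatch_cols\tsequence\n"
        )
        for call in calls:
            seq = aln.ungapped(call.ref_id)[call.ref_start - 1 : call.ref_end]
            fh.write(
                "\t".join(
                    [
                        call.isoform.value,
                        call.ref_id,
                        str(call.ref_start),
                        str(call.ref_end),
                        str(call.length),
                        str(call.columns[0]),
                        str(call.columns[1]),
                        f"{call.mean_cons1:.4f}",
                        f"{call.mean_cons2:.4f}",
                        str(call.n_mismatch_cols),
                        seq,
                    ]
                )
                + "\n"
            )
    written.append(motifs_path)
    for k, logo in enumerate(logos, start=1):
        path = out_dir / f"logo_{k}.tsv"
        df = logo.heights.copy()
        df.index.name = "col"
        df.to_csv(path, sep="\t", float_format="%.6f")
        written.append(path)
    return written


def read_motif_calls(path: str | Path) -> list[MotifCall]:
    calls: list[MotifCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("isoform\t"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 10:
                continue
            calls.append(
                MotifCall(
                    isoform=Isoform(f[0]),
                    ref_id=f[1],
                    ref_start=int(f[2]),
                    ref_end=int(f[3]),
                    columns=(int(f[5]), int(f[6])),
                    mean_cons1=float(f[7]),
                    mean_cons2=float(f[8]),
                    n_mismatch_cols=int(f[9]),
                )
            )
    return calls
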
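"""Per-column conservation/divergence scanning of a joint paralog alignment.

For every column of an alignment containing both isoform families the scan
records (1) whether the two designated reference sequences (e.g. the human
proteins) carry the same residue, and (2) the within-isoform conservation:
the fraction of each family's other members whose residue matches their
reference.  Plotted, match/mismatch gives the classic blue/red dichotomy
and the conservation fractions the per-residue percent-identity traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .records import GAP, UNKNOWN, Alignment, DomainAnnotation, Isoform


@dataclass
class ProfileRow:
    """Statistics of one alignment column.

    ``cons1``/``cons2`` are fractions in [0, 1]; they are NaN where the
    respective reference has a gap (the statistic is undefined there, not
    zero — a family that lost a whole domain must not read as 0% identity).
    ``pos1``/``pos2`` are 1-based ungapped reference coordinates, None at
    reference gaps.
    """

    col: int
    pos1: int | None
    pos2: int | None
    res1: str
    res2: str
    match: bool | None
    cons1: float
    cons2: float


class ConservationProfile:
    def __init__(self, rows: list[ProfileRow], ref1: str, ref2: str):
        self.rows = rows
        self.ref1 = ref1
        self.ref2 = ref2

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "col": [r.col for r in self.rows],
                "pos1": [r.pos1 for r in self.rows],
                "pos2": [r.pos2 for r in self.rows],
                "res1": [r.res1 for r in self.rows],
                "res2": [r.res2 for r in self.rows],
                "match": [r.match for r in self.rows],
                "cons1": [r.cons1 for r in self.rows],
                "cons2": [r.cons2 for r in self.rows],
            }
        )


def conservation_profile(
    aln: Alignment,
    isoform_map: dict[str, Isoform],
    ref1: str,
    ref2: str,
    exclude_reference: bool = True,
) -> ConservationProfile:
    """Column-by-column divergence scan of a joint two-family alignment.

    ``ref1``/``ref2`` are the reference sequences of isoform 1 and 2.  At
    each column, ``cons_k`` is the fraction of family-k sequences (the
    reference itself excluded by default) carrying the reference residue,
    over family members with a non-gap, non-'X' residue at that column.
    """
    for ref, iso in ((ref1, Isoform.ISO1), (ref2, Isoform.ISO2)):
        if ref not in aln:
            raise ValueError(f"reference {ref!r} not in alignment")
        if isoform_map.get(ref) is not iso:
            raise ValueError(f"reference {ref!r} is not labeled {iso.value}")
    members1 = [s for s in aln.ids if isoform_map.get(s) is Isoform.ISO1]
    members2 = [s for s in aln.ids if isoform_map.get(s) is Isoform.ISO2]
    for iso, members in ((Isoform.ISO1, members1), (Isoform.ISO2, members2)):
        if len(members) < 2:
            raise ValueError(
                f"need at least 2 sequences labeled {iso.value}, "
                f"got {len(members)}"
            )
    if exclude_reference:
        members1 = [s for s in members1 if s != ref1]
        members2 = [s for s in members2 if s != ref2]

    row1, row2 = aln.row(ref1), aln.row(ref2)
    fam1 = [aln.row(s) for s in members1]
    fam2 = [aln.row(s) for s in members2]

    rows: list[ProfileRow] = []
    for c in range(aln.n_cols):
        r1, r2 = row1[c], row2[c]
        match = (r1 == r2) if (r1 != GAP and r2 != GAP) else None
        cons1 = _column_conservation(r1, (s[c] for s in fam1))
        cons2 = _column_conservation(r2, (s[c] for s in fam2))
        rows.append(
            ProfileRow(
                col=c + 1,
                pos1=aln.col_to_residue(ref1, c + 1),
                pos2=aln.col_to_residue(ref2, c + 1),
                res1=r1,
                res2=r2,
                match=match,
                cons1=cons1,
                cons2=cons2,
            )
        )
    return ConservationProfile(rows, ref1, ref2)


def _column_conservation(ref_res: str, residues) -> float:
    if ref_res == GAP:
        return math.nan
    agree = total = 0
    for r in residues:
        if r == GAP or r == UNKNOWN:
            continue
        total += 1
        if r == ref_res:
            agree += 1
    return agree / total if total else math.nan


def domain_identity_summary(
    profile: ConservationProfile,
    annotations: list[DomainAnnotation],
    ref_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-domain (min, max, mean) of each family's conservation fraction.

    An annotation on ``profile.ref1`` selects columns whose ``pos1`` falls in
    its span (likewise ref2/pos2); both families' statistics are summarized
    over those columns.
    """
    records = []
    for ann in annotations:
        if ann.sequence_id == profile.ref1:
            pos_of = lambda r: r.pos1  # noqa: E731
        elif ann.sequence_id == profile.ref2:
            pos_of = lambda r: r.pos2  # noqa: E731
        else:
            raise ValueError(
                f"annotation on {ann.sequence_id!r} does not refer to a "
                f"profile reference ({profile.ref1!r}, {profile.ref2!r})"
            )
        max_pos = max(
            (pos_of(r) for r in profile.rows if pos_of(r) is not None),
            default=0,
        )
        if ann.end > max_pos:
            raise IndexError(
                f"domain {ann.domain.value} [{ann.start},{ann.end}] exceeds "
                f"reference length {max_pos}"
            )
        selected = [
            r for r in profile.rows
            if pos_of(r) is not None and ann.start <= pos_of(r) <= ann.end
        ]
        for which in ("cons1", "cons2"):
            vals = [getattr(r, which) for r in selected]
            vals = [v for v in vals if not math.isnan(v)]
            records.append(
                {
                    "reference": ann.sequence_id,
                    "domain": ann.domain.value,
                    "statistic": which,
                    "n_cols": len(vals),
                    "min": min(vals) if vals else math.nan,
                    "max": max(vals) if vals else math.nan,
                    "mean": sum(vals) / len(vals) if vals else math.nan,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

def profile_to_tsv(profile: ConservationProfile, path, header_comment: str = "") -> None:
    """Write the profile as TSV; conservation reported as percent in [0,100]."""
    if not profile.rows:
        raise ValueError("profile is empty")
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# ref1={profile.ref1}\tref2={profile.ref2}\n")
        fh.write("col\tpos1\tpos2\tres1\tres2\tmatch\tcons1_pct\tcons2_pct\n")
        for r in profile.rows:
            fh.write(
                "\t".join(
                    [
                        str(r.col),
                        "NA" if r.pos1 is None else str(r.pos1),
                        "NA" if r.pos2 is None else str(r.pos2),
                        r.res1,
                        r.res2,
                        "NA" if r.match is None else str(int(r.match)),
                        "NA" if math.isnan(r.cons1) else f"{100 * r.cons1:.4f}",
                        "NA" if math.isnan(r.cons2) else f"{100 * r.cons2:.4f}",
                    ]
                )
                + "\n"
            )


def profile_from_tsv(path) -> ConservationProfile:
    ref1 = ref2 = ""
    rows: list[ProfileRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# ref1="):
                fields = dict(p.split("=", 1) for p in line[2:].split("\t"))
                ref1, ref2 = fields["ref1"], fields["ref2"]
                continue
            if line.startswith("#") or line.startswith("col\t") or not line:
                continue
            f = line.split("\t")
            rows.append(
                ProfileRow(
                    col=int(f[0]),
                    pos1=None if f[1] == "NA" else int(f[1]),
                    pos2=None if f[2] == "NA" else int(f[2]),
                    res1=f[3],
                    res2=f[4],
                    match=None if f[5] == "NA" else bool(int(f[5])),
                    cons1=math.nan if f[6] == "NA" else float(f[6]) / 100.0,
                    cons2=math.nan if f[7] == "NA" else float(f[7]) / 100.0,
                )
            )
    return ConservationProfile(rows, ref1, ref2)
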
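"""seqio: parsing, coordinate maps, and global alignment vs brute force."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paraloglens.records import (
    Alignment,
    Domain,
    DomainAnnotation,
    Isoform,
    SequenceRecord,
)
from paraloglens.seqio import (
    alignment_identity,
    extract_domain,
    global_align,
    load_matrix,
    read_alignment,
    read_fasta,
    read_isoform_map,
    write_alignment,
    write_fasta,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# FASTA / side-car map
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACDE\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "s1"
        assert recs[0].residues == "ACDE"
        assert recs[0].isoform is Isoform.OTHER

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.warns(UserWarning):
            assert read_fasta(p) == []

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">s1\nACDE\n>s1\nACDF\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_sidecar_map_fills_labels(self, tmp_path):
        fasta = tmp_path / "a.fasta"
        fasta.write_text(">s1\nACDE\n>s2\nACDF\n")
        tsv = tmp_path / "map.tsv"
        tsv.write_text("seq_id\tspecies\tisoform\ns1\thuman\tISO1\n")
        recs = read_fasta(fasta, tsv)
        assert recs[0].species == "human"
        assert recs[0].isoform is Isoform.ISO1
        assert recs[1].isoform is Isoform.OTHER

    def test_bad_isoform_label_rejected(self, tmp_path):
        tsv = tmp_path / "map.tsv"
        tsv.write_text("s1\thuman\tEPAC9\n")
        with pytest.raises(ValueError, match="unknown isoform"):
            read_isoform_map(tsv)

    def test_roundtrip(self, tmp_path):
        recs = [
            SequenceRecord("s1", "ACDEFGHIKLMNPQRSTVWY" * 5, description="x y"),
            SequenceRecord("s2", "MKV"),
        ]
        p = tmp_path / "out.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.residues, r.description) for r in back] == [
            (r.id, r.residues, r.description) for r in recs
        ]


class TestReadAlignment:
    def test_fasta(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nAC-E\n>b\nACDE\n")
        aln = read_alignment(p, "fasta")
        assert aln.n_cols == 4
        assert aln.row("a") == "AC-E"

    def test_ragged_lengths_named(self, tmp_path):
        p = tmp_path / "aln.fasta"
        p.write_text(">a\nACE\n>b\nACDE\n")
        with pytest.raises(ValueError, match="ragged.*'b'"):
            read_alignment(p, "fasta")

    def test_all_gap_column_rejected(self):
        with pytest.raises(ValueError, match="all-gap"):
            Alignment(["a", "b"], ["A-C", "A-C"])

    def test_clustal_matches_fasta(self, tmp_path):
        aln = Alignment(["a", "b"], ["AC-E", "ACDE"])
        fa, cl = tmp_path / "x.fasta", tmp_path / "x.aln"
        write_alignment(aln, fa, "fasta")
        write_alignment(aln, cl, "clustal")
        from_fa = read_alignment(fa, "fasta")
        from_cl = read_alignment(cl, "clustal")
        assert from_fa.ids == from_cl.ids
        assert from_fa.rows == from_cl.rows


# ---------------------------------------------------------------------------
# Coordinate maps
# ---------------------------------------------------------------------------

class TestCoordinates:
    @pytest.mark.parametrize(
        "col,expected", [(1, 1), (2, None), (3, 2), (4, 3)]
    )
    def test_hand_counted(self, col, expected):
        aln = Alignment(["r", "q"], ["A-CD", "AXCD"])
        assert aln.col_to_residue("r", col) == expected

    def test_out_of_range(self):
        aln = Alignment(["r", "q"], ["A-CD", "AXCD"])
        with pytest.raises(IndexError):
            aln.col_to_residue("r", 5)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.sampled_from(AA + "-"), min_size=4, max_size=30))
    def test_roundtrip_bijection(self, chars):
        row = "".join(chars)
        if set(row) == {"-"}:
            row = "A" + row[1:]
        ungapped = row.replace("-", "")
        if not ungapped:
            return
        aln = Alignment(["r", "pad"], [row, "A" * len(row)])
        for col in range(1, aln.n_cols + 1):
            res = aln.col_to_residue("r", col)
            if res is not None:
                assert aln.residue_to_col("r", res) == col
        for res in range(1, len(ungapped) + 1):
            assert aln.col_to_residue("r", aln.residue_to_col("r", res)) == res


# ---------------------------------------------------------------------------
# Domain extraction
# ---------------------------------------------------------------------------

class TestExtractDomain:
    def test_interior_and_whole(self):
        rec = SequenceRecord("s", "ACDEFG")
        sub = extract_domain(rec, DomainAnnotation("s", Domain.RA, 2, 4))
        assert sub.residues == "CDE"
        assert sub.id == "s_RA"
        whole = extract_domain(rec, DomainAnnotation("s", Domain.GEF, 1, 6))
        assert whole.residues == "ACDEFG"

    def test_out_of_range(self):
        rec = SequenceRecord("s", "ACDEFG")
        with pytest.raises(IndexError):
            extract_domain(rec, DomainAnnotation("s", Domain.RA, 5, 9))


# ---------------------------------------------------------------------------
# Global alignment
# ---------------------------------------------------------------------------

def brute_force_global_score(a, b, matrix, gap_open, gap_extend):
    """Enumerate every global alignment path; affine gap = open + (L-1)*ext."""
    best = -np.inf

    def recurse(i, j, score, last):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if last == "u" else gap_open
            recurse(i + 1, j, score - cost, "u")
        if j < len(b):
            cost = gap_extend if last == "l" else gap_open
            recurse(i, j + 1, score - cost, "l")

    recurse(0, 0, 0.0, "m")
    return best


class TestGlobalAlign:
    def test_identity_case(self):
        seq = "ACDEFGHIK"
        rec = SequenceRecord("s", seq)
        res = global_align(rec, rec)
        assert res.identity_pct == 100.0
        mat = load_matrix("BLOSUM62")
        assert res.score == sum(mat[c, c] for c in seq)

    def test_single_mismatch(self):
        res = global_align(SequenceRecord("a", "ACDE"), SequenceRecord("b", "ACDF"))
        assert res.identity_pct == pytest.approx(75.0)

    def test_unknown_matrix_name(self):
        with pytest.raises(ValueError, match="unknown substitution matrix"):
            global_align(
                SequenceRecord("a", "ACDE"), SequenceRecord("b", "ACDF"),
                matrix="NOTAMATRIX",
            )

    def test_x_excluded_from_identity(self):
        ident, compared, pct = alignment_identity("AXCD", "AXCD")
        assert (ident, compared) == (3, 3)
        assert pct == 100.0

    def test_score_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        mat = load_matrix("BLOSUM62")
        for _ in range(200):
            la, lb = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            a = "".join(rng.choice(list(AA), la))
            b = "".join(rng.choice(list(AA), lb))
            res = global_align(SequenceRecord("a", a), SequenceRecord("b", b))
            expected = brute_force_global_score(a, b, mat, 10.0, 0.5)
            assert res.score == pytest.approx(expected), (a, b)

    def test_identity_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = "".join(rng.choice(list(AA), int(rng.integers(5, 30))))
            b = "".join(rng.choice(list(AA), int(rng.integers(5, 30))))
            fwd = global_align(SequenceRecord("a", a), SequenceRecord("b", b))
            rev = global_align(SequenceRecord("b", b), SequenceRecord("a", a))
            assert fwd.identity_pct == pytest.approx(rev.identity_pct)

    def test_degapped_alignment_reproduces_inputs(self):
        a, b = "MKVLAT", "MKLT"
        res = global_align(SequenceRecord("a", a), SequenceRecord("b", b))
        assert res.aligned_a.replace("-", "") == a
        assert res.aligned_b.replace("-", "") == b
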
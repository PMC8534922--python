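# External reference data (user-supplied)

Two acceptance checks compare this package's output against published
figures for the EPAC paralog family (EPAC1/RAPGEF3 and EPAC2/RAPGEF4).
They need real protein sequences, which the library never downloads
itself.  Place the following files in this directory to enable them:

## 1. `epac_references.fasta` + `epac_domains.tsv`

Four full-length protein sequences fetched once from UniProt/NCBI, with
these exact FASTA ids:

    EPAC1_human      (human RAPGEF3, UniProt O95398)
    EPAC1_zebrafish  (zebrafish rapgef3)
    EPAC2_human      (human RAPGEF4, UniProt Q8WZA2)
    EPAC2_zebrafish  (zebrafish rapgef4)

`scripts/fetch_references.py` downloads and renames them given the four
accessions.  `epac_domains.tsv` gives the CBD-B and GEF domain spans per
sequence (tab-separated: seq_id, domain, start, end — 1-based inclusive),
e.g. taken from the UniProt feature annotations:

    seq_id	domain	start	end
    EPAC1_human	CBD_B	169	281
    EPAC1_human	GEF	620	868
    ...

## 2. `epac_orthologs_msa.fasta` + `epac_orthologs_map.tsv`

A user-built multiple sequence alignment of EPAC1 and EPAC2 orthologs
from several species (e.g. aligned with MAFFT), containing sequences
named `EPAC1_human` and `EPAC2_human`, plus the side-car isoform map
(seq_id, species, isoform with isoform in ISO1/ISO2).  This enables the
best-effort motif-coordinate check; its outcome depends on the ortholog
set chosen.
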
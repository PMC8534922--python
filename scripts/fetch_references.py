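#!/usr/bin/env python
"""One-time helper: download the four EPAC reference sequences from UniProt.

Usage:
    python scripts/fetch_references.py \
        --epac1-human O95398 --epac2-human Q8WZA2 \
        --epac1-zebrafish <accession> --epac2-zebrafish <accession> \
        --out data/external/epac_references.fasta

Requires network access; the library itself never fetches anything.
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

UNIPROT_FASTA = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def fetch(accession: str) -> str:
    with urllib.request.urlopen(UNIPROT_FASTA.format(acc=accession)) as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    for name in ("epac1-human", "epac1-zebrafish",
                 "epac2-human", "epac2-zebrafish"):
        parser.add_argument(f"--{name}", required=True,
                            help=f"UniProt accession for {name}")
    parser.add_argument("--out", type=Path,
                        default=Path("data/external/epac_references.fasta"))
    args = parser.parse_args()

    out_lines: list[str] = []
    for name in ("epac1_human", "epac1_zebrafish",
                 "epac2_human", "epac2_zebrafish"):
        accession = getattr(args, name)
        text = fetch(accession)
        seq = "".join(
            line.strip() for line in text.splitlines() if not line.startswith(">")
        )
        iso, species = name.split("_")
        out_lines.append(f">{iso.upper()}_{species} {accession}")
        out_lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text("\n".join(out_lines) + "\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
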
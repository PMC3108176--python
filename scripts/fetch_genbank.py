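#!/usr/bin/env python
"""Fetch the published marine-fish COI survey (GenBank EF607296-EF607616).

Downloads the 321 barcode sequences, builds ``sequences.fasta`` and a
``taxonomy.tsv`` skeleton (species parsed from the GenBank definition lines;
genus derived from the binomial; family/order/class left blank for manual or
programmatic completion from a fish taxonomy source), into the directory
given on the command line:

    python scripts/fetch_genbank.py data/real

Network access to NCBI E-utilities is required.  The analysis pipeline and
its acceptance checks consume only the resulting FASTA + TSV pair; this
helper is the one place that touches the network.
"""

from __future__ import annotations

import csv
import sys
import time
from pathlib import Path

from Bio import Entrez, SeqIO

ACCESSIONS = [f"EF{n}" for n in range(607296, 607617)]
BATCH = 100

Entrez.email = "anonymous@example.org"  # set your own address per NCBI policy


def main(out_dir: str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for start in range(0, len(ACCESSIONS), BATCH):
        batch = ACCESSIONS[start:start + BATCH]
        with Entrez.efetch(db="nucleotide", id=",".join(batch),
                           rettype="gb", retmode="text") as handle:
            records.extend(SeqIO.parse(handle, "genbank"))
        time.sleep(0.4)  # NCBI rate limit

    fasta_path = out / "sequences.fasta"
    taxonomy_path = out / "taxonomy.tsv"
    with open(fasta_path, "w") as fasta, open(taxonomy_path, "w", newline="") as tsv:
        writer = csv.writer(tsv, delimiter="\t")
        writer.writerow(["record_id", "species", "genus", "family", "order",
                         "class", "accession"])
        for rec in records:
            organism = rec.annotations.get("organism", "")
            genus = organism.split()[0] if organism else ""
            lineage = rec.annotations.get("taxonomy", [])
            fasta.write(f">{rec.id}\n{rec.seq}\n")
            family = next((t for t in lineage if t.endswith("idae")), "")
            order = next((t for t in lineage if t.endswith("iformes")), "")
            writer.writerow([rec.id, organism, genus, family, order,
                             "Actinopterygii", rec.name])
    print(f"wrote {len(records)} records to {fasta_path} and {taxonomy_path}")


if __name__ == "__main__":
    if len(sys.argv) != 2:
        sys.exit(__doc__)
    main(sys.argv[1])
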
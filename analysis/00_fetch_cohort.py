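#!/usr/bin/env python
"""Fetch the published capuchin-monkey MHC class I cohort from GenBank.

Requires internet access (NCBI E-utilities). Downloads accessions
KM219732-KM219782 — the 12-individual Cebus albifrons population: 29 unique
MHC-G-like and 22 unique MHC-B full-length cDNAs — aligns each locus class
with mafft (the cDNAs are same-length and nearly indel-free, so this is a
formality), tags each record with its individual, and writes

    data/genbank/cebus_mhc_g.fasta
    data/genbank/cebus_mhc_b.fasta

which the cohort-reproduction acceptance tests and 05_reproduce_cohort.py
consume. Individual tags are taken from the GenBank isolate/clone
qualifiers; records whose qualifiers do not identify the animal must be
tagged by hand (header format: name|individual).
"""

import subprocess
import sys
import time
import urllib.request
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "data" / "genbank"
EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = [f"KM219{n}" for n in range(732, 783)]


def fetch(acc: str) -> str:
    url = f"{EUTILS}?db=nuccore&id={acc}&rettype=gb&retmode=text"
    with urllib.request.urlopen(url, timeout=30) as fh:
        return fh.read().decode()


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    raw = OUT / "raw"
    raw.mkdir(exist_ok=True)
    for acc in ACCESSIONS:
        target = raw / f"{acc}.gb"
        if target.exists():
            continue
        print(f"fetching {acc}", file=sys.stderr)
        target.write_text(fetch(acc))
        time.sleep(0.4)  # NCBI rate limit

    from Bio import SeqIO

    g_records, b_records = [], []
    for acc in ACCESSIONS:
        rec = SeqIO.read(raw / f"{acc}.gb", "genbank")
        desc = rec.description
        source = next(f for f in rec.features if f.type == "source")
        individual = (
            source.qualifiers.get("isolate", source.qualifiers.get("clone", ["?"]))[0]
        ).replace(" ", "_")
        name = desc.split(" ")[-1].rstrip(".") or acc
        header = f"{name}|{individual}"
        entry = (header, str(rec.seq).upper())
        # locus class from the definition line
        if "-G" in desc or "G-like" in desc:
            g_records.append(entry)
        else:
            b_records.append(entry)

    for fname, records in (("cebus_mhc_g_unaligned.fasta", g_records), ("cebus_mhc_b_unaligned.fasta", b_records)):
        with open(OUT / fname, "w") as fh:
            for header, seq in records:
                fh.write(f">{header}\n{seq}\n")
    for stem in ("cebus_mhc_g", "cebus_mhc_b"):
        with open(OUT / f"{stem}.fasta", "w") as fh:
            subprocess.run(
                ["mafft", "--auto", str(OUT / f"{stem}_unaligned.fasta")],
                stdout=fh, check=True,
            )
    print(f"wrote {len(g_records)} MHC-G-like and {len(b_records)} MHC-B cDNAs under {OUT}")


if __name__ == "__main__":
    main()
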
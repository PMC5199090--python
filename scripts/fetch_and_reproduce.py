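#!/usr/bin/env python
"""One-time GenBank fetch and published-table reproduction (needs network).

Downloads the deposited orang-utan control-region haplotypes and the
published complete sequences, extracts the control region from whole-genome
records, de-duplicates at full-control-region resolution (one novel
haplotype matches the published genome X97708 and is dropped, leaving the
35 novel + 3 published = 38-sequence panel), aligns with mafft, and stores:

    data/genbank_cr_raw.fasta       de-duplicated unaligned control regions
    data/genbank_cr_aligned.fasta   the 38-sequence mafft alignment

It then prints the diversity table across the registered segments and the
delimited hypervariable regions.  Re-running is idempotent.  The stored
alignment is what tests/test_acceptance.py's published-table test and the
optional block of scripts/acceptance.py consume.

Usage:  python scripts/fetch_and_reproduce.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import subprocess
import sys
import tempfile
import time
import urllib.parse
import urllib.request
from pathlib import Path

import ctrlregion as cr

REPO = Path(__file__).resolve().parent.parent
DATA = REPO / "data"

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"

NOVEL = [f"KX4275{i}" for i in range(42, 75)] + [
    "KU523975", "KU523976", "KU523977"]
PUBLISHED_GENOMES = ["X97707", "X97708", "X97709"]
PUBLISHED_CR = ["X98472"]
#: control region span on the X97707 complete genome
CR_SPAN = (15484, 16499)


def efetch(accessions: list[str], email: str) -> dict[str, str]:
    q = urllib.parse.urlencode({
        "db": "nucleotide", "id": ",".join(accessions),
        "rettype": "fasta", "retmode": "text", "email": email,
    })
    with urllib.request.urlopen(f"{EUTILS}?{q}", timeout=120) as fh:
        text = fh.read().decode()
    time.sleep(0.4)  # NCBI rate courtesy
    out: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0].split(".")[0]
            out[name] = ""
        elif name:
            out[name] += line.strip()
    return out


def extract_cr(seq: str, reference_cr: str) -> str:
    """Best infix match of the reference control region in a longer record."""
    import edlib

    res = edlib.align(reference_cr, seq.upper(), task="locations", mode="HW")
    start, end = res["locations"][0]
    return seq[start : end + 1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", default="anonymous@example.org",
                    help="contact email passed to NCBI E-utilities")
    args = ap.parse_args()

    DATA.mkdir(exist_ok=True)
    print(f"fetching {len(NOVEL)} novel + "
          f"{len(PUBLISHED_GENOMES) + len(PUBLISHED_CR)} published records...")
    seqs = efetch(NOVEL, args.email)
    pub = efetch(PUBLISHED_GENOMES + PUBLISHED_CR, args.email)
    missing = [a for a in NOVEL if a not in seqs]
    if missing:
        sys.exit(f"missing accessions from fetch: {missing}")

    ref_cr = pub["X97707"][CR_SPAN[0] - 1 : CR_SPAN[1]]
    published_cr: dict[str, str] = {}
    for acc in ("X97707", "X97709"):
        published_cr[acc] = extract_cr(pub[acc], ref_cr)
    published_cr["X98472"] = (
        pub["X98472"] if len(pub["X98472"]) < 2000
        else extract_cr(pub["X98472"], ref_cr)
    )
    x97708_cr = extract_cr(pub["X97708"], ref_cr)

    # novel records may carry flanking coding bases: keep the CR portion
    novel_cr: dict[str, str] = {}
    for acc, s in seqs.items():
        novel_cr[acc] = s if len(s) < 1200 else extract_cr(s, ref_cr)

    # de-duplicate at full-CR resolution: drop novel sequences identical to
    # the published X97708 control region (haplotype S4), then any
    # identical novel pair (keep the first accession)
    seen: set[str] = {x97708_cr.upper()}
    records: list[cr.SeqRecord] = []
    dropped: list[str] = []
    for acc in NOVEL:
        s = novel_cr[acc].upper()
        if s in seen:
            dropped.append(acc)
            continue
        seen.add(s)
        records.append(cr.SeqRecord(acc, s))
    print(f"dropped as duplicates at CR resolution: {dropped or 'none'}")
    for acc, s in published_cr.items():
        records.append(cr.SeqRecord(acc, s.upper()))
    print(f"panel size: {len(records)} (expected 38)")

    raw_path = DATA / "genbank_cr_raw.fasta"
    cr.write_fasta(records, raw_path)

    with tempfile.TemporaryDirectory() as td:
        out = Path(td) / "aligned.fasta"
        with open(out, "w") as fh:
            subprocess.run(
                ["mafft", "--auto", "--inputorder", str(raw_path)],
                stdout=fh, check=True,
            )
        aligned = cr.read_fasta(out)
    aln_path = DATA / "genbank_cr_aligned.fasta"
    cr.write_fasta(
        [cr.SeqRecord(r.id, r.sequence) for r in aligned], aln_path)
    aln = cr.read_alignment(aln_path)
    print(f"alignment: {aln.n_records} sequences x {aln.n_cols} columns\n")

    specs = [cr.get_segment(n) for n in cr.segment_names()]
    print(cr.diversity.segment_diversity_table(aln, specs).to_string(
        index=False))
    full = cr.diversity_summary(aln)
    print(f"\ncomplete CR: sites={full.n_sites_analyzed} h={full.h} "
          f"S={full.S} ({full.eta}) k={full.k:.3f}")
    regions = cr.delimit_regions(cr.window_profile(aln), aln)
    for r in regions.hypervariable:
        print(f"hypervariable interval: columns {r.start}-{r.end}")


if __name__ == "__main__":
    main()
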
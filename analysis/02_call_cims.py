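#!/usr/bin/env python
"""Call crosslink-induced mutations (CIMs) from the wild-type IP library.

Reads the simulated coverage and C->T mismatch bedGraphs, applies the hard
filter (m > 1, 0.01 < m/k < 0.5, A-then-C reference context on the
transcript strand), and reports recovery against the planted-site registry.
"""

import argparse
from pathlib import Path

import pandas as pd

from flym6a.cims_calling import CimFilterParams, TagPileup, call_cims
from flym6a.io_formats import (
    BedRecord,
    read_fasta,
    read_transcript_models,
    read_tsv_table,
    write_bed,
    write_tsv_table,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=ROOT / "scratch" / "sim")
    args = ap.parse_args()

    genome = read_fasta(args.simdir / "genome.fa")
    models = read_transcript_models(args.simdir / "models.gtf")
    pileup = TagPileup.from_bedgraphs(
        "wt_ip",
        args.simdir / "wt_ip.coverage.bedgraph",
        args.simdir / "wt_ip.ct_mismatch.bedgraph",
        genome.lengths(),
    )
    sites = call_cims(pileup, genome, CimFilterParams(), models=models)

    registry = read_tsv_table(
        args.simdir / "planted_sites.tsv",
        {"contig": str, "cim_pos": int, "dependence": str},
    )
    planted = set(zip(registry["contig"], registry["cim_pos"]))
    n_hit = sum((s.contig, s.cim_pos) in planted for s in sites)
    print(f"called {len(sites)} CIMs; {n_hit} coincide with the "
          f"{len(planted)} planted sites "
          f"(sensitivity {n_hit / len(planted):.1%}, "
          f"precision {n_hit / len(sites):.1%})")

    df = pd.DataFrame(
        {
            "contig": [s.contig for s in sites],
            "cim_pos": [s.cim_pos for s in sites],
            "m6a_pos": [s.m6a_pos for s in sites],
            "strand": [s.strand for s in sites],
            "m": [s.m for s in sites],
            "k": [s.k for s in sites],
            "ratio": [round(s.ratio, 4) for s in sites],
        }
    )
    (ROOT / "results").mkdir(exist_ok=True)
    write_tsv_table(df, ROOT / "results" / "cims.tsv")
    write_bed(
        [
            BedRecord(s.contig, s.cim_pos, s.cim_pos + 1,
                      name=f"m{s.m}_k{s.k}", score=round(1000 * s.ratio),
                      strand=s.strand)
            for s in sites
        ],
        ROOT / "results" / "cims.bed",
    )
    print(f"tables -> results/cims.tsv, results/cims.bed")


if __name__ == "__main__":
    main()
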
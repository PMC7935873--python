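#!/usr/bin/env python
"""Sequence context of CIMs inside the top writer-dependent peaks.

Builds the position frequency matrix around the methylated A for CIMs in
the top-1000 dependent peaks and reports the IUPAC consensus, which should
read out the planted AAACT context.
"""

import argparse
from pathlib import Path

from flym6a.cims_calling import CimSite
from flym6a.io_formats import read_fasta, read_tsv_table, write_tsv_table
from flym6a.motif_context import consensus, extract_contexts, frequency_matrix
from flym6a.peak_analysis import Peak

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=ROOT / "scratch" / "sim")
    ap.add_argument("--n-top", type=int, default=1000)
    ap.add_argument("--flank", type=int, default=5)
    args = ap.parse_args()

    genome = read_fasta(args.simdir / "genome.fa")
    cims_df = read_tsv_table(
        ROOT / "results" / "cims.tsv",
        {"contig": str, "cim_pos": int, "m6a_pos": int, "strand": str,
         "m": int, "k": int},
    )
    cims = [
        CimSite(r.contig, int(r.cim_pos), int(r.m6a_pos), r.strand,
                int(r.m), int(r.k))
        for r in cims_df.itertuples()
    ]
    peaks_df = read_tsv_table(
        ROOT / "results" / "peaks.tsv",
        {"contig": str, "start": int, "end": int, "label": str, "score": float},
    )
    peaks = [
        Peak(r.contig, int(r.start), int(r.end), float(r.score),
             int(r.start), r.label)
        for r in peaks_df.itertuples()
    ]
    from flym6a.cims_calling import cims_in_top_peaks

    top = cims_in_top_peaks(cims, peaks, args.n_top)
    contexts, dropped = extract_contexts(top, genome, args.flank)
    matrix = frequency_matrix(contexts)
    cons = consensus(matrix, min_freq=0.2)
    center = args.flank
    print(f"{len(top)} CIMs in the top {args.n_top} dependent peaks "
          f"({dropped} dropped at contig edges)")
    print(f"consensus ({-args.flank}..+{args.flank}, 0 = methylated A): {cons}")
    print(f"core at -2..+1: {cons[center - 2:center + 2]}")

    out = matrix.to_frame().round(4).reset_index(names="base")
    write_tsv_table(out, ROOT / "results" / "cim_context_matrix.tsv")
    print("matrix -> results/cim_context_matrix.tsv")


if __name__ == "__main__":
    main()
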
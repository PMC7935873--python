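#!/usr/bin/env python
"""Metagene profiles of miCLIP and input signal over methylated genes.

Projects each gene's longest transcript onto the fixed 1500-bin metagene
(5'UTR 200, CDS 1000, 3'UTR 300 bins), normalizes per gene, and averages
over the genes that carry writer-dependent peaks.  Also builds the
peak-centered heatmap matrix (body rescaled to 200 bins, 500-nt flanks).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from flym6a.cims_calling import TagPileup
from flym6a.io_formats import (
    SignalTrack,
    read_fasta,
    read_transcript_models,
    read_tsv_table,
    write_tsv_table,
)
from flym6a.metagene import aggregate_metagene, ratio_profile
from flym6a.peak_analysis import Peak, PeakParams, peak_matrix

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", type=Path, default=ROOT / "scratch" / "sim")
    args = ap.parse_args()

    genome = read_fasta(args.simdir / "genome.fa")
    sizes = genome.lengths()
    models = read_transcript_models(args.simdir / "models.gtf")
    ip_pile = TagPileup.from_bedgraphs(
        "wt_ip", args.simdir / "wt_ip.coverage.bedgraph",
        args.simdir / "wt_ip.ct_mismatch.bedgraph", sizes)
    in_pile = TagPileup.from_bedgraphs(
        "wt_input", args.simdir / "wt_input.coverage.bedgraph",
        args.simdir / "wt_input.ct_mismatch.bedgraph", sizes)
    ip = SignalTrack({c: a.astype(float) for c, a in ip_pile.coverage.items()})
    inp = SignalTrack({c: a.astype(float) for c, a in in_pile.coverage.items()})

    peaks_df = read_tsv_table(
        ROOT / "results" / "peaks.tsv",
        {"contig": str, "start": int, "end": int, "label": str, "score": float,
         "summit": int},
    )
    dep = peaks_df[peaks_df["label"] == "dependent"]
    span = {m.gene_id: (m.contig, *m.span) for m in models}
    target_genes = sorted(
        g for g, (c, s, e) in span.items()
        if ((dep["contig"] == c) & (dep["start"] < e) & (dep["end"] > s)).any()
    )
    print(f"{len(target_genes)} genes carry writer-dependent peaks")

    prof_ip, prof_in = aggregate_metagene(ip, inp, models, target_genes)
    df = prof_ip.to_frame().rename(columns={"value": "ip"})
    df["input"] = prof_in.to_frame()["value"]
    df["ip_over_input"] = np.round(ratio_profile(prof_ip, prof_in), 4)
    df["ip"] = df["ip"].round(6)
    df["input"] = df["input"].round(6)
    write_tsv_table(df, ROOT / "results" / "metagene.tsv")

    utr5_share = df.loc[df["segment"] == "utr5", "ip"].sum()
    print(f"metagene over {prof_ip.n_genes} genes: "
          f"{utr5_share:.1%} of IP signal mass in the 5'UTR bins "
          f"(input: {df.loc[df['segment'] == 'utr5', 'input'].sum():.1%})")

    dep_peaks = [
        Peak(r.contig, int(r.start), int(r.end), float(r.score),
             int(r.summit), "dependent")
        for r in dep.itertuples()
    ]
    mat = peak_matrix(dep_peaks, ip_pile, in_pile, PeakParams())
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    np.savetxt(scratch / "peak_heatmap_matrix.tsv", mat, delimiter="\t", fmt="%.4g")
    body = np.nanmean(mat[:, 50:250])
    flank = np.nanmean(np.concatenate([mat[:, :50], mat[:, 250:]], axis=1))
    print(f"heatmap matrix {mat.shape}: mean body enrichment {body:.2f}x vs "
          f"flank {flank:.2f}x -> scratch/peak_heatmap_matrix.tsv")
    print("profile -> results/metagene.tsv")


if __name__ == "__main__":
    main()
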
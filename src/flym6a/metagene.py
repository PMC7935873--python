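"""Metagene profiles over a fixed 1500-bin transcript coordinate system.

Per-transcript signal is lifted from genomic to mature-transcript
coordinates, each of the 5'UTR / CDS / 3'UTR segments is independently
rescaled to 200 / 1000 / 300 bins by area-preserving piecewise-constant
resampling, the 1500-vector is normalized to sum 1, and gene sets are
aggregated by the arithmetic mean of per-gene vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io_formats import SignalTrack, TranscriptModel, longest_by_gene

SEGMENT_NAMES = ("utr5", "cds", "utr3")


@dataclass
class MetageneConfig:
    seg_bins: Tuple[int, int, int] = (200, 1000, 300)
    min_total: float = 0.0  # transcripts with total signal <= this are skipped

    def __post_init__(self):
        if any(b <= 0 for b in self.seg_bins):
            raise ValueError("seg_bins must be positive")

    @property
    def n_bins(self) -> int:
        return sum(self.seg_bins)

    def segment_labels(self) -> np.ndarray:
        labels = []
        for name, n in zip(SEGMENT_NAMES, self.seg_bins):
            labels.extend([name] * n)
        return np.array(labels)


@dataclass
class MetageneProfile:
    """Aggregate 1500-bin profile: mean of per-gene normalized vectors."""

    values: np.ndarray
    n_genes: int
    config: MetageneConfig = field(default_factory=MetageneConfig)
    per_gene: Optional[pd.DataFrame] = None  # rows = genes, cols = bins

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(self.config.n_bins),
                "segment": self.config.segment_labels(),
                "value": self.values,
            }
        )


def resample_mean(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Rescale a piecewise-constant signal to ``n_bins`` per-bin means.

    The original positions are partitioned linearly into ``n_bins``
    fractional windows; each output bin is the length-weighted mean of the
    signal over its window (area-preserving: a uniform input stays uniform,
    and the overall mean is unchanged for any length ratio).
    """
    values = np.asarray(values, dtype=float)
    L = values.size
    if L == 0:
        raise ValueError("cannot resample an empty signal")
    edges = np.linspace(0.0, L, n_bins + 1)
    cum = np.concatenate(([0.0], np.cumsum(values)))
    cum_at = np.interp(edges, np.arange(L + 1), cum)
    widths = np.diff(edges)
    return np.diff(cum_at) / widths


def transcript_signal(track: SignalTrack, model: TranscriptModel) -> np.ndarray:
    """Lift a genomic track to mature-transcript coordinates (5'->3',
    exon-only; minus-strand transcripts read the track right-to-left)."""
    arr = track[model.contig]
    span0, span1 = model.span
    if span1 > arr.size:
        raise ValueError(f"{model.transcript_id} extends past contig end")
    return arr[model.genomic_positions()]


def scale_to_metagene(
    signal: np.ndarray,
    model: TranscriptModel,
    cfg: Optional[MetageneConfig] = None,
) -> Optional[np.ndarray]:
    """Per-gene normalized 1500-vector, or None when the transcript is
    skipped (no annotated UTR on either side, or total signal below the
    threshold)."""
    cfg = cfg or MetageneConfig()
    utr5, cds, utr3 = model.segment_lengths()
    if utr5 == 0 or cds == 0 or utr3 == 0:
        return None
    signal = np.asarray(signal, dtype=float)
    if signal.size != model.mature_length:
        raise ValueError("signal length does not match mature length")
    if signal.sum() <= cfg.min_total:
        return None
    parts = [
        resample_mean(signal[:utr5], cfg.seg_bins[0]),
        resample_mean(signal[utr5:utr5 + cds], cfg.seg_bins[1]),
        resample_mean(signal[utr5 + cds:], cfg.seg_bins[2]),
    ]
    vec = np.concatenate(parts)
    total = vec.sum()
    if total <= 0:
        return None
    return vec / total


def _profile_for_track(
    track: SignalTrack,
    chosen: Dict[str, TranscriptModel],
    cfg: MetageneConfig,
    keep_per_gene: bool,
) -> MetageneProfile:
    rows, ids = [], []
    for gene_id in sorted(chosen):
        model = chosen[gene_id]
        try:
            vec = scale_to_metagene(transcript_signal(track, model), model, cfg)
        except ValueError:
            vec = None
        if vec is not None:
            rows.append(vec)
            ids.append(gene_id)
    if not rows:
        return MetageneProfile(np.zeros(cfg.n_bins), 0, cfg)
    mat = np.vstack(rows)
    per_gene = pd.DataFrame(mat, index=ids) if keep_per_gene else None
    return MetageneProfile(mat.mean(axis=0), len(ids), cfg, per_gene)


def aggregate_metagene(
    track_ip: SignalTrack,
    track_input: SignalTrack,
    models: Sequence[TranscriptModel],
    gene_set: Optional[Iterable[str]] = None,
    cfg: Optional[MetageneConfig] = None,
    keep_per_gene: bool = False,
) -> Tuple[MetageneProfile, MetageneProfile]:
    """Mean metagene profiles of the IP and input libraries over a gene
    set (default: all genes), using each gene's longest transcript.

    Transcripts are skipped per-library (a gene with zero signal in one
    library still contributes to the other); ``n_genes`` on each profile
    reports how many genes entered that mean.
    """
    cfg = cfg or MetageneConfig()
    chosen = longest_by_gene(models)
    if gene_set is not None:
        wanted = set(gene_set)
        chosen = {g: m for g, m in chosen.items() if g in wanted}
    prof_ip = _profile_for_track(track_ip, chosen, cfg, keep_per_gene)
    prof_in = _profile_for_track(track_input, chosen, cfg, keep_per_gene)
    return prof_ip, prof_in


def ratio_profile(
    prof_ip: MetageneProfile, prof_in: MetageneProfile, eps: float = 1e-9
) -> np.ndarray:
    """Bin-wise IP/input ratio of the two aggregate profiles."""
    return (prof_ip.values + eps) / (prof_in.values + eps)
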
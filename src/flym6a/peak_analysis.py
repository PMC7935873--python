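"""IP-over-input enriched-region calling with a genetic-null control.

The differential comparison is a per-position two-hypothesis Poisson
log-likelihood ratio between the IP and input pileups after scaling the
deeper library down to the shallower one.  Qualifying positions are merged
across gaps of at most ``g`` nt and regions shorter than ``l`` nt are
dropped (g=20, l=120 by default).  Wild-type regions are labeled
*dependent* or *independent* on the writer by how much of their length
stays enriched in the knockout libraries; compound regions are split at
clear local minima between summits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cims_calling import TagPileup
from .io_formats import SignalTrack
from .metagene import resample_mean

LN10 = np.log(10.0)


@dataclass
class PeakParams:
    g: int = 20  # max merge gap, nt
    l: int = 120  # min region length, nt
    llr_cutoff: float = 2.0  # log10 likelihood-ratio threshold
    pseudocount: float = 1.0
    valley_ratio: float = 0.5  # split when valley < ratio x lower summit
    flank: int = 500  # heatmap flank, nt
    dependence_overlap: float = 0.5  # >= this fraction enriched in mutant
    min_child: int = 30  # children shorter than this re-merge
    body_bins: int = 200
    flank_bin: int = 10

    def __post_init__(self):
        if self.g < 0 or self.l <= 0:
            raise ValueError("need g >= 0 and l > 0")
        if self.llr_cutoff <= 0:
            raise ValueError("llr_cutoff must be positive")
        if not 0.0 < self.valley_ratio < 1.0:
            raise ValueError("valley_ratio must be in (0,1)")


@dataclass
class Peak:
    contig: str
    start: int
    end: int
    score: float  # mean log10 LLR over the interval (WT track)
    summit: int  # position of the enrichment maximum
    label: str = "dependent"  # dependent | independent | mutant_only
    gene_ids: List[str] = field(default_factory=list)
    category: str = ""  # transcript-segment annotation, filled later

    @property
    def length(self) -> int:
        return self.end - self.start


def _scale_factors(ip: TagPileup, inp: TagPileup) -> Tuple[float, float]:
    """Scale the deeper library down to the shallower library's total."""
    t_ip, t_in = ip.total_coverage(), inp.total_coverage()
    if t_ip == 0 or t_in == 0:
        raise ValueError("zero-depth library")
    if t_ip > t_in:
        return t_in / t_ip, 1.0
    return 1.0, t_ip / t_in


def enrichment_track(
    ip: TagPileup, inp: TagPileup, params: Optional[PeakParams] = None
) -> SignalTrack:
    """Per-position log10 Poisson likelihood ratio of "IP elevated" over
    "common rate", zero wherever scaled IP does not exceed scaled input.

    With pseudocounted, depth-scaled counts x_ip, x_in the statistic is
    [x_ip ln(x_ip/m) + x_in ln(x_in/m)] / ln 10 with m = (x_ip + x_in)/2,
    the generalized LR for two Poisson observations sharing a rate.
    """
    params = params or PeakParams()
    if set(ip.contigs()) != set(inp.contigs()):
        raise ValueError("IP and input pileups cover different contigs")
    s_ip, s_in = _scale_factors(ip, inp)
    pc = params.pseudocount
    out: Dict[str, np.ndarray] = {}
    for contig in ip.contigs():
        x_ip = s_ip * ip.coverage[contig] + pc
        x_in = s_in * inp.coverage[contig] + pc
        m = 0.5 * (x_ip + x_in)
        llr = (x_ip * np.log(x_ip / m) + x_in * np.log(x_in / m)) / LN10
        llr[x_ip <= x_in] = 0.0
        out[contig] = llr
    return SignalTrack(out)


def call_regions(
    track: SignalTrack, params: Optional[PeakParams] = None
) -> List[Tuple[str, int, int]]:
    """Threshold -> merge -> length-filter.

    Positions with LLR >= cutoff form runs; runs separated by <= g nt are
    merged; merged runs shorter than l nt are discarded.  Output is sorted
    and non-overlapping.
    """
    params = params or PeakParams()
    regions: List[Tuple[str, int, int]] = []
    for contig in sorted(track.contigs()):
        mask = track[contig] >= params.llr_cutoff
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        merged: List[List[int]] = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= params.g:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        for s, e in merged:
            if e - s >= params.l:
                regions.append((contig, s, e))
    return regions


def _region_peak(
    contig: str, start: int, end: int, track: SignalTrack, label: str
) -> Peak:
    window = track[contig][start:end]
    return Peak(
        contig=contig,
        start=start,
        end=end,
        score=float(window.mean()),
        summit=start + int(np.argmax(window)),
        label=label,
    )


def classify_dependence(
    wt_regions: Sequence[Tuple[str, int, int]],
    wt_track: SignalTrack,
    mut_track: SignalTrack,
    params: Optional[PeakParams] = None,
) -> List[Peak]:
    """Label every WT region dependent/independent on the writer.

    A region is *independent* when at least ``dependence_overlap`` of its
    length also passes the LLR cutoff in the mutant track (the signal
    persists without the writer), otherwise *dependent*.  Regions passing
    only in the mutant are appended with label *mutant_only*.
    """
    params = params or PeakParams()
    peaks: List[Peak] = []
    for contig, start, end in wt_regions:
        frac = float(
            np.mean(mut_track[contig][start:end] >= params.llr_cutoff)
        )
        label = "independent" if frac >= params.dependence_overlap else "dependent"
        peaks.append(_region_peak(contig, start, end, wt_track, label))
    wt_by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for contig, start, end in wt_regions:
        wt_by_contig.setdefault(contig, []).append((start, end))
    for contig, start, end in call_regions(mut_track, params):
        overlaps = any(
            start < e and s < end for s, e in wt_by_contig.get(contig, ())
        )
        if not overlaps:
            peaks.append(_region_peak(contig, start, end, mut_track, "mutant_only"))
    peaks.sort(key=lambda p: (p.contig, p.start))
    return peaks


def _find_summits(signal: np.ndarray) -> List[Tuple[int, float]]:
    """Local maxima of a 1-D signal; a plateau counts once, at its
    midpoint.  Endpoints qualify when the signal falls away from them."""
    n = signal.size
    if n == 0:
        return []
    summits: List[Tuple[int, float]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and signal[j + 1] == signal[i]:
            j += 1
        left_lower = i == 0 or signal[i - 1] < signal[i]
        right_lower = j == n - 1 or signal[j + 1] < signal[i]
        if left_lower and right_lower and not (i == 0 and j == n - 1):
            summits.append(((i + j) // 2, float(signal[i])))
        elif i == 0 and j == n - 1:
            summits.append((n // 2, float(signal[i])))
        i = j + 1
    return summits


def split_peaks(
    peaks: Sequence[Peak],
    ip_track: SignalTrack,
    params: Optional[PeakParams] = None,
) -> List[Peak]:
    """Split compound peaks at clear local minima of the raw IP signal.

    Between each pair of adjacent summits, the peak is cut at the valley
    minimum when its value is below ``valley_ratio`` times the lower of
    the two summit heights.  Children inherit the parent label and score;
    children shorter than ``min_child`` nt are re-merged with their taller
    neighbor.  The union of children always equals the parent interval.
    """
    params = params or PeakParams()
    out: List[Peak] = []
    for peak in peaks:
        signal = ip_track[peak.contig][peak.start:peak.end]
        summits = _find_summits(signal)
        cuts: List[int] = []
        for (i0, h0), (i1, h1) in zip(summits, summits[1:]):
            seg = signal[i0:i1 + 1]
            vmin = float(seg.min())
            if vmin < params.valley_ratio * min(h0, h1):
                cuts.append(i0 + int(np.argmin(seg)))
        bounds = [0] + cuts + [peak.length]
        children = [
            [bounds[i], bounds[i + 1]] for i in range(len(bounds) - 1)
        ]
        # re-merge undersized children with the taller neighbor
        while len(children) > 1:
            short = [
                idx
                for idx, (s, e) in enumerate(children)
                if e - s < params.min_child
            ]
            if not short:
                break
            idx = short[0]
            height = lambda c: float(signal[c[0]:c[1]].max())
            if idx == 0:
                nbr = 1
            elif idx == len(children) - 1:
                nbr = idx - 1
            else:
                nbr = idx - 1 if height(children[idx - 1]) >= height(
                    children[idx + 1]
                ) else idx + 1
            lo, hi = sorted((idx, nbr))
            children[lo] = [children[lo][0], children[hi][1]]
            del children[hi]
        for s, e in children:
            sub = signal[s:e]
            out.append(
                Peak(
                    contig=peak.contig,
                    start=peak.start + s,
                    end=peak.start + e,
                    score=peak.score,
                    summit=peak.start + s + int(np.argmax(sub)),
                    label=peak.label,
                    gene_ids=list(peak.gene_ids),
                    category=peak.category,
                )
            )
    out.sort(key=lambda p: (p.contig, p.start))
    return out


def rank_peaks(peaks: Sequence[Peak]) -> List[Peak]:
    """Descending by score; ties broken by (contig, start) so the order is
    independent of input permutation."""
    return sorted(peaks, key=lambda p: (-p.score, p.contig, p.start))


def peak_matrix(
    peaks: Sequence[Peak],
    ip: TagPileup,
    inp: TagPileup,
    params: Optional[PeakParams] = None,
) -> np.ndarray:
    """Heatmap matrix: one row per peak of input-normalized IP signal.

    Each row is 50 upstream flank bins (10-nt, unscaled), 200 peak-body
    bins (body rescaled to fixed width), and 50 downstream flank bins.
    Flank bins falling outside the contig are NaN.  Rows are sorted by
    descending row mean.
    """
    params = params or PeakParams()
    s_ip, s_in = _scale_factors(ip, inp)
    pc = params.pseudocount
    n_flank_bins = params.flank // params.flank_bin
    rows = []
    for peak in peaks:
        cov_ip = ip.coverage[peak.contig]
        cov_in = inp.coverage[peak.contig]
        ratio = (s_ip * cov_ip + pc) / (s_in * cov_in + pc)
        body = resample_mean(ratio[peak.start:peak.end], params.body_bins)

        def flank_bins(lo: int, hi: int) -> np.ndarray:
            vals = np.full(
                ((hi - lo) // params.flank_bin,), np.nan
            )
            for b in range(vals.size):
                s = lo + b * params.flank_bin
                e = s + params.flank_bin
                if s >= 0 and e <= ratio.size:
                    vals[b] = ratio[s:e].mean()
            return vals

        left = flank_bins(peak.start - params.flank, peak.start)
        right = flank_bins(peak.end, peak.end + params.flank)
        assert left.size == right.size == n_flank_bins
        rows.append(np.concatenate([left, body, right]))
    if not rows:
        return np.empty((0, 2 * n_flank_bins + params.body_bins))
    mat = np.vstack(rows)
    order = np.argsort(-np.nanmean(mat, axis=1), kind="stable")
    return mat[order]
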
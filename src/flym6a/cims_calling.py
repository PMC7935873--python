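"""Crosslink-induced mutation (CIM) calling.

Antibody crosslinking in miCLIP leaves a C-to-T transition signature in
reverse-transcribed tags immediately 3' of the methylated adenosine.  A
putative m6A site is a position whose mismatch evidence passes the hard
filter m > 1 and 0.01 < m/k < 0.5 (m = tags with the transition, k = tags
spanning the position), with the reference reading A-then-C in transcript
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np

from .io_formats import GenomeSeq, SignalTrack, read_bedgraph, write_bedgraph


class TagPileup:
    """Per-position unique-tag coverage k and C->T mismatch count m for one
    library, one array pair per contig.  0 <= m[i] <= k[i] everywhere."""

    def __init__(
        self,
        name: str,
        coverage: Mapping[str, np.ndarray],
        mismatches: Mapping[str, np.ndarray],
    ):
        if set(coverage) != set(mismatches):
            raise ValueError("coverage and mismatch contigs differ")
        self.name = name
        self.coverage: Dict[str, np.ndarray] = {}
        self.mismatches: Dict[str, np.ndarray] = {}
        for contig in coverage:
            k = np.asarray(coverage[contig], dtype=np.int64)
            m = np.asarray(mismatches[contig], dtype=np.int64)
            if k.shape != m.shape:
                raise ValueError(f"array length mismatch on {contig!r}")
            if np.any(k < 0) or np.any(m < 0):
                raise ValueError("negative counts")
            if np.any(m > k):
                raise ValueError(
                    f"mismatch count exceeds coverage on {contig!r}"
                )
            self.coverage[contig] = k
            self.mismatches[contig] = m

    def contigs(self) -> List[str]:
        return list(self.coverage)

    def contig_sizes(self) -> Dict[str, int]:
        return {c: arr.size for c, arr in self.coverage.items()}

    def total_coverage(self) -> int:
        return int(sum(arr.sum() for arr in self.coverage.values()))

    def to_bedgraphs(self, coverage_path: str | Path, mismatch_path: str | Path) -> None:
        write_bedgraph(SignalTrack(self.coverage), coverage_path)
        write_bedgraph(SignalTrack(self.mismatches), mismatch_path)

    @classmethod
    def from_bedgraphs(
        cls,
        name: str,
        coverage_path: str | Path,
        mismatch_path: str | Path,
        contig_sizes: Mapping[str, int],
    ) -> "TagPileup":
        cov = read_bedgraph(coverage_path, contig_sizes)
        mis = read_bedgraph(mismatch_path, contig_sizes)
        return cls(name, cov.data, mis.data)


@dataclass
class CimFilterParams:
    """The site filter: m > m_min_exclusive and ratio_lo < m/k < ratio_hi
    (all bounds strict), at reference A-then-C positions."""

    m_min_exclusive: int = 1
    ratio_lo: float = 0.01
    ratio_hi: float = 0.5
    require_ref_c: bool = True
    require_preceding_a: bool = True

    def __post_init__(self):
        if not (0 <= self.ratio_lo < self.ratio_hi <= 1):
            raise ValueError("need 0 <= ratio_lo < ratio_hi <= 1")


@dataclass(frozen=True)
class CimSite:
    """A filtered putative m6A site.

    ``cim_pos`` is the mutated C (0-based genomic), ``m6a_pos`` the
    adjacent A 5' of it in transcript orientation: cim_pos - 1 on the plus
    strand, cim_pos + 1 on the minus strand.
    """

    contig: str
    cim_pos: int
    m6a_pos: int
    strand: str
    m: int
    k: int

    @property
    def ratio(self) -> float:
        return self.m / self.k


def _candidate_mask(
    seq_arr: np.ndarray, strand: str, require_c: bool, require_a: bool
) -> np.ndarray:
    """Positions whose reference context satisfies the sequence clauses on
    ``strand``.

    Plus strand: base C at i with A at i-1.  Minus strand: the C of the
    transcript appears as G on the reference, with the preceding (transcript
    5') A at i+1 appearing as T.
    """
    n = seq_arr.size
    mask = np.ones(n, dtype=bool)
    if strand == "+":
        if require_c:
            mask &= seq_arr == ord("C")
        if require_a:
            prev_a = np.zeros(n, dtype=bool)
            prev_a[1:] = seq_arr[:-1] == ord("A")
            mask &= prev_a
    else:
        if require_c:
            mask &= seq_arr == ord("G")
        if require_a:
            next_t = np.zeros(n, dtype=bool)
            next_t[:-1] = seq_arr[1:] == ord("T")
            mask &= next_t
    return mask


def _transcript_strands(models, sizes: Mapping[str, int]) -> Dict[str, Dict[str, np.ndarray]]:
    """Per contig, boolean masks of positions covered by a transcript of
    each strand (exon spans including introns)."""
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for m in models:
        per = out.setdefault(
            m.contig,
            {s: np.zeros(sizes[m.contig], dtype=bool) for s in "+-"},
        )
        s0, s1 = m.span
        per[m.strand][s0:s1] = True
    return out


def call_cims(
    pileup: TagPileup,
    genome: GenomeSeq,
    params: CimFilterParams | None = None,
    models=None,
) -> List[CimSite]:
    """Call CIMs from one library's pileup.

    Returns every position satisfying all filter clauses, on either strand
    (at most one site per strand per position), sorted by
    (contig, cim_pos, strand).  Because pileups are unstranded, passing
    ``models`` assigns sites to the annotated transcript strand: within a
    gene only the gene's strand is considered (intergenic positions keep
    both strands).
    """
    params = params or CimFilterParams()
    strand_masks = (
        _transcript_strands(models, pileup.contig_sizes())
        if models is not None
        else None
    )
    sites: List[CimSite] = []
    for contig in pileup.contigs():
        if contig not in genome:
            raise ValueError(f"contig {contig!r} missing from genome")
        k = pileup.coverage[contig]
        m = pileup.mismatches[contig]
        if len(genome[contig]) != k.size:
            raise ValueError(f"pileup/genome length mismatch on {contig!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(k > 0, m / np.maximum(k, 1), 0.0)
        passing = (
            (m > params.m_min_exclusive)
            & (ratio > params.ratio_lo)
            & (ratio < params.ratio_hi)
        )
        if not passing.any():
            continue
        seq_arr = np.frombuffer(genome[contig].encode(), dtype=np.uint8)
        for strand in "+-":
            mask = passing & _candidate_mask(
                seq_arr, strand, params.require_ref_c, params.require_preceding_a
            )
            if strand_masks is not None and contig in strand_masks:
                genic = strand_masks[contig]["+"] | strand_masks[contig]["-"]
                mask &= strand_masks[contig][strand] | ~genic
            for pos in np.flatnonzero(mask):
                pos = int(pos)
                m6a = pos - 1 if strand == "+" else pos + 1
                sites.append(
                    CimSite(
                        contig=contig,
                        cim_pos=pos,
                        m6a_pos=m6a,
                        strand=strand,
                        m=int(m[pos]),
                        k=int(k[pos]),
                    )
                )
    sites.sort(key=lambda s: (s.contig, s.cim_pos, s.strand))
    return sites


def cims_in_top_peaks(
    cims: Sequence[CimSite], peaks: Sequence, n_top: int
) -> List[CimSite]:
    """CIMs falling inside the ``n_top`` highest-scoring dependent peaks.

    Membership is half-open: a CIM at a peak's end coordinate is outside.
    Peaks must carry ``label``, ``score``, ``contig``, ``start``, ``end``.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    dependent = [p for p in peaks if p.label == "dependent"]
    dependent.sort(key=lambda p: (-p.score, p.contig, p.start))
    top = dependent[:n_top]
    by_contig: Dict[str, List] = {}
    for p in top:
        by_contig.setdefault(p.contig, []).append((p.start, p.end))
    kept = []
    for site in cims:
        for s, e in by_contig.get(site.contig, ()):
            if s <= site.cim_pos < e:
                kept.append(site)
                break
    return kept
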
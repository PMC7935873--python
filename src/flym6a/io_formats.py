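"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: everything in memory is 0-based, half-open
([start, end)), matching BED/bedGraph.  GTF input (1-based, inclusive) is
converted at the boundary and never stored 1-based.  Signal tracks are kept
unstranded; strand enters only through transcript models and reverse
complementation of sequence context.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSeq:
    """A genome: mapping of contig name to an upper-case sequence string."""

    def __init__(self, contigs: Mapping[str, str]):
        clean: Dict[str, str] = {}
        for name, seq in contigs.items():
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )
            clean[name] = seq
        self._contigs = clean

    def __getitem__(self, contig: str) -> str:
        return self._contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self._contigs

    def __len__(self) -> int:
        return len(self._contigs)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeSeq) and self._contigs == other._contigs

    def contigs(self) -> List[str]:
        return list(self._contigs)

    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._contigs.items()}

    def base(self, contig: str, pos: int) -> str:
        """Single base at a 0-based position."""
        return self._contigs[contig][pos]

    def slice(self, contig: str, start: int, end: int) -> str:
        """Subsequence over [start, end); caller must stay in bounds."""
        if start < 0 or end > len(self._contigs[contig]):
            raise IndexError(f"[{start},{end}) outside contig {contig!r}")
        return self._contigs[contig][start:end]


def read_fasta(path: str | Path) -> GenomeSeq:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSeq(contigs)


def write_fasta(genome: GenomeSeq, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome[name]), id=name, description="")
        for name in genome.contigs()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus optional CDS bounds (all genomic,
    0-based half-open).  Segment lengths are reported in mature-transcript
    (exonic) space, 5'->3' on the transcript strand."""

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: List[Tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"degenerate exon [{s},{e})")
        for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError("exons overlap")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be given together")
        if self.cds_start is not None:
            if not (self.cds_start < self.cds_end):
                raise ValueError("empty CDS")
            # CDS must fall inside the exon union
            for pos in (self.cds_start, self.cds_end - 1):
                if not any(s <= pos < e for s, e in self.exons):
                    raise ValueError(
                        f"CDS bound {pos} outside exons of {self.transcript_id}"
                    )

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinates of mature positions, in transcript 5'->3' order."""
        parts = [np.arange(s, e) for s, e in self.exons]
        pos = np.concatenate(parts)
        return pos[::-1] if self.strand == "-" else pos

    def _exonic_count_in(self, start: int, end: int) -> int:
        return sum(max(0, min(e, end) - max(s, start)) for s, e in self.exons)

    def segment_lengths(self) -> Tuple[int, int, int]:
        """(5'UTR, CDS, 3'UTR) lengths in mature-transcript space.

        Without an annotated CDS the whole transcript counts as 5'UTR=0,
        CDS=0, 3'UTR=0 is meaningless, so a ValueError is raised instead.
        """
        if self.cds_start is None:
            raise ValueError(f"{self.transcript_id} has no CDS")
        span0, span1 = self.span
        cds = self._exonic_count_in(self.cds_start, self.cds_end)
        before = self._exonic_count_in(span0, self.cds_start)
        after = self._exonic_count_in(self.cds_end, span1)
        if self.strand == "+":
            utr5, utr3 = before, after
        else:
            utr5, utr3 = after, before
        assert utr5 + cds + utr3 == self.mature_length
        return utr5, cds, utr3

    def transcript_to_genomic(self, tpos: int) -> int:
        """Genomic coordinate of mature-transcript position ``tpos``."""
        return int(self.genomic_positions()[tpos])

    def start_codon_interval(self) -> Tuple[int, int]:
        """Genomic half-open interval of the 3-nt window at the CDS start."""
        if self.cds_start is None:
            raise ValueError("no CDS")
        if self.strand == "+":
            return self.cds_start, self.cds_start + 3
        return self.cds_end - 3, self.cds_end


def _parse_gtf_attributes(text: str) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for chunk in text.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_transcript_models(path_gtf: str | Path) -> List[TranscriptModel]:
    """Parse exon/CDS features of a GTF into TranscriptModels.

    GTF coordinates are 1-based inclusive; they are converted to 0-based
    half-open here and never stored otherwise.
    """
    path_gtf = Path(path_gtf)
    if not path_gtf.exists():
        raise FileNotFoundError(path_gtf)
    exons: Dict[Tuple[str, str], dict] = {}
    for line in path_gtf.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF line: {line!r}")
        contig, _, feature, start, end, _, strand, _, attr_text = fields
        if feature not in ("exon", "CDS"):
            continue
        attrs = _parse_gtf_attributes(attr_text)
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise ValueError(f"missing gene_id/transcript_id in: {line!r}")
        key = (attrs["gene_id"], attrs["transcript_id"])
        rec = exons.setdefault(
            key, {"contig": contig, "strand": strand, "exons": [], "cds": []}
        )
        iv = (int(start) - 1, int(end))  # 1-based inclusive -> 0-based half-open
        rec[{"exon": "exons", "CDS": "cds"}[feature]].append(iv)
    models = []
    for (gene_id, transcript_id), rec in exons.items():
        cds_start = cds_end = None
        if rec["cds"]:
            cds_start = min(s for s, _ in rec["cds"])
            cds_end = max(e for _, e in rec["cds"])
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=transcript_id,
                contig=rec["contig"],
                strand=rec["strand"],
                exons=rec["exons"],
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return models


def longest_by_gene(models: Iterable[TranscriptModel]) -> Dict[str, TranscriptModel]:
    """Per gene, the transcript with the greatest mature (exonic) length.

    Ties are broken by lexicographic transcript_id so selection is
    deterministic.
    """
    best: Dict[str, TranscriptModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.mature_length > cur.mature_length
            or (m.mature_length == cur.mature_length
                and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return best


class SignalTrack:
    """Dense per-position non-negative signal, one array per contig."""

    def __init__(self, data: Mapping[str, np.ndarray]):
        self.data: Dict[str, np.ndarray] = {}
        for contig, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise ValueError("per-contig signal must be 1-D")
            if np.any(arr < 0):
                raise ValueError(f"negative values on contig {contig!r}")
            self.data[contig] = arr

    @classmethod
    def zeros(cls, contig_sizes: Mapping[str, int]) -> "SignalTrack":
        return cls({c: np.zeros(n) for c, n in contig_sizes.items()})

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.data[contig]

    def contigs(self) -> List[str]:
        return list(self.data)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if set(self.data) != set(other.data):
            return False
        return all(np.array_equal(self.data[c], other.data[c]) for c in self.data)


def _format_value(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def read_bedgraph(path: str | Path, contig_sizes: Mapping[str, int]) -> SignalTrack:
    """Read a 4-column bedGraph into a dense track.

    Positions not covered by any interval are 0 (bedGraph semantics).
    Overlapping intervals and negative values are rejected.
    """
    track = SignalTrack.zeros(contig_sizes)
    last_end: Dict[str, int] = {}
    seen: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            contig, start, end, value = line.split("\t")
            start, end, value = int(start), int(end), float(value)
            if value < 0:
                raise ValueError(f"negative bedGraph value at {contig}:{start}")
            if contig not in track.data:
                raise ValueError(f"unknown contig {contig!r}")
            seen.setdefault(contig, []).append((start, end))
            track.data[contig][start:end] = value
    for contig, ivs in seen.items():
        ivs.sort()
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping bedGraph intervals on {contig}")
    return track


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write nonzero runs as merged constant intervals (sorted)."""
    with open(path, "w") as fh:
        for contig in sorted(track.data):
            arr = track.data[contig]
            if arr.size == 0:
                continue
            # run-length encode
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{contig}\t{s}\t{e}\t{_format_value(v)}\n")


@dataclass
class BedRecord:
    contig: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start},{self.end})")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")


def write_bed(records: Sequence[BedRecord], path: str | Path) -> None:
    """Emit BED6, tab-separated, sorted by (contig, start, end)."""
    recs = sorted(records, key=lambda r: (r.contig, r.start, r.end))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.name}\t"
                f"{_format_value(r.score)}\t{r.strand}\n"
            )


def read_bed(path: str | Path) -> List[BedRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            records.append(
                BedRecord(f[0], int(f[1]), int(f[2]), f[3], float(f[4]), f[5])
            )
    return records


def read_tsv_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Typed TSV with header; the literal token "NA" marks missing values.

    ``schema`` maps required column names to dtypes; extra columns are kept
    as-is, missing ones raise.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = set(schema) - set(df.columns)
    if missing:
        raise ValueError(f"TSV {path} lacks columns: {sorted(missing)}")
    for col, dtype in schema.items():
        if dtype in (int, "int"):
            # integer columns with NA are kept as nullable Int64
            df[col] = df[col].astype("Int64" if df[col].isna().any() else np.int64)
        elif dtype in (float, "float"):
            df[col] = df[col].astype(float)
        elif dtype in (bool, "bool"):
            df[col] = df[col].map(
                {True: True, False: False, "True": True, "False": False}
            ).astype(bool)
        else:
            df[col] = df[col].astype(str)
    return df


def write_tsv_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
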
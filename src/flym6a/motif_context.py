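"""Sequence context around called CIMs: position frequency matrices and an
IUPAC consensus (AAACD recovery on the fly methylome).

The matrix is centered on the methylated A (position 0); the crosslinked,
mutated C is at +1.  Minus-strand contexts are reverse-complemented so all
sites read in transcript 5'->3' orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cims_calling import CimSite
from .io_formats import GenomeSeq, reverse_complement

BASES = "ACGT"

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N", frozenset(): "N",
}


@dataclass
class ContextMatrix:
    """4 x (2*flank+1) relative base frequencies around the methylated A."""

    freq: np.ndarray  # rows A,C,G,T; columns -flank..+flank
    n_sites: int
    flank: int

    def __post_init__(self):
        if self.freq.shape != (4, 2 * self.flank + 1):
            raise ValueError("frequency matrix shape mismatch")
        col_sums = self.freq.sum(axis=0)
        if self.n_sites and not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("columns must sum to 1")

    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freq, index=list(BASES), columns=self.offsets()
        )


def extract_contexts(
    cims: Sequence[CimSite], genome: GenomeSeq, flank: int = 5
) -> Tuple[List[str], int]:
    """(2*flank+1)-mers centered on each site's methylated A.

    Minus-strand windows are reverse-complemented so position +1 is always
    the mutated C in transcript space.  Sites whose window leaves the
    contig, or spans an ambiguous base, are dropped; the drop count is
    returned alongside.
    """
    contexts: List[str] = []
    n_dropped = 0
    for site in cims:
        seq = genome[site.contig]
        lo = site.m6a_pos - flank
        hi = site.m6a_pos + flank + 1
        if lo < 0 or hi > len(seq):
            n_dropped += 1
            continue
        window = seq[lo:hi]
        if site.strand == "-":
            window = reverse_complement(window)
        if "N" in window:
            n_dropped += 1
            continue
        contexts.append(window)
    return contexts, n_dropped


def frequency_matrix(contexts: Sequence[str]) -> ContextMatrix:
    if not contexts:
        raise ValueError("no contexts to tabulate")
    width = len(contexts[0])
    if width % 2 != 1:
        raise ValueError("context width must be odd")
    if any(len(c) != width for c in contexts):
        raise ValueError("contexts differ in width")
    counts = np.zeros((4, width))
    index = {b: i for i, b in enumerate(BASES)}
    for ctx in contexts:
        for col, base in enumerate(ctx):
            counts[index[base], col] += 1
    return ContextMatrix(
        freq=counts / len(contexts), n_sites=len(contexts), flank=width // 2
    )


def consensus(matrix: ContextMatrix, min_freq: float = 0.2) -> str:
    """IUPAC string: per column, the code covering every base whose
    frequency is at least ``min_freq``."""
    letters = []
    for col in range(matrix.freq.shape[1]):
        included = frozenset(
            BASES[i] for i in range(4) if matrix.freq[i, col] >= min_freq
        )
        letters.append(_IUPAC[included])
    return "".join(letters)
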
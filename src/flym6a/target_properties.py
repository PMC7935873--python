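"""Peak annotation, target binning, and property comparisons.

Peaks are assigned to transcript segments with a fixed precedence (other,
intron, start codon, 5'UTR, 3'UTR, CDS: first overlap wins); genes are
binned by their number of writer-dependent peaks; and each bin's property
distribution (differential expression, mRNA half-life, translational
efficiency) is compared against a bootstrap background built from genes
without peaks, using two-sided two-sample Kolmogorov-Smirnov tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special

from .io_formats import TranscriptModel, longest_by_gene
from .peak_analysis import Peak

CATEGORY_ORDER = ("other", "intron", "start_codon", "utr5", "utr3", "cds")


class GeneAnnotationIndex:
    """Interval lookups against each gene's longest transcript."""

    def __init__(self, models: Sequence[TranscriptModel]):
        self.chosen = longest_by_gene(models)
        self._by_cat: Dict[str, Dict[str, List[Tuple[int, int]]]] = {
            cat: {} for cat in ("span", "intron", "start_codon", "utr5", "utr3", "cds")
        }
        self._spans: Dict[str, List[Tuple[int, int, str]]] = {}
        for gene_id in sorted(self.chosen):
            m = self.chosen[gene_id]

            def add(cat: str, iv: Tuple[int, int]):
                if iv[0] < iv[1]:
                    self._by_cat[cat].setdefault(m.contig, []).append(iv)

            span = m.span
            add("span", span)
            self._spans.setdefault(m.contig, []).append((span[0], span[1], gene_id))
            for (s0, e0), (s1, _) in zip(m.exons, m.exons[1:]):
                add("intron", (e0, s1))
            if m.cds_start is not None:
                add("start_codon", m.start_codon_interval())
                for s, e in m.exons:
                    add("cds", (max(s, m.cds_start), min(e, m.cds_end)))
                    before = (max(s, span[0]), min(e, m.cds_start))
                    after = (max(s, m.cds_end), min(e, span[1]))
                    if m.strand == "+":
                        add("utr5", before)
                        add("utr3", after)
                    else:
                        add("utr5", after)
                        add("utr3", before)
        for cat in self._by_cat.values():
            for ivs in cat.values():
                ivs.sort()

    def overlaps(self, cat: str, contig: str, start: int, end: int) -> bool:
        ivs = self._by_cat[cat].get(contig, ())
        for s, e in ivs:
            if s >= end:
                break
            if start < e:
                return True
        return False

    def genes_overlapping(self, contig: str, start: int, end: int) -> List[str]:
        hits = [
            g
            for s, e, g in self._spans.get(contig, ())
            if start < e and s < end
        ]
        return sorted(hits)


def annotate_peak(peak: Peak, index: GeneAnnotationIndex) -> str:
    """Transcript-segment category with fixed precedence; first match wins.

    A peak not overlapping any transcript span is "other"; otherwise the
    categories intron, start_codon, utr5, utr3, cds are tested in order.
    """
    if not index.overlaps("span", peak.contig, peak.start, peak.end):
        return "other"
    for cat in ("intron", "start_codon", "utr5", "utr3", "cds"):
        if index.overlaps(cat, peak.contig, peak.start, peak.end):
            return cat
    # inside a span but in no feature (should not happen with full models)
    return "other"


def annotate_peaks(
    peaks: Sequence[Peak], index: GeneAnnotationIndex
) -> List[Peak]:
    """Fill category and gene_ids on every peak, in place; returns peaks."""
    for p in peaks:
        p.category = annotate_peak(p, index)
        p.gene_ids = index.genes_overlapping(p.contig, p.start, p.end)
    return list(peaks)


def category_fractions(peaks: Sequence[Peak]) -> pd.Series:
    """Fraction of peaks per category (the pie chart); sums to 1."""
    if not peaks:
        raise ValueError("no peaks to tabulate")
    counts = pd.Series([p.category for p in peaks]).value_counts()
    frac = counts / counts.sum()
    return frac.reindex([c for c in CATEGORY_ORDER if c in frac.index])


def bin_genes_by_peak_count(
    peaks: Sequence[Peak],
    all_genes: Iterable[str],
    edges: Tuple[int, ...] = (1, 2, 3),
) -> pd.Series:
    """Gene -> bin label by number of *dependent* peaks.

    With the default edges the labels are none / 1 / 2 / 3+ ("none" means
    zero dependent peaks; independent peaks do not count).  The result is
    a partition of ``all_genes``.
    """
    edges = tuple(edges)
    if not edges or list(edges) != sorted(edges):
        raise ValueError("edges must be ascending and non-empty")
    counts: Dict[str, int] = {g: 0 for g in all_genes}
    for p in peaks:
        if p.label != "dependent":
            continue
        for g in p.gene_ids:
            if g in counts:
                counts[g] += 1
    labels = {}
    for gene, n in counts.items():
        if n == 0:
            labels[gene] = "none"
            continue
        lab = None
        for lo, hi in zip(edges, edges[1:]):
            if lo <= n < hi:
                lab = str(lo) if hi == lo + 1 else f"{lo}-{hi - 1}"
                break
        labels[gene] = lab if lab is not None else f"{edges[-1]}+"
    return pd.Series(labels, name="bin")


def bin_labels(edges: Tuple[int, ...] = (1, 2, 3)) -> List[str]:
    labs = []
    for lo, hi in zip(edges, edges[1:]):
        labs.append(str(lo) if hi == lo + 1 else f"{lo}-{hi - 1}")
    labs.append(f"{edges[-1]}+")
    return labs


@dataclass
class BootstrapConfig:
    n_draws: int = 1000
    draw_size: Optional[int] = None  # default: size of the compared bin
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.draw_size is not None and self.draw_size < 1:
            raise ValueError("draw_size must be >= 1")


def bootstrap_background(
    values: pd.Series,
    none_genes: Iterable[str],
    cfg: BootstrapConfig,
    draw_size: Optional[int] = None,
) -> np.ndarray:
    """Concatenation of ``n_draws`` seeded resamples (with replacement) of
    the no-peak genes' property values."""
    pool = values.reindex(list(none_genes)).dropna().to_numpy(dtype=float)
    if pool.size == 0:
        raise ValueError("empty background pool")
    pool = np.sort(pool)  # resample independent of input row order
    size = draw_size or cfg.draw_size or pool.size
    rng = np.random.default_rng(cfg.seed)
    return rng.choice(pool, size=cfg.n_draws * size, replace=True)


@dataclass
class KsResult:
    D: float
    p: float
    n_x: int
    n_y: int


def _ks_distance(x: np.ndarray, y: np.ndarray) -> float:
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(np.sort(x), grid, side="right") / x.size
    cdf_y = np.searchsorted(np.sort(y), grid, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    effective_n_y: Optional[int] = None,
) -> KsResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D is the exact sup-distance between the two ECDFs (right-continuous
    step functions); the p-value comes from the asymptotic Kolmogorov
    distribution at effective size n_x n_y / (n_x + n_y), with the
    standard finite-sample argument correction.  When ``y`` is a bootstrap
    expansion of a smaller pool, pass the pool size as ``effective_n_y``
    so the p-value reflects the information actually present.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    d = _ks_distance(x, y)
    n_y_eff = effective_n_y if effective_n_y is not None else y.size
    ne = x.size * n_y_eff / (x.size + n_y_eff)
    arg = (np.sqrt(ne) + 0.12 + 0.11 / np.sqrt(ne)) * d
    p = float(np.clip(special.kolmogorov(arg), 0.0, 1.0))
    if d == 0.0:
        p = 1.0
    return KsResult(D=d, p=max(p, np.finfo(float).tiny), n_x=int(x.size), n_y=int(y.size))


PROPERTY_COLUMNS = ("log2fc", "half_life_hours", "translational_efficiency")


def compare_bins(
    properties: pd.DataFrame,
    bins: pd.Series,
    cfg: Optional[BootstrapConfig] = None,
    property_columns: Sequence[str] = PROPERTY_COLUMNS,
) -> pd.DataFrame:
    """One KS comparison per (non-"none" bin, property) against the
    bootstrap background of no-peak genes.

    ``properties`` must carry a ``gene_id`` column; missing values are
    dropped per comparison.  Returns a table of
    (bin, property, n, n_bg_pool, D, p, median_bin, median_bg).
    """
    cfg = cfg or BootstrapConfig()
    props = properties.set_index("gene_id")
    bins = bins.reindex(props.index).fillna("none")
    none_genes = bins.index[bins == "none"]
    rows = []
    bin_order = [b for b in bins.unique() if b != "none"]
    for prop in property_columns:
        values = props[prop]
        pool = values.reindex(none_genes).dropna()
        for b in sorted(bin_order):
            x = values[bins == b].dropna().to_numpy(dtype=float)
            if x.size == 0:
                continue
            bg = bootstrap_background(
                values, none_genes, cfg, draw_size=x.size
            )
            res = ks_two_sample(x, bg, effective_n_y=pool.size)
            rows.append(
                {
                    "bin": b,
                    "property": prop,
                    "n": x.size,
                    "n_bg_pool": int(pool.size),
                    "D": res.D,
                    "p": res.p,
                    "median_bin": float(np.median(x)),
                    "median_bg": float(np.median(bg)),
                }
            )
    return pd.DataFrame(rows).sort_values(["property", "bin"]).reset_index(drop=True)


def ecdf_table(
    properties: pd.DataFrame,
    bins: pd.Series,
    property_columns: Sequence[str] = PROPERTY_COLUMNS,
) -> pd.DataFrame:
    """Long-format ECDF points per (bin, property), for cumulative plots."""
    props = properties.set_index("gene_id")
    bins = bins.reindex(props.index).fillna("none")
    rows = []
    for prop in property_columns:
        for b in sorted(bins.unique()):
            x = np.sort(props[prop][bins == b].dropna().to_numpy(dtype=float))
            if x.size == 0:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "property": prop,
                        "bin": b,
                        "value": x,
                        "ecdf": np.arange(1, x.size + 1) / x.size,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
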
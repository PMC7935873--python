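"""Synthetic data with the statistical structure the pipeline assumes.

Generates a toy transcriptome with planted m6A sites (5'UTR-biased, in an
AAACT context), the four miCLIP tag pileups (wild-type/writer-mutant x
IP/input), gene-level property tables with a planted translational-
efficiency effect, olfactory-conditioning occupancy traces, and replicate
spectral-count tables with planted m6A readers.  Every generator is fully
deterministic under its seed, and every planted feature is returned in a
registry so downstream recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cims_calling import TagPileup
from .io_formats import (
    GenomeSeq,
    TranscriptModel,
    write_fasta,
    write_tsv_table,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# fixed per-stage stream keys so staged calls stay independent but are all
# reproducible from one config seed
_STAGE_GENOME = 11
_STAGE_SITES = 12
_STAGE_LIBS = 13
_STAGE_PROPS = 14
_STAGE_BEHAVIOR = 15
_STAGE_SPECTRA = 16


@dataclass
class SimConfig:
    """Study conditions for the miCLIP arm of the simulation.

    Lengths are mean segment lengths in nt; ``context`` is the planted
    sequence written at each site with the methylated A at
    ``context_offset`` (the crosslinked C immediately 3' of it).  IP
    enrichment decays linearly from ``ip_enrichment``-fold inside
    ``enrich_core`` nt of a site to 1x at ``enrich_reach`` nt, emulating
    fragment pileup around a crosslink.
    """

    n_genes: int = 500
    utr5_len: int = 300
    cds_len: int = 1500
    utr3_len: int = 400
    len_cv: float = 0.15
    frac_methylated: float = 0.35
    # P(1), P(2), ... sites per methylated gene
    sites_per_gene_dist: Tuple[float, ...] = (0.35, 0.25, 0.16, 0.10, 0.08, 0.06)
    frac_dependent: float = 0.8
    segment_bias: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    context: str = "AAACT"
    context_offset: int = 2
    ip_enrichment: float = 8.0
    depth: float = 30.0
    cim_rate: float = 0.15
    error_rate: float = 0.001
    te_effect: float = 0.7
    enrich_core: int = 100
    enrich_reach: int = 130
    frac_minus_strand: float = 0.5
    exons_per_gene: int = 1
    intron_len: int = 60
    intergenic: int = 200
    contig: str = "chrS"
    seed: int = 0

    def __post_init__(self):
        for name in ("frac_methylated", "frac_dependent", "frac_minus_strand"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if abs(sum(self.sites_per_gene_dist) - 1.0) > 1e-9:
            raise ValueError("sites_per_gene_dist must sum to 1")
        if abs(sum(self.segment_bias) - 1.0) > 1e-9:
            raise ValueError("segment_bias must sum to 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 < self.cim_rate < 1.0:
            raise ValueError("cim_rate must be in (0,1)")
        n = len(self.context)
        if not (0 <= self.context_offset < n - 1):
            raise ValueError("context_offset must leave room for the C")
        if self.context[self.context_offset] != "A":
            raise ValueError("context must carry A at context_offset")
        if self.context[self.context_offset + 1] != "C":
            raise ValueError("context must carry C just 3' of the A")
        if self.enrich_reach <= self.enrich_core:
            raise ValueError("enrich_reach must exceed enrich_core")

    def rng(self, stage: int, seed: Optional[int] = None) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed if seed is None else seed])


@dataclass(frozen=True)
class PlantedSite:
    """One planted m6A site (ground truth for recovery scoring)."""

    gene_id: str
    contig: str
    m6a_pos: int  # genomic position of the methylated A
    cim_pos: int  # genomic position of the crosslinked C (3' in transcript space)
    dependence: str  # "dependent" | "independent"
    strand: str = "+"
    tpos: int = 0  # mature-transcript position of the A
    segment: str = "utr5"  # utr5 | cds | utr3


def _draw_length(rng, mean: int, cv: float, minimum: int, multiple: int = 1) -> int:
    val = int(round(rng.normal(mean, cv * mean)))
    val = max(minimum, val)
    return (val // multiple) * multiple if multiple > 1 else val


def simulate_transcriptome(
    cfg: SimConfig,
) -> Tuple[GenomeSeq, List[TranscriptModel]]:
    """One transcript per gene, laid out along a shared contig.

    Segment lengths are drawn around the configured means; strand is
    random per gene; multi-exon layout (``exons_per_gene`` > 1) inserts
    fixed-length introns, splitting the mature sequence into near-equal
    exons.
    """
    rng = cfg.rng(_STAGE_GENOME)
    models: List[TranscriptModel] = []
    pieces: List[np.ndarray] = []
    cursor = 0

    def random_seq(n: int) -> np.ndarray:
        return rng.choice(_BASES, size=n)

    for i in range(cfg.n_genes):
        gene_id = f"g{i + 1:04d}"
        utr5 = _draw_length(rng, cfg.utr5_len, cfg.len_cv, 60)
        cds = _draw_length(rng, cfg.cds_len, cfg.len_cv, 150, multiple=3)
        utr3 = _draw_length(rng, cfg.utr3_len, cfg.len_cv, 60)
        mature = utr5 + cds + utr3
        strand = "-" if rng.random() < cfg.frac_minus_strand else "+"

        pieces.append(random_seq(cfg.intergenic))
        cursor += cfg.intergenic
        gene_start = cursor

        n_ex = max(1, cfg.exons_per_gene)
        base = mature // n_ex
        sizes = [base] * n_ex
        sizes[-1] += mature - base * n_ex
        exons = []
        pos = gene_start
        for j, size in enumerate(sizes):
            exons.append((pos, pos + size))
            pieces.append(random_seq(size))
            cursor = pos + size
            pos = cursor
            if j < n_ex - 1:
                pieces.append(random_seq(cfg.intron_len))
                cursor += cfg.intron_len
                pos = cursor

        model = TranscriptModel(
            gene_id=gene_id,
            transcript_id=f"t{i + 1:04d}",
            contig=cfg.contig,
            strand=strand,
            exons=exons,
        )
        # mature-space CDS interval -> genomic bounds via the exon map
        gp = model.genomic_positions()
        if strand == "+":
            cds_slice = gp[utr5:utr5 + cds]
        else:
            cds_slice = gp[utr5:utr5 + cds]
        model.cds_start = int(cds_slice.min())
        model.cds_end = int(cds_slice.max()) + 1
        models.append(model)

    pieces.append(random_seq(cfg.intergenic))
    seq = b"".join(p.tobytes() for p in pieces).decode()
    genome = GenomeSeq({cfg.contig: seq})
    for m in models:
        assert m.segment_lengths()[1] > 0
    return genome, models


def plant_m6a_sites(
    genome: GenomeSeq,
    models: Sequence[TranscriptModel],
    cfg: SimConfig,
) -> Tuple[GenomeSeq, List[PlantedSite]]:
    """Write the planted context into the sequence at each chosen site.

    Site segments are drawn i.i.d. from ``segment_bias``; writer dependence
    is drawn per gene (all sites of a gene share it), so that every
    IP-enriched region is homogeneous in its genetic dependence.  Sites
    within a gene keep a minimal separation so contexts never collide.
    """
    rng = cfg.rng(_STAGE_SITES)
    ctx = cfg.context
    off = cfg.context_offset
    min_sep = len(ctx) + 3
    seqs = {c: bytearray(genome[c].encode()) for c in genome.contigs()}
    n_sites_choices = np.arange(1, len(cfg.sites_per_gene_dist) + 1)

    n_meth = int(round(cfg.frac_methylated * len(models)))
    meth_idx = rng.choice(len(models), size=n_meth, replace=False)
    sites: List[PlantedSite] = []
    for gi in sorted(meth_idx):
        model = models[gi]
        utr5, cds, utr3 = model.segment_lengths()
        mature = model.mature_length
        seg_bounds = {
            "utr5": (0, utr5),
            "cds": (utr5, utr5 + cds),
            "utr3": (utr5 + cds, mature),
        }
        dependence = (
            "dependent" if rng.random() < cfg.frac_dependent else "independent"
        )
        n_sites = int(rng.choice(n_sites_choices, p=cfg.sites_per_gene_dist))
        placed: List[Tuple[int, str]] = []
        for _ in range(n_sites):
            seg = ["utr5", "cds", "utr3"][
                int(rng.choice(3, p=cfg.segment_bias))
            ]
            a, b = seg_bounds[seg]
            lo = max(a, off)
            hi = min(b, mature - (len(ctx) - off))
            if hi <= lo:
                continue  # segment too small to host the context
            for _attempt in range(100):
                t = int(rng.integers(lo, hi))
                if all(abs(t - p) >= min_sep for p, _ in placed):
                    placed.append((t, seg))
                    break
        gp = model.genomic_positions()
        for t, seg in placed:
            for j, base in enumerate(ctx):
                tj = t - off + j
                g = int(gp[tj])
                b = base if model.strand == "+" else _COMP[base]
                seqs[model.contig][g] = ord(b)
            sites.append(
                PlantedSite(
                    gene_id=model.gene_id,
                    contig=model.contig,
                    m6a_pos=int(gp[t]),
                    cim_pos=int(gp[t + 1]),
                    dependence=dependence,
                    strand=model.strand,
                    tpos=t,
                    segment=seg,
                )
            )
    planted_genome = GenomeSeq(
        {c: bytes(s).decode() for c, s in seqs.items()}
    )
    sites.sort(key=lambda s: (s.contig, s.cim_pos))
    return planted_genome, sites


def _enrichment_multiplier(
    length: int, site_tpos: Sequence[int], cfg: SimConfig
) -> np.ndarray:
    """Per-mature-position IP fold enrichment: max over site profiles of a
    flat-top (core) linearly-decaying (to reach) bump."""
    mult = np.ones(length)
    if not site_tpos:
        return mult
    pos = np.arange(length)
    for t in site_tpos:
        d = np.abs(pos - t)
        shoulder = np.clip(
            (cfg.enrich_reach - d) / (cfg.enrich_reach - cfg.enrich_core), 0.0, 1.0
        )
        mult = np.maximum(mult, 1.0 + (cfg.ip_enrichment - 1.0) * shoulder)
    return mult


def simulate_miclip_libraries(
    genome: GenomeSeq,
    models: Sequence[TranscriptModel],
    sites: Sequence[PlantedSite],
    cfg: SimConfig,
    seed: Optional[int] = None,
) -> Dict[str, TagPileup]:
    """The four tag pileups: wt_ip, wt_input, mut_ip, mut_input.

    Input coverage is Poisson(depth) per mature position.  IP coverage is
    Poisson(depth x multiplier) with the enrichment bump around every site
    (wild type) or around writer-independent sites only (mutant).  C->T
    mismatch counts are Binomial(k, cim_rate) at the crosslinked C in IP
    libraries where the site is active, and Binomial(k, error_rate)
    everywhere else.
    """
    rng = cfg.rng(_STAGE_LIBS, seed)
    sizes = genome.lengths()
    sites_by_gene: Dict[str, List[PlantedSite]] = {}
    for s in sites:
        sites_by_gene.setdefault(s.gene_id, []).append(s)

    libs = {}
    for name in ("wt_ip", "wt_input", "mut_ip", "mut_input"):
        libs[name] = {
            "k": {c: np.zeros(n, dtype=np.int64) for c, n in sizes.items()},
            "m": {c: np.zeros(n, dtype=np.int64) for c, n in sizes.items()},
        }

    for model in models:
        L = model.mature_length
        gp = model.genomic_positions()
        gene_sites = sites_by_gene.get(model.gene_id, [])
        all_tpos = [s.tpos for s in gene_sites]
        indep_tpos = [s.tpos for s in gene_sites if s.dependence == "independent"]
        mult = {
            "wt_ip": _enrichment_multiplier(L, all_tpos, cfg),
            "wt_input": np.ones(L),
            "mut_ip": _enrichment_multiplier(L, indep_tpos, cfg),
            "mut_input": np.ones(L),
        }
        active_cims = {
            "wt_ip": [s.tpos + 1 for s in gene_sites],
            "wt_input": [],
            "mut_ip": [s.tpos + 1 for s in gene_sites if s.dependence == "independent"],
            "mut_input": [],
        }
        for name, lib in libs.items():
            k = rng.poisson(cfg.depth * mult[name])
            m = rng.binomial(k, cfg.error_rate)
            for tc in active_cims[name]:
                m[tc] = rng.binomial(k[tc], cfg.cim_rate)
            lib["k"][model.contig][gp] = k
            lib["m"][model.contig][gp] = m

    return {
        name: TagPileup(name, lib["k"], lib["m"]) for name, lib in libs.items()
    }


def simulate_property_tables(
    models: Sequence[TranscriptModel],
    sites: Sequence[PlantedSite],
    cfg: SimConfig,
    seed: Optional[int] = None,
    log2fc_sd: float = 0.5,
    half_life_median: float = 4.0,
    half_life_sigma: float = 0.6,
    te_sigma: float = 0.5,
    frac_missing: float = 0.02,
) -> pd.DataFrame:
    """Gene-level property table: log2fc, half_life_hours,
    translational_efficiency.

    Fold change and half-life are independent of methylation (null
    structure); log2-TE is decreased by ``cfg.te_effect`` per planted
    writer-dependent site (planted inverse association).  A small fraction
    of entries is missing (NA) to exercise per-analysis dropping.
    """
    rng = cfg.rng(_STAGE_PROPS, seed)
    n_dep: Dict[str, int] = {}
    for s in sites:
        if s.dependence == "dependent":
            n_dep[s.gene_id] = n_dep.get(s.gene_id, 0) + 1
    rows = []
    for model in models:
        d = n_dep.get(model.gene_id, 0)
        log2fc = rng.normal(0.0, log2fc_sd)
        half_life = float(
            np.exp(np.log(half_life_median) + rng.normal(0.0, half_life_sigma))
        )
        te = float(
            np.exp(rng.normal(0.0, te_sigma)) * 2.0 ** (-cfg.te_effect * d)
        )
        rows.append((model.gene_id, log2fc, half_life, te))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "log2fc", "half_life_hours", "translational_efficiency"],
    )
    if frac_missing > 0:
        for col in ("log2fc", "half_life_hours", "translational_efficiency"):
            mask = rng.random(len(df)) < frac_missing
            df.loc[mask, col] = np.nan
    return df


@dataclass
class BehaviorSimConfig:
    """Occupancy-trace simulation for the two-odor conditioning assay.

    Each unit runs two reciprocal trials (OCT- and MCH-conditioned); within
    a trial every fly follows a two-state Markov chain over the chamber
    sides whose stationary probability of the unconditioned side is the
    group's avoidance bias.  ``switchiness`` is the per-frame total
    transition propensity (side-switch rate).
    """

    n_units: int = 14
    flies_per_unit: int = 12
    fps: int = 5
    test_seconds: int = 120
    window_seconds: int = 30
    group_bias: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.71, "test": 0.58}
    )
    switchiness: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.window_seconds > self.test_seconds:
            raise ValueError("analysis window exceeds test duration")
        for g, p in self.group_bias.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"bias for group {g!r} outside [0,1]")
        if not 0.0 < self.switchiness <= 1.0:
            raise ValueError("switchiness must be in (0,1]")


def simulate_behavior(cfg: BehaviorSimConfig) -> pd.DataFrame:
    """Per-frame side counts for every (group, unit, trial_odor).

    Columns: group, unit, trial_odor, frame, n_conditioned_side,
    n_unconditioned_side.  State 1 = unconditioned (safe) side; the
    stationary probability of state 1 equals the group bias.
    """
    rng = np.random.default_rng([_STAGE_BEHAVIOR, cfg.seed])
    n_frames = cfg.fps * cfg.test_seconds
    frames = np.arange(n_frames)
    records = []
    for group in cfg.group_bias:  # insertion order: deterministic
        p = cfg.group_bias[group]
        a = p * cfg.switchiness  # P(cond -> uncond)
        b = (1.0 - p) * cfg.switchiness  # P(uncond -> cond)
        n_traj = cfg.n_units * 2  # two reciprocal trials per unit
        state = (
            rng.random((n_traj, cfg.flies_per_unit)) < p
        ).astype(np.int8)
        uncond = np.empty((n_traj, n_frames), dtype=np.int64)
        for f in range(n_frames):
            uncond[:, f] = state.sum(axis=1)
            u = rng.random(state.shape)
            go_up = (state == 0) & (u < a)
            go_down = (state == 1) & (u < b)
            state = np.where(go_up, 1, np.where(go_down, 0, state))
        for unit in range(cfg.n_units):
            for oi, odor in enumerate(("OCT", "MCH")):
                traj = uncond[unit * 2 + oi]
                records.append(
                    pd.DataFrame(
                        {
                            "group": group,
                            "unit": f"{group}_u{unit + 1:03d}",
                            "trial_odor": odor,
                            "frame": frames,
                            "n_conditioned_side": cfg.flies_per_unit - traj,
                            "n_unconditioned_side": traj,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


@dataclass
class SpectralSimConfig:
    """Replicate spectral counts for m6A-probe vs A-probe pulldowns."""

    mean_count: float = 20.0
    dispersion_sigma: float = 0.5  # lognormal spread of protein baselines
    fold: float = 8.0  # planted probe preference of readers/repelled
    frac_absent: float = 0.08  # background proteins missing from one replicate
    seed: int = 0


def simulate_spectral_counts(
    n_proteins: int,
    n_readers: int,
    n_repelled: int,
    cfg: SpectralSimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Counts for ``n_proteins`` background plus planted readers/repelled.

    Background proteins draw both probes from the same Poisson mean;
    readers have the m6A-probe mean multiplied by ``cfg.fold`` (repelled:
    the A-probe mean).  A fraction of background proteins is absent from
    one replicate (present=False, count 0) to exercise the consistency
    filter.  Returns (table, truth) where truth maps protein -> planted
    class.
    """
    rng = np.random.default_rng([_STAGE_SPECTRA, cfg.seed])
    names, classes = [], []
    for i in range(n_proteins):
        names.append(f"P{i + 1:04d}")
        classes.append("background")
    for i in range(n_readers):
        names.append(f"reader_{i + 1}")
        classes.append("bound")
    for i in range(n_repelled):
        names.append(f"repelled_{i + 1}")
        classes.append("repelled")

    rows = []
    for name, cls in zip(names, classes):
        base = float(
            cfg.mean_count * np.exp(rng.normal(0.0, cfg.dispersion_sigma))
        )
        means = {"m6A": base, "A": base}
        if cls == "bound":
            means["m6A"] = base * cfg.fold
        elif cls == "repelled":
            means["A"] = base * cfg.fold
        absent_rep = 0
        if cls == "background" and rng.random() < cfg.frac_absent:
            absent_rep = int(rng.integers(1, 3))
        for rep in (1, 2):
            for probe in ("m6A", "A"):
                if rep == absent_rep:
                    rows.append((name, probe, rep, 0, False))
                else:
                    rows.append(
                        (name, probe, rep, int(rng.poisson(means[probe])), True)
                    )
    table = pd.DataFrame(
        rows, columns=["protein", "probe", "replicate", "count", "present"]
    )
    truth = pd.DataFrame({"protein": names, "planted_class": classes})
    return table, truth


@dataclass
class MiclipDataset:
    """A complete simulated miCLIP experiment plus ground truth."""

    config: SimConfig
    genome: GenomeSeq
    models: List[TranscriptModel]
    sites: List[PlantedSite]
    pileups: Dict[str, TagPileup]
    properties: pd.DataFrame


def simulate_miclip_dataset(cfg: SimConfig) -> MiclipDataset:
    """Run the full miCLIP arm of the simulator under one config."""
    genome, models = simulate_transcriptome(cfg)
    genome, sites = plant_m6a_sites(genome, models, cfg)
    pileups = simulate_miclip_libraries(genome, models, sites, cfg)
    props = simulate_property_tables(models, sites, cfg)
    return MiclipDataset(cfg, genome, models, sites, pileups, props)


def write_gtf(models: Sequence[TranscriptModel], path: str | Path) -> None:
    """Emit exon and CDS features, converting back to 1-based inclusive."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for s, e in m.exons:
                fh.write(
                    f"{m.contig}\tsim\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_start is not None:
                for s, e in m.exons:
                    cs, ce = max(s, m.cds_start), min(e, m.cds_end)
                    if cs < ce:
                        fh.write(
                            f"{m.contig}\tsim\tCDS\t{cs + 1}\t{ce}\t.\t"
                            f"{m.strand}\t.\t{attrs}\n"
                        )


def sites_table(sites: Sequence[PlantedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in sites],
            "contig": [s.contig for s in sites],
            "m6a_pos": [s.m6a_pos for s in sites],
            "cim_pos": [s.cim_pos for s in sites],
            "dependence": [s.dependence for s in sites],
            "strand": [s.strand for s in sites],
            "tpos": [s.tpos for s in sites],
            "segment": [s.segment for s in sites],
        }
    )


def write_miclip_dataset(data: MiclipDataset, outdir: str | Path) -> None:
    """Write exactly the formats the readers consume: FASTA, GTF, one
    (coverage, mismatch) bedGraph pair per library, and TSV tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(data.genome, outdir / "genome.fa")
    write_gtf(data.models, outdir / "models.gtf")
    for name, pileup in data.pileups.items():
        pileup.to_bedgraphs(
            outdir / f"{name}.coverage.bedgraph",
            outdir / f"{name}.ct_mismatch.bedgraph",
        )
    write_tsv_table(sites_table(data.sites), outdir / "planted_sites.tsv")
    write_tsv_table(data.properties, outdir / "gene_properties.tsv")
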
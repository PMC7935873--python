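from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from flym6a import behavior_stats as bs
from flym6a import probe_proteomics as pp
from flym6a.io_formats import reverse_complement
from flym6a.synthetic_data import (
    BehaviorSimConfig,
    SimConfig,
    SpectralSimConfig,
    plant_m6a_sites,
    simulate_behavior,
    simulate_miclip_dataset,
    simulate_miclip_libraries,
    simulate_property_tables,
    simulate_spectral_counts,
    simulate_transcriptome,
    write_miclip_dataset,
)

SMALL = SimConfig(n_genes=30, seed=1)


class TestTranscriptome:
    def test_identical_bytes_under_same_seed(self, tmp_path):
        for sub in ("a", "b"):
            data = simulate_miclip_dataset(SMALL)
            write_miclip_dataset(data, tmp_path / sub)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_segment_lengths_sum_to_mature_length(self):
        _, models = simulate_transcriptome(SMALL)
        for m in models:
            utr5, cds, utr3 = m.segment_lengths()
            assert utr5 + cds + utr3 == m.mature_length

    def test_cds_length_mean_matches_configuration(self):
        cfg = SimConfig(n_genes=500, cds_len=900, seed=3)
        _, models = simulate_transcriptome(cfg)
        lengths = np.array([m.segment_lengths()[1] for m in models])
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - 900) < 3 * se + 1.5  # +1.5: codon rounding

    def test_multi_exon_layout_keeps_mature_length(self):
        cfg = replace(SMALL, exons_per_gene=3)
        _, models = simulate_transcriptome(cfg)
        for m in models:
            assert len(m.exons) == 3
            utr5, cds, utr3 = m.segment_lengths()
            assert utr5 + cds + utr3 == m.mature_length


class TestPlantedSites:
    def test_planted_context_written_at_registered_positions(self):
        data = simulate_miclip_dataset(SMALL)
        cfg = data.config
        by_tid = {m.gene_id: m for m in data.models}
        for s in data.sites:
            model = by_tid[s.gene_id]
            gp = model.genomic_positions()
            lo = s.tpos - cfg.context_offset
            tx_seq = "".join(
                data.genome.base(s.contig, int(g))
                for g in gp[lo:lo + len(cfg.context)]
            )
            if model.strand == "-":
                tx_seq = "".join(reverse_complement(b) for b in tx_seq)
            assert tx_seq == cfg.context
            expected = ("A", "C") if s.strand == "+" else ("T", "G")
            got = (
                data.genome.base(s.contig, s.m6a_pos),
                data.genome.base(s.contig, s.cim_pos),
            )
            assert got == expected

    def test_forced_segment_bias_puts_all_sites_in_utr5(self):
        cfg = replace(SMALL, segment_bias=(1.0, 0.0, 0.0))
        genome, models = simulate_transcriptome(cfg)
        _, sites = plant_m6a_sites(genome, models, cfg)
        assert sites and all(s.segment == "utr5" for s in sites)

    def test_default_bias_recovers_utr5_fraction_binomially(self):
        # one site per gene so segment draws are unconstrained by spacing
        cfg = SimConfig(
            n_genes=1200, frac_methylated=1.0,
            sites_per_gene_dist=(1.0,), seed=2,
        )
        genome, models = simulate_transcriptome(cfg)
        _, sites = plant_m6a_sites(genome, models, cfg)
        assert len(sites) >= 1000
        frac = np.mean([s.segment == "utr5" for s in sites])
        se = np.sqrt(0.8 * 0.2 / len(sites))
        assert abs(frac - 0.8) < 3 * se


class TestMiclipLibraries:
    def test_enrichment_follows_dependence(self, pipeline):
        data = pipeline.data
        cfg = data.config
        for dep, lib, enriched in [
            ("dependent", "mut_ip", False),
            ("independent", "mut_ip", True),
            ("dependent", "wt_ip", True),
            ("independent", "wt_ip", True),
        ]:
            sites = [s for s in data.sites if s.dependence == dep]
            cov = np.array(
                [data.pileups[lib].coverage[s.contig][s.m6a_pos] for s in sites]
            )
            ratio = cov.mean() / cfg.depth
            if enriched:
                assert ratio > 0.8 * cfg.ip_enrichment
            else:
                assert ratio < 1.5

    def test_planted_cim_ratios_pass_filter_bounds(self, pipeline):
        data = pipeline.data
        ok = 0
        for s in data.sites:
            k = data.pileups["wt_ip"].coverage[s.contig][s.cim_pos]
            m = data.pileups["wt_ip"].mismatches[s.contig][s.cim_pos]
            if k > 0 and m > 1 and 0.01 < m / k < 0.5:
                ok += 1
        assert ok / len(data.sites) >= 0.95

    def test_input_libraries_carry_no_planted_mismatch_signal(self, pipeline):
        data = pipeline.data
        m_at_sites = np.array(
            [
                data.pileups["wt_input"].mismatches[s.contig][s.cim_pos]
                for s in data.sites
            ]
        )
        # error-rate mismatches only: mean well below 1 at depth 30
        assert m_at_sites.mean() < 0.5


class TestPropertyTables:
    def test_te_decreases_monotonically_with_planted_site_count(self, pipeline):
        data = pipeline.data
        n_dep = {}
        for s in data.sites:
            if s.dependence == "dependent":
                n_dep[s.gene_id] = n_dep.get(s.gene_id, 0) + 1
        props = data.properties.set_index("gene_id")["translational_efficiency"]
        means = {}
        for k in (0, 1, 2, 3):
            genes = [
                g for g in props.index
                if n_dep.get(g, 0) == k or (k == 3 and n_dep.get(g, 0) >= 3)
            ]
            means[k] = props.reindex(genes).dropna().mean()
        assert means[3] < means[2] < means[1] < means[0]

    def test_half_life_distribution_independent_of_methylation(self):
        from scipy.stats import ks_2samp

        cfg = SimConfig(n_genes=2000, seed=4)
        data = simulate_miclip_dataset(cfg)
        meth = {s.gene_id for s in data.sites}
        props = data.properties.set_index("gene_id")["half_life_hours"].dropna()
        x = props[props.index.isin(meth)]
        y = props[~props.index.isin(meth)]
        assert ks_2samp(x, y).statistic < 0.05  # D -> 0 for same distribution


class TestBehaviorTraces:
    def test_total_bias_gives_maximal_pi(self):
        cfg = BehaviorSimConfig(n_units=4, group_bias={"g": 1.0}, seed=0)
        pis = bs.pi_table(simulate_behavior(cfg), cfg.fps, cfg.window_seconds)
        assert np.allclose(pis["half_pi_oct"], 0.5)
        assert np.allclose(pis["full_pi"], 1.0)

    def test_unbiased_flies_give_zero_mean_pi(self):
        cfg = BehaviorSimConfig(n_units=1000, group_bias={"g": 0.5}, seed=0)
        pis = bs.pi_table(simulate_behavior(cfg), cfg.fps, cfg.window_seconds)
        se = pis["full_pi"].std(ddof=1) / np.sqrt(len(pis))
        assert abs(pis["full_pi"].mean()) < 3 * se

    def test_trace_bytes_deterministic_under_seed(self, tmp_path):
        cfg = BehaviorSimConfig(n_units=3, seed=9)
        paths = []
        for name in ("a.tsv", "b.tsv"):
            p = tmp_path / name
            simulate_behavior(cfg).to_csv(p, sep="\t", index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()


class TestSpectralCounts:
    def test_planted_reader_ratio_near_log2_fold(self):
        ratios = []
        for seed in range(20):
            tab, _ = simulate_spectral_counts(
                300, 1, 0, SpectralSimConfig(seed=seed)
            )
            r = pp.enrichment_ratios(tab)
            ratios.append(r.loc["reader_1"].mean())
        assert abs(np.mean(ratios) - 3.0) < 0.3  # log2(8) = 3

    def test_background_ratio_near_zero(self):
        tab, _ = simulate_spectral_counts(400, 0, 0, SpectralSimConfig(seed=1))
        r = pp.enrichment_ratios(tab)
        assert abs(r.to_numpy().mean()) < 0.1

    def test_absent_proteins_flagged_not_silently_dropped(self):
        tab, _ = simulate_spectral_counts(
            400, 2, 0, SpectralSimConfig(seed=3, frac_absent=0.2)
        )
        absent = tab[~tab["present"]]
        assert len(absent) > 0
        assert (absent["count"] == 0).all()
        # readers are always recovered in both replicates
        assert tab[tab["protein"].str.startswith("reader")]["present"].all()
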
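import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import brute_force_ks_distance
from flym6a.io_formats import TranscriptModel
from flym6a.peak_analysis import Peak
from flym6a.target_properties import (
    BootstrapConfig,
    GeneAnnotationIndex,
    annotate_peak,
    annotate_peaks,
    bin_genes_by_peak_count,
    bootstrap_background,
    category_fractions,
    compare_bins,
    ecdf_table,
    ks_two_sample,
)


@pytest.fixture
def index():
    # plus-strand gene: span 100-400, exons (100,250),(310,400),
    # CDS 160-380 -> 5'UTR 100-160, start codon 160-163, 3'UTR 380-400
    m1 = TranscriptModel("gA", "t1", "c", "+", [(100, 250), (310, 400)],
                         cds_start=160, cds_end=380)
    # minus-strand gene: 5'UTR at the high end
    m2 = TranscriptModel("gB", "t2", "c", "-", [(600, 900)],
                         cds_start=650, cds_end=850)
    return GeneAnnotationIndex([m1, m2])


def peak(start, end, label="dependent"):
    return Peak("c", start, end, score=1.0, summit=start, label=label)


class TestAnnotationPrecedence:
    def test_intergenic_peak_is_other(self, index):
        assert annotate_peak(peak(450, 550), index) == "other"

    def test_start_codon_beats_utr5(self, index):
        assert annotate_peak(peak(150, 165), index) == "start_codon"

    def test_utr5_only(self, index):
        assert annotate_peak(peak(110, 150), index) == "utr5"

    def test_utr3_beats_cds(self, index):
        assert annotate_peak(peak(370, 395), index) == "utr3"

    def test_intron_beats_start_codon_and_rest(self, index):
        assert annotate_peak(peak(260, 320), index) == "intron"

    def test_cds_only(self, index):
        assert annotate_peak(peak(200, 240), index) == "cds"

    def test_minus_strand_utr5_on_high_side(self, index):
        assert annotate_peak(peak(860, 880), index) == "utr5"
        assert annotate_peak(peak(610, 640), index) == "utr3"


class TestCategoryFractions:
    def test_fraction_arithmetic(self, index):
        peaks = [peak(110, 150), peak(110, 150), peak(200, 240), peak(450, 500)]
        annotate_peaks(peaks, index)
        frac = category_fractions(peaks)
        assert frac.to_dict() == {"other": 0.25, "utr5": 0.5, "cds": 0.25}
        assert frac.sum() == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            category_fractions([])

    def test_planted_site_segments_recovered_binomially(self, pipeline):
        """Single-nucleotide annotation of the planted sites recovers the
        configured 0.8/0.1/0.1 segment bias (clustering distorts the
        peak-level fractions, so the binomial check is at site level)."""
        index = GeneAnnotationIndex(pipeline.data.models)
        sites = pipeline.data.sites
        site_peaks = [
            Peak(s.contig, s.m6a_pos, s.m6a_pos + 1, 1.0, s.m6a_pos, "dependent")
            for s in sites
        ]
        annotate_peaks(site_peaks, index)
        frac_utr5 = np.mean([p.category == "utr5" for p in site_peaks])
        se = np.sqrt(0.8 * 0.2 / len(site_peaks))
        assert abs(frac_utr5 - 0.8) < 3 * se

    def test_five_prime_region_dominates_peak_annotations(self, pipeline):
        frac = category_fractions(pipeline.split)
        five_prime = frac.get("utr5", 0) + frac.get("start_codon", 0)
        assert five_prime > 0.5


class TestBinning:
    def _peaks(self):
        out = []
        for gene, n, label in [("g1", 0, "dependent"), ("g2", 2, "independent"),
                               ("g3", 1, "dependent"), ("g4", 5, "dependent")]:
            for i in range(n):
                p = peak(1000 * i, 1000 * i + 10, label)
                p.gene_ids = [gene]
                out.append(p)
        return out

    def test_dependent_only_rule_and_edges(self):
        bins = bin_genes_by_peak_count(self._peaks(), ["g1", "g2", "g3", "g4"])
        assert bins.to_dict() == {"g1": "none", "g2": "none", "g3": "1", "g4": "3+"}

    def test_partition_of_gene_universe(self, pipeline):
        bins = pipeline.bins
        genes = [m.gene_id for m in pipeline.data.models]
        assert sorted(bins.index) == sorted(genes)
        assert bins.notna().all()


class TestBootstrap:
    def test_single_value_pool(self):
        values = pd.Series({"g1": 5.0, "g2": 7.0})
        bg = bootstrap_background(values, ["g1"], BootstrapConfig(n_draws=10, seed=0),
                                  draw_size=3)
        assert bg.shape == (30,) and np.all(bg == 5.0)

    def test_deterministic_under_seed(self):
        values = pd.Series(np.arange(50, dtype=float),
                           index=[f"g{i}" for i in range(50)])
        pool = [f"g{i}" for i in range(40)]
        cfg = BootstrapConfig(n_draws=100, seed=3)
        a = bootstrap_background(values, pool, cfg, draw_size=10)
        b = bootstrap_background(values, pool, cfg, draw_size=10)
        assert np.array_equal(a, b)

    def test_resampling_mean_consistent_with_pool(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.normal(size=200),
                         index=[f"g{i}" for i in range(200)])
        pool = list(vals.index)
        bg = bootstrap_background(vals, pool, BootstrapConfig(n_draws=1000, seed=1),
                                  draw_size=20)
        se = vals.std(ddof=1) / np.sqrt(bg.size)
        assert abs(bg.mean() - vals.mean()) < 3 * se * 2  # draws overlap: slack x2

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_background(pd.Series(dtype=float), [], BootstrapConfig())


class TestKsTwoSample:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.D == 0.0 and r.p == 1.0

    def test_disjoint_supports(self):
        r = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert r.D == 1.0

    def test_interleaved_example(self):
        assert ks_two_sample([1, 3], [2, 4]).D == 0.5

    def test_distance_matches_exhaustive_oracle_small_samples(self):
        rng = np.random.default_rng(13)
        grid = np.array([0.0, 0.25, 0.5, 1.0, 2.0])
        for nx, ny in itertools.product(range(1, 9), range(1, 9)):
            x = rng.choice(grid, size=nx)
            y = rng.choice(grid, size=ny)
            assert ks_two_sample(x, y).D == pytest.approx(
                brute_force_ks_distance(x, y), abs=1e-12
            )

    def test_distance_agrees_with_scipy(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            x = rng.normal(size=rng.integers(5, 60))
            y = rng.normal(size=rng.integers(5, 60))
            assert ks_two_sample(x, y).D == pytest.approx(
                stats.ks_2samp(x, y).statistic, abs=1e-12
            )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestCompareBins:
    def _tables(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(200)]
        props = pd.DataFrame(
            {
                "gene_id": genes,
                "log2fc": rng.normal(size=200),
                "half_life_hours": rng.lognormal(1, 0.5, 200),
                "translational_efficiency": rng.lognormal(0, 0.5, 200),
            }
        )
        labels = ["none"] * 150 + ["1"] * 30 + ["2"] * 15 + ["3+"] * 5
        bins = pd.Series(labels, index=genes)
        return props, bins

    def test_invariant_to_row_order(self):
        props, bins = self._tables()
        cfg = BootstrapConfig(n_draws=50, seed=5)
        a = compare_bins(props, bins, cfg)
        shuffled = props.sample(frac=1.0, random_state=9).reset_index(drop=True)
        b = compare_bins(shuffled, bins, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_one_row_per_bin_and_property(self):
        props, bins = self._tables()
        res = compare_bins(props, bins, BootstrapConfig(n_draws=20, seed=0))
        assert len(res) == 9  # 3 bins x 3 properties
        assert set(res["bin"]) == {"1", "2", "3+"}

    def test_planted_te_effect_recovered(self, pipeline):
        res = compare_bins(
            pipeline.data.properties, pipeline.bins,
            BootstrapConfig(seed=0),
            property_columns=("translational_efficiency",),
        ).set_index("bin")
        assert res.loc["3+", "p"] < 0.05
        meds = [res.loc[b, "median_bin"] for b in ("3+", "2", "1")]
        assert meds[0] < meds[1] < meds[2] < res["median_bg"].iloc[0]

    def test_ecdf_export_reaches_one(self):
        props, bins = self._tables()
        tab = ecdf_table(props, bins)
        for (_, _), sub in tab.groupby(["property", "bin"]):
            assert sub["ecdf"].iloc[-1] == pytest.approx(1.0)
            assert sub["value"].is_monotonic_increasing
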
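import numpy as np
import pytest

from oracles import brute_force_regions, brute_force_summits, poisson_llr
from flym6a.cims_calling import TagPileup
from flym6a.io_formats import SignalTrack
from flym6a.peak_analysis import (
    Peak,
    PeakParams,
    call_regions,
    classify_dependence,
    enrichment_track,
    peak_matrix,
    rank_peaks,
    split_peaks,
)


def pileup(name, arr):
    arr = np.asarray(arr, dtype=int)
    return TagPileup(name, {"c": arr}, {"c": np.zeros_like(arr)})


class TestEnrichmentTrack:
    def test_identical_libraries_give_zero(self):
        cov = np.array([5, 10, 0, 3] * 10)
        t = enrichment_track(pileup("ip", cov), pileup("in", cov))
        assert np.all(t["c"] == 0)

    def test_pure_depth_difference_normalized_away(self):
        cov = np.array([5, 10, 2, 3] * 10)
        t = enrichment_track(pileup("ip", 2 * cov), pileup("in", cov))
        assert np.allclose(t["c"], 0, atol=1e-12)

    def test_single_elevated_position_matches_direct_formula(self):
        base = np.full(100, 10)
        ip = base.copy()
        ip[50] = 50
        inp = base.copy()
        inp[50] = 5
        params = PeakParams(pseudocount=1.0)
        t = enrichment_track(pileup("ip", ip), pileup("in", inp), params)
        s_ip = inp.sum() / ip.sum()  # deeper library scaled down
        expect = poisson_llr(s_ip * 50 + 1.0, 5 + 1.0)
        assert t["c"][50] == pytest.approx(expect, rel=1e-9)

    def test_zero_depth_library_rejected(self):
        with pytest.raises(ValueError, match="zero-depth"):
            enrichment_track(pileup("ip", [0, 0]), pileup("in", [1, 1]))


class TestCallRegions:
    def test_gap_within_g_merged_and_short_region_dropped(self):
        params = PeakParams(g=20, l=120, llr_cutoff=2.0)
        llr = np.zeros(600)
        llr[100:170] = 5.0  # 70 nt
        llr[185:255] = 5.0  # gap 15 <= 20 -> merged, total 155 >= 120
        llr[400:500] = 5.0  # isolated 100 nt < 120 -> dropped
        got = call_regions(SignalTrack({"c": llr}), params)
        assert got == [("c", 100, 255)]

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(11)
        params = PeakParams(g=5, l=12, llr_cutoff=1.0)
        for _ in range(100):
            llr = rng.exponential(0.8, size=300)
            got = call_regions(SignalTrack({"c": llr}), params)
            expect = brute_force_regions(llr, 1.0, 5, 12)
            assert [(s, e) for _, s, e in got] == expect

    def test_output_disjoint_sorted_and_long_enough(self, pipeline):
        prev_end = -1
        for contig, s, e in pipeline.regions:
            assert e - s >= pipeline.params.l
            assert s > prev_end - pipeline.params.g  # non-overlapping
            prev_end = e


class TestClassifyDependence:
    def test_constructed_labels(self):
        wt = np.zeros(500)
        wt[100:250] = 5.0
        wt[300:450] = 5.0
        mut = np.zeros(500)
        mut[300:450] = 5.0  # persists only at the second region
        params = PeakParams()
        regions = call_regions(SignalTrack({"c": wt}), params)
        peaks = classify_dependence(
            regions, SignalTrack({"c": wt}), SignalTrack({"c": mut}), params
        )
        assert [(p.start, p.label) for p in peaks] == [
            (100, "dependent"),
            (300, "independent"),
        ]

    def test_mutant_only_regions_emitted_separately(self):
        wt = np.zeros(500)
        mut = np.zeros(500)
        mut[100:300] = 5.0
        params = PeakParams()
        peaks = classify_dependence(
            [], SignalTrack({"c": wt}), SignalTrack({"c": mut}), params
        )
        assert [p.label for p in peaks] == ["mutant_only"]

    def test_labels_partition_wt_regions(self, pipeline):
        wt_ivs = {(c, s, e) for c, s, e in pipeline.regions}
        labeled = {
            (p.contig, p.start, p.end)
            for p in pipeline.peaks
            if p.label in ("dependent", "independent")
        }
        mutant_only = {
            (p.contig, p.start, p.end)
            for p in pipeline.peaks
            if p.label == "mutant_only"
        }
        assert labeled == wt_ivs
        assert not (mutant_only & wt_ivs)

    def test_planted_dependence_recovered(self, recovery_pipeline):
        data = recovery_pipeline.data
        dep_ivs = [
            (p.start, p.end)
            for p in recovery_pipeline.peaks
            if p.label == "dependent"
        ]

        def in_dep(pos):
            return any(s <= pos < e for s, e in dep_ivs)

        dep_sites = [s for s in data.sites if s.dependence == "dependent"]
        ind_sites = [s for s in data.sites if s.dependence == "independent"]
        recall = np.mean([in_dep(s.cim_pos) for s in dep_sites])
        mislabel = np.mean([in_dep(s.cim_pos) for s in ind_sites])
        assert recall >= 0.90
        assert mislabel <= 0.05


class TestSplitPeaks:
    def _run(self, signal, **kw):
        params = PeakParams(**kw)
        peak = Peak("c", 0, len(signal), score=1.0, summit=0, label="dependent")
        return split_peaks([peak], SignalTrack({"c": np.asarray(signal, float)}), params)

    def test_monotone_signal_unchanged(self):
        got = self._run(np.linspace(1, 50, 200))
        assert [(p.start, p.end) for p in got] == [(0, 200)]

    def test_twin_summits_with_deep_valley_split(self):
        sig = np.concatenate(
            [np.linspace(10, 100, 80), np.linspace(100, 30, 40),
             np.linspace(30, 80, 40), np.linspace(80, 10, 80)]
        )
        got = self._run(sig)
        assert len(got) == 2
        # children tile the parent exactly
        assert got[0].start == 0 and got[1].end == len(sig)
        assert got[0].end == got[1].start

    def test_shallow_valley_not_split(self):
        sig = np.concatenate(
            [np.linspace(10, 100, 80), np.linspace(100, 50, 40),
             np.linspace(50, 80, 40), np.linspace(80, 10, 80)]
        )
        assert len(self._run(sig)) == 1  # valley 50 >= 0.5 x 80

    def test_valley_rule_matches_extrema_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            sig = np.abs(rng.normal(50, 20, size=rng.integers(60, 200)))
            got = self._run(sig, min_child=1)
            summits = brute_force_summits(sig)
            expected_cuts = 0
            for a, b in zip(summits, summits[1:]):
                valley = sig[a:b + 1].min()
                if valley < 0.5 * min(sig[a], sig[b]):
                    expected_cuts += 1
            assert len(got) == expected_cuts + 1

    def test_children_inherit_label_and_tile_parent(self, pipeline):
        parents = {
            (p.contig, p.start, p.end): p.label for p in pipeline.peaks
        }
        covered = {}
        for child in pipeline.split:
            host = next(
                (key for key in parents
                 if key[0] == child.contig
                 and key[1] <= child.start and child.end <= key[2]),
                None,
            )
            assert host is not None
            assert child.label == parents[host]
            covered[host] = covered.get(host, 0) + child.length
        for (c, s, e), total in covered.items():
            assert total == e - s

    def test_undersized_children_remerged(self):
        sig = np.concatenate(
            [np.linspace(10, 100, 10), np.linspace(100, 2, 10),
             np.linspace(2, 90, 100), np.linspace(90, 10, 100)]
        )
        got = self._run(sig, min_child=50)
        assert len(got) == 1


class TestRankAndMatrix:
    def test_ties_broken_by_genomic_coordinate(self):
        peaks = [
            Peak("c2", 5, 10, 3.0, 6, "dependent"),
            Peak("c1", 50, 60, 3.0, 55, "dependent"),
            Peak("c1", 5, 10, 8.0, 6, "dependent"),
        ]
        got = rank_peaks(peaks)
        assert [(p.contig, p.start) for p in got] == [
            ("c1", 5), ("c1", 50), ("c2", 5)
        ]
        assert rank_peaks(peaks[::-1]) == got

    def test_uniform_enrichment_gives_flat_body_and_flanks(self):
        n = 2000
        ip = np.full(n, 10)
        inp = np.full(n, 10)
        ip[800:1000] = 40  # 4x body
        peak = Peak("c", 800, 1000, 1.0, 900, "dependent")
        params = PeakParams(pseudocount=0.0)
        mat = peak_matrix([peak], pileup("ip", ip), pileup("in", inp), params)
        row = mat[0]
        s_ip = inp.sum() / ip.sum()
        body_expect = 4 * s_ip
        assert np.allclose(row[50:250], body_expect, rtol=1e-9)
        assert np.allclose(row[:50], s_ip, rtol=1e-9)
        assert np.allclose(row[250:], s_ip, rtol=1e-9)

    def test_contig_edge_flank_marked_missing(self):
        ip = np.full(700, 20)
        inp = np.full(700, 10)
        peak = Peak("c", 0, 200, 1.0, 10, "dependent")
        mat = peak_matrix([peak], pileup("ip", ip), pileup("in", inp))
        assert np.isnan(mat[0][:50]).all()
        assert not np.isnan(mat[0][50:]).any()

    def test_dependent_rows_hotter_than_mutant_evaluation(self, pipeline):
        data = pipeline.data
        dep = [p for p in pipeline.peaks if p.label == "dependent"]
        wt_mat = peak_matrix(
            dep, data.pileups["wt_ip"], data.pileups["wt_input"], pipeline.params
        )
        mut_mat = peak_matrix(
            dep, data.pileups["mut_ip"], data.pileups["mut_input"], pipeline.params
        )
        assert np.nanmean(wt_mat) > 2 * np.nanmean(mut_mat)
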
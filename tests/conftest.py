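import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from flym6a import peak_analysis as pa
from flym6a import target_properties as tp
from flym6a.cims_calling import call_cims, cims_in_top_peaks
from flym6a.io_formats import SignalTrack
from flym6a.synthetic_data import SimConfig, simulate_miclip_dataset


@dataclass
class Pipeline:
    """A simulated dataset pushed through the whole peak pipeline."""

    data: object
    params: pa.PeakParams
    wt_track: SignalTrack
    mut_track: SignalTrack
    regions: list
    peaks: list
    split: list
    bins: object
    cims: list
    top_cims: list

    @property
    def planted_positions(self):
        return {(s.contig, s.cim_pos) for s in self.data.sites}


def _run_pipeline(cfg: SimConfig) -> Pipeline:
    data = simulate_miclip_dataset(cfg)
    params = pa.PeakParams()
    wt = pa.enrichment_track(data.pileups["wt_ip"], data.pileups["wt_input"], params)
    mut = pa.enrichment_track(data.pileups["mut_ip"], data.pileups["mut_input"], params)
    regions = pa.call_regions(wt, params)
    peaks = pa.classify_dependence(regions, wt, mut, params)
    ip_sig = SignalTrack(
        {c: a.astype(float) for c, a in data.pileups["wt_ip"].coverage.items()}
    )
    split = pa.split_peaks(peaks, ip_sig, params)
    tp.annotate_peaks(split, tp.GeneAnnotationIndex(data.models))
    bins = tp.bin_genes_by_peak_count(split, [m.gene_id for m in data.models])
    cims = call_cims(data.pileups["wt_ip"], data.genome, models=data.models)
    top = cims_in_top_peaks(cims, split, 1000)
    return Pipeline(data, params, wt, mut, regions, peaks, split, bins, cims, top)


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    """Default study conditions, seed 0."""
    return _run_pipeline(SimConfig(seed=0))


@pytest.fixture(scope="session")
def recovery_pipeline() -> Pipeline:
    """The 200-gene, seed-7 configuration used for planted-site recovery."""
    return _run_pipeline(SimConfig(n_genes=200, seed=7))
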
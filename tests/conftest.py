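import numpy as np
import pytest

from polyspread import (
    SimulationConfig,
    build_coverage,
    compute_scaling_factor,
    select_target_regions,
    simulate_experiment,
)


TINY_BASE = dict(
    genome_length=1_200_000,
    n_chroms=1,
    n_peaks=50,
    peak_width_range=(1500, 3000),
    peak_gap_range=(10_000, 14_000),
    n_genes=100,
    ip_depth=400_000,
    input_depth=100_000,
    spikein_depth=20_000,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_experiment():
    """A desk-scale two-condition experiment: spreading WT vs confined KO."""
    wt = SimulationConfig(**TINY_BASE, decay_length=1200.0, global_level=1.0)
    ko = SimulationConfig(**TINY_BASE, decay_length=0.0, global_level=0.3)
    return simulate_experiment({"WT": wt, "KO": ko})


@pytest.fixture(scope="session")
def tiny_regions(tiny_experiment):
    return select_target_regions(
        tiny_experiment.peaks["SUZ12"], tiny_experiment.peaks["RING1B"]
    )


@pytest.fixture(scope="session")
def tiny_tracks(tiny_experiment):
    """Spike-in-scaled IP coverage per condition (H3K27me3 samples only)."""
    tracks = {}
    for sample in tiny_experiment.samples:
        if sample.antibody != "H3K27me3":
            continue
        factor = compute_scaling_factor(sample, "spikein")
        tracks[sample.condition] = build_coverage(
            sample.ip_target, fragment_length=50, binsize=25, factor=factor
        )
    return tracks
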
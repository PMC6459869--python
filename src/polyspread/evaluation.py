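"""Reference evaluation experiments for the pipeline's key properties.

Each function simulates a complete ChIP-Rx experiment under fixed study
conditions, runs the normal analysis path (scaling, coverage, target-region
selection, spreading table) and returns the measured quantities together with
their analytic expectations.  These back both the acceptance test suite and
``scripts/acceptance.py``.

Problem sizes are chosen so counting noise is small against the quantity under
test (see docs/methods.md): 300 domains per genome throughout; read depths per
experiment range from 1e6 (normalization recovery) to 2e7 (replicate
correlation, where the per-flank fragment count must push measurement noise
well below the between-domain spreading variance).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .normalization import build_coverage, compute_scaling_factor
from .regions import select_target_regions
from .spreading_stats import (
    compare_densities,
    ratio_correlation,
    records_frame,
    spreading_table,
)
from .synthetic_data import (
    SimulationConfig,
    expected_flank_ratio,
    simulate_experiment,
)

__all__ = [
    "spikein_recovery",
    "flank_ratio_grid",
    "spreading_discrimination",
    "active_fraction_recovery",
]


def _ip_track(sample, basis="spikein", fragment_length=50, binsize=25):
    factor = compute_scaling_factor(sample, basis)
    return build_coverage(sample.ip_target, fragment_length, binsize, factor)


def spikein_recovery(seed: int) -> dict:
    """Two conditions differing only in global signal level (1.0 vs 0.5).

    Returns the between-condition ratio of genome-wide mean IP signal under
    spike-in scaling (should recover the 0.5 global level, up to the small
    uniform-background contribution) and under library-size scaling (pinned
    to 1 by construction, so the global loss is invisible).
    """
    base = dict(seed=seed % 2**31)
    full = SimulationConfig(**base, global_level=1.0)
    half = SimulationConfig(**base, global_level=0.5)
    exp = simulate_experiment({"full": full, "half": half},
                              include_h3k36me3=False)
    means = {}
    for basis in ("spikein", "libsize"):
        for s in exp.samples:
            track = _ip_track(s, basis, fragment_length=200, binsize=200)
            means[(basis, s.condition)] = track.genome_mean()
    n = sum(s.ip_target.n_reads for s in exp.samples)
    return {
        "spikein_ratio": means[("spikein", "half")] / means[("spikein", "full")],
        "libsize_ratio": means[("libsize", "half")] / means[("libsize", "full")],
        "true_global_level": 0.5,
        "n_reads": n,
    }


GRID_LAMBDAS = (0.0, 300.0, 600.0, 1200.0, 2400.0)


def flank_ratio_grid(
    seed: int, lambdas: tuple[float, ...] = GRID_LAMBDAS, flank_bp: int = 1200
) -> dict:
    """Median empirical out/in ratio across a decay-length grid.

    Saturated inside signal (300-fold over background), homogeneous decay per
    condition (no between-domain dispersion), so the median ratio should match
    the closed form (lambda/F)(1 - e^(-F/lambda)) per condition.
    """
    base = dict(
        seed=seed % 2**31,
        enrichment=300.0,
        decay_dispersion=0.0,
        frac_peaks_nonsig=0.0,
        frac_unpaired=0.0,
        ip_depth=3_000_000,
        input_depth=100_000,
    )
    configs = {
        f"lam{int(lam)}": SimulationConfig(**base, decay_length=lam)
        for lam in lambdas
    }
    exp = simulate_experiment(configs, include_h3k36me3=False)
    regions = select_target_regions(exp.peaks["SUZ12"], exp.peaks["RING1B"])
    out = {}
    for sample, lam in zip(exp.samples, lambdas):
        track = _ip_track(sample)
        frame = records_frame(spreading_table(track, regions, flank_bp))
        frame = frame[~frame.clipped]
        median = float(pd.concat([frame.ratio5, frame.ratio3]).median())
        out[lam] = {
            "median_ratio": median,
            "expected_ratio": expected_flank_ratio(lam, flank_bp),
            "n_regions": int(len(frame)),
        }
    return out


def spreading_discrimination(seed: int, flank_bp: int = 300) -> dict:
    """Spreading WT (two replicates) against a confined, globally reduced KO.

    300 co-occupied domains per condition; WT decay length 1200 bp with
    between-domain lognormal dispersion, KO fully confined at 30% global
    level.  The flank window (300 bp) is kept small against the WT decay
    length so the WT out/in ratio sits near 1, the regime the statistic is
    designed to contrast against confinement.
    """
    base = dict(
        seed=seed % 2**31,
        genome_length=3_600_000,
        n_chroms=2,
        n_peaks=300,
        peak_width_range=(1000, 2000),
        peak_gap_range=(6000, 9000),
        margin=8000,
        n_genes=300,
        enrichment=100.0,
        decay_dispersion=0.75,
        frac_peaks_nonsig=0.0,
        frac_unpaired=0.0,
        ip_depth=20_000_000,
        input_depth=100_000,
        spikein_depth=50_000,
    )
    wt = dict(decay_length=1200.0, global_level=1.0)
    ko = dict(decay_length=0.0, global_level=0.3)
    configs = {
        "WT_rep1": SimulationConfig(**base, **wt),
        "WT_rep2": SimulationConfig(**base, **wt),
        "KO": SimulationConfig(**base, **ko),
    }
    exp = simulate_experiment(configs, include_h3k36me3=False)
    regions = select_target_regions(exp.peaks["SUZ12"], exp.peaks["RING1B"])
    frames = {}
    for sample in exp.samples:
        frame = records_frame(
            spreading_table(_ip_track(sample), regions, flank_bp)
        ).set_index("region_id")
        frames[sample.condition] = frame[~frame.clipped]
    common = frames["WT_rep1"].index
    ttest = compare_densities(
        frames["WT_rep1"].ratio5, frames["KO"].loc[common].ratio5, "student_t"
    )
    reg = ratio_correlation(
        frames["WT_rep1"].ratio5, frames["WT_rep2"].loc[common].ratio5
    )
    return {
        "wt_median_ratio": float(frames["WT_rep1"].ratio5.median()),
        "ko_median_ratio": float(frames["KO"].ratio5.median()),
        "t_statistic": ttest.statistic,
        "t_pvalue": ttest.p_value,
        "replicate_r_squared": reg.r_squared,
        "n_regions": int(len(common)),
        "flank_bp": flank_bp,
    }


def active_fraction_recovery(seed: int) -> dict:
    """Recover the simulated fraction of transcribed (H3K36me3+) genes."""
    import collections

    from .normalization import Sample, subtract_input
    from .regions import stratify_genes

    cfg = SimulationConfig(
        seed=seed % 2**31,
        genome_length=2_400_000,
        n_chroms=1,
        n_peaks=100,
        n_genes=220,
        frac_active=0.4,
        frac_peaks_nonsig=0.0,
        frac_unpaired=0.0,
        ip_depth=800_000,
        input_depth=200_000,
    )
    exp = simulate_experiment({"WT": cfg})
    regions = select_target_regions(exp.peaks["SUZ12"], exp.peaks["RING1B"])
    sample = next(s for s in exp.samples if s.antibody == "H3K36me3")
    ip = build_coverage(sample.ip_target, 200, 50,
                        compute_scaling_factor(sample, "libsize"))
    inp = build_coverage(sample.input_target, 200, 50,
                         compute_scaling_factor(
                             Sample("x", "x", sample.input_target), "libsize"))
    labels = stratify_genes(exp.genes, regions, subtract_input(ip, inp))
    counts = collections.Counter(labels.values())
    frac = counts["K36pos"] / (counts["K36pos"] + counts["K36neg"])
    return {
        "k36pos_fraction": frac,
        "true_fraction": cfg.frac_active,
        "n_genes": len(exp.genes),
    }
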
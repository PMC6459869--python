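import collections

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyspread.io_formats import GeneModel, GenomicInterval, Peak
from polyspread.normalization import Sample, build_coverage, compute_scaling_factor, subtract_input
from polyspread.regions import (
    TargetRegion,
    assign_promoters,
    select_target_regions,
    spreading_flanks,
    stratify_genes,
)
from polyspread.tracks import CoverageTrack


def _peak(chrom, start, end, name, nlp=2.0):
    return Peak(GenomicInterval(chrom, start, end), name, nlp * 10, nlp)


def _random_peaks(rng, n, prefix):
    peaks = []
    for i in range(n):
        start = int(rng.integers(0, 99_000))
        width = int(rng.integers(100, 1500))
        nlp = float(rng.uniform(0, 4))
        peaks.append(_peak(f"chr{rng.integers(1, 4)}", start, start + width,
                           f"{prefix}{i:04d}", nlp))
    return peaks


def _brute_force_selection(suz12, ring1b, min_nlp=1.0, min_overlap=1):
    selected = []
    for s in suz12:
        if s.neg_log10_p < min_nlp:
            continue
        best, best_key = None, None
        for r in ring1b:
            if r.neg_log10_p < min_nlp:
                continue
            ov = s.interval.overlap(r.interval)
            if ov >= min_overlap:
                key = (-ov, r.interval.start, r.name)
                if best_key is None or key < best_key:
                    best, best_key = r, key
        if best is not None:
            selected.append((s.name, best.name))
    order = {}
    for s in suz12:
        order[s.name] = (s.interval.chrom, s.interval.start, s.interval.end)
    return sorted(selected, key=lambda t: order[t[0]])


class TestSelectTargetRegions:
    def test_single_overlap(self):
        suz = [_peak("chr1", 100, 200, "s1"), _peak("chr1", 300, 400, "s2")]
        ring = [_peak("chr1", 150, 250, "r1")]
        (region,) = select_target_regions(suz, ring)
        assert region.peak.name == "s1" and region.partner.name == "r1"
        # the SUZ12 span defines the region
        assert region.interval == suz[0].interval

    def test_significance_filter_excludes(self):
        suz = [_peak("chr1", 100, 200, "s1", nlp=0.5)]
        ring = [_peak("chr1", 150, 250, "r1")]
        assert select_target_regions(suz, ring) == []

    def test_min_overlap_threshold(self):
        suz = [_peak("chr1", 100, 200, "s1")]
        ring = [_peak("chr1", 190, 300, "r1")]
        assert len(select_target_regions(suz, ring, min_overlap=10)) == 1
        assert select_target_regions(suz, ring, min_overlap=11) == []

    def test_matches_brute_force_on_random_peaks(self):
        rng = np.random.default_rng(123)
        suz = _random_peaks(rng, 400, "s")
        ring = _random_peaks(rng, 400, "r")
        got = [(t.peak.name, t.partner.name) for t in select_target_regions(suz, ring)]
        assert got == _brute_force_selection(suz, ring)


class TestSpreadingFlanks:
    def test_flank_geometry(self):
        region = TargetRegion(_peak("chr1", 5000, 7000, "s"), _peak("chr1", 5000, 7000, "r"))
        fl = spreading_flanks(region, 1200)
        assert fl.out5 == GenomicInterval("chr1", 3800, 5000)
        assert fl.out3 == GenomicInterval("chr1", 7000, 8200)
        assert not fl.clipped

    def test_minus_strand_gene_swaps_labels(self):
        gene = GeneModel(GenomicInterval("chr1", 5000, 7000, "-"), "g")
        region = TargetRegion(_peak("chr1", 5000, 7000, "s"),
                              _peak("chr1", 5000, 7000, "r"),
                              gene=gene, orientation="gene_strand")
        fl = spreading_flanks(region, 1200)
        assert fl.out5 == GenomicInterval("chr1", 7000, 8200)
        assert fl.out3 == GenomicInterval("chr1", 3800, 5000)

    def test_clipping_at_chromosome_start(self):
        region = TargetRegion(_peak("chr1", 500, 2000, "s"), _peak("chr1", 500, 2000, "r"))
        fl = spreading_flanks(region, 1200)
        assert fl.out5 == GenomicInterval("chr1", 0, 500)
        assert fl.clipped5 and fl.clipped

    def test_no_room_at_all(self):
        region = TargetRegion(_peak("chr1", 0, 2000, "s"), _peak("chr1", 0, 2000, "r"))
        fl = spreading_flanks(region, 1200)
        assert fl.out5 is None and fl.clipped5

    @given(
        start=st.integers(0, 50_000),
        width=st.integers(100, 5000),
        flank=st.integers(1, 4000),
    )
    @settings(max_examples=100, deadline=None)
    def test_flanks_disjoint_from_inside(self, start, width, flank):
        region = TargetRegion(
            _peak("c", start, start + width, "s"), _peak("c", start, start + width, "r")
        )
        fl = spreading_flanks(region, flank, chrom_lengths={"c": 60_000})
        widths = 0
        for out in (fl.out5, fl.out3):
            if out is not None:
                assert out.overlap(fl.inside) == 0
                widths += len(out)
        if not fl.clipped:
            assert widths == 2 * flank


class TestAssignPromoters:
    GENES = [
        GeneModel(GenomicInterval("chr1", 1200, 3000, "+"), "gA"),
        GeneModel(GenomicInterval("chr1", 5000, 9000, "+"), "gB"),
    ]

    def test_nearest_tss_within_window(self):
        peaks = [_peak("chr1", 900, 1100, "p")]
        assert assign_promoters(peaks, self.GENES, 2500)["p"].gene_id == "gA"

    def test_outside_window_unassigned(self):
        peaks = [_peak("chr1", 20_000, 20_200, "p")]
        assert assign_promoters(peaks, self.GENES, 2500) == {}

    def test_equidistant_tie_breaks_lexicographically(self):
        genes = [
            GeneModel(GenomicInterval("chr1", 2000, 4000, "+"), "gB"),
            GeneModel(GenomicInterval("chr1", 0, 1000, "-"), "gA"),  # tss 999
        ]
        # peak center 1500 is 501 bp from gA's TSS (999) and 500 from gB's (2000)
        peaks = [_peak("chr1", 1400, 1602, "p")]  # center 1501 -> tie not yet
        got = assign_promoters(peaks, genes, 2500)
        assert got["p"].gene_id == "gB"
        # exact tie: center 1500 is 500.5... make a true tie at distances 500/500
        peaks = [_peak("chr1", 1399, 1601, "p")]  # center 1500
        genes2 = [
            GeneModel(GenomicInterval("chr1", 2000, 4000, "+"), "gB"),
            GeneModel(GenomicInterval("chr1", 0, 1001, "-"), "gA"),  # tss 1000
        ]
        assert assign_promoters(peaks, genes2, 2500)["p"].gene_id == "gA"


class TestStratifyGenes:
    def _flat_track(self, value=0.0, length=200_000):
        n = length // 50
        return CoverageTrack(
            50, {"chr1": np.full(n, float(value))}, {"chr1": length}, scaled=True
        )

    def _region(self, start, end):
        return TargetRegion(_peak("chr1", start, end, "s"), _peak("chr1", start, end, "r"))

    def test_pcg_precedence_over_k36(self):
        gene = GeneModel(GenomicInterval("chr1", 10_000, 14_000, "+"), "g")
        labels = stratify_genes(
            [gene], [self._region(9000, 11_000)], self._flat_track(5.0)
        )
        assert labels == {"g": "PcG"}

    def test_flat_zero_track_all_k36neg(self):
        genes = [
            GeneModel(GenomicInterval("chr1", 10_000, 14_000, "+"), "g1"),
            GeneModel(GenomicInterval("chr1", 50_000, 53_000, "-"), "g2"),
        ]
        labels = stratify_genes(genes, [], self._flat_track(0.0))
        assert set(labels.values()) == {"K36neg"}

    def test_labels_partition_gene_set(self, tiny_experiment, tiny_regions):
        sample = next(
            s for s in tiny_experiment.samples if s.antibody == "H3K36me3"
        )
        track = build_coverage(
            sample.ip_target, 200, 50, compute_scaling_factor(sample, "libsize")
        )
        labels = stratify_genes(tiny_experiment.genes, tiny_regions, track)
        assert len(labels) == len(tiny_experiment.genes)
        counts = collections.Counter(labels.values())
        assert sum(counts.values()) == len(tiny_experiment.genes)

    def test_recovers_active_fraction(self):
        # all domains significant and partnered so non-PcG genes are exactly
        # the background genes, 40% of which carry gene-body signal
        from polyspread.synthetic_data import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(
            genome_length=1_200_000, n_chroms=1, n_peaks=50,
            peak_width_range=(1500, 3000), peak_gap_range=(10_000, 14_000),
            n_genes=100, frac_active=0.4, frac_peaks_nonsig=0.0,
            frac_unpaired=0.0, ip_depth=400_000, input_depth=100_000,
            spikein_depth=20_000, seed=19,
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
        assert frac == pytest.approx(0.4, abs=0.05)
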
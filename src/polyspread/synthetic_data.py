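"""Synthetic ChIP-Rx experiments with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, for two or more conditions sharing one genome layout:

* **Enrichment domains** (SUZ12-peak-like) whose signal is flat inside the
  bound span and decays outside it with an exponential boundary kernel
  ``exp(-d / lambda)``; each domain draws its own decay length multiplier from a
  lognormal so domains differ in spreading extent, as real Polycomb domains do.
* **A global signal level** ``g`` in [0, 1] multiplying enrichment only.  The
  realized target-genome IP yield scales with the total immunoprecipitated
  material, while the exogenous spike-in yield stays constant — the physics
  that makes spike-in normalization recover ``g`` when library-size scaling
  cannot.
* **Transcribed-body H3K36me3 signal** on a configurable fraction of
  non-Polycomb genes, for gene stratification.
* **Background and input reads** uniform over the target genome.

Reads are emitted as single-end 5' positions with strand, as BED-style
intervals of the configured read length; fragment extension happens downstream
in :mod:`polyspread.normalization`.

Target and spike-in genomes live in one coordinate namespace distinguished by
chromosome prefixes (``t_`` / ``s_``).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomicInterval, Peak, write_genes, write_peaks
from .normalization import ReadSet, Sample

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "spreading_profile",
    "expected_flank_ratio",
    "simulate_experiment",
    "write_truth",
    "read_truth",
    "write_experiment",
]

TRUTH_COLUMNS = [
    "condition",
    "peak_id",
    "chrom",
    "start",
    "end",
    "decay_length_bp",
    "global_level",
    "expected_in_rel",
    "expected_out5_rel",
    "expected_out3_rel",
    "expected_ratio",
    "flank_bp",
]


@dataclass
class SimulationConfig:
    """One condition of a ChIP-Rx simulation.

    Layout fields (genome geometry, peak/gene placement, seed) must be shared
    across the conditions of one experiment; ``decay_length``, ``global_level``
    and depths may vary per condition.

    ``ip_depth`` is the *nominal* target-genome IP depth of the sample at full
    signal (``global_level = 1``); the realized expected depth scales with the
    total immunoprecipitated material, i.e. by ``W(g)/W(1)`` where ``W`` is the
    summed per-bp IP propensity.  ``background_rate`` (reads/bp) is used
    directly only when ``ip_depth`` is 0.
    """

    # geometry (shared across conditions)
    genome_length: int = 6_000_000
    n_chroms: int = 2
    n_peaks: int = 300
    peak_width_range: tuple[int, int] = (1500, 3000)
    peak_gap_range: tuple[int, int] = (10_000, 14_000)
    margin: int = 8_000
    n_genes: int = 600
    frac_active: float = 0.4
    decay_dispersion: float = 0.75  # lognormal sigma of per-domain decay multiplier
    frac_peaks_nonsig: float = 0.05  # SUZ12 calls below the significance cutoff
    frac_unpaired: float = 0.10  # SUZ12 peaks without a RING1B partner call
    spikein_genome_length: int = 600_000
    read_length: int = 36
    seed: int = 1337
    # condition-specific signal model
    decay_length: float = 1200.0
    enrichment: float = 100.0
    global_level: float = 1.0
    background_rate: float = 0.005
    ip_depth: int = 1_000_000
    input_depth: int = 500_000
    spikein_depth: int = 50_000
    fragment_length: int = 200

    LAYOUT_FIELDS = (
        "genome_length", "n_chroms", "n_peaks", "peak_width_range",
        "peak_gap_range", "margin", "n_genes", "frac_active",
        "decay_dispersion", "frac_peaks_nonsig", "frac_unpaired",
        "spikein_genome_length", "read_length", "seed",
    )

    def __post_init__(self) -> None:
        for name in ("genome_length", "n_chroms", "n_peaks", "n_genes",
                     "ip_depth", "input_depth", "spikein_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.global_level <= 1.0:
            raise ValueError("global_level must be in [0, 1]")
        if self.decay_length < 0:
            raise ValueError("decay_length must be >= 0")
        if self.enrichment < 1.0:
            raise ValueError("enrichment is fold over background; must be >= 1")
        if self.peak_width_range[0] < 100 or self.peak_width_range[0] > self.peak_width_range[1]:
            raise ValueError("invalid peak_width_range")
        if self.fragment_length < self.read_length:
            raise ValueError("fragment_length must be >= read_length")


@dataclass
class ExperimentLayout:
    """Shared genome geometry: domains, per-domain decay multipliers, genes."""

    chrom_lengths: dict[str, int]
    spikein_lengths: dict[str, int]
    peaks: dict[str, list[Peak]]  # "SUZ12" and "RING1B" call sets incl. decoys
    domain_spans: list[GenomicInterval]  # true domains, index-aligned with mults
    decay_mult: np.ndarray
    genes: list[GeneModel]
    active_gene_ids: set[str]
    pcg_gene_ids: set[str]


@dataclass
class SimulatedExperiment:
    samples: list[Sample]
    peaks: dict[str, list[Peak]]
    genes: list[GeneModel]
    truth: pd.DataFrame
    layout: ExperimentLayout
    configs: dict[str, SimulationConfig]


def spreading_profile(distance_bp, decay_length: float):
    """Relative enrichment ``exp(-d/lambda)`` beyond a domain edge.

    ``lambda = 0`` is the fully confined limit: 1 at the edge, 0 beyond.
    Accepts scalars or arrays of distances.
    """
    d = np.asarray(distance_bp, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_bp must be >= 0")
    if decay_length < 0:
        raise ValueError("decay_length must be >= 0")
    if decay_length == 0:
        out = np.where(d == 0, 1.0, 0.0)
    else:
        out = np.exp(-d / decay_length)
    return float(out) if np.isscalar(distance_bp) else out


def expected_flank_ratio(decay_length: float, flank_bp: float) -> float:
    """Closed-form expected out/in density ratio over a flank ``[0, F]``.

    For saturated inside signal, the mean relative enrichment over the flank is
    ``(lambda/F) * (1 - exp(-F/lambda))``; 0 in the confined limit.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    if decay_length <= 0:
        return 0.0
    return (decay_length / flank_bp) * (1.0 - math.exp(-flank_bp / decay_length))


# ---------------------------------------------------------------------------
# layout


def _build_layout(cfg: SimulationConfig) -> ExperimentLayout:
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    per_chrom = cfg.genome_length // cfg.n_chroms
    chrom_lengths = {f"t_chr{i + 1}": per_chrom for i in range(cfg.n_chroms)}
    spikein_lengths = {"s_chr1": cfg.spikein_genome_length}

    w0, w1 = cfg.peak_width_range
    g0, g1 = cfg.peak_gap_range
    chroms = list(chrom_lengths)
    domains: list[GenomicInterval] = []
    gaps: list[tuple[str, int, int]] = []  # inter-domain space usable for decoys/genes
    ci, pos = 0, cfg.margin
    while len(domains) < cfg.n_peaks:
        width = int(rng.integers(w0, w1 + 1))
        chrom = chroms[ci]
        if pos + width + cfg.margin > chrom_lengths[chrom]:
            ci += 1
            pos = cfg.margin
            if ci >= len(chroms):
                raise ValueError(
                    "genome_length too small for the requested domain layout"
                )
            continue
        domains.append(GenomicInterval(chrom, pos, pos + width))
        gap = int(rng.integers(g0, g1 + 1))
        gaps.append((chrom, pos + width, min(pos + width + gap, chrom_lengths[chrom])))
        pos += width + gap

    decay_mult = rng.lognormal(0.0, cfg.decay_dispersion, size=cfg.n_peaks)

    # peak calls: SUZ12 spans == true domains; RING1B partners jittered
    n_nonsig = int(round(cfg.frac_peaks_nonsig * cfg.n_peaks))
    nonsig = set(rng.choice(cfg.n_peaks, size=n_nonsig, replace=False)) if n_nonsig else set()
    n_unpaired = int(round(cfg.frac_unpaired * cfg.n_peaks))
    unpaired = set(rng.choice(cfg.n_peaks, size=n_unpaired, replace=False)) if n_unpaired else set()

    suz12: list[Peak] = []
    ring1b: list[Peak] = []
    for i, dom in enumerate(domains):
        nlp = float(rng.uniform(0.0, 0.9)) if i in nonsig else float(1.0 + rng.exponential(3.0))
        suz12.append(Peak(dom, f"suz12_{i:04d}", score=nlp * 10, neg_log10_p=nlp))
        if i not in unpaired:
            jitter = int(0.1 * len(dom))
            s = dom.start + int(rng.integers(-jitter, jitter + 1))
            e = dom.end + int(rng.integers(-jitter, jitter + 1))
            s, e = max(0, s), max(max(0, s) + 50, e)
            r_nlp = float(1.0 + rng.exponential(3.0))
            ring1b.append(
                Peak(GenomicInterval(dom.chrom, s, e), f"ring1b_{i:04d}",
                     score=r_nlp * 10, neg_log10_p=r_nlp)
            )
    # decoy calls inside gaps: significant but unpartnered, alternating sets
    n_decoy = cfg.n_peaks // 10
    decoy_gaps = [g for g in gaps if g[2] - g[1] >= 2 * cfg.margin // 2 + 2000]
    for j in range(min(n_decoy, len(decoy_gaps))):
        chrom, lo, hi = decoy_gaps[j * len(decoy_gaps) // max(n_decoy, 1)]
        width = int(rng.integers(600, 1001))
        start = lo + 1500
        if start + width + 1500 > hi:
            continue
        iv = GenomicInterval(chrom, start, start + width)
        nlp = float(1.0 + rng.exponential(2.0))
        if j % 2 == 0:
            suz12.append(Peak(iv, f"suz12_decoy_{j:03d}", nlp * 10, nlp))
        else:
            ring1b.append(Peak(iv, f"ring1b_decoy_{j:03d}", nlp * 10, nlp))

    # genes: one Polycomb gene per domain (TSS at domain center), background
    # genes in the gaps with >= 3 kb clearance from any domain edge
    genes: list[GeneModel] = []
    pcg_ids: set[str] = set()
    for i, dom in enumerate(domains):
        strand = "+" if rng.random() < 0.5 else "-"
        tss = (dom.start + dom.end) // 2
        length = int(rng.integers(2000, 5001))
        if strand == "+":
            iv = GenomicInterval(dom.chrom, tss, tss + length, "+")
        else:
            iv = GenomicInterval(dom.chrom, max(0, tss - length + 1), tss + 1, "-")
        gid = f"pcg_{i:04d}"
        genes.append(GeneModel(iv, gid))
        pcg_ids.add(gid)

    n_background = max(0, cfg.n_genes - len(genes))
    clearance = 3000
    bg_genes: list[GeneModel] = []
    for chrom, lo, hi in gaps:
        if len(bg_genes) >= n_background:
            break
        lo2, hi2 = lo + clearance, hi - clearance
        if hi2 - lo2 < 2200:
            continue
        length = int(rng.integers(2000, min(5001, hi2 - lo2 + 1)))
        start = int(rng.integers(lo2, hi2 - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"bg_{len(bg_genes):04d}"
        bg_genes.append(GeneModel(GenomicInterval(chrom, start, start + length, strand), gid))
    genes.extend(bg_genes)

    n_active = int(round(cfg.frac_active * len(bg_genes)))
    active_idx = rng.choice(len(bg_genes), size=n_active, replace=False) if n_active else []
    active_ids = {bg_genes[int(i)].gene_id for i in active_idx}

    return ExperimentLayout(
        chrom_lengths=chrom_lengths,
        spikein_lengths=spikein_lengths,
        peaks={"SUZ12": suz12, "RING1B": ring1b},
        domain_spans=domains,
        decay_mult=decay_mult,
        genes=genes,
        active_gene_ids=active_ids,
        pcg_gene_ids=pcg_ids,
    )


# ---------------------------------------------------------------------------
# read sampling


def _domain_profile(layout: ExperimentLayout, decay_length: float) -> dict[str, np.ndarray]:
    """Per-bp relative enrichment profile P (before enrichment x global_level)."""
    profile = {c: np.zeros(n) for c, n in layout.chrom_lengths.items()}
    for dom, mult in zip(layout.domain_spans, layout.decay_mult):
        arr = profile[dom.chrom]
        arr[dom.start:dom.end] += 1.0
        lam = decay_length * float(mult)
        if lam <= 0:
            continue
        dmax = int(min(12 * lam, len(arr)))
        tail = np.exp(-np.arange(1, dmax + 1) / lam)
        left = min(dmax, dom.start)
        if left:
            arr[dom.start - left:dom.start] += tail[:left][::-1]
        right = min(dmax, len(arr) - dom.end)
        if right:
            arr[dom.end:dom.end + right] += tail[:right]
    return profile


def _gene_body_profile(layout: ExperimentLayout) -> dict[str, np.ndarray]:
    profile = {c: np.zeros(n) for c, n in layout.chrom_lengths.items()}
    for g in layout.genes:
        if g.gene_id in layout.active_gene_ids:
            iv = g.interval
            profile[iv.chrom][iv.start:iv.end] += 1.0
    return profile


def _sample_reads(
    rng: np.random.Generator,
    weights: dict[str, np.ndarray],
    n_reads: int,
    read_length: int,
    chrom_lengths: dict[str, int],
    genome: str,
) -> ReadSet:
    chroms = list(weights)
    totals = np.array([weights[c].sum() for c in chroms])
    by_chrom = {}
    counts = rng.multinomial(n_reads, totals / totals.sum()) if n_reads else [0] * len(chroms)
    for chrom, n in zip(chroms, counts):
        w = weights[chrom]
        cum = np.cumsum(w)
        pos = np.searchsorted(cum, rng.random(int(n)) * cum[-1], side="right")
        pos = np.minimum(pos, len(w) - 1).astype(np.int64)
        plus = rng.random(int(n)) < 0.5
        length = chrom_lengths[chrom]
        starts = np.where(plus, pos, np.maximum(pos - read_length + 1, 0))
        ends = np.where(plus, np.minimum(pos + read_length, length), pos + 1)
        by_chrom[chrom] = (starts, ends, plus)
    return ReadSet(by_chrom, chrom_lengths, genome=genome)


def _uniform_reads(
    rng: np.random.Generator,
    n_reads: int,
    read_length: int,
    chrom_lengths: dict[str, int],
    genome: str,
) -> ReadSet:
    weights = {c: np.ones(n) for c, n in chrom_lengths.items()}
    return _sample_reads(rng, weights, n_reads, read_length, chrom_lengths, genome)


def _truth_rows(
    condition: str, cfg: SimulationConfig, layout: ExperimentLayout, flank_bp: int
) -> list[dict]:
    rows = []
    # enrichment is fold over background, so the signal amplitude is (E - 1)
    eg = (cfg.enrichment - 1.0) * cfg.global_level
    for dom, mult, peak in zip(
        layout.domain_spans, layout.decay_mult, layout.peaks["SUZ12"]
    ):
        lam = cfg.decay_length * float(mult)
        ratio = expected_flank_ratio(lam, flank_bp)
        rows.append({
            "condition": condition,
            "peak_id": peak.name,
            "chrom": dom.chrom,
            "start": dom.start,
            "end": dom.end,
            "decay_length_bp": lam,
            "global_level": cfg.global_level,
            "expected_in_rel": 1.0 + eg,
            "expected_out5_rel": 1.0 + eg * ratio,
            "expected_out3_rel": 1.0 + eg * ratio,
            "expected_ratio": ratio,
            "flank_bp": flank_bp,
        })
    return rows


def simulate_experiment(
    configs: Mapping[str, SimulationConfig],
    include_h3k36me3: bool = True,
    truth_flank_bp: int = 1200,
) -> SimulatedExperiment:
    """Simulate all conditions of one ChIP-Rx experiment.

    All configs must agree on the layout fields (geometry, gene placement,
    seed); conditions are processed in mapping order with independent but
    seed-derived random streams, so identical inputs give byte-identical
    outputs.
    """
    if not configs:
        raise ValueError("at least one condition required")
    items = list(configs.items())
    ref_cfg = items[0][1]
    for name, cfg in items[1:]:
        for f in SimulationConfig.LAYOUT_FIELDS:
            if getattr(cfg, f) != getattr(ref_cfg, f):
                raise ValueError(
                    f"condition {name!r}: layout field {f!r} differs from "
                    f"{items[0][0]!r}; conditions must share one layout"
                )

    layout = _build_layout(ref_cfg)
    genome_bp = sum(layout.chrom_lengths.values())
    children = np.random.SeedSequence(ref_cfg.seed, spawn_key=(1,)).spawn(
        2 * len(items) + 1
    )

    samples: list[Sample] = []
    truth_rows: list[dict] = []
    for idx, (condition, cfg) in enumerate(items):
        rng = np.random.default_rng(children[idx])
        profile = _domain_profile(layout, cfg.decay_length)
        sum_p = sum(p.sum() for p in profile.values())
        amp = cfg.enrichment - 1.0  # fold over background -> additive amplitude
        weights = {
            c: 1.0 + amp * cfg.global_level * p
            for c, p in profile.items()
        }
        w_now = genome_bp + amp * cfg.global_level * sum_p
        w_nominal = genome_bp + amp * sum_p
        if cfg.ip_depth > 0:
            expected_ip = cfg.ip_depth * w_now / w_nominal
        else:
            expected_ip = cfg.background_rate * w_now
        n_ip = int(rng.poisson(expected_ip))
        ip_target = _sample_reads(
            rng, weights, n_ip, cfg.read_length, layout.chrom_lengths, "target"
        )
        input_target = _uniform_reads(
            rng, int(rng.poisson(cfg.input_depth)), cfg.read_length,
            layout.chrom_lengths, "target",
        )
        # spike-in material is constant: same expected depth whatever global_level
        ip_spike = _uniform_reads(
            rng, int(rng.poisson(cfg.spikein_depth)), cfg.read_length,
            layout.spikein_lengths, "spikein",
        )
        input_spike = _uniform_reads(
            rng, int(rng.poisson(cfg.spikein_depth)), cfg.read_length,
            layout.spikein_lengths, "spikein",
        )
        samples.append(Sample(condition, "H3K27me3", ip_target, ip_spike,
                              input_target, input_spike))
        truth_rows.extend(_truth_rows(condition, cfg, layout, truth_flank_bp))

    if include_h3k36me3:
        condition, cfg = items[0]
        rng = np.random.default_rng(children[len(items)])
        profile = _gene_body_profile(layout)
        weights = {c: 1.0 + (cfg.enrichment - 1.0) * p for c, p in profile.items()}
        total_w = sum(w.sum() for w in weights.values())
        if cfg.ip_depth > 0:
            n_ip = int(rng.poisson(cfg.ip_depth))
        else:
            n_ip = int(rng.poisson(cfg.background_rate * total_w))
        samples.append(Sample(
            condition, "H3K36me3",
            _sample_reads(rng, weights, n_ip, cfg.read_length,
                          layout.chrom_lengths, "target"),
            _uniform_reads(rng, int(rng.poisson(cfg.spikein_depth)),
                           cfg.read_length, layout.spikein_lengths, "spikein"),
            _uniform_reads(rng, int(rng.poisson(cfg.input_depth)),
                           cfg.read_length, layout.chrom_lengths, "target"),
            _uniform_reads(rng, int(rng.poisson(cfg.spikein_depth)),
                           cfg.read_length, layout.spikein_lengths, "spikein"),
        ))

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return SimulatedExperiment(
        samples=samples,
        peaks=layout.peaks,
        genes=layout.genes,
        truth=truth,
        layout=layout,
        configs=dict(items),
    )


def write_truth(experiment: SimulatedExperiment, path: str | Path) -> None:
    """Ground-truth TSV: one row per (condition, domain) with expected densities."""
    experiment.truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_experiment(experiment: SimulatedExperiment, outdir: str | Path) -> dict:
    """Write the full experiment (reads BED, peaks narrowPeak, genes, truth).

    Returns a manifest dict of the files written.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"samples": {}, "files": {}}
    write_peaks(experiment.peaks["SUZ12"], outdir / "suz12.narrowPeak")
    write_peaks(experiment.peaks["RING1B"], outdir / "ring1b.narrowPeak")
    write_genes(experiment.genes, outdir / "genes.bed")
    write_truth(experiment, outdir / "truth.tsv")
    with open(outdir / "chrom_sizes.tsv", "w", encoding="utf-8") as fh:
        for c, n in {**experiment.layout.chrom_lengths,
                     **experiment.layout.spikein_lengths}.items():
            fh.write(f"{c}\t{n}\n")
    manifest["files"] = {
        "suz12": "suz12.narrowPeak", "ring1b": "ring1b.narrowPeak",
        "genes": "genes.bed", "truth": "truth.tsv",
        "chrom_sizes": "chrom_sizes.tsv",
    }
    for sample in experiment.samples:
        tag = f"{sample.condition}_{sample.antibody}"
        sdir = outdir / tag
        sdir.mkdir(exist_ok=True)
        files = {}
        for role in ("ip_target", "ip_spikein", "input_target", "input_spikein"):
            rs: ReadSet | None = getattr(sample, role)
            if rs is not None:
                rs.write_bed(sdir / f"{role}.bed")
                files[role] = f"{tag}/{role}.bed"
        manifest["samples"][tag] = files
    def _plain(d: dict) -> dict:
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {name: _plain(asdict(cfg)) for name, cfg in experiment.configs.items()}, fh
        )
    return manifest
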
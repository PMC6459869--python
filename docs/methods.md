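# Methods

## Signal model and normalization

Coverage tracks are built the classical ChIP-seq way: each single-end read is
extended to the expected fragment length (default 200 bp) from its 5′ end in
the strand direction, fragment coverage is averaged per fixed-width bin
(default 50 bp), and the per-sample scaling factor is applied. Two scaling
bases are implemented:

* **spikein** (ChIP-Rx): α = 10⁶ / N(IP reads on the exogenous genome).
  Because the spike-in chromatin amount is constant across samples, α is an
  absolute per-sample calibration: a uniform 2× loss of the mark halves the
  spike-in-scaled signal. The convention is reads-per-million-spike-in; any
  fixed rescaling of α would cancel in every between-sample comparison the
  pipeline makes, so only the ordering it preserves matters.
* **libsize**: α = 10⁶ / N(IP reads on the target genome) — deliberately
  blind to global changes; kept as the contrast case.

Input subtraction is per-bin `max(ip − input, 0)` after each track is scaled
by its own factor; input tracks are scaled by their own library size, since
an input library has no meaningful IP spike-in contract. Negative bins are
clamped because signal tracks are nonnegative by contract.

## Target regions and the spreading ratio

Target regions are SUZ12 peaks with −log10(p) ≥ 1 that overlap (≥ 1 bp by
default) a RING1B peak passing the same cutoff; the SUZ12 span defines the
region and the maximal-overlap RING1B call is recorded as the partner. The
cutoff is read as p ≤ 0.1 — the lenient peak-call significance filter —
since keeping only *non*-significant calls would contradict the notion of a
significant bound region.

For a region with span `[s, e)` and flank width F (default 1200 bp,
alternative 4000), densities are computed inside `[s, e)` and over
`[s − F, s)` and `[e, e + F)` (labels strand-swapped when the region is
oriented by an assigned minus-strand gene). Density is the exact per-bp mean
of the piecewise-constant binned track, partial bins weighted by overlap.
The spreading ratio is `(d_out + ε)/(d_in + ε)` with ε = 0.01 signal/bp on
both terms, which bounds ratios on null tracks without distorting real
signal (halving or doubling ε moves the default-simulation median by < 1%;
tested). Ratios are reported out/in — ≈1 for free spreading, → 0 for
confinement — and both directions are emitted in the tables since the
opposite convention ("IN/OUT") also appears in the literature.

Clipped flanks (chromosome ends) are flagged and excluded from distribution
tests by default so window widths stay comparable.

Caveat: the ratio is only meaningful where inside enrichment clearly exceeds
background. When a condition's global level is near zero, d_in approaches the
background density and the ratio drifts back toward 1 (visible in the dKO
condition of `analysis/04_spreading.py`); such conditions should be read
through the normalization result, not the spreading ratio.

## Comparative statistics

Between-condition ratio distributions are compared with the classical
pooled-variance two-sample Student's t (Welch by flag). Rank-sum (Wilcoxon)
comparisons use the exact null distribution for small tie-free samples and
the tie-corrected normal approximation otherwise; an all-tied input returns
p = 1 by convention. Paired per-region ratios are related by ordinary least
squares with Pearson r and r². A minimal Poisson enrichment scorer
(upper-tail p of the observed IP fragment count against an input-derived
expectation, floored at λ = 1, tail including the observed count) provides
a promoter-level ranking for top-fraction analyses; it is a stand-in for a
peak caller's promoter p-values and is labelled as plumbing, not a
contribution.

## Profile matrices

Reference-point matrices cover TSS ± 5 kb at 50 bp bins (200 columns);
scale-regions matrices resample each gene body to 100 columns by
length-weighted averaging plus 1 kb flanks at 50 bp (140 columns).
Minus-strand rows are reversed so column 0 is always 5′. Out-of-chromosome
bins are zero-filled and the row flagged (signal-track semantics; flagged
rows can be dropped) rather than set to NA. Matrices sharing one antibody
are scaled by a single pooled 1/(max − min) factor computed over all cells
of all matrices in the set — the pooled scope is what makes cross-sample
heatmap intensities comparable — and ranking (by signal, ascending or
descending, ties by region id) is a stable permutation applied to all
matrices alike.

Gene stratification: a gene is *PcG* when its promoter (TSS ± 2.5 kb)
overlaps a target region, whatever its H3K36me3 level (precedence rule);
remaining genes split into *K36pos*/*K36neg* on gene-body mean H3K36me3
density. The default split is a deterministic two-class 1-D k-means
(centers initialized at the min and max): the positive/negative distinction
is a bimodal classification, and a median cut would force the positive
fraction to one half regardless of how many genes are actually transcribed.
A median rule and an absolute threshold remain available.

## The synthetic experiment

The generator emulates exactly the features the analysis depends on:

* **Domains.** n non-overlapping enrichment domains (default 300, widths
  1.5–3 kb, gaps 10–14 kb) on a compact genome (default 6 Mb over 2
  chromosomes). Inside a domain the relative IP propensity is the
  enrichment fold over background (default 100); outside it decays as
  exp(−d/λ). Each domain draws a private multiplier on λ from a lognormal
  (σ = 0.75 by default): real Polycomb domains differ widely in spreading
  extent, and this between-domain variance is what makes per-region ratios
  reproducible between replicates rather than pure counting noise. The
  expected flank ratio has the closed form (λ/F)(1 − e^(−F/λ)), stored per
  domain in the truth table.
* **Global level.** A factor g ∈ [0, 1] multiplies the enrichment amplitude
  only (background unchanged). The realized target-genome IP yield scales
  with the total immunoprecipitated material, W(g)/W(1) where W is the
  summed per-bp propensity — `ip_depth` is the nominal depth at g = 1 —
  while spike-in reads are drawn at constant expected depth regardless of
  g. This is the physics that makes spike-in normalization recover g and
  library-size normalization miss it, and both behaviours are asserted in
  the tests.
* **Peak calls and genes.** SUZ12 calls sit on the true domains (a
  configurable 5% below the significance cutoff), RING1B partners are
  jittered copies (10% missing), and decoy calls in the gaps exercise the
  selection filter. One Polycomb gene sits under each domain (TSS at the
  domain center); background genes occupy the gaps with ≥ 3 kb clearance,
  and a configurable fraction (default 0.4) carries H3K36me3 gene-body
  signal in a separate antibody sample.
* **Reads.** Single-end 36 bp reads with strand, 5′ positions drawn from
  the propensity profile (Poisson totals, inverse-CDF positions); input
  reads uniform on the target genome; spike-in reads uniform on a separate
  600 kb exogenous genome carried in the same files under an `s_` chromosome
  prefix. Identical configs and seed give byte-identical output.

What the generator does **not** model: sequence, mappability, GC bias, PCR
duplicates, diploidy, fragment-size variability, or peak-calling itself.
Passing tests therefore demonstrate correctness of the statistics under the
stated stochastic model, not robustness to alignment artifacts of real data.
The simulated genome is also far denser in domains (~25% of the genome
within decay range) than a mammalian genome (few percent); one consequence
is that library-size-scaled input subtraction over-subtracts on these
fixtures (the IP's background share of reads is far below the input's
uniform share), so the ratio analyses on synthetic data run on the scaled IP
track directly — at 100-fold enrichment the background contributes < 1% to
the ratio — while `subtract_input` is exercised on its own contract.

## Evaluation problem sizes

The reference experiments (`polyspread.evaluation`) fix their own scales:
normalization recovery uses the default genome at 10⁶ nominal IP reads per
condition; the closed-form decay grid (λ ∈ {0, 300, 600, 1200, 2400} bp,
F = 1200) uses 300-fold enrichment, zero decay dispersion and 3×10⁶ reads so
the median's counting error is ≈ 0.3%; the WT/confined discrimination uses
300 domains, a 300 bp flank (kept small against λ = 1200 so the WT ratio
sits in its near-1 regime) and 2×10⁷ nominal reads, putting per-flank
counting noise (≈ 1.7%) well below the between-domain ratio spread
(≈ 10%) so replicate r² reflects the shared biology. Coverage for these
checks is built at 50 bp fragments / 25 bp bins: the closed form describes
point deposition, and short fragments keep boundary smoothing bias below 1%.

## Numerical choices

* Exponential tails are materialized to 12λ (truncation < 10⁻⁵ relative).
* Per-bp accumulation uses difference arrays; bin values are exact
  fragment-bp overlaps divided by the bin width, and the final partial bin
  of a chromosome is divided by the full bin width (its value reads as
  coverage of the covered bp only).
* Ties break deterministically everywhere: maximal-overlap partner by
  (overlap, start, name); promoter assignment by gene id; rankings by
  (signal, region id).
* Seeds: one integer seed per experiment; per-condition streams are spawned
  from it in mapping order, so adding a condition does not perturb earlier
  ones' layout (the layout stream is separate).

## Known limitations

* The decay-kernel family is fixed (exponential); the closed-form oracle and
  truth table are tied to it.
* Spreading flank labels default to gene-strand orientation when a gene is
  assigned and genomic left/right otherwise; both conventions are available
  because published figures rarely state which was used.
* The Poisson promoter score ignores local background variation (no
  multi-scale λ as in a real peak caller).
* No multiple-testing correction across regions: the pipeline reports
  distribution-level tests, not per-region significance.
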
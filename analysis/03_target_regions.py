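"""Select Polycomb target regions: significant SUZ12 peaks with RING1B support.

Applies the -log10(p) >= 1 cutoff to both call sets and keeps SUZ12 peaks
overlapping a passing RING1B peak, writing the regions as BED plus a TSV
sidecar with the partner call and nearest-TSS gene assignment.
"""
import pandas as pd

from common import build_experiment, outdir
from polyspread import assign_promoters, select_target_regions

out = outdir("03_target_regions")
exp = build_experiment(include_h3k36me3=False)

suz12, ring1b = exp.peaks["SUZ12"], exp.peaks["RING1B"]
regions = select_target_regions(suz12, ring1b, min_neglog10p=1.0)
genes = assign_promoters([t.peak for t in regions], exp.genes, window_bp=2500)

rows = []
with open(out / "target_regions.bed", "w") as fh:
    for t in regions:
        iv = t.interval
        fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.region_id}\t0\t.\n")
        gene = genes.get(t.region_id)
        rows.append({
            "region_id": t.region_id, "chrom": iv.chrom,
            "start": iv.start, "end": iv.end,
            "partner": t.partner.name,
            "gene": gene.gene_id if gene else "",
        })
pd.DataFrame(rows).to_csv(out / "target_regions.tsv", sep="\t", index=False)

n_sig = sum(1 for p in suz12 if p.neg_log10_p >= 1.0)
print(f"SUZ12 calls: {len(suz12)} ({n_sig} significant at -log10 p >= 1)")
print(f"RING1B calls: {len(ring1b)}")
print(f"co-occupied target regions: {len(regions)}")
print(f"regions with a promoter assignment: {sum(1 for r in rows if r['gene'])}")
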
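"""Variant enrichment at peak centers against a random-region null.

Counts SNVs per peak, tests whether Common-DARs carry variants more
often than HFD-DARs (Fisher odds ratio), and compares variant density
in the peak-center zone (+-25 bp) and the flank (26-250 bp) against
width-matched random genomic regions.
"""

from strainatac import (
    RunConfig, SimConfig, class_variant_enrichment, generate, run_pipeline,
    sample_random_regions, zone_enrichment,
)

data = generate(SimConfig(seed=1))
out = run_pipeline(data, RunConfig(seed=1, stages=[
    "normalize", "batch", "differential", "classify", "activity",
    "variant_integration",
]))

pt = out["peak_table"]
for cls in ("Common", "Chow", "HFD", "NonDAR"):
    sub = pt[pt["dar_class"] == cls]
    print(f"{cls:7s}: {(sub['n_variants'] >= 1).mean():.1%} of "
          f"{len(sub)} peaks overlap a variant")

enr = class_variant_enrichment(pt).set_index(["class_a", "class_b"])
row = enr.loc[("Common", "HFD")]
print(f"Common vs HFD variant enrichment: OR {row['odds_ratio']:.2f}, "
      f"p {row['p']:.2e}")

common = pt[pt["dar_class"] == "Common"]
bg = sample_random_regions(common, 10, data.chrom_sizes, rng_seed=2)
for z in zone_enrichment(common, data.variants, bg):
    print(f"Common {z.zone:6s} zone: {z.observed_variants} variants, "
          f"OR {z.result.odds_ratio:.1f} vs random regions "
          f"(p {z.result.p_value:.1e})")
# a large center-zone OR with a flank OR near 1 shows variants
# concentrate exactly where they perturb accessibility
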
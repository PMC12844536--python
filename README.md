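# strainatac

Strain-resolved analysis of how genetic variation shapes chromatin
accessibility, transcription-factor binding and gene expression.

When two inbred mouse strains are profiled with bulk ATAC-seq and
RNA-seq, the differences in chromatin accessibility between them are
largely genetic: nucleosome-free regions (NFRs) that differ between
strains tend to carry single-nucleotide variants at their centers, and
those variants often disrupt the binding motif of the transcription
factor whose footprint occupies the region. `strainatac` implements the
full chain of inference that connects these layers for a two-strain x
two-diet design:

- **DAR classification.** Each NFR is tested for differential
  accessibility between strains within each diet (moderated linear model
  on batch-corrected logCPM) and classified *Common* (DAR on both diets),
  *Chow*, *HFD*, or *NonDAR*, at FDR < 0.01 and fold change > 50%
  (|log2FC| > log2 1.5). Genes get the analogous
  NonDEG/Diet/Diet+strain/Strain taxonomy at FDR < 0.05.
- **Activity classes.** NFRs flanked by H3K27ac signal (within ±1 kb)
  are *Active* — candidate functional regulatory regions.
- **Variant-zone enrichment.** SNV density in the peak-center zone
  (±25 bp) and flank (26–250 bp) is compared against width-matched random
  genomic regions with Fisher's exact test on base-pair rates.
- **Allelic motif scoring.** For each variant inside a footprint, both
  alleles are scored against the TF's position weight matrix over every
  window and strand covering the variant; p-values come from the *exact*
  distribution of the log-odds score under the background, computed by
  dynamic programming on a discretized score lattice (threshold p ≤ 1e-4).
  The scaled effect Δ = (s̃_alt − s̃_ref) classifies changes as
  neutral (|Δ| ≤ 0.1), weak, or strong (|Δ| ≥ 0.4).
- **Footprints and AC-footprints.** A footprint score is the
  flank-minus-center mean of depth-normalized Tn5 cut counts around a
  motif-anchored site; per-strain scores give a diet-matched strain
  difference. An **AC-footprint** (altered-motif corresponding footprint)
  is a site where a significantly altered motif's allelic score and the
  strain footprint-score difference agree in sign — the signature of a
  variant changing TF occupancy directly.
- **Peak–gene linking.** DAR pairs within 1 Mb are correlated
  (Spearman on logCPM; rolling mean over 501-pair windows against
  distance), and each gene's expression is correlated with every DAR in
  cumulative windows (promoter … 1 Mb) around its most-active TSS.

Because real strain sequencing data is not bundled, the package ships a
first-class **synthetic-data generator** (`strainatac.simulate`) that
emulates the full study — NB-distributed counts with planted
variant-driven DARs, a contaminating cell-type sample cluster, H3K27ac
flanking, motif-anchored cut-site profiles whose footprint depth is a
logistic function of the strain allele's motif score — with complete
ground truth, so every stage is validated by recovery, calibration and
enumeration-oracle tests.

## Worked example

```python
from strainatac import SimConfig, RunConfig, generate, run_pipeline, truth_report

data = generate(SimConfig(seed=1))          # 2000 peaks, 600 genes, 23 samples
out = run_pipeline(data, RunConfig(seed=1)) # all stages
```

Running `python examples/02_differential_accessibility.py` prints:

```
1950 of 2000 peaks pass the logCPM > -3 filter
confounded cluster: ['B6_HFD_1', 'B6_HFD_2', 'B6_chow_1', 'B6_chow_2', 'S129_HFD_1', 'S129_chow_1', 'S129_chow_2']
{'NonDAR': 1539, 'Common': 157, 'Chow': 148, 'HFD': 106}
Common-DAR recovery: sensitivity 0.87, observed FDR 0.006 (planted 180, called 157)
```

The seven planted contamination samples are found by PCA + 2-means and
residualized out; the moderated test then recovers 87% of the planted
Common-DARs with an observed false discovery rate of 0.6%. Downstream,
`python examples/05_footprints_ac.py` prints:

```
500 footprint sites; 416 bound in >= 1 group; 152 AC-footprints
AC enrichment in Common-DARs vs non-DARs: OR 41.9 (95% CI 22.6-77.5), p 2.0e-45
footprint-difference vs allelic-score Spearman (Common): rho 0.86, p 8.7e-28
|score diff| strong vs neutral motifs: Wilcoxon p 1.4e-15, effect r 0.73
TFs with >= 90% of motif-altering variants showing AC-footprints: ['TFcore0']
```

AC-footprints concentrate almost entirely in Common-DARs, strain
footprint differences track allelic motif scores (rho 0.86), and
stronger motif disruptions produce larger occupancy shifts — the
pipeline's central readout that genetically altered binding sites drive
differential accessibility.

The other scripts in `examples/` cover dataset simulation, variant-zone
enrichment, exact allelic motif scoring, and peak-gene linking; each
prints a few annotated numbers and runs in seconds.

A thin CLI wraps the same stages:

```bash
strainatac simulate --seed 1 --outdir data/
strainatac run --indir data/ --outdir results/ --seed 1
```

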
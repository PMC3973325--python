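# gantcscope

Analysis toolkit for the methylome and regulatory footprint of CcrM-type
orphan adenine methyltransferases in *Alphaproteobacteria*-like genomes.

CcrM methylates the adenine of 5'-GANTC-3' (a reverse-complement
palindrome, one methylatable adenine per strand) once per cell cycle, so a
replicating chromosome carries a moving front of hemi-methylated motifs
behind the fork. `gantcscope` implements the four computational analyses
such a study needs, end to end, plus a synthetic-data module that
generates the whole study with known ground truth:

1. **Motif statistics** — counts of GANTC (and the 24 pentanucleotides of
   the same structure) in whole genomes, coding, RNA and intergenic
   partitions, with expected counts from single-base composition:
   `E[genome] = freq(G)·freq(A)·freq(T)·freq(C)·L` (the central N
   contributes a factor 1) and length-proportional allocation to
   partitions. Obs/exp < 1 flags motif depletion.
2. **IPD methylome** — per-strand methylated-population fractions from
   SMRT kinetics via the two-state linear mixture
   `r = f·r_full + (1−f)·1`, calibrated on a constitutively methylating
   strain (`r_full`), with `r_hemi = (r_full+1)/2`. Strand adenines with
   mean IPD ratio below a threshold τ (default 2.4 ≈ 20% fully methylated)
   are under-methylated; motifs are classified full / asymmetric /
   under-methylated, profiled in 20-kb windows with circular LOESS
   smoothing, and tested for the origin–terminus replication-timing
   gradient (Spearman ρ with permutation p).
3. **Promoter conservation** — GANTC presence in the 200 bp upstream of
   each translational start, and conservation counts across an ortholog
   promoter panel.
4. **DE enrichment** — classification of gene-level log2 ratios and
   BH-adjusted p-values into significant/up/down/strong sets
   (p_adj < 0.01, ≥2-fold), Fisher's exact enrichment of regulons, COG
   classes, promoter-motif and conservation properties, candidate
   direct-target tables, and the excess-count estimate
   `n·(1 − 1/fold)` of directly regulated genes.

## Worked example

Simulate a 200-kb study and run every stage:

```bash
gantcscope simulate --seed 7 --genome-length 200000 --n-genes 200 --outdir sim
gantcscope run --config sim/pipeline.cfg --outdir run
```

The run report (`run/report.json`) contains, among others:

```json
"ipd_methylome": {
  "r_full": 7.68769, "r_hemi": 4.34385, "tau": 2.4,
  "tally": {"full": 320, "asymmetric": 11, "under_methylated": 24, "no_data": 0},
  "gradient_rho": 0.703873, "gradient_p": 9.999e-05, "n_sites": 355
},
"motif_statistics": {
  "observed_genome": 355,
  "ratios": {"genome": 0.454438, "coding": 0.817323, "intergenic": 1.68914, "rna": 1.47187}
}
```

Reading this: the calibration recovered the fully methylated IPD ratio
(7.69, truth 7.68, hence hemi value 4.34); the caller recovered exactly
the 24 bilaterally under-methylated and 11 asymmetric sites the generator
planted; the positive Spearman ρ (p < 10⁻⁴) detects the planted
replication-timing gradient (origin-proximal motifs hemi-methylated in
more of the population); and GANTC is depleted genome-wide (obs/exp 0.45)
but over-represented in intergenic DNA relative to coding DNA, as planted.
`run/` also holds per-site calls, the smoothed window profile, promoter
flags, the enrichment battery and the candidate direct-target table as
TSV.

Every stage is also a library call (`gantcscope.scan_motif`,
`calibrate`, `call_sites`, `promoter_motif_flags`, `fisher_enrichment`,
…) and a standalone subcommand (`motif-stats`, `methylome`, `promoters`,
`enrich`).

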
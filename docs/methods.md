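# Methods

## The two-state mixing model

A SMRT inter-pulse-duration (IPD) ratio at a template base is the measured
polymerase pause divided by the value predicted for unmethylated DNA; m6A
elevates it strongly. At a motif adenine observed across a mixed
population of chromosomes, the coverage-averaged ratio is modelled as a
linear mixture of two states,

    r = f · r_full + (1 − f) · 1,

where `f` is the fraction of chromosomes methylated at that strand
position, `r_full` the population-average ratio of a site methylated in
every chromosome, and 1 the unmethylated value by construction of the
ratio. `r_full` is not assumed: it is calibrated as the mean ratio over
motif adenines in a constitutively methylating strain (mean, because the
population average is itself the mixture statistic; a trimmed-mean option
exists for robustness). The hemi-methylated reference value follows as
`r_hemi = (r_full + 1)/2`, and the estimator of `f` is the inverse
mixture `(r − 1)/(r_full − 1)`, clipped to [0, 1] (unclipped values are
retained in output for diagnostics). With the conventional calibration
`r_full = 7.68`, the under-methylation threshold τ = 2.4 corresponds to
~21% of chromosomes fully methylated on that strand, or ~42%
hemi-methylated.

Assumptions worth stating: (i) linearity of the coverage average in the
methylated fraction — exact for an average of per-molecule values; (ii)
the unmethylated baseline is 1 on both strands; (iii) `r_full` is
homogeneous across sites, which sequence context violates mildly in real
kinetics (see *Limitations*).

## Site classification

Each GANTC carries one methylatable adenine per strand: for a motif at
0-based start `s`, the forward adenine at `s+1` and the reverse-strand
adenine at `s+3` in forward coordinates. The threshold is applied per
strand-adenine mean ratio: a strand is under-methylated iff its mean
ratio is strictly below τ (the boundary side is a convention; τ itself is
the configurable quantity). A motif is *under-methylated* when both
strands are under, *asymmetric* when exactly one is, *full* otherwise,
and *no-data* when either strand lacks coverage ≥ the minimum (default 5
reads — low enough to keep essentially every site at realistic coverage,
high enough to avoid single-read calls). A site-mean mode (average the
two strand ratios, threshold once) is available but collapses the
asymmetric class by construction.

## Chromosomal profile and gradient statistic

Window profiles average the raw IPD ratios in non-overlapping 20-kb
tiles and rescale them so `r_full` maps to 100% (whole population fully
methylated) and `r_hemi` to 0% (uniformly hemi-methylated). Smoothing is
LOESS — tricube-weighted local linear regression on window midpoints with
a k-nearest-neighbour bandwidth of `ceil(span · n)` windows (span default
0.75, the conventional default of the standard R fitting routine) —
written in-house because the fit must wrap the circular origin junction
(one bandwidth of windows is mirrored across it) and because the tests
verify it point-for-point against a direct weighted-least-squares oracle;
it is additionally cross-checked against statsmodels' LOWESS. Local
linear fits reproduce straight-line profiles exactly, which the tests
exploit. Fewer than 4 non-empty windows is an error.

The replication-timing gradient is summarised by the Spearman
correlation between circular distance to the origin and the site-level
methylated fraction (mean of the two strand estimates), with a
seeded 10⁴-permutation two-sided p-value. Constant inputs return ρ = 0,
p = 1 rather than NaN.

## Motif statistics

Counting is single-strand on the provided sequence: genome counts on the
forward strand (GANTC is its own reverse complement, so the genome count
is strand-invariant; non-palindromic patterns are reported for the given
strand), feature counts on each feature's coding strand, each feature
scanned individually so concatenation cannot create junction artifacts.
Overlapping matches all count (GANTC cannot overlap itself, so this is
neutral for the headline motif). Windows containing N never match, and N
bases are excluded from base-frequency numerators and denominators.
Intergenic observed counts are defined by subtraction
(genome − coding − RNA), which can go negative when genes overlap; a
warning is emitted in that case rather than silently re-defining the
quantity. Expected counts use the product of single-base frequencies over
the pattern's non-N positions times the sequence length; partition
expectations allocate the genome-wide observed total proportionally to
partition length, so they tile exactly to the total.

## Promoters and conservation

The promoter of a gene is exactly the `promoter_length` (default 200) bp
upstream of its annotated translational start on its own strand, applied
uniformly regardless of upstream gene overlap — operonic context is
deliberately not modelled, and the window length is a flag. A motif is
"in the promoter" when its forward-strand 5' start coordinate lies in the
window; occurrences straddling the gene-proximal boundary therefore count
when they start inside. Windows wrap on circular contigs and truncate
with a warning on linear ones. Conservation counts are row sums of a
per-species ortholog-promoter presence matrix supplied as input (ortholog
inference is out of scope); the default synthetic panel has 5 species.

## Differential expression and enrichment

Log-ratios are log2 throughout, so "≥2-fold" means |log2 ratio| ≥ 1.
Significance is strict: p_adj < α (default 0.01), Benjamini–Hochberg
adjusted. `simple_de` is a deliberately lightweight stand-in for a
moderated microarray fit, used on synthetic replicate matrices only: a
per-gene Welch t test with BH adjustment. At triplicates the Welch
approximation is conservative (its effective df can fall to ~2, capping
attainable p-values near 1/(2t²)), so a small number of genuinely
perturbed genes always lands above a strict BH cut-off — a property of
the test, documented here because recovery-style checks must not expect
100% recall from it.

Enrichment uses Fisher's exact test on the 2×2 (in-set × has-property)
table, one-sided for over-representation by default; the reported
direction (fold < 1 ⇒ "under") is descriptive and does not alter the
sidedness, because choosing sidedness from the observed fold would double
the type-I rate. Fold enrichment is the in-set property frequency
relative to the universe-wide frequency, the universe defaulting to all
genes with expression data. Raw p-values at 0.05 mirror the conventional
presentation of such figure panels; a BH column is appended for the
battery. The excess-count estimate `round(n·(1 − 1/fold))` converts an
observed count and its fold enrichment into the number of genes beyond
chance (floored at zero when fold ≤ 1).

## The synthetic-data generator

What it emulates — and its defaults, which are the study conditions used
throughout the tests and the acceptance script:

- **Genome**: 1-Mb circular chromosome, 900 non-overlapping genes (mean
  800 bp, 5% RNA genes) on an even grid with jitter, uniform base
  composition by default (GC configurable). GANTC sites are planted at
  1.5/kb in coding and 3/kb in intergenic DNA (≈2000 sites total,
  reproducing intergenic over-representation); accidental background
  occurrences are scrubbed by point mutation, so the genome's motif
  complement is *exactly* the planted truth table, and planted sites are
  ≥5 bp apart (GANTC cannot overlap itself).
- **Methylation state**: the hemi-methylated population fraction h
  interpolates linearly in circular distance from the origin between 0.8
  (origin) and 0.1 (terminus); the per-strand methylated fraction is
  f = 1 − h/2, identical on both strands because the gradient is
  strand-symmetric. 24 sites are planted at f = 0 on both strands and 11
  at f = 0 on one uniformly chosen strand.
- **Kinetics**: per molecule, lognormal IPD ratio with mean `r_full_true`
  = 7.68 if that molecule's strand is methylated (probability f) and mean
  1 otherwise, CV 0.3 (a free parameter: real per-molecule kinetic
  dispersion is not published at this granularity; lognormal for positive
  support and a heavy right tail). Coverage is Poisson(50) floored at 1.
  The observed value is the per-molecule mean, so E[obs] = f·r_full +
  (1−f) exactly, and CV = 0 with f ∈ {0, 1} is noise-free.
- **Expression**: triplicate log2 intensities per condition, baseline
  N(10, 1.5), replicate noise SD 0.1 (typical post-normalization array
  replicate scatter; chosen once so that a triplicate Welch fit has real
  power at p_adj < 0.01, without which the coupling structure below would
  be undetectable). 10% of genes are planted at ±2 log2 units, and the
  probability that a motif-bearing gene is chosen for the down set is
  multiplied by 4 (renormalised), planting the promoter–expression
  coupling the enrichment stage is meant to detect.
- **Gene sets and orthologs**: named regulon-style sets with configurable
  planted overlap with the down-regulated truth, single-letter functional
  labels, and a Bernoulli ortholog-promoter presence panel whose per-gene
  propensity can be conditioned on the focal promoter flag.

Determinism: every generator draws from `default_rng([seed, stream])`
with a fixed per-generator stream index, so a plan plus seed reproduces
byte-identical files across runs and platforms.

What the generator does **not** emulate — hence what green tests do not
show about real data: sequence-context variation of `r_full`, read-level
alignment artefacts and mapping bias, probe effects and intensity-
dependent variance in arrays, operon structure (DE effects are
independent across genes), horizontal motif clustering beyond the two
densities, and real phylogenetic correlation in the ortholog panel.

## Problem sizes used in the test suite

The acceptance-style checks run the full study scale (1-Mb genome, ~2000
sites) for site-class recovery and the gradient statistic — a few seconds
each — while unit and property tests use 50–260-kb genomes and 100–2000
gene expression matrices; the null-calibration checks use 200–500
simulated seeds of small (100–600 gene) matrices. These sizes were chosen
so the statistical assertions (type-I rate within ±0.02, ≥95% power at
coupling 4, MAE ≤ 0.05) have the resolution they claim.

## Known limitations

- The intergenic subtraction inherits any double-counting from
  overlapping annotations; the warning is the only mitigation.
- Calibration assumes the companion strain is fully methylated at every
  site; planted-under sites that remain unmethylated in such a strain
  would bias `r_full` downward slightly in real data (the generator's
  reference mode forces f = 1 everywhere, matching the assumption).
- The permutation p-value of the gradient statistic is two-sided; with
  ~2000 sites and the default gradient it saturates at its resolution
  (1/(N+1) for 10⁴ permutations).
- `simple_de` is not a moderated fit and should not be used on real
  array data; gene-level statistics from a proper pipeline can be
  supplied directly as a TSV instead.
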
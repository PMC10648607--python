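# Methods

## The metric and the pipeline

The degree of splicing (DS) of gene *g* in sample *s* at TPM threshold θ is
the number of isoforms of *g* with TPM strictly above θ in *s*; if none
qualify, DS = 0. The strict inequality and the zero rule are applied
uniformly everywhere (DS matrices, overall splicing, presence calls). The
zero is deliberate: it encodes "no detectable expression here", which is a
signal for the constrained analysis but a confound for others — hence the
two variants run side by side:

- **all genes**: every gene detected in at least one sample, zeros kept;
- **constrained (no-zero)**: only genes with DS > 0 in every sample, i.e.
  splicing of steadily expressed genes.

Three thresholds (0.1, 1, 10 TPM) are carried through the pipeline by
default. At θ = 0.1 essentially every detected isoform counts; at θ = 10
detection is nearly insensitive to sequencing depth, so remaining
between-type differences are more plausibly biological. The per-type
*overall splicing* summary is the ratio of two within-type means: mean
qualifying-isoform count divided by mean expressing-gene count. The
defining sentence admits a second reading (mean of per-sample ratios); the
ratio-of-means form was chosen because it degrades gracefully when a sample
has few expressed genes, and the two coincide whenever counts are constant
across a type's samples.

Binned abundance distributions use geometric bins (factor 10^0.5, so
consecutive bin means differ about threefold) starting at 0.1 TPM, each bin
left-open right-closed — (0.1, 0.316] is the first. Two averaging modes are
implemented because they genuinely differ for low-abundance isoforms:
per-sample binning averaged within a type (with a Student-t 95% interval
over samples, n as small as 3), and binning of per-isoform means taken
across the type's samples with zeros included. An isoform detected in one
sample at 0.3 TPM and undetected in two others lands in the first bin under
the second mode but contributes only a third of a count under the first;
the low bins are therefore mode-sensitive by design, not by accident.

## PCA and gene selection

Samples are observations, genes variables. Genes are mean-centred across
samples; no unit-variance scaling is applied, so genes with larger DS
variance weigh more and the loadings are entries of unit eigenvectors in
[−1, 1]. The decomposition is a deterministic full SVD (11 × ~10⁴ is tiny);
explained variance uses the (n−1) sample-variance convention, which makes
the variance of a score column equal its component's explained variance.
SVD sign ambiguity is removed by flipping each component so its
largest-magnitude loading is positive.

Gene selection per component: Tukey box-plot outliers of the loadings
(quartiles by linear interpolation — the most common box-plot convention;
the whisker factor k = 1.5 and the quartile method are both exposed), then
one-way ANOVA of each outlier gene's DS values grouped by type, keeping
p < α (default 0.01, raw). No multiple-testing correction is applied by
default — the selection is a screening step feeding an external enrichment
tool, and the raw-p filter is the conventional practice this package
mirrors; a Benjamini–Hochberg option exists. Two caveats are documented
rather than "fixed": ANOVA on small integer counts with groups of 3/5/3
violates normality, and the F test is used as a ranking/screening device;
with zero within-group variance the F statistic is degenerate, reported as
F = 0, p = 1 when group means agree and p = 0 with a `degenerate` flag when
they differ.

## Characteristic isoforms

An isoform is *present* in a type when its TPM exceeds the threshold in at
least one sample of the type (`any_sample`, default) or in all of them
(`all_samples`); an isoform present in exactly one type is *characteristic*
of it. The any-sample default is the weakest reading of "detected in one
type" and matches the packaged reference set; the quorum is configurable
because the choice is genuinely open. Protein status comes from a
user-supplied annotation table (closed vocabulary: Canonical form, Protein
isoform, Predicted, unannotated); no external database is queried.

## The synthetic generator

The generator emulates the downstream shape of a direct RNA nanopore
experiment, not the reads:

- **Catalog**: per-gene isoform counts from a truncated geometric on
  1..max_isoforms (p = 0.5), giving a realistic mean of ~1.9 isoforms/gene
  and overall splicing in the observed 1.2–2.1 band.
- **Expression**: per-gene lognormal with log-SD 2.5, shared across types,
  so a sizeable fraction of genes sits near the detection limit — the
  regime where depth matters.
- **Usage**: a per-gene flat Dirichlet baseline; a `diff_fraction` (0.5) of
  genes receives type-specific usage by mixing the baseline with an
  independent Dirichlet draw, `(base + d·draw)/(1 + d)`. At divergence
  d = 0 all types are byte-identical; the between-type total-variation
  distance is monotone in d.
- **Noise**: multiplicative lognormal per transcript per sample, CV 0.2.
- **Dropout**: an isoform with expected abundance *a* (TPM scale) escapes
  detection with probability exp(−depth·a/T₀), T₀ = 1 TPM — smooth and
  monotone in both depth and abundance. No published detection law exists
  for direct RNA nanopore data; this is an explicit modelling choice,
  exposed as a knob. Surviving abundances are renormalised to sum to 10⁶.
- **Design**: 3 liver (depth 0.5) + 5 HepG2 (depth 1.0) + 3 Huh7 (depth
  0.8) — liver shallower, as tissue specimens typically sequence worse than
  cultured cells.
- **Seeding**: one master seed; catalog, usage, expression and each sample
  draw from independently derived streams, so stages are reproducible in
  isolation.

What the generator does *not* model: read-level error, GC/length biases,
batch effects, correlated noise between isoforms of a gene, and any
realistic dropout law. Passing recovery tests therefore show that the
pipeline extracts planted type structure of this specific form, not that it
would behave identically on real nanopore data.

Two standard scenes are used in tests and the acceptance script, both 2000
genes in the 3/5/3 design (large enough for stable silhouettes and a
well-populated ANOVA null, small enough to run in seconds):

- **divergent** (d = 1, default depths): the three types separate in
  PC1–PC2 of the DS matrix at θ = 10 with silhouette ≈ 0.8. θ = 10 is the
  natural choice here: usage differences translate deterministically into
  DS differences there, while at θ = 0.1 the type signal rides mostly on
  stochastic dropout.
- **null** (d = 0, *equal* depths): with identical usage and depth the
  per-type DS distributions are exchangeable, silhouette is ≈ 0, and the
  per-gene ANOVA rejection rate at α = 0.01 falls inside the 99% binomial
  band. Equal depth is essential: unequal depth alone induces real
  (technical) distributional differences that ANOVA correctly detects, so
  a d = 0 scene with the default depths is not a null. The rate is computed
  over genes with any across-sample DS variation; genes constant across
  all samples yield F = 0, p = 1 and cannot reject by construction.

## Numerical and format choices

- TPM values are written at 17 significant digits and parsed with
  correctly-rounded float conversion, so a written scene reads back
  bit-exactly.
- Transcript/gene version suffixes (".N") are stripped by default on all
  readers (Gencode tolerance); a flag retains them.
- TPM is *not* renormalised after the protein-coding filter: thresholds
  apply to as-quantified values, preserving the order quantify → filter →
  threshold.
- Assembly takes the sorted union of transcripts across samples, so the
  matrix is invariant to input order up to column permutation.
- PCA of a constant matrix returns all-zero explained-variance ratios with
  a warning instead of NaNs.
- The pipeline writes TSVs with %.10g floats and a manifest without
  timestamps, making reruns byte-identical.
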
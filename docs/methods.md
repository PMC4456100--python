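# Methods

This note records the models, conventions, parameter choices and known
limitations behind `tespread`. It is the package's own account of its
science; every empirical number quoted here is computed by the test suite or
by `scripts/acceptance.py`.

## Coordinates and annotation handling

All intervals are internally 0-based, half-open. GFF3 (1-based, closed) is
converted on read and back on write; BED and bedGraph pass through
unchanged. Per gene, the isoform with the largest summed exon length is
kept. The euchromatic filter retains only features fully contained in a
euchromatin interval and drops chromosome "4"/"chr4" entirely. Analysis
genes additionally require (i) no TE overlapping any exon — TEs wholly
inside introns are allowed and define the `in_gene` category — and (ii) the
full ±10 kb neighbourhood inside euchromatin, so distance categories are
never truncated by a heterochromatin boundary. A user-supplied exclusion
list supports robustness re-analyses that remove externally flagged genes
(e.g. genes heterochromatic in other strains or cell lines); the package
deliberately does not bundle any such external track.

## Gene–TE geometry

Distance is the minimal edge-to-edge bp separation between the gene span
and the TE span; overlap means distance 0 and category `in_gene`. The
distance bins are half-open `(a, b]`, so a TE at exactly 1,000 bp is
`within_1kb`; a TE abutting the gene boundary (distance 0, no overlap) also
counts as `within_1kb`. In per-bin TE counts, a TE spanning several bins is
counted once, in the bin of its closest edge. For nearest-TE analyses, a
gene with two or more TEs at exactly the same minimal bp distance is
excluded (exact-bp ties only). Distance tertiles are equal-size thirds by
rank, recomputed per dataset rather than fixed in bp. Gene density counts
gene midpoints (including the focal gene) in a centred 100-kb window;
recombination rates are linearly interpolated at the gene midpoint and
clamped to the map range at the edges.

Where the anchor for gene–TE distance was genuinely open (span edge vs
TSS), the span edge was chosen because it matches the kb-bin framing of the
flanking-window analyses; the choice is isolated in `te_gene_distance` for
sensitivity testing.

## Density tracks and the decay profile

Tracks are per-chromosome step functions of background-subtracted read
density (reads/bp). Steps with negative density carry no evidence of
enrichment and are clamped to zero; clamping is idempotent and every
downstream density is ≥ 0. Interval means are length-weighted over the
native steps (no re-binning to fixed windows). Genic density is the
exon-length-weighted mean over the longest isoform's exons, i.e. the per-bp
mean over the exon union.

The decay profile takes, for each TE, its left and right 10-kb flanks
separately; a flank enters only if it lies entirely on-chromosome and is
entirely intergenic (overlapping no gene or TE span), because functional
sequence is systematically depleted of repressive marks and would bias the
decay estimate. Accepted flanks contribute all ten 1-kb window means at
once, indexed outward from the TE edge, with left and right flanks pooled
by index.

The null ensemble draws, per replicate and per template TE, one
uniform-random segment of identical length on the same chromosome and
inside the same 4-Mb locality bin (TE assigned to its bin by midpoint;
segments must fit the bin, falling back to the whole chromosome with a
logged warning when a TE exceeds its bin). Null segments may land on genes
or real TEs — only the intergenic flank filter constrains the windows,
exactly as for real TEs. Given a seed the sampled segments are
bit-reproducible. Window contrasts use the two-sided Mann–Whitney U test
(sidedness was an open choice; two-sided is the conservative default
throughout the package).

The stage-enrichment count flags, per stage, genes at or above the
empirical (1−q) quantile (linear interpolation) of that stage's gene
densities, with q = 0.10 by default and 0.25 supported, and optionally
drops genes below the first quartile in every stage before counting.

## piRNA density

Each of a read's *n* genomic mappings carries weight 1/*n*, so a read
contributes exactly one read in total and high-copy families are neither
discarded nor inflated. A mapping counts toward a feature if it overlaps it
by ≥ 1 bp (full containment was not required; the any-overlap rule is
documented and isolated for sensitivity testing), on the feature's strand
for sense density and the opposite strand for antisense, divided by feature
length. A unique-only mode (n = 1 reads) is provided as a cross-check;
tests verify the two modes are rank-correlated on synthetic families.

## Allele expression permutation test

Expression is converted to within-sample ranks (rank 1 = highest; average
ranks on ties, which are rare for continuous intensity data), because
between-array scale differences make raw values incomparable.
Zero-expression genes are dropped per sample, since no expression cannot be
distinguished from no signal. Per gene and window, a strain is `with_te`
if any TE site in the window is called present, `without_te` if all are
absent, and missing if any is no-call with none present. The statistic is
mean rank(with) − mean rank(without); positive values mean the with-TE
alleles are expressed lower. All C(n, k) label assignments are enumerated
(the observed one included, so p > 0), and the one-tailed p is the fraction
of assignments with a difference ≥ the observed. Genes need at least two
alleles per group and more than 20 possible assignments to be testable
(otherwise p < 0.05 is unreachable). Above a configurable enumeration cap
the test refuses rather than silently switching to Monte-Carlo.

Excess significance builds the 2×2 table of observed significant/
insignificant counts against the α·N expectation, with the expected count
rounded half away from zero, and reports the one-sided ("greater") Fisher
exact p plus the sample cross-product odds ratio. The odds ratio is
reported but never used as an exact oracle, because a conditional-MLE
estimator would give slightly different values on the same table.

False-positive-rate calibration samples genes with no TE alleles, draws a
(n_with, n_without) pair per gene from an observed group-size spectrum,
randomly partitions strains accordingly, and repeats for 100 replicate gene
sets. Because the permutation p-values are discrete (multiples of 1/C) and
super-uniform, the expected rate sits slightly below the nominal 5% — the
calibration's reference spectrum is skewed toward few with-TE alleles
(n_with = 2–4), as the skewed TE frequency spectrum dictates for real
panels. The joint (n_with, n_without) spectrum is matched, not just the
with-group size.

## Population-frequency statistics

A TE's population frequency is n_present / (n_present + n_absent) over
called genomes; a TE present in no genome beyond the reference has
frequency 0 and `observed = False`. Partial Spearman correlations use the
pairwise-rho formula on rank-transformed data with a t approximation on
n − 3 df; the residual-based construction (correlating rank-regression
residuals) is kept as the test oracle for the formula. The family-aware
ANOVA models log density (genes with positive density only, since the
zero-inflated density distribution admits no useful transform) on
observed-status, family, and their interaction, degrading gracefully when
only one family or too few families with both states are present; the
companion mixed model treats family as a random intercept and reports the
sign of the TE-frequency coefficient. The logistic models regress TE
presence on a predictor and its square (density or stage count, plus
recombination rate and its square) with single-term backward elimination
minimising AIC, stopping when no removal helps; a quadratic term shields
its linear parent (hierarchy rule — the elimination policy was an open
choice and retained-term identities are not asserted against any external
table). Complete separation is flagged rather than hidden.

## Synthetic study system

The generator emulates the statistical structure the analyses assume; its
defaults are the package's study conditions and were chosen once, as
follows:

* **Geometry** — two 12-Mb chromosome arms (three 4-Mb locality bins each)
  with 200-kb heterochromatic margins; 450 genes (2–8 kb, 2–4 exons) laid
  out in blocks with 12–25-kb gaps; 80% of genes receive an adjacent TE at
  a distance spread over the analysis bins; 12% receive an intronic TE of
  family-typical length (the insertion widens its host intron, as real
  intronic TEs do); 100 standalone TEs are padded by ≥ 11 kb so their
  flanks stay intergenic for decay profiling.
* **Families and piRNA** — 12 families with Zipf-like copy-number weights;
  family piRNA abundance proportional to copy number with lognormal noise,
  normalised to mean 1 (copy number is the empirical driver of piRNA
  amount); 50,000 reads allocated to families by abundance × sequence
  length; half of the reads of multi-copy families map at homologous
  offsets across up to 8 copies with correct n-hit counts; 70% of reads are
  antisense to their TE.
* **Silencing and spreading** — per-TE Bernoulli silencing, shared across
  stages, with logistic probability rising in family abundance and TE
  length (intercept −5, abundance coefficient 2 on log1p(10·abundance),
  length coefficient 0.25/kb — roughly 40–50% of TEs silenced with a strong
  family gradient). Density = background 0.05 + per-step noise (sd 0.05)
  + regional 5-kb-scale noise (sd 0.05) + A·exp(−d/λ) around silenced TEs
  with A = 0.5 reads/bp and λ = 1,000 bp, integrated exactly over each
  200-bp step (so window means match the closed-form integral to machine
  precision). λ = 1 kb encodes that the observed elevation is mostly gone
  by ~2 kb; the regional noise term represents chromatin-state variation
  from processes other than TE silencing and sets a realistic noise floor
  that per-step noise alone (which averages out over exons) would not.
  Amplitudes attenuate geometrically to 0.5× across the nine stages,
  mirroring the weakening of associations at later stages.
* **Population** — per-TE insertion frequency from Beta(0.5, 3) (skewed,
  many rare insertions), multiplied by exp(−2.5) when the TE is silenced —
  the selection signal; realised frequencies from 131 binomially sampled
  genomes with 5% no-calls. The 21-strain expression panel draws genotypes
  from the same frequencies; expression = gene baseline N(8, 2) (correlated
  between sexes) + N(0, 0.5) noise − 1.5 for strains carrying a silenced TE
  within 10 kb. Setting the effect and the coupling to zero yields the null
  panel used for calibration.

Effect sizes were set so that the generator's designed causal structure
(silencing ← piRNA targeting; spreading → genic H3K9me3; silencing → lower
frequency and lower neighbour expression) is detectable without ambiguity
at this desk-scale sample size (~350–400 gene–TE pairs), while the
resulting rank correlations stay in the modest range typical of real
chromatin data.

**What the generator does not emulate:** tissue heterogeneity within a
stage; mappability artefacts and read-depth variation; linkage between TE
sites; family-specific insertion-site preferences; transposition–selection
balance through time (frequencies are drawn, not evolved); and any direct
piRNA silencing of genes beyond a small uniform genic read fraction.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of the designed structure — not that real
data would show effects of this size.

## Numerical conventions

Empirical quantiles use linear interpolation with ≥ at the threshold.
Expected-significant counts round half away from zero. Permutation-tail
comparisons use a 1e-9 tolerance so floating-point noise cannot flip a ≥
at equality. Fisher tests are one-sided "greater" where the hypothesis is
an excess, two-sided otherwise; Mann–Whitney tests are two-sided
everywhere. All randomness flows from a single seed through named
substreams, so each generator stage is independently reproducible.

## Problem sizes

The default study system (450 genes, ~500 TEs, nine stages, 131 + 21
genomes, 50,000 reads) generates in a few seconds and supports the full
analysis chain; the calibration uses 100 replicates of ~85–100 genes each
(~8,500–10,000 exhaustive tests). Null ensembles of 1,000 replicates are
supported; tests and examples use 10–200 replicates, which already bound
the null band tightly at these track sizes.
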
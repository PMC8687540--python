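# Methods

This note documents the statistical models and numerical choices behind
`rbptraits`, the assumptions of the synthetic cohort generator, and the
limits of what passing tests demonstrate about real data.

## Quantification

Size factors come from the median-of-ratios estimator applied **jointly**
to the pooled RNA-seq and Ribo-seq libraries: per gene, the geometric mean
across all libraries (genes containing any zero are excluded from the
reference, the standard convention); per library, the median of
count/geomean ratios.  Joint estimation matters because translational
efficiency (TE) is a cross-assay ratio — per-assay normalization would fold
assay-specific depth into TE.  A consequence of the shared reference worth
knowing: rescaling one library rescales every factor by a common constant
(factor *ratios* scale exactly; individual factors do not).

TE(g, s) = ribo_norm(g, s) / rna_norm(g, s); entries with zero normalized
RNA are missing and stay missing — downstream correlations are
pairwise-complete, no imputation anywhere.  FPKM uses the CDS length
because counting is CDS-restricted.  The expression filter keeps genes
with mean FPKM strictly above 1 and at least one read in both assays in at
least 20 samples (both thresholds configurable).

PSI for a cassette exon is mean(IJ_up, IJ_down) / (mean(IJ_up, IJ_down) +
EJ), with the two inclusion junctions averaged so that inclusion and
exclusion coverage are on the same per-event scale.  Estimates are masked
below a total junction coverage of 10 (configurable) to avoid unstable
0/0-type ratios at low depth.

## CLIP target derivation

Peak scores interpret IP and input reads as library fractions with a 0.5
pseudocount on both counts (raw read sums would make log2(p/q) depend on
sequencing depth; the single pseudocount policy keeps the information
content, the fold change and the binomial rate consistent and defined at
zero counts).  The enrichment p-value is the upper binomial tail of the IP
count at the input rate; the test is pluggable since nothing downstream
depends on its exact form beyond the p ≤ 1e-5 filter.

**IDR.** Replicate scores are rank-transformed to normal scores and fitted
by EM with a two-component Gaussian mixture: a reproducible component with
common mean μ ≥ 0, variance σ² and correlation ρ ∈ [0, 0.999], and an
irreproducible component of independent standard normals.  Initialization
π = 0.5, ρ = 0.8, μ = 1, σ² = 1; tolerance 1e-6 on the log-likelihood;
at most 500 iterations (non-convergence raises, reporting the last delta).
A peak's IDR is the cumulative mean of the irreproducibility posterior
taken in order of increasing posterior — monotone in rank discordance by
construction.  This is a deliberate simplification of the semiparametric
copula IDR (no marginal re-estimation step); it is fitted per RBP on the
matched replicate peaks and at least 20 matched peaks are required.  Two
properties follow from the mixture arithmetic and are worth keeping in
mind when choosing cutoffs: (i) consistently *low* peaks are rank-
concordant and therefore look reproducible — IDR measures reproducibility,
not signal, which is why the published filter combines it with fold-change
and enrichment cutoffs; (ii) a strict IDR < 0.01 cutoff is only attainable
when the irreproducible fraction of the peak set is modest, as it is in
real replicate peak sets.

Filtering is exactly as printed: IDR < 0.01 (strict), p ≤ 1e-5, FC > 8
(strict).  Overlap pooling chains same-strand overlaps by single linkage
(the underlying description is silent on chained overlaps) and keeps the
smallest enrichment p, ties broken by larger information content, then by
leftmost start.  A gene becomes a target when any surviving peak overlaps
one of its transcripts on the same strand; the binding region of a peak is
decided by its midpoint with priority CDS > 5'UTR > 3'UTR > intron when
transcripts disagree.

## Correlation and collinearity

Spearman uses midranks; its p-value is the t approximation for n ≥ 10 and
an exhaustive permutation of the rank vector below that.  Pairs with fewer
than 10 complete observations (configurable) yield a missing record rather
than an unstable estimate.  BH adjustment is applied within one RBP × one
trait family (the RBP's own CLIP targets); a global-family switch exists
but the per-RBP convention matches how per-RBP retention is defined.  All
tests are two-sided.

Partial correlation is computed on ranks (residuals of linear fits on the
rank-transformed conditioning set), so it degrades gracefully alongside
Spearman; its p uses n − 2 − k degrees of freedom.  The collinearity
filter re-tests each significant (RBP, target) pair partialling out the
other RBPs in the cluster; a target survives when the BH-adjusted partial
p stays ≤ α *and* the partial coefficient keeps its sign.  Fisher-Z
comparison of two coefficients uses se = √(1/(n₁−3) + 1/(n₂−3)).

## Empirical enrichment

The null distribution draws N sets of targets uniformly without
replacement from the expressed universe minus the RBP's own gene
(self-correlation would otherwise leak in) and counts BH-significant
correlations per set with **exactly the same family convention** as the
observed count — a consistency requirement, since BH significance depends
on the family.  Empirical p = #{null ≥ observed}/N, floored at 1/N: a
finite set of sampled nulls cannot certify a smaller value.  Glass' Δ uses
the sample (n−1) standard deviation of the null.  Classification applies
BH across RBPs per trait to the empirical p-values; multifunctional means
significant in both traits.  Target-set overlap is reported as
100·|A∩B|/|A∪B| (the union denominator is our choice; it is configurable
in interpretation, not silently switched).  The default N is 100,000;
the bundled benchmarks use N = 2,000–5,000, which is ample for the
α = 0.05 decisions they check.

## Replication

For each RBP, discovery-significant pairs are looked up in a second
cohort's correlation table; the replicated fraction counts sign agreement
(a replication coefficient of exactly 0 counts as non-replicated).  The
permutation test permutes the replication coefficients among the RBP's
pairs (within-RBP, not global) and reports
p = (1 + #{perm ≥ obs}) / (1 + n_perm) — the +1 smoothing keeps p
positive and the estimator valid.  BH across RBPs.

## Target features

Correlation-profile clustering: Euclidean distance on rows with missing
correlations imputed as 0 for the distance only, complete linkage;
RBP–RBP target-overlap dendrograms use 1 − Jaccard with average linkage
(neither linkage is externally fixed; both are configurable).  Group
comparisons (CDS lengths, isoform TE, MFE) use the two-sided Wilcoxon
rank-sum test — exact when min(n, m) ≤ 8 with no ties, normal
approximation with tie correction otherwise — BH-adjusted when batched
across RBPs.

**Folding.**  The built-in engine is a weighted Nussinov dynamic program:
GC/CG = −3, AU/UA = −2, GU/UG = −1, minimum hairpin loop of 3 unpaired
bases, energy = sum of pair energies, no pseudoknots, O(n³).  It is not a
thermodynamic model (no stacking, dangles or loop entropies) — it is an
exactly testable structural-complexity score, verified against exhaustive
enumeration of all nested structures for short sequences.  One exact
symmetry holds (sequence reversal); reverse-*complement* symmetry does
not, because a G·U wobble maps to the non-pairing A·C.  Normalized MFE is
energy per nucleotide; sequences shorter than 20 nt are excluded from
group comparisons.  A thermodynamic engine can be passed per call
(`engine=` accepts any str → float scorer; `fold_mfe_rnafold` wraps
ViennaRNA's RNAfold when the executable is available).

Length-matched subsampling draws 50 genes per group (configurable)
stratified on deciles of the pooled length distribution, merging adjacent
strata when one is short, and accepts a draw only when every pairwise
rank-sum p on lengths exceeds 0.1 (up to 100 redraws).

Ubiquity: an RBP is ubiquitously expressed when strictly more than 30
tissues show TPM ≥ 10 in a tissue-averaged TPM table.

## The synthetic cohort

The generator emulates the data-generating process the analysis assumes:

* **Dose.**  Each RBP has a latent per-sample standard normal dose z; its
  own expression is lognormal around a high baseline with log-sd 0.5 in z.
* **Effects.**  A planted target's log mean mRNA and/or log TE shifts by
  β·sign·z (β = 1 by default, signs random ±1 per target); effects from
  multiple RBPs add on the log scale, which keeps means positive and
  composes cleanly.  Dual-trait RBPs get disjoint mRNA/TE target sets by
  default (overlap configurable), mirroring the low-overlap phenomenon the
  classification is meant to detect.  Null RBPs bind genes (real CLIP
  peaks) with zero effect.
* **Counts.**  Gene baselines are lognormal (log-mean ln 150, log-sd 1);
  per-sample expected proportions are scaled to a library size drawn
  uniformly from 400k–600k; counts are negative binomial with dispersion
  0.1 (variance μ + 0.1μ²).  Ribo-seq means are RNA means times a
  lognormal TE baseline (log-sd 0.25) times the TE effects.  The real
  cohort's dispersion and effect-size distribution are unknown; these are
  free, explicitly chosen parameters, not calibrations.
* **CLIP.**  Bound genes receive 1–3 peaks whose IP enrichment shares a
  lognormal signal across replicates (fold change lognormal around 18,
  log-sd 0.6; replicate log-noise 0.1) over a Poisson input of 10–30
  reads.  Decoy peaks appear on unbound genes at rate 0.02 and are
  input-like in log-expectation but with *independent* per-replicate
  spurious enrichment (log-sd 1.2) — i.e., genuinely irreproducible, which
  is the failure mode the IDR filter exists to catch.  Bound genes are
  missed at rate 0.1.
* **Annotation.**  One multi-exon transcript per gene; 5'UTR/CDS/3'UTR
  lengths lognormal with medians 120/1500/500 nt (CDS rounded to a
  multiple of 3), exon count 1 + Poisson(3), strands random; GTF emitted
  1-based inclusive, peaks 0-based half-open BED.
* **5'UTRs.**  "Structured" sequences contain GC-rich palindromic stems
  with short loops; "unstructured" ones are A/C-dominated and nearly
  pairing-free.  In the bundled fixture, negatively-correlating TE targets
  are structured — a stylized version of structure-dependent translational
  control.
* **Splicing.**  Designated cassette exons follow
  logit(PSI) = logit(PSI₀) + 2·coupling·z + noise with PSI₀ ∈ U(0.3, 0.7)
  and Gaussian logit noise (sd 0.3); junction counts are Poisson at ~60×
  coverage with the two inclusion junctions sampled independently, so the
  PSI estimator recovers the planted value in expectation.  The inclusion
  isoform carries a log-TE offset.

**What the generator does not emulate**: GC or mappability bias, gene–gene
correlation beyond shared RBP doses, isoform-level quantification
ambiguity, batch effects, cell-type mixture, CLIP crosslink sequence bias,
and annotation errors.  Passing the benchmarks therefore shows the
pipeline is *correct and calibrated under its own assumptions* — type-I
error control, recovery of planted effects, exactness against enumeration
— not that real-cohort discoveries are guaranteed at the same rates.

## Benchmark problem sizes

The bundled acceptance checks run at: 20-gene universe with all 15,504
5-gene subsets (enrichment exactness); 200 effect-free RBPs × 1,000 genes
× 80 samples with 2,000 null sets (type-I ≤ 0.08 at α = 0.05); 24 planted
RBPs (6 per class) × 2,000 genes × 80 samples with 5,000 null sets
(≥ 90% label recovery, dual overlap < 30%); 1,000 random instances per
statistical kernel against brute-force oracles; 100 sequences ≤ 12 nt
against exhaustive folding enumeration; 500 RBPs × 1,000 permutations for
permutation-p uniformity, with 1,000–3,000 evaluable pairs per RBP — the
large-target-set regime.  The pair count matters because the replicated
fraction is a discrete statistic: its tie-inclusive permutation p-value is
validly conservative, and with only a few hundred pairs the tie masses
(up to ~6% per support point) produce one-sided ECDF gaps that a
500-sample KS test against the exact uniform can detect.  At a few
thousand pairs the discreteness is negligible and the p-values are
uniform to KS resolution.  The end-to-end smoke fixture uses 400 genes ×
40 samples with 1,000 null sets, sized so the whole suite runs comfortably
on one CPU.

## Known limitations

* The IDR is a simplified Gaussian-copula EM, not a numerical clone of
  the reference implementation; absolute IDR values are comparable only
  within a fit.
* The binomial enrichment p ignores overdispersion between input and IP
  libraries.
* The folding engine's energies are ordinal, not thermodynamic; MFE
  differences between groups are meaningful, absolute values are not
  kcal/mol.
* Per-RBP BH families make significant-target counts non-comparable
  across RBPs with very different target-set sizes; the enrichment null
  inherits and thereby neutralizes this.
* The PSI formula follows the averaged-flanking-junction convention; other
  definitions length-normalize differently.
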
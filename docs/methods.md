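# Methods

This note documents the models and estimators implemented in `rcnvclock`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real data.

## Coordinates and units

All genomic intervals are 1-based inclusive base pairs internally; BED
export converts to 0-based half-open at the boundary only. Genetic map
positions are centimorgans at interfaces; coalescence arithmetic uses
Morgans (1 M = 100 cM). Genetic position at an arbitrary base pair is
piecewise-linear interpolation between map knots; beyond the outermost
knots the terminal interval's rate is extrapolated.

## Consensus CNV calls

A CNV enters the analysis only when both callers report it for the same
sample with the same state (deletion/duplication) and a reciprocal overlap

  RO(a, b) = min(|a∩b| / |a|, |a∩b| / |b|)

of at least 0.5 (the threshold is inclusive), and the consensus segment
spans at least 10 probes and 10 kb. Matching within a sample is greedy by
descending RO (ties: leftmost start, then shortest call), each input call
used at most once; this makes the result deterministic and independent of
argument order. The consensus segment is the *intersection* of the matched
pair — conservative, and it keeps the probe-count filter meaningful; union
and caller-A-priority endpoints are available as options. The consensus
probe count is recounted from probe positions when they are supplied,
otherwise the smaller of the pair's counts is used.

## rCNV loci

Same-state consensus calls are clustered across individuals by
single-linkage with RO ≥ 0.5, after a canonical sort so the clustering is
independent of input order. Because array breakpoints are only accurate to
roughly 10 kb, an optional endpoint tolerance links calls whose start and
end both agree within the tolerance even when RO misses the threshold.
Locus boundaries are the coordinate-wise median of member segments (robust
to breakpoint jitter). A locus with ≥ 2 distinct carriers is recurrent; a
sample contributing two member calls to one cluster is counted once, with
a warning.

Cross-population sharing matches loci one-to-one, best overlap first.
The default rule (`band_or_overlap`) accepts either a physical overlap or
a shared cytogenetic band with matching state, because loci typed on
different arrays in different cohorts can have disjoint printed intervals
yet plainly be the same variant; strict-overlap and band-only rules are
available. Gene annotation classifies each gene interval as fully
contained, partially overlapped, or outside a locus.

## Coalescence dating (Gamma method)

**Model.** Carrier lineages are assumed independent (a star genealogy):
each side's shared genetic length is Exponential(rate τ), per-haplotype
5′+3′ totals are Gamma(2, τ), and the total over n haplotypes is
Gamma(2n, τ). The point estimate is τ̂ = 2/l_ave; the CI takes the
Gamma(2n) quantiles divided by n·l_ave. The CI therefore reflects sampling
of shared lengths only; recombination-map uncertainty is reported
separately as a ±20% rate sensitivity band (τ̂/1.2, τ̂/0.8) rather than
folded into the interval, since no principled map-error model is
available.

**Windows.** By default the 60 SNPs nearest the locus on each side are
used, ordered outward. For deletions, SNPs inside the CNV are hemizygous
and carry no phase information; dating uses flanking SNPs only. Carriers'
CNV-bearing haplotypes are identified by interior missingness (deletions)
or, failing that, by agreement with the carrier-modal flanking haplotype.

**Shared-haplotype extension.** Scanning outward, a haplotype extends
while it matches the inferred ancestral allele; missing alleles are
neutral (they neither terminate extension nor spoil a rescue). A mismatch
is rescued iff the next five SNPs all match (`rescue_len` configurable;
0 disables). A second mismatch inside the lookahead makes the *first*
mismatch the breakpoint. The ancestral allele at each SNP is estimated
*progressively*: the majority over the other haplotypes still extending at
that position (leave-one-out, ties to allele 0). A whole-window static
modal is available as an option but is biased: beyond roughly ln2/τ most
carriers have recombined, the static modal drifts to the population major
allele, and long shared segments are truncated — in simulation this
inflated τ̂ by ~25%. With the progressive reference, once a single
haplotype survives it has nothing left to share with, so it terminates at
the last pair-divergence point; the maximum shared haplotype is only
identifiable from sharing between at least two carriers.

**Breakpoint placement.** The breakpoint is recorded at the last
concordant SNP before the first unrescued mismatch. The half-spacing this
gives up relative to the true (unobserved) recombination point offsets the
chance-match overrun — background alleles agree with the reference at
~60-70% per SNP, so the scan runs one to two SNPs past the true breakpoint
on average. In calibration simulations this convention is near-unbiased
(mean τ̂ ≈ 99 at τ = 100), where a midpoint convention retains a ~2%
downward bias in τ̂.

**Censoring.** A side with no breakpoint inside the window contributes the
window's genetic length as a lower bound and is flagged; the estimator
warns when the censoring fraction exceeds 0.2, since τ̂ is then biased
downward. Haplotypes entirely missing in a window are excluded with a
warning.

**Weights.** Haplotypes are grouped by identical (5′, 3′) breakpoint
signatures and l_ave is the weight-averaged total length, weights being
group sizes. With per-haplotype totals this equals the simple mean; the
grouping is retained because shared breakpoints are reported and because a
side-wise weighting variant is a natural extension.

**Relatives.** First- and second-degree relatives should be excluded
before dating (`exclude_relatives`, KING φ ≥ 0.0884, dropping the member
of each pair with more missingness), since close relatives share flanking
haplotypes for genealogical rather than coalescent reasons.

**Group comparisons.** Ages of locus groups are compared with a two-sided
Mann–Whitney U (exact enumeration when both groups ≤ 8 and untied,
tie-corrected normal approximation otherwise). Age–abundance association
is Pearson correlation with the least-squares slope of carrier frequency
on age and a t-distribution p on n − 2 df.

**Haplotype-background confirmation.** `share_support` reports the mean
per-SNP concordance of carrier haplotypes with their modal haplotype over
the 10 SNPs nearest the CNV on each side. Common-origin carriers exceed
0.9; pooled non-IBD haplotypes concentrate near the chance-match rate
(~0.6–0.7). Per-SNP concordance, rather than an all-SNP exact match, keeps
a genuine recombination just inside the flank from disqualifying an
otherwise concordant carrier.

## Kinship and association

**KING-robust kinship.** φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(i) + N_Aa(j))
over pairwise-complete SNPs, after excluding SNPs with missing rate > 0.1
or MAF < 0.01. The estimator needs no allele-frequency estimates, making
it robust to structure; duplicates give exactly 0.5, parent–offspring
≈ 0.25, unrelated ≈ 0. A pair with no heterozygous sites in either member
is undefined (NaN, with a warning).

**2×2 association.** Pearson χ² without continuity correction when every
expected cell exceeds 5 (the χ² validity condition), Fisher's exact test
otherwise; the path taken is recorded. The odds ratio uses the
Haldane–Anscombe 0.5 correction iff any cell is zero; the 95% CI is the
Woolf log-OR Wald interval; Bonferroni adjustment is min(1, m·p).

**Kinship-adjusted model.** The full logistic mixed model with a dense
kinship random effect is approximated by fixed-effect adjustment: the
leading eigenvectors of the kinship matrix with zeroed diagonal, ranked by
λ², added until ≥ 80% of the off-diagonal Frobenius mass Σ_{i≠j} φ_ij²
(= Σλ², exactly) is captured, at most 10. A matrix with no off-diagonal
mass contributes no adjustment, so an unrelated cohort reduces exactly to
plain logistic regression on carrier + age + sex. Perfect separation falls
back to Firth-penalised (Jeffreys-prior) estimation, flagged in the
output. This is an approximation: with strong, pervasive relatedness a
low-rank fixed-effect summary absorbs less confounding than a full random
effect, and numerical agreement with a mixed-model fit is not expected.

**Power threshold.** The minimum detectable carrier frequency solves
power(f) = target for the two-sided Wald test on log OR, using the
standard two-variance approximation
power = Φ((|log OR| − z_{1−α/2}·SE₀)/SE₁), with SE₀ from null-expected and
SE₁ from alternative-expected cell counts; the noncarrier case probability
is solved so the cohort-wide case fraction is matched. f is found by
bisection to 1e-4. A one-variance formula using only alternative-expected
cells was rejected: at large OR the tiny carrier-control cell dominates
Σ1/cell and the criterion degenerates to demanding several expected
carrier-controls, roughly tripling the threshold relative to standard
practice. At n = 387, case fraction 0.60, OR = 10, power 0.8, α = 0.05
the implemented formula gives f ≈ 2.7%.

## Burden

Per sample: CNV count, and gene load = distinct genes overlapped (fully or
partially) by any of the sample's CNVs, each gene once per sample; samples
without calls appear with zeros. Case–control comparison is a two-sided
Mann–Whitney per metric with group means ± SD, deliberately unadjusted for
covariates and labelled exploratory in the output.

## Synthetic cohorts

The generator emulates exactly the process the dating model assumes, so
that every downstream stage can be tested with known truth:

- a founder haplotype carrying the CNV, transmitted `tau_true` generations;
  under the default star genealogy each carrier side's breakpoint distance
  is an independent Exponential(rate τ) draw in Morgans. A `tree` option
  builds a Kingman coalescent (timescale set so E[TMRCA] = τ) and places
  recombination as a Poisson process along each lineage's root path,
  producing the correlated shared lengths that violate the independence
  assumption — the known failure mode;
- background haplotypes drawn per SNP from allele frequencies
  ~ U(0.1, 0.5), with **no linkage disequilibrium**. An LD-free background
  is the conservative easy case for shared-haplotype detection (chance
  sharing is shorter-ranged than in real data); an LD-aware background is
  future work;
- SNPs placed at equal genetic spacing, 40 SNPs/cM by default —
  genotyping-array scale while keeping simulations small; deletion
  carriers are hemizygous (interior SNPs missing on the CNV haplotype);
- per-allele genotyping error 0.002 (flip 0↔1 after descent), typical of
  post-QC array data;
- two callers corrupt the true interval with Gaussian breakpoint jitter
  (SD 5 kb, snapped to the nearest probe; exact when the SD is 0),
  per-carrier dropout 0.05 and per-sample spurious calls 0.05;
- phenotypes from a logistic model, baseline prevalence 0.60 (the scale of
  a deeply affected founder cohort) and carrier odds ratio 3; a second,
  CNV-independent diagnosis flag exists so the derived "any diagnosis"
  outcome differs from the primary one.

Same seed and configuration give bit-identical outputs.

What passing tests on these cohorts do **not** show: robustness to LD
(chance flanking sharing in real data is longer than simulated), to
phasing error (haplotypes are emitted phased), to intensity-level caller
artifacts, or to sex chromosomes. Real-data coalescence times and
mixed-model odds ratios are not reproducible from the package alone; the
simulation recovery suites stand in for them.

## Calibration and problem sizes

The parameter-recovery suite uses star-genealogy cohorts with τ = 100,
50 carrier haplotypes, a uniform 1 cM/Mb map and no genotyping error, and
dates each with flanking windows of 10 cM per side (400 SNPs at the
default density; the genetic span, not the SNP count, is what matters for
censoring). Over 100 seeds the median τ̂ falls within a few percent of
truth and the empirical 95% CI coverage is 0.90–0.97. With genotyping
error 0.005 the five-SNP rescue roughly halves the mean |τ̂ − τ| relative
to rescue-disabled scans, which are biased upward (spurious mismatches
truncate shared lengths). Association calibration uses 2000 null 2×2
replicates at n = 400. These sizes keep the full suite under a minute of
simulation time while leaving Monte-Carlo error well inside the asserted
bands.

## Known limitations

- τ̂ assumes lineage independence; genuine genealogical structure
  (`genealogy="tree"`) correlates shared lengths and makes the CI too
  narrow. Relative exclusion mitigates but does not remove this.
- Heavy censoring (windows short relative to 1/τ) biases τ̂ downward even
  with the lower-bound convention; the estimator warns beyond 20%
  censoring. Conversely the progressive reference cannot see sharing past
  the last pair-divergence, slightly truncating the single longest
  haplotype.
- The kinship-eigenvector adjustment is a fixed-effect approximation to a
  mixed model (above).
- The rank-sum p in `kinship_compare` treats pairs as independent although
  pairs sharing an individual are correlated; it is descriptive only.
- PennCNV-style input parsing covers the common `.rawcnv` layout; the
  exact export formats of array-calling pipelines vary, and the TSV
  dialect is the canonical interchange format here.
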
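# rcnvclock

Recurrent copy-number variants (rCNVs) in founder populations are often
identical-by-descent: dozens of carriers inherit the same deletion or
duplication, on the same flanking haplotype, from a single ancestor.
`rcnvclock` is a Python toolkit for the full analysis chain such studies
run on SNP-array cohorts:

1. **Consensus CNV calling** — merge two callers' call sets, keeping calls
   detected by both with ≥ 50% reciprocal overlap, spanning ≥ 10 probes and
   ≥ 10 kb (`cnv_consensus`).
2. **rCNV detection** — cluster consensus calls across individuals into
   loci, compute carrier frequencies, match loci across populations, and
   annotate genes (`rcnv_detection`).
3. **Coalescence dating** — estimate how many generations ago each rCNV
   arose from the genetic length of the shared flanking haplotype
   (`haplotype_coalescence`).
4. **Kinship-aware association** — KING-robust kinship from SNP genotypes,
   carrier × diagnosis 2×2 tests with Bonferroni adjustment, a
   kinship-eigenvector-adjusted logistic model, and a power-based minimum
   detectable carrier frequency (`kinship_assoc`).
5. **CNV burden** — per-individual event counts and gene load with
   nonparametric case–control comparison (`burden`).

A first-class synthetic-cohort generator (`synthetic_data`) simulates the
process the dating model assumes — a founder haplotype transmitted τ
generations under recombination against a genetic map, plus genotyping
error, two noisy callers, and phenotypes with a configurable carrier odds
ratio — so the whole pipeline is testable against known truth.

## The dating model

Scanning outward from the CNV, each carrier haplotype matches the ancestral
haplotype until its first historical recombination. A single mismatch is
"rescued" (attributed to mutation or genotyping error) when the next five
SNPs all match. Under independent carrier lineages each side's shared
genetic length is Exponential(rate τ), so the per-haplotype 5′+3′ total is
Gamma(2, τ) and

  τ̂ = 2 / l_ave,

where l_ave is the weighted mean of per-haplotype total shared lengths in
Morgans (weights = numbers of haplotypes sharing a breakpoint). The total
length over n haplotypes is Gamma(2n, τ), giving quantile confidence
intervals

  CI = ( q(α/2; 2n) / (n·l_ave), q(1−α/2; 2n) / (n·l_ave) ).

See `docs/methods.md` for estimator details, assumptions and limitations.

## Worked example

```python
from rcnvclock import (
    SimulationConfig, simulate_cohort, emit_callsets,
    ConsensusParams, merge_consensus, group_recurrent, date_rcnv,
)

config = SimulationConfig(seed=5)           # 200 samples, 50 carriers, tau = 100
haps, gmap, truth, pheno = simulate_cohort(config)
set_a, set_b = emit_callsets(truth, haps, config.caller_noise, seed=6)

consensus = merge_consensus(set_a, set_b, ConsensusParams())
loci = [l for l in group_recurrent(consensus, cohort_size=config.n_samples)
        if l.recurrent]
locus = max(loci, key=lambda l: l.carrier_count)
print(f"{len(consensus)} consensus calls -> locus "
      f"{locus.chrom}:{locus.start}-{locus.end} ({locus.state}, "
      f"{locus.carrier_count} carriers, frequency {locus.carrier_frequency:.2f})")

est, summary = date_rcnv(locus, haps, gmap, sorted(locus.carriers),
                         k_per_side=400, years_per_generation=28)
print(f"l_ave = {summary.l_ave:.4f} M over {summary.n_haplotypes} haplotypes")
print(f"tau_hat = {est.tau_hat:.0f} generations "
      f"(95% CI {est.ci[0]:.0f}-{est.ci[1]:.0f}), "
      f"~{est.years:.0f} years at 28 y/generation")
```

prints

```
47 consensus calls -> locus 1:14762501-15237501 (deletion, 47 carriers, frequency 0.23)
l_ave = 0.0219 M over 47 haplotypes
tau_hat = 91 generations (95% CI 74-111), ~2556 years at 28 y/generation
```

Three of the 50 simulated carriers were lost to caller dropout; the
consensus calls still pin the locus to within a probe spacing of the true
500 kb deletion, and the 95% interval brackets the true age of 100
generations. The same stages are exposed as a command line
(`rcnvclock simulate | consensus | rcnv | date | assoc | burden`).

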
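# Methods

This note documents the statistical models behind `microase`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical choices that affect results.

## Joint genotyping

Reads from every sample are pooled per SNP (all samples derive from one
cell line, so they share a genotype). The caller is a three-genotype Bayes
classifier:

- **Prior**: Hardy–Weinberg at the site's population alternate-allele
  frequency f: ((1−f)², 2f(1−f), f²) for (RR, RA, AA).
- **Likelihood**: Binomial(n_ref; n_ref+n_alt, p_g) with p_RR = 1−ε,
  p_RA = 0.5, p_AA = ε. Reads matching neither allele (n_other) are
  excluded from this likelihood — conditioning on ref+alt reads keeps the
  three-genotype model binomial and well identified — but they do inform ε
  through an independent Binomial(n_total, ε) factor.
- **Error rate**: ε is a single global parameter estimated by EM.
  The E-step computes genotype posteriors; the M-step is the exact
  maximizer of the expected complete-data log-likelihood,

      ε̂ = [Σ post(RR)·n_alt + post(AA)·n_ref + Σ n_other] /
          [Σ (post(RR)+post(AA))·(n_ref+n_alt) + Σ n_total],

  i.e. expected miscalled reads over the reads at risk of miscall. Because
  this is textbook EM, the observed-data log-likelihood is non-decreasing
  (asserted in tests); convergence at Δlog-lik < 1e-8 or 100 iterations.
  ε is initialized at 0.01 and clipped to [1e-6, 0.49]. A per-sample ε is
  deliberately out of scope.

Posteriors are computed in log space. Sites with zero pooled ref+alt
coverage keep the prior and are flagged uncallable, as are exact posterior
ties (never silently argmax a tie). Heterozygotes are selected at
posterior(RA) ≥ 0.99 — genotyping errors masquerade as extreme allelic
imbalance, so precision is prioritized over recall; the cutoff is a config
parameter.

Panel filtering removes SNPs with folded MAF < 0.05 (the boundary value
0.05 is kept) and SNPs inside exclusion intervals supplied as BED. Panel
and pileup positions are 1-based; BED is 0-based half-open; the conversion
happens in exactly one place (`filter_panel`).

The pileup parser implements the samtools text dialect: `.`/`,` are
reference matches, letters are mismatches, `^X`/`$` read boundaries,
`+N…`/`-N…` indel runs, `*`/`>`/`<` placeholders — only base calls are
counted, and only at or above the base-quality cutoff (default Phred 13).

## Allelic imbalance (ASE)

At a het site with n = n_ref + n_alt ≥ 20 reads in one sample, the raw
reference fraction r = n_ref/n is corrected for symmetric miscalls,
ρ = (r − ε)/(1 − 2ε), clamped into the interior by δ = 1/(2n) (half a
read's worth of proportion, so monoallelic sites stay finite; clamped sites
are flagged in the output), and summarized as

    β = log(ρ / (1 − ρ)),   se(β) = [n ρ (1−ρ)]^(−1/2) · √((M+n)/(M+1)).

The first factor is the inverse square root of the binomial Fisher
information in the β parameterization; the second inflates it for
beta-binomial overdispersion with concentration M (mean-p, concentration-M
parameterization: shapes pM and (1−p)M; M → ∞ recovers the binomial, and
(M+n)/(M+1) is exactly the beta-binomial variance inflation of ρ̂).

M is estimated once per dataset by maximizing the beta-binomial likelihood
with both shapes M/2 (mean 0.5) across het sites — a null-dominant
assumption, since most sites carry no imbalance — via bounded search on
log M over [0, log 1e6]. Two fallbacks: fewer than 50 usable sites returns
the binomial limit with a warning flag, and the estimate collapses to the
binomial limit whenever finite M does not improve the likelihood beyond
the χ²₁ 5% point, because the likelihood is nearly flat in M once data
look binomial and an interior optimum there is an artifact of the plateau.

Testing is Wald: z = β/se, p = 2Φ(−|z|). The same (β, se) pair feeds the
interaction contrast below, which keeps the two tests internally
consistent (a likelihood-ratio test would be marginally more accurate at
low coverage but would not supply the se the contrast needs). FDR within
each sample uses Storey q-values with fixed λ = 0.5 —
π̂₀ = min(1, #{p > λ}/(m(1−λ))), q = monotonized π̂₀·m·p/rank — which is
robust at the few thousand tests per sample this design produces; ASE
events are called at q < 0.10. Samples are tested separately; experimental
replicates of a condition should be pooled at the count level upstream.

## Conditional ASE (cASE)

For each (treatment, control) pair and each site with ≥ 20 reads in both
members,

    Z_Δ = (β_T − β_C) / √(se_T² + se_C²).

Z_Δ is only asymptotically standard normal; the residual miscalibration is
removed empirically by dividing all scores by the spread of the Z_Δ values
from the control-versus-control pair, in which no interaction can exist.
The spread is the **about-zero** standard deviation √(mean z²), not the
mean-centered one: the null contrast has expectation zero by symmetry, so
the scale estimate should not absorb a (noisy) location term; a
`center=True` switch restores the mean-centered convention. One pooled
null SD is used across all pairs (a per-stratum variant would need far
more null contrasts than one control pair provides). If the null pool has
fewer than 100 contrasts a warning is emitted; if it is degenerate (all
zeros) normalization is skipped with scale 1, which still yields p = 1
everywhere in that degenerate situation.

P_Δ = 2Φ(−|z_norm|), and the empirical FDR at each observed test P-value
t is the tail ratio

    efdr(t) = [#{p_null ≤ t}/|null|] / [#{p_test ≤ t}/|test|],

monotonized by a running minimum from the largest threshold downward and
capped at 1. Tied P-values share one efdr by construction. The efdr pool
is global across treatment pairs by default (`per_pair_efdr=True` for the
alternative); each pair tests its eligible sites independently, with no
cross-pair combination. Significance: efdr < 0.12.

## DE gene sets

The module consumes a transcript-level results table (it does not fit the
expression model itself). A transcript is DE iff |log2FC| > 0.25 **and**
BH-adjusted P < 0.1, both strict, with BH applied per condition when an
adjusted column is absent. A gene is DE in a condition iff at least one of
its transcripts is; its direction is "+"/"−" only when every DE transcript
agrees, else "mixed". The direction-consistent ("ALL") set requires DE in
every condition with one shared non-mixed direction — the strictest
reading; mixed-direction genes stay in per-condition sets but never in
ALL. The expressed-gene universe is every gene in the input table. Venn
region counts are exact for 2–3 conditions; beyond that only pairwise and
full-intersection overlaps are reported.

## Enrichment

All designs are two-by-two tables in an explicit universe. The Fisher
two-sided P follows the probability-mass convention (total probability of
fixed-margin tables no more likely than observed; `scipy.stats.
fisher_exact`, verified in tests against an exhaustive fixed-margin
enumeration). Odds ratio is the cross-product ratio (∞ flagged when
b·c = 0 with a·d > 0); fold enrichment is observed/expected overlap,
a/(row₁·col₁/N).

The GWAS-trait design restricts the universe to expressed genes present in
the catalog under any trait; rows split it into the direction-consistent
DE set versus the rest, columns into the focal trait versus other traits.
A gene carrying both the focal and other traits counts as the focal trait
(membership is per-trait, so focal membership wins). The threshold scan
takes each gene's minimum association P per trait, forms the trait set at
each −log10 P cutoff (default grid 5 to 12 by 0.25), and reports per
cutoff the observed and expected overlap, fold, and Fisher P, plus the
max-fold cutoff. No multiple-testing correction is applied across traits
(nominal per-trait values are reported, noted in output).

Category (GO-style) representation uses two one-sided hypergeometric tests
per category, reported two-sided as min(1, 2·min(p_over, p_under)), BH
across categories, enrichment = observed/expected, and a closed
expected-count band [10, 500] flag for interpretable category sizes.

## Synthetic data

The generator's defaults mirror the emulated coculture design: conditions
(T1, T2, T3, C4, C6) with pairs T1→C4, T2→C4, T3→C6 and the (C6, C4)
control contrast as empirical null; one sample per condition; 2000 SNPs;
folded MAF ~ Uniform(0.05, 0.5); coverage ~ NegBin(mean 80, dispersion
10); miscall rate ε = 0.005; beta-binomial concentration M = 300 (mild
overdispersion typical of allele-resolved RNA-seq); ASE planted at 5% of
het sites with |β| ~ |N(0, 0.5²)| conditioned on ≥ 0.25, random sign,
shared across conditions; cASE planted at 5% of het sites as Δβ of
magnitude 1.5, random sign, added in treatment conditions only. Per
sample, total coverage is drawn first, "other" reads are carved out
binomially at rate ε, and the remainder splits ref/alt beta-binomially at
the error-folded mean p = logistic(β)(1−ε) + (1−logistic(β))ε (1−ε at RR,
ε at AA). Everything is deterministic given the seed.

The DE generator plants null transcripts at |log2FC| < 0.2 with P ≥ 0.2
and DE transcripts at |log2FC| ∈ (0.3, 2.5) with P ≤ 1e-4, so planted
truth coincides exactly with the strict-threshold call set; it also plants
direction-flipped genes, mixed-direction genes, and boundary transcripts
at |log2FC| = 0.25 exactly to exercise the set rules. The GWAS generator
gives every gene each trait independently at base rate 0.05, multiplies
the focal trait's membership odds by the planted odds ratio inside the DE
truth set, and draws stronger association P-values (−log10 P ~ U(6, 25)
versus U(5, 12)) inside that overlap so fold enrichment rises with cutoff
stringency. Within the restricted-universe TRAIT/OTHER design, the
recovered sample OR is consistent for the planted conditional odds.

**What passing tests do and do not show.** The generator reproduces the
count laws the estimators assume (genotype mixture, miscalls,
overdispersion, planted effects), so green calibration tests demonstrate
internal statistical correctness — not robustness to what real data add:
mapping bias toward the reference allele, position-correlated errors,
multi-SNP haplotypes within genes, library-size imbalance between
replicates, or catalog annotation noise. Mapping-bias filtering in
particular is assumed to have happened upstream.

## Numerical choices and edge cases

- Genotype posteriors and EM in log space (`logsumexp`); posterior-sum
  invariant 1e-9.
- fit_ase clamp δ = 1/(2n) recorded per site; se > 0 guaranteed.
- Storey λ fixed at 0.5; π̂₀ capped at 1 (then q ≡ BH).
- efdr 0/0 tails: a test P with no null mass below it gets efdr 0 before
  monotonization.
- Ties: argmax ties in genotyping → uncallable; P-value ties in efdr share
  one value; BH/Storey use stable sorts, so outputs are permutation-exact.
- Degenerate inputs: empty universe, empty grids, missing traits, pairs
  referencing unknown samples, and sub-coverage sites all raise or skip
  with explicit messages; a pair with no doubly-covered sites is recorded
  as empty, not fatal.

## Known limitations

- The overdispersion estimate M̂ is biased downward when many sites carry
  true imbalance (the null-dominant assumption): with 10% of het sites
  carrying planted effects, M̂ ≈ 40–50 against a generating M = 300. The
  bias is conservative — it inflates standard errors — and the calibration
  tests confirm type-I control is kept; power at small effects pays.
- One global ε and one pooled null SD; no per-sample or per-stratum
  variants.
- No haplotype-level aggregation of SNPs within a gene, no phasing, no
  multi-allelic sites, and no read-level simulation (counts only).

## Study sizes used by the reproduction script

`scripts/acceptance.py` uses 2000 sites for null calibration, 500 sites
for effect recovery, 20 pipeline replicates (2000 sites each) for cASE
calibration and recovery, and a 15,000-gene catalog over 20 seeds for
enrichment recovery — sizes at which the Monte-Carlo standard errors are
small relative to every band being checked.
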
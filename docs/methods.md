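# Methods

## Problem and data model

Allele-specific expression (ASE) is inferred from RNA-seq reads overlapping
heterozygous biallelic SNPs. For individual *i* at SNP *s* the data are the
read counts (REF, ALT, OTHER): bases matching the reference allele, the
alternative allele, or neither. The reference ratio REF/(REF+ALT) is the
central statistic; 0.5 means balanced expression. OTHER bases arise from
sequencing error or from genotyping error (a homozygote miscalled as a
heterozygote), and are excluded from the ratio but drive one of the
filters. Genotypes are assumed to come from a separate DNA assay of the
whole cohort, so Hardy–Weinberg equilibrium (HWE) and genotyping rate are
computed on the genotyping matrix, not on RNA-derived calls.

## Filter cascade

Stages run in a fixed order; each reports SNPs/reads in and out:

1. **Heterozygosity** — only SNPs with ≥1 heterozygous individual.
2. **Coverage** — records with fewer than `min_reads` (default 15,
   boundary inclusive) REF+ALT+OTHER reads are dropped, then SNPs with no
   surviving record. The threshold is applied per (SNP, individual)
   record; a pooled-per-SNP scope is available via
   `min_reads_scope="pooled"`, but pooled totals in real cohorts are
   orders of magnitude above 15, which would make the pooled rule vacuous.
3. **HWE** — exact conditional test (default): conditioning on the
   observed allele counts, every possible heterozygote count *h* has
   probability proportional to the multinomial weight × 2^h; the two-sided
   p sums configurations no more probable than the observed one. SNPs kept
   at p > `hwe_alpha` (default 10⁻⁵). A 1-df chi-square variant is
   available (`hwe_method="chisq"`).
4. **Genotyping rate** — fraction of non-missing calls across all
   genotyped individuals > 0.95.
5. **Mappability** — input annotation, kept at score ≥ 1.0 (uniquely
   mappable). Computing mappability tracks is upstream of this package.
6. **Genotyping-error test** — overall error *e* = ΣOTHER/Σreads over the
   full input table; per SNP, an exact two-sided binomial test
   (minimum-likelihood convention) of the pooled OTHER count against *e*.
   SNPs rejecting at p < 0.05 are excluded as likely genotyping errors or
   random monoallelic expression. With *e* = 0 any OTHER read gives p = 0
   (always excluded); that is a definition, not an error condition.

With every threshold at its degenerate extreme the cascade reduces to
"restrict to SNPs with a heterozygote", a property the tests pin.

## ASE engines

All engines test H₀: reference ratio = 0.5 per SNP and adjust with
Benjamini–Hochberg across SNPs (step-up, adjusted values capped at 1).
Two-sided p-values follow the minimum-likelihood convention (sum of
outcomes no more probable than observed, with a 1+10⁻⁷ relative tie
tolerance).

- **binomial** — exact binomial test on counts pooled over individuals.
- **nb_aggregate** — the conditional NB test below on the pooled counts
  with a fixed dispersion of 0.1.
- **nb_individual** (default) — the conditional NB test on per-individual
  counts with a per-SNP estimated dispersion.

**Conditional NB exact test.** Model the REF-group and ALT-group counts of
the n individuals as two independent NB samples with equal exposure and
common dispersion φ. The group sums are NB with size r = n/φ, and
conditional on the pooled total T the REF sum follows a distribution with
weights Γ(k+r)Γ(T−k+r) / (k!(T−k)!), free of the nuisance mean — a
beta-binomial(T; r, r) shape. The test enumerates k = 0..T. As φ → 0 the
conditional law converges to Binomial(T, ½), so the NB engine degrades
gracefully to the binomial test; the suite checks this limit and matches
the full distribution against a direct nbinom-product enumeration oracle.

**Dispersion estimation.** The estimator is built from the quantity the
conditional test actually needs: the within-SNP spread of the allelic
split. With fitted split proportion π̂, the binomial Pearson statistic
χ² = Σ(REF_i − π̂t_i)²/(π̂(1−π̂)t_i) has expectation (n−1) + ρΣ(t_i−1)
under an intraclass correlation ρ, giving the moment estimate
ρ̂ = (χ² − (n−1))/Σ(t_i−1), clipped to [0, 1). Two independent NB(μ, φ)
groups conditioned on their total split with ρ = φ/(2+φ), so the
dispersion handed to the test is φ̂ = 2ρ̂/(1−ρ̂), clamped to [0, 10]. A
naive exposure-weighted NB Pearson estimator would target ≈ φ/(2+φ)
instead of φ (conditioning on per-individual totals absorbs half the
marginal variance), which both biases recovery on iid-NB data and is the
wrong scale for the conditional test; the ρ-based route fixes both. A
single heterozygote cannot support estimation: the configurable fallback
(default 0.1, matching the aggregate engine's fixed value) is returned
with a flag. Monoallelic SNPs (π̂ ∈ {0,1}) carry no split-variance
information and get φ̂ = 0.

**Bias diagnostics.** Among FDR-significant SNPs: counts above/below 0.5
(ties at exactly 0.5 in neither group), a two-sided binomial skew test, a
read-weighted pooled ratio, and mean ratio per pooled-depth bin (defaults
[15,30), [30,60), [60,120), [120,∞)) — residual reference-genome bias
shows up as an above-0.5 excess concentrated at low depth.

## Cross-tissue sharing

Restricted to SNPs eligible in both tissues, significant SNPs (FDR < α by
default; a raw-p scale is exposed because both conventions appear in the
literature) are partitioned into both / A-only / B-only. The permutation
null redraws both sets (sizes fixed at the observed values) uniformly
without replacement from the eligible pool B = 10,000 times and records
the overlap; p = (1 + #{null ≥ observed})/(B + 1), which floors at
≈ 10⁻⁴ rather than reaching zero. Redrawing both sets keeps the test
symmetric in the tissues; a single-set mode is available. The null-overlap
mean equals the hypergeometric expectation size_a·size_b/N, which the
tests verify. Direction concordance is the fraction of SNPs whose ratio
falls on the same side of 0.5 in both tissues, compared between sharing
groups by Fisher's exact test. Differential ASE between tissues reuses the
group LRT with tissue as the label (unpaired cohorts).

## Differential ASE (beta-binomial LRT)

Per SNP, REF_i | t_i ~ BetaBinomial(t_i; μc, (1−μ)c) with c = (1−ρ)/ρ, so
μ is the group's true reference ratio and ρ the between-individual
overdispersion. The test compares group-specific μ against a common μ with
a shared ρ (1 df, chi-square reference). This engine is specified here as
the canonical differential-ASE model because it acts directly on the
allelic ratio and handles overdispersion; generic count-model packages can
be run in many unstated configurations, and a self-contained likelihood
keeps the test reproducible.

Numerics: the likelihood is evaluated via gammaln/betaln; for
ρ < 10⁻¹⁰ the binomial limit is used because the concentration
(1−ρ)/ρ then makes the gammaln differences cancel catastrophically (the
likelihood error can exceed thousands of log units at ρ ≈ 10⁻¹⁷). MLEs
come from L-BFGS-B on the natural scale with μ bounded to
[10⁻⁶, 1−10⁻⁶] and ρ to [0, 0.999]; an "abnormal" line-search exit on the
flat ρ → 0 boundary is re-checked with a Nelder-Mead polish and only
flagged non-converged if the polish moves the objective materially
(> 10⁻³). The LRT statistic is clamped at 0. A single record pins ρ = 0
(not estimable, flagged); `rho_fixed=0` yields the pure two-proportion
binomial LRT, checked against a closed-form oracle.

Pairing: the paired test drops individuals missing a timepoint and treats
timepoint as a fixed effect with shared ρ — both samples of an individual
condition on the same heterozygous genotype, so their ratios are directly
comparable; a per-individual random-effects model is out of scope. Groups
with a single heterozygote are tested but flagged `low_confidence`, since
a ratio of 1.00 in a singleton is indistinguishable from a genotyping
error. Note the shared-ρ null can absorb part of a single-outlier signal,
so such SNPs get decisive but far milder p-values than a naive binomial
contrast would suggest — a deliberate robustness property.

## Synthetic data generator

The generator emulates a two-cohort cardiac design: an unpaired cohort
with a binary clinical label (default 62 individuals, 34% positive) and a
paired baseline/post cohort (default 76), disjoint individuals. Per SNP:
MAF ~ Uniform(maf_range), genotypes multinomial in HWE proportions, calls
missing independently at 1 − genotyping_rate. Per heterozygote: depth ~
NB(depth_mean = 40, shape = 5) — RNA-seq site coverage is overdispersed,
hence NB rather than Poisson; OTHER ~ Binomial(depth, error_rate = 0.005),
drawn first so error_rate is a per-base probability on the same scale as
the pipeline's estimate *e*; the remainder splits REF/ALT by a
beta-binomial with mean clamp(true ratio + ref_bias, 10⁻⁶, 1−10⁻⁶) and
correlation overdispersion_rho = 0.01. ASE SNPs (ase_fraction, default
10%) get ratios uniform in ase_ratio_range = (0.65, 0.95), mirrored below
0.5 with probability ½ so the generator itself injects no net reference
bias; ref_bias is a separate additive knob (additive rather than
multiplicative because its effect is symmetric and interpretable around
0.5). A shared_ase_fraction of ASE SNPs carries the same ratio in both
tissues; the rest are active in one tissue (0.5 in the other). Injected
group/paired effects are named in a truth ledger; an effect placed on a
SNP without a heterozygote in an affected group is kept in the ledger
flagged untestable, with a warning. Identical (config, seed) reproduce
bit-identical tables.

What the generator does **not** emulate: read sequences and alignment
(counts are drawn directly; a separate synthetic SAM writer realises a
count table as uniquely mapped all-match reads for testing the counting
path), linkage between SNPs, gene structure, depth–GC covariation, and
allelic effects correlated across SNPs in a gene. Passing tests therefore
validate the statistical machinery under the stated model, not robustness
to alignment artefacts in real data — those are exactly what the filter
cascade and bias diagnostics are for.

## Calibration and problem sizes

The evaluation module fixes the study conditions used by the reproduction
script and the acceptance tests: the null configuration uses 1000 SNPs, 50
individuals (MAF 0.3–0.5, ~20 heterozygotes/SNP), depth mean 70 (median
pooled depth ≈ 1600), error 0, bias 0, and ρ = 0 — balanced binomial
splits, under which all four tests' raw p < 0.05 rates sit near 5%.
Exact tests on discrete support are slightly conservative: at pooled
depths of a few hundred the rejection rate drops toward 3% and the
p-value distribution's KS distance from uniform approaches 0.05 from
discreteness alone, which is why calibration is evaluated at pooled depths
in the thousands. Recovery uses μ = 0.7, ρ = 0.05, n = 200 heterozygotes
at depth ≈ 80 over 50 seeds; power uses a 0.5-vs-0.9 group effect, 30
heterozygotes/group, depth 100, ρ = 0.01, 50 replicates. Permutation
machinery is benchmarked at an eligible pool of 1000 with 100/100 sets at
B = 10⁴.

## Known limitations

- No read-level bias correction (e.g. allele-aware realignment); residual
  reference bias is diagnosed, not removed.
- No haplotype phasing or gene-level aggregation; SNPs are independent
  tests, and reads spanning two heterozygous SNPs count toward each
  independently.
- No covariate adjustment in the differential tests.
- The per-SNP moment dispersion does not share information across SNPs;
  with few heterozygotes it is noisy, and the fixed-dispersion aggregate
  engine is the conservative alternative.
- Multi-allelic SNPs and indels are out of scope; genotypes are 0/1/2
  biallelic calls.
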
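# Methods

## Statistical model

All inference starts from per-sample reference/alternate read counts at
candidate SNPs (pre-tabulated upstream from mpileup-style pileups; alignment
and mapping-bias correction are out of scope). Counts of reference reads k
out of n = ref + alt are modelled as beta-binomial with mean p and intra-class
dispersion ρ ∈ [0, 1):

    E[k] = n p,    Var[k] = n p (1 − p) (1 + (n − 1) ρ),

parameterized by Beta shapes a = p·m, b = (1 − p)·m with m = 1/ρ − 1. ρ = 0
degenerates to the binomial; at or below ρ = 1e-5 the code switches to exact
binomial formulas (the variance inflation there is under 0.1% at the coverages
involved, and the digamma differences that the general path uses lose
precision at huge shape parameters).

### Genotyping

For one individual, all samples are evaluated jointly (not merged): the
posterior over genotypes (RR, RA, AA) combines a Hardy–Weinberg prior
((1−f)², 2f(1−f), f²) from the population alternate-allele frequency f with
per-sample likelihoods, and a SNP is called heterozygous when
P(RA | data) ≥ 0.99. Two deliberate likelihood choices:

* The homozygote components are **binomial** at means 1−ε and ε, where ε is
  the base-calling error probability. Miscalled reads are a per-read
  technical error; a beta-binomial at mean ~1e-3 with a biological-scale
  dispersion would have Beta shape b = ε·m < 1, a pathologically heavy tail
  that makes a strongly imbalanced heterozygote look like a homozygote with
  errors.
* The heterozygote component is beta-binomial at mean 0.5 with dispersion
  max(ρ_s, 0.1). Flooring the dispersion lets the het model tolerate genuine
  allele-specific expression: without it, exactly the SNPs with strong ASE —
  the ones the downstream tests exist to find, induced ASE above all — fail
  the het call, and the survivors are selection-biased toward weak imbalance.

ε is fixed (default 1e-3, configurable), not estimated by EM.

### Per-SNP ASE fit

For each called het SNP in each sample with **more than 40** ref+alt reads
(strictly; 40 reads is filtered, flagged untested), the allelic imbalance is

    β = logit(p̂),   p̂ = argmax of the beta-binomial likelihood with ρ fixed
                        at the sample's estimate,

with the standard error from the observed Fisher information on the logit
scale (closed-form digamma/trigamma derivatives), z = β̂/se, p = 2Φ(−|z|),
and BH q-values within each sample (ASE is reported per sample and
condition). When either allele has zero reads, 0.5 is added to both counts
before the fit and the result flagged. The score in p is strictly monotone,
so the MLE is found by vectorized bisection (90 iterations, bracket width far
below float spacing); positive β means the reference allele is
over-expressed.

One consequence worth knowing: a single beta-binomial observation carries an
information floor — as coverage → ∞ the variance of β̂ tends to roughly
ρ/(p(1−p)), not zero (at ρ = 0.01 that is ≈ 0.2 on the logit scale). Wald
intervals are calibrated against this floor (the tests assert 93–97% coverage
at coverage 2000), and consistency holds on the allelic-proportion scale,
where the tests assert a median error below 0.05 at that depth.

### Dispersion estimation

ρ is estimated per sample by maximizing the beta-binomial likelihood of
putative het SNPs (both alleles ≥ 10% of reads, coverage over the filter)
with the mean fixed at 0.5, bounded search on [1e-6, 0.5] to 1e-8. Genuine
ASE SNPs in the candidate set masquerade as extra dispersion, so the fit is
iteratively trimmed: candidates whose two-sided tail probability under the
current balanced fit is BH-significant at 5% are dropped and the likelihood
re-maximized until the clean set stabilizes. On effect-free data the trim
removes almost nothing; with ~7% planted ASE it removes the inflation
entirely (verified in the test suite). Samples with fewer than 20 usable SNPs
fall back to a fit pooled across samples.

## The GxE tests

### Induced ASE

A SNP shows induced ASE when all four hold: treatment coverage > 40 reads;
treatment ASE q ≤ 0.10; control ref+alt coverage < 10·(D_C/D_T), where D are
the library depths — at equal depths a 40:10 ratio, i.e. control expression at
least fourfold below the minimum testable level; and depth-normalized
SNP-level log2 fold change log2(((n_T+1)/D_T)/((n_C+1)/D_C)) > log2(5). The
+1 pseudocount keeps the ratio finite at zero control coverage. Only the
depth *ratio* enters, so any proportional depth definition (per-million
factor, TPM denominator) gives identical calls, and calls are invariant to
rescaling both depths.

### ΔAST

Z_Δ = (β̂_T − β̂_C)/√(se_T² + se_C²), computed for every pair in which both
members independently pass the coverage filter. Each treatment sample is
compared to the control sample named in the manifest; the CO1-vs-CO2 pair of
the same individual and batch supplies the null. Raw Z_Δ are divided by the
null SD within a calibration stratum (cell type × batch; strata with fewer
than 30 null pairs use the pooled SD), p-values are 2Φ(−|z|), and
significance is thresholded on the empirical FDR
min(1, ECDF_null(t)/ECDF_obs(t)) with inclusive (≤) comparisons, evaluated at
the observed p-values, with each observation's q the minimum over thresholds
at or above its own p. This is the ECDF-ratio analogue of permutation FDR;
because it implicitly sets π₀ = 1 it is mildly conservative, and the
realized false-discovery proportion at the 10% cutoff averages just under
the nominal level in the calibration study the acceptance script runs.

### Configuration Bayes factors

For each pair, four mutually exclusive configurations are scored against the
no-ASE null through the asymptotic marginal likelihood of (β̂_T, β̂_C):

* *shared*: β_T = θ + δ_T, β_C = θ + δ_C with θ ~ N(0, φ²) and independent
  δ ~ N(0, ω²), giving a bivariate normal marginal with covariance
  [[se_T²+φ²+ω², φ²], [φ², se_C²+φ²+ω²]];
* *treatment-only* / *control-only*: the active condition gets the whole
  prior variance φ²+ω² (the single-condition Wakefield Bayes factor
  √(se²/(se²+ψ²))·exp(β̂²ψ²/(2se²(se²+ψ²)))), the inactive one contributes
  identically under configuration and null.

The prior grid is not fixed by theory; the default crosses total
variance φ²+ω² ∈ {0.01, 0.04, 0.16, 0.64, 2.56} with heterogeneity fractions
ω²/(φ²+ω²) ∈ {0, 0.25, 0.5}, equal weights, configurable. All BF arithmetic
is in log space with log-sum-exp averaging; raw BFs are materialized only at
call time, capped at exp(700). cASE is called when
BF_treatment − BF_shared > 30 (control symmetric); the threshold applies by
default to the difference of **raw** BFs, per the contrast's literal
definition, with a log10-difference mode behind a flag since Bayes factors
are conventionally reported on the log10 scale. When neither contrast
clears the threshold the pair is labelled *shared* if BF_shared > 1, else
*none*. Closed forms are verified against brute-force numeric integration to
1e-6 relative error in the test suite.

### EDGE

EDGE(s,t) = Pearson(Z_{s,CO1}, Z_{s,CO2}) / Pearson(Z_{s,t}, Z_{s,c}) over
per-SNP standardized effects Z = β̂/se, pooled across individuals within a
cell type. The two correlations use each pair's own tested-in-both SNP set by
default (a strict four-way-intersection mode exists). The index is reported
as undefined when the denominator is ≤ 0.05, rather than returning a huge or
negative ratio. With the control pair in the treatment slot the two
correlations are the same computation, so the index is exactly 1 in floating
point. Scale invariance and monotone growth with the planted cASE fraction
are asserted in the tests.

## Synthetic data generator

`simulate_experiment` emulates the design the analysis assumes: individuals
genotyped under HWE at SNPs with MAF ~ U(0.05, 0.5); per-SNP expression
factors lognormal(0, 0.5) and per-sample library factors lognormal(0, 0.2)
scaling a negative-binomial read depth (mean 120, size 5 by default); counts
beta-binomial with ρ = 0.02 and base-calling error ε = 1e-3 (deep-RNA-seq
regime values); for every individual × batch, one sample per treatment plus
two vehicle controls drawn independently from identical true parameters.
Planted effect classes at het SNPs — shared ASE, treatment-only cASE,
control-only cASE, and induced ASE (control coverage multiplied by 0.01) —
with logit-scale magnitudes sign·N(1.5, 0.25²): no empirical law for true
cASE effect sizes exists, so the default is a deliberately strong,
clearly-detectable regime rather than an estimate of any real dataset.
Homozygous rows are recorded with class "none" and zero true effects; only
RA genotypes carry effects. iASE SNPs keep their cis effect in the control
(beta_C_true = beta_T_true); the control is simply unexpressed.
Default planted fractions (5% shared, 1% + 1% cASE, 0.5% iASE) are several
times higher than the ~1% ASE-gene rate typical of real samples, to give the
tests signal at desk scale.

`simulate_paired_ase` is a focused companion for calibration studies: every
SNP heterozygous, coverage drawn as floor + negative-binomial excess
(default 200 + NB(mean 100, size 10), making a stated minimum depth literal),
one treatment and two control samples per SNP. The differential-test
calibration studies supply the generator's ρ to the fits directly; the full
pipeline estimates it.

What the generator does **not** emulate: mapping bias and alignment
artifacts, genotyping-panel errors, correlated effects among nearby SNPs or
within genes, sample contamination or swaps, and any realistic distribution
of effect sizes. Passing tests therefore demonstrate internal statistical
correctness and calibration under the stated model, not robustness to those
real-data pathologies.

## Numerical and interface choices

* Coverage filter "> 40 reads" is `min_coverage = 41` everywhere.
* MLE root-finding: 90 bisection steps on the strictly decreasing score;
  ties and degenerate inputs (zero counts) handled by the continuity
  correction; dispersion search tolerance 1e-8.
* Empirical-FDR thresholds are evaluated at observed p-values with inclusive
  comparisons — deterministic under ties.
* Identical seeds give byte-identical simulator output and pipeline result
  files; the count-table reader parses floats in round-trip precision so
  write→read→write is byte-stable.
* The pipeline validates the samples manifest (every treatment paired to a
  control of the same individual and batch; both CO1 and CO2 present in any
  batch with treatments) before any computation.
* Stages are pure frame-to-frame functions; re-running one stage from
  on-disk intermediates reproduces the full-run output exactly.

## Limitations

* Genotyping accuracy and het-call behavior are tuned for the deep-coverage
  regime; at very low coverage the 0.99 het-posterior threshold is
  conservative and the ASE filter removes most SNPs anyway.
* The ΔAST null calibration assumes the two vehicle controls are exchangeable
  with the treatment's control under the null; batch effects that break that
  exchangeability are not modelled.
* The Bayes-factor test inherits the arbitrariness of its prior grid; calls
  near the threshold move with the grid, which is why the grid is exposed as
  a parameter.
* Problem sizes in the tests and the acceptance study (thousands of SNPs,
  tens of replicates) are chosen for desk-scale runs; the statistical
  properties asserted are those that are stable at that scale.
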
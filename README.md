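# casekit

Conditional allele-specific expression (cASE) analysis for paired
treatment/control RNA-seq designs.

At a heterozygous SNP, unequal expression of the two alleles (allele-specific
expression, ASE) is the signature of a *cis*-regulatory variant, measured
within one individual and therefore free of *trans* and environmental
confounding between samples. When cells from the same individual are assayed
under a treatment and a matched vehicle control, a *change* in ASE between the
two conditions is a gene-by-environment (GxE) interaction read out in a single
person. `casekit` implements that analysis end to end:

* **Joint genotyping and ASE inference** — beta-binomial model of
  reference-allele counts. Genotypes (RR/RA/AA) are called per individual from
  all samples jointly under a Hardy–Weinberg prior; for every heterozygous SNP
  with more than 40 ref+alt reads, the allelic imbalance
  β = logit(reference fraction) is estimated by maximum likelihood with the
  sample's dispersion ρ, with Wald standard errors and Benjamini–Hochberg
  q-values within each sample.
* **Induced ASE (iASE)** — SNPs with significant ASE under treatment whose
  gene is essentially unexpressed in the control: treatment coverage > 40
  reads, ASE q ≤ 0.10, control coverage < 10·(D_C/D_T) reads (a 40:10 ratio at
  equal library depths D), and SNP-level fold change > 5.
* **ΔAST, a quantitative differential test** — per SNP and individual,
  Z_Δ = (β̂_T − β̂_C) / √(se_T² + se_C²). The design carries **two**
  vehicle-control sets (CO1, CO2) per batch; CO1-vs-CO2 pairs give an
  empirical null used twice: Z_Δ is rescaled by the null SD, and significance
  is thresholded on an empirical FDR, FDR(t) = ECDF_null(t)/ECDF_obs(t) with a
  monotone (q-value-style) envelope.
* **Configuration Bayes factors** — a qualitative "on/off" test scoring four
  mutually exclusive models per pair (no ASE / shared ASE with random effects
  / treatment-only / control-only) with Wakefield-style asymptotic Bayes
  factors averaged over a prior-variance grid; cASE is called from the
  contrast BF_treatment − BF_shared > 30 (and symmetrically for control).
* **EDGE index** — per cell type s and treatment t,
  EDGE(s,t) = Pearson(Z_{s,CO1}, Z_{s,CO2}) / Pearson(Z_{s,t}, Z_{s,c}),
  a genome-wide measure of how far a treatment displaces genetic effects;
  exactly 1 for the control conditions, larger for perturbing treatments.
* **Synthetic-data generator** — simulates the full paired design (HWE
  genotypes at MAF ≥ 5%, overdispersed coverage, beta-binomial counts with
  base-calling error, two vehicle controls per batch) with planted shared-ASE,
  cASE and iASE effects and a ground-truth table, so every stage is testable
  without external data.

## Worked example

The numbered scripts under `analysis/` run a complete simulated study
(3 individuals × 2 treatments × 2 batches, 4000 SNPs, mean coverage 120,
ρ = 0.02) and write all result tables under `results/`:

```sh
python analysis/01_simulate_experiment.py
python analysis/02_genotype_and_ase.py
python analysis/03_gxe_tests.py
python analysis/04_edge_index.py
```

Output of the run (abridged):

```
het calls: 4476 of 12000 individual x SNP pairs
ASE fits (coverage > 40): 32331
significant ASE at 10% FDR: 1538 fits (4.76% of tested)
iASE calls: 57 (planted iase among them: 57, ...)
effect pairs: 15112 treatment-control, 7541 control-control
differential-test cASE at 10% empirical FDR: 114 pairs, 94 planted cASE
Bayes-factor cASE calls (contrast > 30): 84, matching planted class: 80

cell_type     condition   r_null     r_tc     edge
simulated dexamethasone 0.451846 0.367825 1.228426
simulated      caffeine 0.451846 0.373385 1.210132

 frac_case_treatment  median_edge
                0.00     1.014194
                0.05     1.064742
                0.10     1.144854
                0.20     1.262224
                0.30     1.338357
```

Reading this: about a third of individual×SNP pairs are heterozygous and
testable; 4.8% of fitted SNP-samples show ASE at 10% FDR. All 57 induced-ASE
calls land on planted iASE SNPs. The differential test calls 114 pairs at its
10% empirical-FDR cutoff, 94 of them planted cASE, and the stricter
Bayes-factor contrast calls 84. The EDGE index sits above 1 for both
treatments (each plants 1% treatment-only cASE plus shared ASE), and the final
sweep shows the index rising monotonically as the planted cASE fraction grows.

The same pipeline is available as a CLI (`casekit simulate`, `casekit all`,
and per-stage subcommands; see `casekit --help`) for running on real
tab-delimited allele-count tables with a samples manifest.

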
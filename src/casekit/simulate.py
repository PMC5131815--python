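"""Synthetic allele-count experiments with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: individuals genotyped under Hardy-Weinberg equilibrium at SNPs with
MAF in [0.05, 0.5], overdispersed per-SNP read depth, beta-binomial allele
counts with base-calling error, and — crucially for the GxE tests — a paired
design in which every experimental batch carries one sample per treatment plus
TWO vehicle-control samples (CO1, CO2) drawn independently from identical true
parameters. The duplicated control is what lets the differential test
calibrate its null empirically.

Four effect classes can be planted at heterozygous SNPs, on the logit scale of
the reference-allele proportion:

* ``shared``          — the same allelic imbalance in treatment and control;
* ``treatment_only``  — imbalance under treatment, none in control (cASE);
* ``control_only``    — imbalance in control, none under treatment (cASE);
* ``iase``            — imbalance under treatment while the control's read
                        depth is depressed to near zero (induced ASE).

Everything is driven by one :class:`numpy.random.Generator`, so a seed fixes
the output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .betabinom import sample_betabinomial, shape_from_mean_dispersion, RHO_BINOMIAL
from .errors import ConfigError

CLASSES = ("none", "shared", "treatment_only", "control_only", "iase")
CONTROL_CONDITION = "control"

#: spread of the per-SNP lognormal expression factor and the per-sample
#: lognormal library-size factor (log-scale standard deviations)
SNP_EXPRESSION_SIGMA = 0.5
SAMPLE_DEPTH_SIGMA = 0.2


@dataclass
class SimConfig:
    """Configuration of one simulated experiment.

    Defaults describe the deep-sequencing regime of a paired treatment/control
    RNA-seq design: dispersion rho = 0.02 and base-calling error 1e-3 (typical
    QuASAR-fitted values), mean SNP coverage 120 reads, and a modest mixture of
    planted effects with logit-scale magnitude ~N(1.5, 0.25^2) and random sign.
    """

    n_individuals: int = 3
    n_snps: int = 1000
    treatments: tuple[str, ...] = ("T1",)
    n_batches: int = 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    mean_coverage: float = 120.0
    coverage_dispersion: float = 5.0  # negative-binomial size
    rho: float = 0.02
    epsilon: float = 0.001
    frac_shared_ase: float = 0.05
    frac_case_treatment: float = 0.01
    frac_case_control: float = 0.01
    frac_iase: float = 0.005
    effect_mean: float = 1.5
    effect_sd: float = 0.25
    iase_control_expression_factor: float = 0.01
    cell_type: str = "simulated"
    seed: int = 1

    def __post_init__(self):
        self.treatments = tuple(self.treatments)
        self.maf_range = tuple(self.maf_range)
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ConfigError("need at least one individual and one SNP")
        if self.n_batches < 1 or not self.treatments:
            raise ConfigError("need at least one batch and one treatment")
        fracs = (self.frac_shared_ase, self.frac_case_treatment,
                 self.frac_case_control, self.frac_iase)
        if any(f < 0 for f in fracs) or sum(fracs) > 1.0:
            raise ConfigError("effect fractions must be >= 0 and sum to <= 1")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within [0.05, 0.5]")
        if not (0.0 <= self.rho < 1.0):
            raise ConfigError("rho must lie in [0, 1)")
        if not (0.0 <= self.epsilon <= 0.05):
            raise ConfigError("epsilon must lie in [0, 0.05]")
        if not (0.0 < self.iase_control_expression_factor <= 0.1):
            raise ConfigError("iase_control_expression_factor must lie in (0, 0.1]")
        if self.mean_coverage <= 0 or self.coverage_dispersion <= 0:
            raise ConfigError("mean_coverage and coverage_dispersion must be > 0")
        if self.effect_sd < 0:
            raise ConfigError("effect_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["treatments"] = list(self.treatments)
        d["maf_range"] = list(self.maf_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


class SimResult(NamedTuple):
    counts: pd.DataFrame  # long count table, one row per sample x SNP
    truth: pd.DataFrame  # planted ground truth per SNP x individual x treatment
    manifest: pd.DataFrame  # per-sample metadata incl. pairing and depth
    depths: pd.DataFrame  # sample_id -> realized library depth (millions of reads)


def _negbin(rng, mean, size_param):
    """Negative-binomial draws parameterized by mean and size."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def _draw_counts(rng, n_tot, genotype, p_het, rho, epsilon):
    """Split total reads into (ref, alt, other) given genotypes.

    Reads are miscalled to a non-allele base with probability 2*eps/3; among
    the remaining reads, homozygotes show the off allele with probability eps
    and heterozygotes follow a beta-binomial around ``p_het``.
    """
    n_other = rng.binomial(n_tot, 2.0 * epsilon / 3.0)
    rem = n_tot - n_other
    n_ref = np.zeros_like(n_tot)
    het = genotype == 1
    if het.any():
        if rho < RHO_BINOMIAL:
            n_ref[het] = rng.binomial(rem[het], p_het[het])
        else:
            a, b = shape_from_mean_dispersion(p_het[het], rho)
            lat = rng.beta(a, b)
            n_ref[het] = rng.binomial(rem[het], lat)
    rr = genotype == 0
    if rr.any():
        n_ref[rr] = rem[rr] - rng.binomial(rem[rr], epsilon)
    aa = genotype == 2
    if aa.any():
        n_ref[aa] = rng.binomial(rem[aa], epsilon)
    return n_ref, rem - n_ref, n_other


def simulate_experiment(config: SimConfig) -> SimResult:
    """Generate one full paired experiment plus its truth table.

    For every individual x batch there is one sample per treatment condition
    and two vehicle controls (CO1, CO2) that share identical true parameters
    but independent counts. Identical seeds give byte-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_snps

    # --- SNP panel -------------------------------------------------------
    snp_id = np.array([f"snp{j:06d}" for j in range(J)])
    chrom = np.full(J, "chr1")
    pos = 1000 * (np.arange(J) + 1)
    bases = np.array(["A", "C", "G", "T"])
    ref = bases[np.arange(J) % 4]
    alt = bases[(np.arange(J) + 1) % 4]
    maf = np.round(rng.uniform(cfg.maf_range[0], cfg.maf_range[1], J), 6)
    expr_factor = rng.lognormal(0.0, SNP_EXPRESSION_SIGMA, J)

    # --- planted classes and effects -------------------------------------
    probs = np.array([
        1.0 - cfg.frac_shared_ase - cfg.frac_case_treatment
        - cfg.frac_case_control - cfg.frac_iase,
        cfg.frac_shared_ase, cfg.frac_case_treatment,
        cfg.frac_case_control, cfg.frac_iase,
    ])
    snp_class = rng.choice(len(CLASSES), size=J, p=probs)
    magnitude = rng.normal(cfg.effect_mean, cfg.effect_sd, J)
    sign = rng.choice([-1.0, 1.0], size=J)
    beta = sign * magnitude
    beta_T = np.where(np.isin(snp_class, [1, 2, 4]), beta, 0.0)
    beta_C = np.where(np.isin(snp_class, [1, 3, 4]), beta, 0.0)  # iase keeps its cis effect

    # --- genotypes under HWE ---------------------------------------------
    # genotype coded 0=RR, 1=RA, 2=AA; alt-allele frequency = maf
    geno = np.empty((cfg.n_individuals, J), dtype=np.int64)
    hwe = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf ** 2], axis=1)
    for i in range(cfg.n_individuals):
        u = rng.random(J)
        geno[i] = (u > hwe[:, 0]).astype(np.int64) + (u > hwe[:, 0] + hwe[:, 1])

    # --- samples ----------------------------------------------------------
    individuals = [f"ind{i + 1}" for i in range(cfg.n_individuals)]
    sample_rows = []
    for ind in individuals:
        for b in range(1, cfg.n_batches + 1):
            co1 = f"{ind}_b{b}_CO1"
            co2 = f"{ind}_b{b}_CO2"
            for t in cfg.treatments:
                sample_rows.append((f"{ind}_b{b}_{t}", ind, t, "treatment", b, co1))
            sample_rows.append((co1, ind, CONTROL_CONDITION, "CO1", b, ""))
            sample_rows.append((co2, ind, CONTROL_CONDITION, "CO2", b, ""))

    depth_factor = {row[0]: rng.lognormal(0.0, SAMPLE_DEPTH_SIGMA) for row in sample_rows}

    frames = []
    totals = {}
    geno_codes = {"0": "RR", "1": "RA", "2": "AA"}
    for sample_id, ind, condition, role, batch, ctrl in sample_rows:
        i = individuals.index(ind)
        g = geno[i]
        mu = cfg.mean_coverage * expr_factor * depth_factor[sample_id]
        if role != "treatment":
            mu = np.where(snp_class == 4, mu * cfg.iase_control_expression_factor, mu)
        n_tot = _negbin(rng, mu, cfg.coverage_dispersion)
        b_cond = beta_T if role == "treatment" else beta_C
        p_het = 1.0 / (1.0 + np.exp(-b_cond))
        n_ref, n_alt, n_other = _draw_counts(rng, n_tot, g, p_het, cfg.rho, cfg.epsilon)
        totals[sample_id] = int(n_tot.sum())
        frames.append(pd.DataFrame({
            "sample_id": sample_id, "individual_id": ind, "cell_type": cfg.cell_type,
            "condition": condition, "batch": batch, "chrom": chrom, "pos": pos,
            "snp_id": snp_id, "ref": ref, "alt": alt, "maf": maf,
            "ref_count": n_ref, "alt_count": n_alt, "other_count": n_other,
        }))
    counts = pd.concat(frames, ignore_index=True)

    depths = pd.DataFrame({
        "sample_id": [r[0] for r in sample_rows],
        "depth": [totals[r[0]] / 1e6 for r in sample_rows],
    })
    manifest = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "individual_id", "condition", "role", "batch",
                 "control_sample_id"],
    )
    manifest.insert(2, "cell_type", cfg.cell_type)
    manifest = manifest.merge(depths, on="sample_id")

    # --- truth table ------------------------------------------------------
    truth_frames = []
    for i, ind in enumerate(individuals):
        het = geno[i] == 1
        for t in cfg.treatments:
            truth_frames.append(pd.DataFrame({
                "snp_id": snp_id, "individual_id": ind, "condition": t,
                "class": np.where(het, np.array(CLASSES)[snp_class], "none"),
                "beta_T_true": np.where(het, beta_T, 0.0),
                "beta_C_true": np.where(het, beta_C, 0.0),
                "genotype": [geno_codes[str(gg)] for gg in geno[i]],
            }))
    truth = pd.concat(truth_frames, ignore_index=True)
    return SimResult(counts, truth, manifest, depths)


class PairSim(NamedTuple):
    """Count-level simulation of matched treatment / CO1 / CO2 triples."""

    n_ref: dict  # keys "T", "CO1", "CO2" -> ref-count arrays
    n_alt: dict
    truth: pd.DataFrame  # snp_id, class, beta_T_true, beta_C_true


def simulate_paired_ase(n_pairs: int, rng: np.random.Generator, *,
                        frac_case_treatment: float = 0.10,
                        frac_shared_ase: float = 0.20,
                        frac_case_control: float = 0.0,
                        coverage_floor: int = 200,
                        extra_coverage_mean: float = 100.0,
                        coverage_dispersion: float = 10.0,
                        rho: float = 0.02,
                        effect_mean: float = 1.5,
                        effect_sd: float = 0.25) -> PairSim:
    """Heterozygous SNP-pair triples for differential-test calibration studies.

    A focused companion to :func:`simulate_experiment`: every SNP is
    heterozygous, coverage is ``coverage_floor`` plus an overdispersed
    negative-binomial excess (so a stated minimum depth is literal), and each
    SNP yields one treatment sample and two independent vehicle-control
    samples with identical true parameters.
    """
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    fr = (frac_case_treatment, frac_shared_ase, frac_case_control)
    if any(f < 0 for f in fr) or sum(fr) > 1.0:
        raise ConfigError("fractions must be >= 0 and sum to <= 1")
    classes = rng.choice(
        [2, 1, 3, 0], size=n_pairs,
        p=[frac_case_treatment, frac_shared_ase, frac_case_control,
           1.0 - sum(fr)])
    beta = rng.choice([-1.0, 1.0], n_pairs) * rng.normal(effect_mean, effect_sd, n_pairs)
    beta_T = np.where(np.isin(classes, [1, 2]), beta, 0.0)
    beta_C = np.where(np.isin(classes, [1, 3]), beta, 0.0)
    n_ref, n_alt = {}, {}
    for key, b in (("T", beta_T), ("CO1", beta_C), ("CO2", beta_C)):
        n_tot = coverage_floor + _negbin(
            rng, np.full(n_pairs, extra_coverage_mean), coverage_dispersion)
        p = 1.0 / (1.0 + np.exp(-b))
        n_ref[key] = sample_betabinomial(n_tot, p, rho, rng)
        n_alt[key] = n_tot - n_ref[key]
    truth = pd.DataFrame({
        "snp_id": [f"snp{j:06d}" for j in range(n_pairs)],
        "class": np.array(CLASSES)[classes],
        "beta_T_true": beta_T, "beta_C_true": beta_C,
    })
    return PairSim(n_ref, n_alt, truth)
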
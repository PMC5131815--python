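"""Synthetic-experiment generator: structure, determinism, planted truth."""

import numpy as np
import pandas as pd
import pytest

from casekit.errors import ConfigError
from casekit.simulate import (SimConfig, simulate_experiment, simulate_paired_ase)


def test_null_config_has_no_planted_effects():
    cfg = SimConfig(n_snps=800, n_individuals=2, seed=5, frac_shared_ase=0,
                    frac_case_treatment=0, frac_case_control=0, frac_iase=0)
    sim = simulate_experiment(cfg)
    assert (sim.truth["class"] == "none").all()
    assert (sim.truth["beta_T_true"] == 0).all()
    # pooled reference fraction at het SNPs is balanced
    het = sim.truth[sim.truth.genotype == "RA"][["snp_id", "individual_id"]]
    cts = sim.counts.merge(het.drop_duplicates(), on=["snp_id", "individual_id"])
    n_ref, n = cts["ref_count"].sum(), (cts["ref_count"] + cts["alt_count"]).sum()
    # overdispersed draws: SE of the pooled fraction carries the
    # beta-binomial variance factor (1 + (n_i - 1) rho) at n_i ~ coverage
    se = np.sqrt(0.25 * (1 + cfg.mean_coverage * cfg.rho) / n)
    assert abs(n_ref / n - 0.5) < 3 * se


def test_same_seed_is_byte_identical(tmp_path):
    cfg = SimConfig(n_snps=120, n_individuals=2, seed=9)
    a, b = simulate_experiment(cfg), simulate_experiment(cfg)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    a.counts.to_csv(p1, sep="\t", index=False)
    b.counts.to_csv(p2, sep="\t", index=False)
    assert p1.read_bytes() == p2.read_bytes()


def test_planted_class_fraction_recovered():
    """10% treatment-only cASE among het SNPs, within the binomial 99% CI."""
    cfg = SimConfig(n_snps=5000, n_individuals=1, seed=3, frac_shared_ase=0,
                    frac_case_treatment=0.10, frac_case_control=0, frac_iase=0)
    sim = simulate_experiment(cfg)
    het = sim.truth[sim.truth.genotype == "RA"]
    frac = (het["class"] == "treatment_only").mean()
    half = 2.576 * np.sqrt(0.1 * 0.9 / len(het))
    assert abs(frac - 0.10) < half


def test_truth_invariants():
    cfg = SimConfig(n_snps=2000, n_individuals=2, seed=7, frac_shared_ase=0.1,
                    frac_case_treatment=0.1, frac_case_control=0.1, frac_iase=0.05)
    truth = simulate_experiment(cfg).truth
    t_only = truth[truth["class"] == "treatment_only"]
    c_only = truth[truth["class"] == "control_only"]
    none = truth[truth["class"] == "none"]
    assert (t_only["beta_C_true"] == 0).all() and (t_only["beta_T_true"] != 0).all()
    assert (c_only["beta_T_true"] == 0).all() and (c_only["beta_C_true"] != 0).all()
    assert (none[["beta_T_true", "beta_C_true"]] == 0).all().all()
    hom = truth[truth.genotype != "RA"]
    assert (hom[["beta_T_true", "beta_C_true"]] == 0).all().all()


def test_homozygote_allele_fractions_near_error_rate():
    cfg = SimConfig(n_snps=1500, n_individuals=2, mean_coverage=300, seed=13,
                    frac_shared_ase=0, frac_case_treatment=0, frac_case_control=0,
                    frac_iase=0)
    sim = simulate_experiment(cfg)
    gt = sim.truth.drop_duplicates(["snp_id", "individual_id"])
    cts = sim.counts.merge(gt[["snp_id", "individual_id", "genotype"]],
                           on=["snp_id", "individual_id"])
    for g, expected in (("RR", 1.0 - cfg.epsilon), ("AA", cfg.epsilon)):
        sub = cts[cts.genotype == g]
        frac = sub["ref_count"].sum() / (sub["ref_count"] + sub["alt_count"]).sum()
        assert abs(frac - expected) < 5e-4
    # conservation: ref + alt + other is the draw total, all non-negative
    assert (cts[["ref_count", "alt_count", "other_count"]] >= 0).all().all()


def test_control_duplicates_share_parameters(small_experiment):
    _, sim = small_experiment
    man = sim.manifest
    co = man[man.role.isin(["CO1", "CO2"])]
    assert (co.groupby(["individual_id", "batch"]).size() == 2).all()
    tr = man[man.role == "treatment"]
    assert set(tr.control_sample_id) <= set(man.sample_id)


@pytest.mark.parametrize("kwargs", [
    {"n_snps": 0},
    {"n_individuals": 0},
    {"frac_shared_ase": 0.7, "frac_case_treatment": 0.4},
    {"maf_range": (0.01, 0.5)},
    {"rho": 1.0},
    {"epsilon": 0.2},
    {"iase_control_expression_factor": 0.5},
])
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigError):
        SimConfig(**kwargs)


def test_config_yaml_roundtrip(tmp_path):
    cfg = SimConfig(n_snps=50, treatments=("dex", "caffeine"), seed=2)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert SimConfig.from_yaml(path) == cfg
    path.write_text("n_snps: 10\nbogus_key: 1\n")
    with pytest.raises(ConfigError):
        SimConfig.from_yaml(path)


def test_paired_generator_respects_coverage_floor(rng):
    sim = simulate_paired_ase(500, rng, coverage_floor=200)
    for key in ("T", "CO1", "CO2"):
        assert ((sim.n_ref[key] + sim.n_alt[key]) >= 200).all()
    frac = (sim.truth["class"] == "treatment_only").mean()
    assert abs(frac - 0.10) < 2.576 * np.sqrt(0.1 * 0.9 / 500)
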
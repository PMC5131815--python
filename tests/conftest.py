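import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A seeded 300-SNP paired experiment shared by pipeline-level tests."""
    from casekit.simulate import SimConfig, simulate_experiment

    cfg = SimConfig(n_snps=300, n_individuals=2, mean_coverage=150, seed=42)
    return cfg, simulate_experiment(cfg)


def fit_triples(pair_sim, rho):
    """Fit ASE on the T/CO1/CO2 count triples of a PairSim; returns a dict of
    (beta, se) tuples — the shared scaffolding of the differential-test tests."""
    from casekit.ase import ase_mle

    out = {}
    for key in ("T", "CO1", "CO2"):
        beta, se, _ = ase_mle(pair_sim.n_ref[key], pair_sim.n_alt[key], rho)
        out[key] = (beta, se)
    return out


def pair_frames(pair_sim, fits):
    """Observed (T vs CO1) and null (CO1 vs CO2) effect-pair tables."""
    base = pd.DataFrame({
        "snp_id": pair_sim.truth["snp_id"], "individual_id": "ind1",
        "condition": "treatment", "stratum": "s",
    })
    obs = base.assign(beta_T=fits["T"][0], se_T=fits["T"][1],
                      beta_C=fits["CO1"][0], se_C=fits["CO1"][1])
    nul = base.assign(condition="control",
                      beta_T=fits["CO1"][0], se_T=fits["CO1"][1],
                      beta_C=fits["CO2"][0], se_C=fits["CO2"][1])
    return obs, nul
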
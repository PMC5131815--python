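"""Differential test: Z-score, control-control calibration, empirical FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from casekit.delta_ast import (calibrate_and_pvalues, delta_ast, empirical_fdr,
                               null_sd_by_stratum, z_delta)
from casekit.errors import CalibrationError, PairingError
from casekit.mesh import EffectPair


def pair(bT, bC, seT=0.5, seC=0.5):
    return EffectPair("rs1", "ind1", "t", bT, seT, bC, seC)


class TestZDelta:
    @pytest.mark.parametrize("bT,bC,seT,seC,expected", [
        (0.5, 0.5, 0.3, 0.4, 0.0),
        (1.0, 0.0, 0.5, 0.5, 1.0 / np.sqrt(0.5)),
        (-0.3, 0.3, 0.3, 0.4, -1.2),
    ])
    def test_closed_form(self, bT, bC, seT, seC, expected):
        assert z_delta(pair(bT, bC, seT, seC)) == pytest.approx(expected)

    def test_missing_pair_raises(self):
        with pytest.raises(PairingError):
            z_delta(None)

    def test_antisymmetric_in_conditions(self):
        p = pair(1.2, -0.4, 0.3, 0.6)
        assert z_delta(p) == pytest.approx(-z_delta(p.swapped()))


class TestCalibration:
    def test_normalization_and_pvalue(self, rng):
        null = rng.normal(0, 2.0, 2000)
        z, p = calibrate_and_pvalues([2.0, 0.0], ["s", "s"], null, ["s"] * null.size)
        sd = np.std(null, ddof=1)
        assert z[0] == pytest.approx(2.0 / sd)
        assert p[0] == pytest.approx(2 * stats.norm.sf(2.0 / sd))
        assert p[1] == pytest.approx(1.0)

    def test_standard_normal_null_is_calibrated(self, rng):
        null = rng.normal(0, 1, 10_000)
        sds = null_sd_by_stratum(null, ["s"] * null.size)
        assert 0.97 <= sds["s"] <= 1.03
        _, p = calibrate_and_pvalues(null, ["s"] * null.size, null,
                                     ["s"] * null.size)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_small_stratum_falls_back_to_pooled(self, rng):
        null = rng.normal(0, 2.0, 100)
        strata = ["big"] * 95 + ["tiny"] * 5
        sds = null_sd_by_stratum(null, strata)
        assert "tiny" not in sds and "big" in sds
        z_big, _ = calibrate_and_pvalues([1.0], ["big"], null, strata)
        z_new, _ = calibrate_and_pvalues([1.0], ["unseen"], null, strata)
        assert z_new[0] == pytest.approx(1.0 / sds["__pooled__"])

    def test_too_few_null_pairs_raises(self):
        with pytest.raises(CalibrationError):
            null_sd_by_stratum([0.1] * 10, ["s"] * 10)

    def test_degenerate_null_raises(self):
        with pytest.raises(CalibrationError):
            null_sd_by_stratum([0.0] * 40, ["s"] * 40)


class TestEmpiricalFDR:
    def test_hand_computed_ecdf_ratio(self):
        q = empirical_fdr([0.02, 0.04, 0.5, 0.9], [0.04, 0.3, 0.6, 0.9])
        # FDR(0.04) = (1/4) / (2/4) = 0.5; envelope: [0, 0.5, 2/3, 1]
        np.testing.assert_allclose(q, [0.0, 0.5, 2 / 3, 1.0])

    def test_identical_distributions_give_unit_q(self):
        p = [0.1, 0.2, 0.3, 0.7]
        np.testing.assert_allclose(empirical_fdr(p, p), 1.0)

    def test_null_mass_far_above_observations(self):
        obs = np.linspace(0.001, 0.01, 10)
        np.testing.assert_allclose(empirical_fdr(obs, [0.5, 0.6, 0.9]), 0.0)

    def test_q_monotone_in_p(self, rng):
        obs = rng.uniform(0, 1, 500)
        null = rng.uniform(0, 1, 400)
        q = empirical_fdr(obs, null)
        order = np.argsort(obs)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()

    def test_empty_null_raises(self):
        with pytest.raises(CalibrationError):
            empirical_fdr([0.1], [])


class TestEndToEnd:
    def test_table_level_run(self, rng):
        n = 200
        base = pd.DataFrame({
            "snp_id": [f"rs{i}" for i in range(n)], "individual_id": "i",
            "condition": "t", "stratum": "s",
            "beta_T": rng.normal(0, 1, n), "se_T": 0.3,
            "beta_C": rng.normal(0, 1, n), "se_C": 0.3})
        res = delta_ast(base, base.assign(condition="control"))
        obs = res[~res.is_null_pair]
        assert len(obs) == n
        assert ((obs.p_delta >= 0) & (obs.p_delta <= 1)).all()
        assert obs.q_empirical.notna().all()
        assert res[res.is_null_pair].q_empirical.isna().all()

    def test_missing_columns_raise(self):
        with pytest.raises(PairingError):
            delta_ast(pd.DataFrame({"snp_id": []}), pd.DataFrame({"snp_id": []}))
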
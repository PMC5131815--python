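"""Configuration Bayes factors: closed forms vs numeric integration, calls."""

import numpy as np
import pytest
from scipy import integrate, stats

from casekit.errors import ParameterError
from casekit.mesh import (ConfigurationBF, EffectPair, PriorGrid, call_case,
                          configuration_bfs, configuration_log_bfs_arrays,
                          default_prior_grid, log_wakefield_abf, wakefield_abf)


def integrate_gaussian(f, center, width):
    val, _ = integrate.quad(f, center - 12 * width, center + 12 * width,
                            epsabs=1e-300, epsrel=1e-12, limit=400)
    return val


def oracle_bfs(bT, seT, bC, seC, grid):
    """Brute-force numeric integration of each configuration's marginal."""
    num_s = num_t = num_c = 0.0
    den = stats.norm.pdf(bT, 0, seT) * stats.norm.pdf(bC, 0, seC)
    for phi2, om2, w in zip(grid.phi2, grid.omega2, grid.weights):
        psi2 = phi2 + om2
        if phi2 > 0:
            vT, vC = seT ** 2 + om2, seC ** 2 + om2
            prec = 1 / vT + 1 / vC + 1 / phi2
            center = (bT / vT + bC / vC) / prec
            val = integrate_gaussian(
                lambda th: (stats.norm.pdf(bT, th, np.sqrt(vT))
                            * stats.norm.pdf(bC, th, np.sqrt(vC))
                            * stats.norm.pdf(th, 0, np.sqrt(phi2))),
                center, 1 / np.sqrt(prec))
        else:  # pure heterogeneity: the two conditions decouple
            val = (stats.norm.pdf(bT, 0, np.sqrt(seT ** 2 + om2))
                   * stats.norm.pdf(bC, 0, np.sqrt(seC ** 2 + om2)))
        num_s += w * val
        for bh, se, which in ((bT, seT, "t"), (bC, seC, "c")):
            prec = 1 / se ** 2 + 1 / psi2
            center = (bh / se ** 2) / prec
            v = integrate_gaussian(
                lambda b: stats.norm.pdf(bh, b, se) * stats.norm.pdf(b, 0, np.sqrt(psi2)),
                center, 1 / np.sqrt(prec))
            if which == "t":
                num_t += w * v * stats.norm.pdf(bC, 0, seC)
            else:
                num_c += w * v * stats.norm.pdf(bT, 0, seT)
    return num_s / den, num_t / den, num_c / den


class TestWakefield:
    def test_null_estimate_favors_null(self):
        assert wakefield_abf(0.0, 1.0, 1.0) == pytest.approx(np.sqrt(0.5))

    def test_large_effect_closed_form(self):
        assert wakefield_abf(3.0, 1.0, 1.0) == pytest.approx(
            np.sqrt(0.5) * np.exp(2.25), rel=1e-12)

    def test_matches_numeric_integration(self):
        bh, se, psi2 = 1.7, 0.35, 0.6
        num = integrate_gaussian(
            lambda b: stats.norm.pdf(bh, b, se) * stats.norm.pdf(b, 0, np.sqrt(psi2)),
            bh, np.sqrt(psi2))
        assert wakefield_abf(bh, se, psi2) == pytest.approx(
            num / stats.norm.pdf(bh, 0, se), rel=1e-9)

    def test_vanishing_prior_gives_unit_bf(self):
        assert wakefield_abf(2.0, 0.5, 1e-12) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("se,psi2", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_invalid_parameters(self, se, psi2):
        with pytest.raises(ParameterError):
            log_wakefield_abf(1.0, se, psi2)


class TestConfigurationBFs:
    def test_null_pair_has_all_bfs_below_one(self):
        bf = configuration_bfs(EffectPair("s", "i", "t", 0.0, 0.2, 0.0, 0.2))
        assert bf.bf_shared < 1 and bf.bf_treatment < 1 and bf.bf_control < 1
        assert call_case(bf) == "none"

    def test_treatment_only_effect_maximizes_treatment_bf(self):
        bf = configuration_bfs(EffectPair("s", "i", "t", 2.0, 0.2, 0.0, 0.2))
        assert bf.log_bf_treatment > max(bf.log_bf_shared, bf.log_bf_control)

    def test_shared_effect_maximizes_shared_bf(self):
        bf = configuration_bfs(EffectPair("s", "i", "t", 2.0, 0.2, 2.0, 0.2))
        assert bf.log_bf_shared > max(bf.log_bf_treatment, bf.log_bf_control)

    def test_matches_integration_oracle(self):
        grid = default_prior_grid()
        rng = np.random.default_rng(0)
        for _ in range(8):
            bT, bC = rng.normal(0, 1.5, 2)
            seT, seC = rng.uniform(0.08, 0.4, 2)
            bf = configuration_bfs(EffectPair("s", "i", "t", bT, seT, bC, seC), grid)
            os_, ot, oc = oracle_bfs(bT, seT, bC, seC, grid)
            assert bf.bf_shared == pytest.approx(os_, rel=1e-6)
            assert bf.bf_treatment == pytest.approx(ot, rel=1e-6)
            assert bf.bf_control == pytest.approx(oc, rel=1e-6)

    def test_swapping_conditions_swaps_bfs_exactly(self):
        pair = EffectPair("s", "i", "t", 1.3, 0.25, -0.4, 0.15)
        a, b = configuration_bfs(pair), configuration_bfs(pair.swapped())
        assert a.log_bf_treatment == b.log_bf_control
        assert a.log_bf_control == b.log_bf_treatment
        assert a.log_bf_shared == pytest.approx(b.log_bf_shared, rel=1e-12)

    def test_vectorized_path_matches_scalar(self):
        rng = np.random.default_rng(4)
        bT, bC = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        seT, seC = rng.uniform(0.1, 0.5, 10), rng.uniform(0.1, 0.5, 10)
        lbs, lbt, lbc = configuration_log_bfs_arrays(bT, seT, bC, seC)
        for i in range(10):
            bf = configuration_bfs(EffectPair("s", "i", "t", bT[i], seT[i],
                                              bC[i], seC[i]))
            assert lbs[i] == pytest.approx(bf.log_bf_shared, rel=1e-12)
            assert lbt[i] == pytest.approx(bf.log_bf_treatment, rel=1e-12)
            assert lbc[i] == pytest.approx(bf.log_bf_control, rel=1e-12)


class TestCallCase:
    def bf(self, shared, treat, ctrl):
        return ConfigurationBF("s", "i", "t", np.log(shared), np.log(treat),
                               np.log(ctrl))

    def test_contrast_above_threshold_is_case(self):
        assert call_case(self.bf(1.0, 32.0, 1.0)) == "treatment_cASE"  # stat 31

    def test_contrast_below_threshold_is_not_case(self):
        assert call_case(self.bf(1.2, 31.1, 1.0)) == "shared"  # stat 29.9
        # bf_shared must strictly exceed 1 for a shared call
        assert call_case(self.bf(1.0, 30.9, 1.0)) == "none"

    def test_all_bfs_at_most_one_is_none(self):
        assert call_case(self.bf(0.9, 1.0, 0.8)) == "none"

    def test_control_side_symmetric(self):
        assert call_case(self.bf(1.0, 1.0, 40.0)) == "control_cASE"

    def test_log10_scale_mode(self):
        bf = self.bf(1.0, 10.0 ** 2.4, 1.0)
        assert call_case(bf, threshold=2.0, scale="log10") == "treatment_cASE"

    def test_invalid_prior_grid(self):
        with pytest.raises(ParameterError):
            PriorGrid((0.0,), (0.0,), (1.0,))
        with pytest.raises(ParameterError):
            PriorGrid((0.1, 0.2), (0.0, 0.0), (0.6, 0.6))
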
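"""ASE inference: dispersion fit, genotyping, per-SNP MLE, BH q-values."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from casekit.ase import (SampleModel, ase_mle, bh_fdr, fit_ase, fit_dispersion,
                         genotype_posteriors)
from casekit.betabinom import sample_betabinomial
from casekit.errors import EstimationError, ParameterError

MODEL = SampleModel("s1", rho=1e-6, epsilon=1e-3, depth=1.0)


class TestFitDispersion:
    def test_binomial_counts_give_near_zero_rho(self, rng):
        n = np.full(500, 200)
        k = rng.binomial(n, 0.5)
        assert fit_dispersion(k, n - k) < 0.005

    def test_recovers_true_dispersion(self, rng):
        n = np.full(2000, 200)
        k = sample_betabinomial(n, 0.5, 0.05, rng)
        assert 0.04 <= fit_dispersion(k, n - k) <= 0.06

    def test_too_few_snps_raises(self):
        with pytest.raises(EstimationError, match="pool"):
            fit_dispersion([50] * 5, [50] * 5)


class TestGenotyping:
    def test_no_reads_returns_hwe_prior(self):
        g = genotype_posteriors([0], [0], 0.3, [SampleModel("s", 0.01, 1e-3, 1.0)])
        np.testing.assert_allclose([g.p_RR, g.p_RA, g.p_AA], [0.49, 0.42, 0.09],
                                   atol=1e-12)

    def test_balanced_counts_call_het(self):
        g = genotype_posteriors([25], [25], 0.3, [SampleModel("s", 0.01, 1e-3, 1.0)])
        assert g.p_RA > 0.999 and g.is_het

    def test_monoallelic_counts_call_hom(self):
        g = genotype_posteriors([50], [0], 0.3, [SampleModel("s", 0.01, 1e-3, 1.0)])
        assert g.p_RR > 0.999

    def test_posterior_sums_to_one_across_samples(self):
        models = [SampleModel(f"s{i}", 0.02, 1e-3, 1.0) for i in range(3)]
        g = genotype_posteriors([30, 28, 40], [25, 30, 38], 0.2, models)
        assert abs(g.p_RR + g.p_RA + g.p_AA - 1.0) < 1e-9

    def test_missing_maf_is_an_error(self):
        with pytest.raises(ParameterError):
            genotype_posteriors([10], [10], float("nan"),
                                [SampleModel("s", 0.01, 1e-3, 1.0)])

    def test_imbalanced_het_with_ase_still_called(self):
        """Strong allelic imbalance must not flip the call to homozygous."""
        g = genotype_posteriors([40], [160], 0.3, [SampleModel("s", 0.02, 1e-3, 1.0)])
        assert g.is_het


class TestFitAse:
    def test_symmetric_counts_give_zero_beta(self):
        f = fit_ase(30, 30, MODEL)
        assert f.beta == pytest.approx(0.0, abs=1e-9)
        assert f.p_value == pytest.approx(1.0)

    def test_binomial_limit_closed_form(self):
        """At rho ~ 0 the MLE and SE match the binomial closed forms."""
        f = fit_ase(45, 15, MODEL)
        assert f.beta == pytest.approx(np.log(3), abs=1e-6)
        assert f.se == pytest.approx(np.sqrt(1 / 45 + 1 / 15), abs=1e-6)

    def test_coverage_filter_is_strict(self):
        assert fit_ase(25, 15, MODEL) is None  # 40 reads: not tested
        assert fit_ase(26, 15, MODEL) is not None  # 41 reads: tested

    def test_zero_count_continuity_correction(self):
        f = fit_ase(60, 0, MODEL)
        assert f.corrected and np.isfinite(f.beta) and f.se > 0

    def test_small_dispersion_close_to_binomial(self):
        """The general digamma path just above the binomial branch agrees
        with the closed forms to the scale of the variance inflation."""
        beta, se, _ = ase_mle(np.array([45.0]), np.array([15.0]), 1e-4)
        assert beta[0] == pytest.approx(np.log(3), abs=1e-3)
        assert se[0] == pytest.approx(np.sqrt(1 / 45 + 1 / 15), rel=5e-3)

    def test_dispersion_inflates_se(self):
        b0, s0, _ = ase_mle(np.array([300.0]), np.array([100.0]), 1e-6)
        b1, s1, _ = ase_mle(np.array([300.0]), np.array([100.0]), 0.05)
        assert s1[0] > 2 * s0[0]
        # the overdispersed MLE shrinks slightly toward balance
        assert b1[0] == pytest.approx(b0[0], abs=0.1)

    def test_null_pvalues_calibrated(self, rng):
        """Type-I error of the Wald test at correctly specified dispersion."""
        n = 100 + rng.poisson(60, 5000)
        k = sample_betabinomial(n, 0.5, 0.01, rng)
        beta, se, _ = ase_mle(k, n - k, 0.01)
        p = 2 * stats.norm.sf(np.abs(beta / se))
        for alpha in (0.01, 0.05):
            half = 2.576 * np.sqrt(alpha * (1 - alpha) / p.size)
            assert abs((p < alpha).mean() - alpha) < half


class TestBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0], [1.0]),
        ([0.005, 0.5], [0.01, 0.5]),
    ])
    def test_step_up_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_qvalues_in_range_and_order_preserving(self, p):
        q = bh_fdr(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
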
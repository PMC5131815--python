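"""Joint genotyping and per-SNP beta-binomial ASE inference.

This is a QuASAR-style model: across all samples of one individual the three
genotypes (RR, RA, AA) are scored with a Hardy-Weinberg prior derived from the
population minor-allele frequency and beta-binomial read likelihoods whose
means are 1-eps, 0.5 and eps respectively (eps = base-calling error). For each
heterozygous SNP in each sample, the allelic imbalance is then summarized by

    beta = logit(p),  p = MLE of the reference-allele proportion among
                          ref + alt reads under a beta-binomial with the
                          sample's dispersion rho held fixed,

with a standard error from the observed Fisher information on the logit scale
and a two-sided Wald p-value. Benjamini-Hochberg q-values are computed within
each sample, matching a per-sample-and-condition ASE readout.

Only SNPs with ref + alt coverage strictly greater than 40 reads are tested;
lower-coverage het SNPs are flagged as untested rather than failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .betabinom import RHO_BINOMIAL, betabinom_logpmf, shape_from_mean_dispersion
from .errors import EstimationError, ParameterError

#: coverage filter: a SNP is tested only if n_ref + n_alt > 40 reads
MIN_COVERAGE = 41

#: posterior probability of RA required to call a SNP heterozygous
HET_POSTERIOR = 0.99

RHO_MIN, RHO_MAX = 1e-6, 0.5


@dataclass(frozen=True)
class SampleModel:
    """Per-sample nuisance parameters used by genotyping and the ASE fit."""

    sample_id: str
    rho: float  # beta-binomial dispersion, [1e-6, 0.5]
    epsilon: float  # base-calling error probability, (0, 0.05]
    depth: float  # library depth (per-million scaling factor), > 0

    def __post_init__(self):
        if not (RHO_MIN <= self.rho <= RHO_MAX):
            raise ParameterError(f"rho must be in [{RHO_MIN}, {RHO_MAX}], got {self.rho}")
        if not (0.0 < self.epsilon <= 0.05):
            raise ParameterError(f"epsilon must be in (0, 0.05], got {self.epsilon}")
        if not self.depth > 0:
            raise ParameterError(f"depth must be > 0, got {self.depth}")


@dataclass(frozen=True)
class GenotypePosterior:
    snp_id: str
    individual_id: str
    p_RR: float
    p_RA: float
    p_AA: float

    @property
    def is_het(self) -> bool:
        return self.p_RA >= HET_POSTERIOR


@dataclass(frozen=True)
class ASEFit:
    """Allelic-imbalance estimate for one heterozygous SNP in one sample."""

    snp_id: str
    sample_id: str
    beta: float  # logit of reference-allele proportion (positive = ref over-expressed)
    se: float
    z: float
    p_value: float
    q_value: float = float("nan")
    corrected: bool = False  # True when a 0.5-read continuity correction was applied


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _dispersion_mle(k, n) -> float:
    def nll(rho: float) -> float:
        return -float(np.sum(betabinom_logpmf(k, n, 0.5, rho)))

    res = optimize.minimize_scalar(nll, bounds=(RHO_MIN, RHO_MAX), method="bounded",
                                   options={"xatol": 1e-8})
    return float(np.clip(res.x, RHO_MIN, RHO_MAX))


def fit_dispersion(n_ref, n_alt, *, min_coverage: int = MIN_COVERAGE,
                   min_snps: int = 20, ase_trim_fdr: float = 0.05) -> float:
    """Maximum-likelihood beta-binomial dispersion with the mean fixed at 0.5.

    Estimated from putatively heterozygous SNPs. Genuine ASE SNPs in the
    candidate set would masquerade as extra dispersion, so the fit is
    two-pass: after an initial MLE, candidates whose imbalance is clearly
    inconsistent with a balanced mean under that fit (Benjamini-Hochberg
    ``ase_trim_fdr``) are dropped and the likelihood re-maximized. On
    effect-free data the trim removes almost nothing (the test controls its
    FDR), while strong allelic imbalance no longer inflates the estimate.
    The likelihood is maximized by bounded scalar search to 1e-8 and the
    result clamped to [1e-6, 0.5].

    Raises
    ------
    EstimationError
        If fewer than ``min_snps`` SNPs reach ``min_coverage`` ref+alt reads;
        pool counts across samples and retry.
    """
    n_ref = np.asarray(n_ref, dtype=np.int64)
    n_alt = np.asarray(n_alt, dtype=np.int64)
    n = n_ref + n_alt
    keep = n >= min_coverage
    if keep.sum() < min_snps:
        raise EstimationError(
            f"only {int(keep.sum())} SNPs with coverage >= {min_coverage}; "
            f"need >= {min_snps} — pool counts across samples and retry"
        )
    k, n = n_ref[keep], n[keep]
    rho = _dispersion_mle(k, n)
    if ase_trim_fdr > 0:
        lo = np.minimum(k, n - k)
        prev_kept = k.size
        # iterate trim/refit: each pass tightens the fit, exposing more
        # imbalanced SNPs, until the clean set stabilizes
        for _ in range(8):
            # two-sided tail probability of each count under the balanced fit
            if rho < RHO_BINOMIAL:
                cdf = stats.binom.cdf(lo, n, 0.5)
            else:
                a, _ = shape_from_mean_dispersion(0.5, rho)
                cdf = stats.betabinom.cdf(lo, n, a, a)
            clean = bh_fdr(np.clip(2.0 * cdf, 0.0, 1.0)) > ase_trim_fdr
            if clean.sum() < min_snps or clean.sum() in (clean.size, prev_kept):
                break
            prev_kept = int(clean.sum())
            rho = _dispersion_mle(k[clean], n[clean])
    return float(np.clip(rho, RHO_MIN, RHO_MAX))


# ---------------------------------------------------------------------------
# joint genotyping
# ---------------------------------------------------------------------------

def hwe_prior(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype prior (RR, RA, AA) from the minor/alt allele frequency."""
    f = float(maf)
    return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f ** 2])


#: dispersion floor for the heterozygote component during genotyping. The het
#: likelihood must tolerate genuine allelic imbalance (a strongly imbalanced
#: het SNP is not evidence for a homozygote with miscalls), so it is widened
#: beyond the technical replicate dispersion.
RHO_HET_GENOTYPING = 0.10


def genotype_loglik(n_ref, n_alt, rho, epsilon, *,
                    rho_het: float = RHO_HET_GENOTYPING) -> np.ndarray:
    """Per-observation log-likelihoods for genotypes (RR, RA, AA).

    Vectorized over observations; ``rho``/``epsilon`` may be scalars or arrays
    aligned with the counts. Returns an array of shape (n_obs, 3).

    The het component is beta-binomial at mean 0.5 with ``max(rho, rho_het)``
    so that allele-specific expression does not destroy the het call. The
    homozygote components are binomial at means 1-eps and eps: miscalls are a
    per-read technical error, and a beta-binomial with a tiny mean and a
    biological-scale dispersion would have a Beta shape parameter below one —
    an absurdly heavy tail that absorbs imbalanced heterozygotes.
    """
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    n = n_ref + n_alt
    rho = np.broadcast_to(np.asarray(rho, dtype=float), n_ref.shape)
    eps = np.broadcast_to(np.asarray(epsilon, dtype=float), n_ref.shape)
    out = np.empty(n_ref.shape + (3,), dtype=float)
    out[..., 0] = stats.binom.logpmf(n_ref, n, 1.0 - eps)
    out[..., 2] = stats.binom.logpmf(n_ref, n, eps)
    # group by unique rho so the scipy call stays vectorized
    for r in np.unique(rho):
        sel = rho == r
        out[sel, 1] = betabinom_logpmf(n_ref[sel], n[sel], 0.5,
                                       max(float(r), rho_het))
    return out


def genotype_posteriors(n_ref, n_alt, maf, models, *, snp_id: str = "",
                        individual_id: str = "") -> GenotypePosterior:
    """Posterior genotype probabilities for one individual at one SNP.

    ``n_ref``/``n_alt`` are the per-sample allele counts across all of the
    individual's samples (processed together, not merged); ``models`` is the
    matching sequence of :class:`SampleModel`. The posterior combines the HWE
    prior with the product of per-sample beta-binomial likelihoods.
    """
    if maf is None or (isinstance(maf, float) and not np.isfinite(maf)):
        raise ParameterError("minor allele frequency is required for genotyping")
    n_ref = np.atleast_1d(np.asarray(n_ref, dtype=float))
    n_alt = np.atleast_1d(np.asarray(n_alt, dtype=float))
    models = list(models)
    if len(models) != n_ref.size:
        raise ParameterError("one SampleModel per sample is required")
    rho = np.array([m.rho for m in models])
    eps = np.array([m.epsilon for m in models])
    ll = genotype_loglik(n_ref, n_alt, rho, eps).sum(axis=0)
    logpost = np.log(hwe_prior(maf)) + ll
    post = np.exp(logpost - special.logsumexp(logpost))
    post /= post.sum()
    return GenotypePosterior(snp_id, individual_id, float(post[0]), float(post[1]),
                             float(post[2]))


# ---------------------------------------------------------------------------
# per-SNP ASE fit
# ---------------------------------------------------------------------------

def _score_dp(k, n, p, m):
    """d loglik / dp for the beta-binomial with shapes (p*m, (1-p)*m)."""
    a = p * m
    b = (1.0 - p) * m
    return m * (special.digamma(k + a) - special.digamma(a)
                - special.digamma(n - k + b) + special.digamma(b))


def _obs_info_logit(k, n, p, m):
    """Observed Fisher information for beta = logit(p) at p."""
    a = p * m
    b = (1.0 - p) * m
    d2p = m * m * (special.polygamma(1, k + a) - special.polygamma(1, a)
                   + special.polygamma(1, n - k + b) - special.polygamma(1, b))
    d1p = _score_dp(k, n, p, m)
    w = p * (1.0 - p)
    return -(d2p * w * w + d1p * w * (1.0 - 2.0 * p))


def ase_mle(n_ref, n_alt, rho):
    """Vectorized beta-binomial MLE of the allelic proportion with fixed rho.

    Returns ``(beta, se, corrected)`` arrays. Zero counts on either allele get
    a 0.5-read continuity correction on both alleles before the fit (flagged in
    ``corrected``). The score in p is strictly decreasing, so a plain bisection
    converges unconditionally; 90 iterations take the bracket width far below
    float spacing.
    """
    n_ref = np.asarray(n_ref, dtype=float)
    n_alt = np.asarray(n_alt, dtype=float)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), n_ref.shape).copy()
    if np.any(rho < 0) or np.any(rho >= 1):
        raise ParameterError("rho must lie in [0, 1)")

    corrected = (n_ref == 0) | (n_alt == 0)
    k = np.where(corrected, n_ref + 0.5, n_ref)
    na = np.where(corrected, n_alt + 0.5, n_alt)
    n = k + na

    beta = np.empty_like(k)
    se = np.empty_like(k)

    binom = rho < RHO_BINOMIAL
    if np.any(binom):
        phat = k[binom] / n[binom]
        beta[binom] = np.log(phat / (1.0 - phat))
        se[binom] = np.sqrt(1.0 / k[binom] + 1.0 / na[binom])

    bb = ~binom
    if np.any(bb):
        kk, nn = k[bb], n[bb]
        m = 1.0 / rho[bb] - 1.0
        lo = np.full(kk.shape, 1e-10)
        hi = np.full(kk.shape, 1.0 - 1e-10)
        for _ in range(90):
            mid = 0.5 * (lo + hi)
            pos = _score_dp(kk, nn, mid, m) > 0
            lo = np.where(pos, mid, lo)
            hi = np.where(pos, hi, mid)
        phat = 0.5 * (lo + hi)
        info = _obs_info_logit(kk, nn, phat, m)
        beta[bb] = np.log(phat / (1.0 - phat))
        se[bb] = 1.0 / np.sqrt(info)
    return beta, se, corrected


def fit_ase(n_ref: int, n_alt: int, model: SampleModel, *, snp_id: str = "",
            min_coverage: int = MIN_COVERAGE) -> ASEFit | None:
    """ASE fit for one heterozygous SNP in one sample.

    Returns ``None`` when the SNP does not reach the coverage filter
    (n_ref + n_alt >= ``min_coverage``, i.e. strictly more than 40 reads at the
    default); this is a flag, not an error.
    """
    if n_ref < 0 or n_alt < 0:
        raise ParameterError("allele counts must be >= 0")
    if n_ref + n_alt < min_coverage:
        return None
    beta, se, corrected = ase_mle(np.array([n_ref]), np.array([n_alt]), model.rho)
    b, s = float(beta[0]), float(se[0])
    z = b / s
    p = 2.0 * stats.norm.sf(abs(z))
    return ASEFit(snp_id, model.sample_id, b, s, z, float(p), corrected=bool(corrected[0]))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
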
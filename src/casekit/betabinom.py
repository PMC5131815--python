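"""Beta-binomial primitives shared by the simulator and the ASE model.

The beta-binomial is parameterized throughout by its mean allelic proportion
``p`` and the intra-class dispersion ``rho`` in [0, 1), so that a count of
reference reads k out of n ref+alt reads has

    E[k] = n * p,      Var[k] = n * p * (1 - p) * (1 + (n - 1) * rho).

``rho = 0`` degenerates to the binomial. The shape parameters of the latent
Beta are ``a = p * m`` and ``b = (1 - p) * m`` with ``m = 1/rho - 1``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ParameterError

# At or below this dispersion the Beta mixing is numerically indistinguishable
# from a point mass and the binomial branch is used (avoids digamma
# cancellation at huge shape parameters; covers the smallest dispersion a
# sample model may carry, 1e-6, where the variance inflation is < 0.1%).
RHO_BINOMIAL = 1e-5


def shape_from_mean_dispersion(p, rho):
    """Beta shape parameters (a, b) for mean ``p`` and dispersion ``rho``."""
    m = 1.0 / rho - 1.0
    p = np.asarray(p, dtype=float)
    return p * m, (1.0 - p) * m


def _check_p_rho(p, rho) -> None:
    p = np.asarray(p, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0) or np.any(~np.isfinite(p)):
        raise ParameterError(f"allelic proportion p must lie in [0, 1], got {p!r}")
    if np.any(rho < 0.0) or np.any(rho >= 1.0) or np.any(~np.isfinite(rho)):
        raise ParameterError(f"dispersion rho must lie in [0, 1), got {rho!r}")


def sample_betabinomial(n_trials, p, rho, rng: np.random.Generator):
    """Draw beta-binomial counts.

    Parameters
    ----------
    n_trials : int or array of int
        Number of trials (reads); must be >= 0.
    p : float or array
        Mean success (reference-allele) proportion in [0, 1].
    rho : float
        Dispersion in [0, 1); 0 gives plain binomial sampling.
    rng : numpy.random.Generator
        Source of randomness.

    Returns
    -------
    int or ndarray of int, same shape as the broadcast inputs.
    """
    _check_p_rho(p, rho)
    n_arr = np.asarray(n_trials)
    if np.any(n_arr < 0):
        raise ParameterError("n_trials must be >= 0")
    rho = float(rho)
    if rho < RHO_BINOMIAL:
        out = rng.binomial(n_arr, np.broadcast_to(p, n_arr.shape) if n_arr.shape else p)
    else:
        a, b = shape_from_mean_dispersion(p, rho)
        # exact draws: latent Beta proportion per observation, then binomial
        lat = rng.beta(np.broadcast_to(a, n_arr.shape), np.broadcast_to(b, n_arr.shape))
        out = rng.binomial(n_arr, lat)
    if np.isscalar(n_trials):
        return int(out)
    return out


def betabinom_logpmf(k, n, p, rho):
    """Log-pmf of k reference reads out of n, mean p, dispersion rho.

    Vectorized over all arguments; degenerate means (p in {0, 1}) and the
    binomial limit are handled explicitly.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    rho = float(rho)
    if rho < RHO_BINOMIAL:
        return stats.binom.logpmf(k, n, p)
    a, b = shape_from_mean_dispersion(p, rho)
    return stats.betabinom.logpmf(k, n, a, b)
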
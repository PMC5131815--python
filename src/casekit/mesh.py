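"""Qualitative cASE test via configuration Bayes factors.

For each SNP/individual/treatment-control pair, four mutually exclusive
configurations of allele-specific expression are scored against each other:

1. no ASE in either condition (the null; BF = 1 by definition),
2. ASE shared by both conditions, allowing a random effect in the size,
3. ASE in the treatment only,
4. ASE in the control only.

Each non-null configuration's Bayes factor is an asymptotic (Wakefield-style)
marginal-likelihood ratio computed from the estimated effect and its standard
error, averaged over a grid of prior variances split into a shared component
``phi2`` and a heterogeneity component ``omega2``. Conditional ASE is called
from the contrast ``BF_treatment - BF_shared`` (and symmetrically for the
control), thresholded at 30 by default. All arithmetic is done in log space;
raw BFs are materialized only at call time, capped at exp(700) to avoid
overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import ParameterError

#: default threshold on the BF difference for declaring cASE
BF_THRESHOLD = 30.0

_LOG_BF_CAP = 700.0  # raw BFs are exp-capped here before differencing


@dataclass(frozen=True)
class EffectPair:
    """Matched treatment/control ASE estimates for one SNP and individual."""

    snp_id: str
    individual_id: str
    condition: str
    beta_T: float
    se_T: float
    beta_C: float
    se_C: float

    def __post_init__(self):
        if self.se_T <= 0 or self.se_C <= 0:
            raise ParameterError("standard errors must be > 0")

    def swapped(self) -> "EffectPair":
        return EffectPair(self.snp_id, self.individual_id, self.condition,
                          self.beta_C, self.se_C, self.beta_T, self.se_T)


@dataclass(frozen=True)
class PriorGrid:
    """Prior-variance grid: shared variance phi2, heterogeneity omega2, weights."""

    phi2: tuple[float, ...]
    omega2: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        p, o, w = map(np.asarray, (self.phi2, self.omega2, self.weights))
        if not (len(p) == len(o) == len(w)) or len(p) == 0:
            raise ParameterError("phi2, omega2 and weights must have equal nonzero length")
        if np.any(p < 0) or np.any(o < 0) or np.any((p + o) == 0):
            raise ParameterError("prior variances must be >= 0 and not both 0")
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError("weights must be positive and sum to 1")


def default_prior_grid() -> PriorGrid:
    """Total effect variance in {0.01, 0.04, 0.16, 0.64, 2.56} crossed with
    heterogeneity fractions {0, 0.25, 0.5}, equal weights."""
    totals = [0.01, 0.04, 0.16, 0.64, 2.56]
    het_fracs = [0.0, 0.25, 0.5]
    phi2, omega2 = [], []
    for v in totals:
        for h in het_fracs:
            phi2.append((1.0 - h) * v)
            omega2.append(h * v)
    n = len(phi2)
    return PriorGrid(tuple(phi2), tuple(omega2), tuple([1.0 / n] * n))


def log_wakefield_abf(beta_hat: float, se: float, psi2: float) -> float:
    """Log of the single-condition asymptotic Bayes factor.

    Marginal-likelihood ratio of ``beta ~ N(0, psi2)`` against ``beta = 0``
    given ``beta_hat ~ N(beta, se^2)``:

        sqrt(se^2 / (se^2 + psi2)) * exp( beta_hat^2 psi2 / (2 se^2 (se^2 + psi2)) )
    """
    if se <= 0 or psi2 <= 0:
        raise ParameterError("se and psi2 must be > 0")
    v = se * se
    return 0.5 * np.log(v / (v + psi2)) + beta_hat ** 2 * psi2 / (2.0 * v * (v + psi2))


def wakefield_abf(beta_hat: float, se: float, psi2: float) -> float:
    return float(np.exp(log_wakefield_abf(beta_hat, se, psi2)))


def _log_bvn_ratio(bT, seT, bC, seC, phi2, omega2) -> float:
    """Log BF of the shared configuration at one grid point.

    Under sharing, beta_T = theta + d_T and beta_C = theta + d_C with
    theta ~ N(0, phi2) and independent d ~ N(0, omega2); the marginal of
    (beta_hat_T, beta_hat_C) is bivariate normal with covariance
    [[se_T^2 + phi2 + omega2, phi2], [phi2, se_C^2 + phi2 + omega2]],
    contrasted against diag(se_T^2, se_C^2) under the null.
    """
    vT, vC = seT * seT, seC * seC
    s11 = vT + phi2 + omega2
    s22 = vC + phi2 + omega2
    s12 = phi2
    det1 = s11 * s22 - s12 * s12
    if det1 <= 0:
        raise ParameterError("degenerate shared-configuration covariance")
    q1 = (s22 * bT * bT - 2.0 * s12 * bT * bC + s11 * bC * bC) / det1
    q0 = bT * bT / vT + bC * bC / vC
    return 0.5 * (np.log(vT * vC / det1) + q0 - q1)


@dataclass(frozen=True)
class ConfigurationBF:
    """Grid-averaged Bayes factors for the three non-null configurations."""

    snp_id: str
    individual_id: str
    condition: str
    log_bf_shared: float
    log_bf_treatment: float
    log_bf_control: float
    call: str = ""

    def _raw(self, logbf: float) -> float:
        return float(np.exp(min(logbf, _LOG_BF_CAP)))

    @property
    def bf_shared(self) -> float:
        return self._raw(self.log_bf_shared)

    @property
    def bf_treatment(self) -> float:
        return self._raw(self.log_bf_treatment)

    @property
    def bf_control(self) -> float:
        return self._raw(self.log_bf_control)

    def case_stat_T(self, scale: str = "raw") -> float:
        if scale == "raw":
            return self.bf_treatment - self.bf_shared
        if scale == "log10":
            return (self.log_bf_treatment - self.log_bf_shared) / np.log(10.0)
        raise ParameterError(f"unknown BF scale {scale!r}")

    def case_stat_C(self, scale: str = "raw") -> float:
        if scale == "raw":
            return self.bf_control - self.bf_shared
        if scale == "log10":
            return (self.log_bf_control - self.log_bf_shared) / np.log(10.0)
        raise ParameterError(f"unknown BF scale {scale!r}")


def configuration_bfs(pair: EffectPair, grid: PriorGrid | None = None) -> ConfigurationBF:
    """Grid-averaged configuration Bayes factors for one effect pair.

    Treatment-only and control-only configurations place the whole prior
    variance ``phi2 + omega2`` on the active condition while the inactive one
    contributes identically under the configuration and the null; the shared
    configuration uses the bivariate marginal of :func:`_log_bvn_ratio`.
    """
    grid = grid or default_prior_grid()
    logw = np.log(np.asarray(grid.weights))
    ls, lt, lc = [], [], []
    for phi2, omega2 in zip(grid.phi2, grid.omega2):
        psi2 = phi2 + omega2
        ls.append(_log_bvn_ratio(pair.beta_T, pair.se_T, pair.beta_C, pair.se_C,
                                 phi2, omega2))
        lt.append(log_wakefield_abf(pair.beta_T, pair.se_T, psi2))
        lc.append(log_wakefield_abf(pair.beta_C, pair.se_C, psi2))
    return ConfigurationBF(
        pair.snp_id, pair.individual_id, pair.condition,
        log_bf_shared=float(logsumexp(np.array(ls) + logw)),
        log_bf_treatment=float(logsumexp(np.array(lt) + logw)),
        log_bf_control=float(logsumexp(np.array(lc) + logw)),
    )


def configuration_log_bfs_arrays(beta_T, se_T, beta_C, se_C,
                                 grid: PriorGrid | None = None):
    """Vectorized grid-averaged log BFs over arrays of effect pairs.

    Returns ``(log_bf_shared, log_bf_treatment, log_bf_control)`` arrays; the
    scalar :func:`configuration_bfs` is the reference implementation.
    """
    grid = grid or default_prior_grid()
    bT = np.asarray(beta_T, float)
    sT = np.asarray(se_T, float)
    bC = np.asarray(beta_C, float)
    sC = np.asarray(se_C, float)
    if np.any(sT <= 0) or np.any(sC <= 0):
        raise ParameterError("standard errors must be > 0")
    logw = np.log(np.asarray(grid.weights))
    n_grid = len(grid.phi2)
    ls = np.empty((n_grid,) + bT.shape)
    lt = np.empty_like(ls)
    lc = np.empty_like(ls)
    vT, vC = sT * sT, sC * sC
    for i, (phi2, omega2) in enumerate(zip(grid.phi2, grid.omega2)):
        psi2 = phi2 + omega2
        s11 = vT + psi2
        s22 = vC + psi2
        det1 = s11 * s22 - phi2 * phi2
        q1 = (s22 * bT * bT - 2.0 * phi2 * bT * bC + s11 * bC * bC) / det1
        q0 = bT * bT / vT + bC * bC / vC
        ls[i] = 0.5 * (np.log(vT * vC / det1) + q0 - q1)
        lt[i] = 0.5 * np.log(vT / (vT + psi2)) + bT * bT * psi2 / (2 * vT * (vT + psi2))
        lc[i] = 0.5 * np.log(vC / (vC + psi2)) + bC * bC * psi2 / (2 * vC * (vC + psi2))
    return (logsumexp(ls + logw[:, None], axis=0),
            logsumexp(lt + logw[:, None], axis=0),
            logsumexp(lc + logw[:, None], axis=0))


def call_case_arrays(log_bf_shared, log_bf_treatment, log_bf_control,
                     threshold: float = BF_THRESHOLD, scale: str = "raw"):
    """Vectorized :func:`call_case` over arrays of log BFs.

    Returns ``(calls, case_stat_T, case_stat_C)``.
    """
    lbs = np.asarray(log_bf_shared, float)
    lbt = np.asarray(log_bf_treatment, float)
    lbc = np.asarray(log_bf_control, float)
    if scale == "raw":
        cap = np.exp(np.minimum
                     (np.stack([lbs, lbt, lbc]), _LOG_BF_CAP))
        st = cap[1] - cap[0]
        sc = cap[2] - cap[0]
    elif scale == "log10":
        st = (lbt - lbs) / np.log(10.0)
        sc = (lbc - lbs) / np.log(10.0)
    else:
        raise ParameterError(f"unknown BF scale {scale!r}")
    calls = np.where((st > threshold) & (st >= sc), "treatment_cASE",
                     np.where((sc > threshold) & (sc >= st), "control_cASE",
                              np.where(lbs > 0.0, "shared", "none")))
    return calls, st, sc


def call_case(bfs: ConfigurationBF, threshold: float = BF_THRESHOLD,
              scale: str = "raw") -> str:
    """Classify a pair from its BF contrasts.

    ``treatment_cASE`` when the treatment contrast exceeds the threshold and
    dominates the control contrast; ``control_cASE`` symmetrically; otherwise
    ``shared`` when the shared BF exceeds 1, else ``none``.
    """
    st = bfs.case_stat_T(scale)
    sc = bfs.case_stat_C(scale)
    if st > threshold and st >= sc:
        return "treatment_cASE"
    if sc > threshold and sc >= st:
        return "control_cASE"
    if bfs.log_bf_shared > 0.0:
        return "shared"
    return "none"


def best_configuration(bfs: ConfigurationBF) -> str:
    """Arg-max configuration among null (log BF 0), shared, treatment, control."""
    vals = {"none": 0.0, "shared": bfs.log_bf_shared,
            "treatment_only": bfs.log_bf_treatment, "control_only": bfs.log_bf_control}
    return max(vals, key=vals.get)
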
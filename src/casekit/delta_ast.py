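"""Quantitative cASE test (differential allele-specific test).

For each SNP and individual, the difference between the treatment and matched
control allelic-imbalance estimates is standardized as

    Z_delta = (beta_T - beta_C) / sqrt(se_T^2 + se_C^2).

The paired design ships two independent vehicle controls per batch, so the
same statistic evaluated on CO1-versus-CO2 pairs yields an empirical null:
raw Z_delta scores are divided by the null standard deviation within each
calibration stratum (pooled when a stratum has fewer than 30 null pairs), and
two-sided p-values follow from the standard normal, P = 2 * Phi(-|z|).

Because the null p-values deviate slightly from uniform in finite samples,
significance is thresholded on an empirical FDR: at each candidate p-value
threshold t, FDR(t) = min(1, ECDF_null(t) / ECDF_obs(t)), converted to a
per-observation q by taking the minimum over all thresholds at or above the
observation's own p (a q-value-style monotone envelope). This is the
ECDF-ratio analogue of the permutation FDR used in eQTL studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError, PairingError
from .mesh import EffectPair

#: minimum number of control-control pairs per stratum before pooling
MIN_NULL_PER_STRATUM = 30

POOLED = "__pooled__"


@dataclass(frozen=True)
class CaseTestResult:
    snp_id: str
    individual_id: str
    condition: str
    z_delta: float  # normalized differential Z-score
    p_delta: float  # two-sided p-value
    q_empirical: float
    is_null_pair: bool


def z_delta(pair: EffectPair) -> float:
    """Raw differential Z-score of one treatment/control effect pair."""
    if pair is None:
        raise PairingError("missing effect pair")
    return (pair.beta_T - pair.beta_C) / np.sqrt(pair.se_T ** 2 + pair.se_C ** 2)


def null_sd_by_stratum(null_z, null_strata) -> dict:
    """Per-stratum SD of the control-control Z_delta scores.

    Strata with fewer than :data:`MIN_NULL_PER_STRATUM` null pairs fall back
    to the pooled SD, stored under :data:`POOLED`.
    """
    null_z = np.asarray(null_z, dtype=float)
    if null_z.size < MIN_NULL_PER_STRATUM:
        raise CalibrationError(
            f"need >= {MIN_NULL_PER_STRATUM} control-control pairs, got {null_z.size}")
    pooled = float(np.std(null_z, ddof=1))
    if not np.isfinite(pooled) or pooled <= 0:
        raise CalibrationError("control-control Z_delta SD is zero or undefined")
    out = {POOLED: pooled}
    df = pd.DataFrame({"z": null_z, "stratum": list(null_strata)})
    for key, grp in df.groupby("stratum", sort=False):
        if len(grp) >= MIN_NULL_PER_STRATUM:
            sd = float(grp["z"].std(ddof=1))
            if np.isfinite(sd) and sd > 0:
                out[key] = sd
    return out


def calibrate_and_pvalues(raw_z, strata, null_raw_z, null_strata):
    """Normalize raw Z_delta scores by the stratum null SD and attach p-values.

    Returns ``(z_normalized, p_delta)`` arrays. The same normalization is
    applicable to the null scores themselves (pass them as ``raw_z`` too) so
    that observed and null p-values share a scale for the empirical FDR.
    """
    sds = null_sd_by_stratum(null_raw_z, null_strata)
    raw_z = np.asarray(raw_z, dtype=float)
    sd_vec = np.array([sds.get(s, sds[POOLED]) for s in strata])
    z = raw_z / sd_vec
    p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def empirical_fdr(observed_p, null_p) -> np.ndarray:
    """Empirical q-values from the control-control null p-value distribution.

    For each threshold t among the sorted observed p-values,
    ``FDR(t) = min(1, ECDF_null(t) / ECDF_obs(t))`` with inclusive (<=)
    comparisons; each observation's q is the minimum FDR over thresholds at or
    above its own p. Ties are handled deterministically by the inclusive ECDF.
    """
    obs = np.asarray(observed_p, dtype=float)
    nul = np.sort(np.asarray(null_p, dtype=float))
    if obs.size == 0:
        return np.empty(0)
    if nul.size == 0:
        raise CalibrationError("empty control-control null set")
    order = np.argsort(obs, kind="stable")
    sorted_obs = obs[order]
    ecdf_null = np.searchsorted(nul, sorted_obs, side="right") / nul.size
    # inclusive observed ECDF: count of observed p <= each sorted value
    ecdf_obs = np.searchsorted(sorted_obs, sorted_obs, side="right") / obs.size
    fdr = np.minimum(1.0, ecdf_null / ecdf_obs)
    # monotone envelope: q(p_i) = min over thresholds >= p_i
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def delta_ast(pairs: pd.DataFrame, null_pairs: pd.DataFrame) -> pd.DataFrame:
    """Run the full differential test on tables of effect pairs.

    Both frames need columns ``snp_id, individual_id, condition, beta_T, se_T,
    beta_C, se_C, stratum``; ``null_pairs`` holds the CO1-versus-CO2 pairs.
    Returns one row per input pair (observed then null) with the normalized
    z-score, p-value, empirical q-value and the ``is_null_pair`` flag. Null
    pairs receive q-values from their own exchangeability (observed == null
    would give q = 1), so their q column is left as NaN.
    """
    for frame, name in ((pairs, "pairs"), (null_pairs, "null_pairs")):
        missing = {"beta_T", "se_T", "beta_C", "se_C", "stratum"} - set(frame.columns)
        if missing:
            raise PairingError(f"{name} table is missing columns {sorted(missing)}")
    raw_obs = ((pairs["beta_T"] - pairs["beta_C"])
               / np.sqrt(pairs["se_T"] ** 2 + pairs["se_C"] ** 2)).to_numpy()
    raw_nul = ((null_pairs["beta_T"] - null_pairs["beta_C"])
               / np.sqrt(null_pairs["se_T"] ** 2 + null_pairs["se_C"] ** 2)).to_numpy()
    z_obs, p_obs = calibrate_and_pvalues(raw_obs, pairs["stratum"], raw_nul,
                                         null_pairs["stratum"])
    z_nul, p_nul = calibrate_and_pvalues(raw_nul, null_pairs["stratum"], raw_nul,
                                         null_pairs["stratum"])
    q_obs = empirical_fdr(p_obs, p_nul)
    obs = pairs[["snp_id", "individual_id", "condition"]].copy()
    obs["z_delta"], obs["p_delta"], obs["q_empirical"] = z_obs, p_obs, q_obs
    obs["is_null_pair"] = False
    nul = null_pairs[["snp_id", "individual_id", "condition"]].copy()
    nul["z_delta"], nul["p_delta"], nul["q_empirical"] = z_nul, p_nul, np.nan
    nul["is_null_pair"] = True
    return pd.concat([obs, nul], ignore_index=True)
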
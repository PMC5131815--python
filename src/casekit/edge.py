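"""EDGE index: environmental displacement of genetic effect.

For a cell type ``s`` and treatment ``t``, the index aggregates all per-SNP
standardized ASE effects (Z = beta / se) into one genome-wide measure of how
much the environment displaces genetic effects:

    EDGE(s, t) = Pearson(Z_{s,CO1}, Z_{s,CO2}) / Pearson(Z_{s,t}, Z_{s,c}).

The numerator is the correlation between the two vehicle-control sets — the
technical ceiling of reproducibility — and the denominator the correlation
between treatment and matched control. With the control pair in the treatment
slot the index is exactly one; treatments that perturb ASE at many SNPs lower
the denominator and push the index above one.

The two correlations may use different SNP sets (each pair's own
tested-in-both set); a strict four-way-intersection mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError

#: minimum SNPs in each correlation's intersection set
MIN_SNPS = 10
#: the index is undefined when the treatment-control correlation is this low
R_TC_GUARD = 0.05


@dataclass(frozen=True)
class EdgeResult:
    cell_type: str
    condition: str
    r_null: float  # Pearson(Z_CO1, Z_CO2)
    r_tc: float  # Pearson(Z_treatment, Z_control)
    edge: float  # r_null / r_tc, NaN when undefined
    n_snps_null: int
    n_snps_tc: int
    defined: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def edge(z_treat, z_ctrl, z_co1, z_co2, *, cell_type: str = "", condition: str = "",
         min_snps: int = MIN_SNPS, r_tc_guard: float = R_TC_GUARD,
         intersect_all: bool = False) -> EdgeResult:
    """Compute the EDGE index from four per-SNP Z vectors.

    ``z_treat``/``z_ctrl`` must be aligned element-wise, as must
    ``z_co1``/``z_co2``; NaN entries mark SNPs untested in that sample and are
    dropped pairwise (or four-way when ``intersect_all`` and all vectors share
    one SNP ordering).
    """
    zt, zc = np.asarray(z_treat, float), np.asarray(z_ctrl, float)
    z1, z2 = np.asarray(z_co1, float), np.asarray(z_co2, float)
    if zt.shape != zc.shape or z1.shape != z2.shape:
        raise InsufficientDataError("paired Z vectors must have matching lengths")
    if intersect_all:
        if zt.shape != z1.shape:
            raise InsufficientDataError(
                "four-way intersection requires one shared SNP ordering")
        keep = np.isfinite(zt) & np.isfinite(zc) & np.isfinite(z1) & np.isfinite(z2)
        zt, zc, z1, z2 = zt[keep], zc[keep], z1[keep], z2[keep]
        keep_tc = keep_null = np.ones(keep.sum(), bool)
    else:
        keep_tc = np.isfinite(zt) & np.isfinite(zc)
        keep_null = np.isfinite(z1) & np.isfinite(z2)
        zt, zc = zt[keep_tc], zc[keep_tc]
        z1, z2 = z1[keep_null], z2[keep_null]
    if zt.size < min_snps or z1.size < min_snps:
        raise InsufficientDataError(
            f"need >= {min_snps} SNPs in each correlation "
            f"(got {zt.size} treatment-control, {z1.size} control-control)")
    r_tc = _pearson(zt, zc)
    r_null = _pearson(z1, z2)
    defined = bool(r_tc > r_tc_guard)
    return EdgeResult(cell_type, condition, r_null, r_tc,
                      r_null / r_tc if defined else float("nan"),
                      int(z1.size), int(zt.size), defined)
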
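"""Induced-ASE detection.

A SNP shows induced ASE (iASE) when the treatment sample has well-measured
allelic imbalance while the gene is essentially unexpressed in the matched
control. Four criteria must all hold:

1. treatment ref+alt coverage strictly greater than 40 reads;
2. treatment ASE significant at the chosen FDR (q-value <= 0.10 by default);
3. control ref+alt coverage below ``10 * (D_C / D_T)`` reads, where ``D_C``
   and ``D_T`` are the control and treatment library depths — at equal depths
   this is a 40-reads-to-10 ratio, i.e. control expression at least fourfold
   below the minimum testable level;
4. depth-normalized SNP-level log2 fold change above log2(5).

Only the ratio ``D_C / D_T`` enters, so any proportional definition of library
depth (per-million scaling, TPM denominator, total retained reads) gives
identical calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ase import ASEFit, MIN_COVERAGE
from .errors import ParameterError, PairingError

#: control-coverage cutoff at equal library depths ("40 reads to 10")
CONTROL_COVERAGE_RATIO = 10.0
#: minimum SNP-level fold change, treatment over control
MIN_FOLD_CHANGE = 5.0


@dataclass(frozen=True)
class LibraryPair:
    """Sequencing depths of one matched treatment/control library pair."""

    treatment_sample_id: str
    control_sample_id: str
    depth_treatment: float
    depth_control: float

    def __post_init__(self):
        if self.depth_treatment <= 0 or self.depth_control <= 0:
            raise ParameterError("library depths must be > 0")


@dataclass(frozen=True)
class IaseCall:
    """Outcome of the four-rule induced-ASE test, with per-rule reasons."""

    snp_id: str
    is_iase: bool
    treatment_covered: bool  # > 40 ref+alt reads in treatment
    treatment_significant: bool  # ASE q-value at or below the FDR level
    control_unexpressed: bool  # control coverage < 10 * (D_C / D_T)
    fold_change_passed: bool  # log2 FC > log2(5)
    log2_fold_change: float
    control_cutoff_reads: float


def snp_log2fc(n_treatment: float, n_control: float, pair: LibraryPair) -> float:
    """Depth-normalized SNP-level log2 fold change with a +1 pseudocount.

    ``log2( ((n_T + 1)/D_T) / ((n_C + 1)/D_C) )`` — finite even at zero
    control coverage and exactly 0 for equal normalized counts.
    """
    if n_treatment < 0 or n_control < 0:
        raise ParameterError("read counts must be >= 0")
    return float(np.log2(((n_treatment + 1.0) / pair.depth_treatment)
                         / ((n_control + 1.0) / pair.depth_control)))


def detect_iase(treatment_fit: ASEFit, treatment_total: int, control_total: int,
                pair: LibraryPair, *, fdr: float = 0.10,
                snp_id: str | None = None) -> IaseCall:
    """Apply the four induced-ASE rules to one SNP.

    ``treatment_total``/``control_total`` are ref+alt read totals in the two
    conditions. ``treatment_fit`` must carry the within-sample q-value of the
    treatment ASE test. A ``snp_id`` mismatch between the fit and the caller's
    expectation raises :class:`PairingError`.
    """
    if snp_id is not None and treatment_fit.snp_id != snp_id:
        raise PairingError(
            f"treatment fit is for {treatment_fit.snp_id!r}, expected {snp_id!r}")
    cutoff = CONTROL_COVERAGE_RATIO * (pair.depth_control / pair.depth_treatment)
    lfc = snp_log2fc(treatment_total, control_total, pair)
    covered = treatment_total >= MIN_COVERAGE
    significant = np.isfinite(treatment_fit.q_value) and treatment_fit.q_value <= fdr
    unexpressed = control_total < cutoff
    fc_ok = lfc > np.log2(MIN_FOLD_CHANGE)
    return IaseCall(
        snp_id=treatment_fit.snp_id,
        is_iase=bool(covered and significant and unexpressed and fc_ok),
        treatment_covered=bool(covered),
        treatment_significant=bool(significant),
        control_unexpressed=bool(unexpressed),
        fold_change_passed=bool(fc_ok),
        log2_fold_change=lfc,
        control_cutoff_reads=float(cutoff),
    )
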
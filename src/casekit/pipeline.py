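"""End-to-end orchestration: counts -> genotypes -> ASE -> GxE tests -> EDGE.

Each stage is a pure function from data frames to a data frame, so any single
stage can be re-run from on-disk intermediates and reproduce the full-run
output exactly. :func:`run_pipeline` wires them together, validates the
samples manifest before any computation, and (optionally) writes every result
as a TSV with a stable column order plus a JSON run log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .ase import (MIN_COVERAGE, ase_mle, bh_fdr, fit_dispersion,
                  genotype_loglik, HET_POSTERIOR)
from .delta_ast import delta_ast
from .edge import edge
from .errors import EstimationError, InsufficientDataError, ValidationError
from .iase import CONTROL_COVERAGE_RATIO, MIN_FOLD_CHANGE
from .io import validate_manifest, write_table
from .mesh import (BF_THRESHOLD, PriorGrid, call_case_arrays,
                   configuration_log_bfs_arrays, default_prior_grid)


@dataclass
class PipelineParams:
    """Knobs shared across stages.

    ``rho = None`` estimates the dispersion per sample from putative het SNPs
    (pooling across samples when one is too sparse); a float fixes it.
    """

    epsilon: float = 1e-3
    min_coverage: int = MIN_COVERAGE  # "> 40 reads"
    ase_fdr: float = 0.10
    bf_threshold: float = BF_THRESHOLD
    bf_scale: str = "raw"
    rho: float | None = None
    seed: int = 0


# ---------------------------------------------------------------------------
# stage: per-sample models
# ---------------------------------------------------------------------------

def stage_models(counts: pd.DataFrame, params: PipelineParams) -> pd.DataFrame:
    """Estimate per-sample dispersion and library depth.

    Putative het SNPs (both alleles at >= 10% of reads, coverage over the
    filter) feed the dispersion fit; samples with too few fall back to a fit
    pooled over all samples.
    """
    rows = []
    pooled_rho = None
    total = counts["ref_count"] + counts["alt_count"]
    minor = np.minimum(counts["ref_count"], counts["alt_count"])
    cand = (total >= params.min_coverage) & (minor / total.clip(lower=1) >= 0.10)
    for sample_id, grp in counts.groupby("sample_id", sort=False):
        depth = float((grp["ref_count"] + grp["alt_count"]
                       + grp["other_count"]).sum()) / 1e6
        sel = cand.loc[grp.index]
        if params.rho is not None:
            rho = params.rho
        else:
            try:
                rho = fit_dispersion(grp.loc[sel, "ref_count"],
                                     grp.loc[sel, "alt_count"],
                                     min_coverage=params.min_coverage)
            except EstimationError:
                if pooled_rho is None:
                    pooled_rho = fit_dispersion(
                        counts.loc[cand, "ref_count"], counts.loc[cand, "alt_count"],
                        min_coverage=params.min_coverage)
                rho = pooled_rho
        rows.append({"sample_id": sample_id, "rho": max(rho, 1e-6),
                     "epsilon": params.epsilon, "depth": depth})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stage: joint genotyping
# ---------------------------------------------------------------------------

def stage_genotype(counts: pd.DataFrame, models: pd.DataFrame) -> pd.DataFrame:
    """Posterior genotype per individual x SNP from all samples jointly."""
    df = counts.merge(models[["sample_id", "rho", "epsilon"]], on="sample_id")
    ll = genotype_loglik(df["ref_count"].to_numpy(), df["alt_count"].to_numpy(),
                        df["rho"].to_numpy(), df["epsilon"].to_numpy())
    df = df.assign(_llRR=ll[:, 0], _llRA=ll[:, 1], _llAA=ll[:, 2])
    agg = df.groupby(["individual_id", "snp_id"], sort=False).agg(
        llRR=("_llRR", "sum"), llRA=("_llRA", "sum"), llAA=("_llAA", "sum"),
        maf=("maf", "first")).reset_index()
    f = agg["maf"].to_numpy()
    logpost = np.stack([
        2 * np.log1p(-f) + agg["llRR"],
        np.log(2 * f * (1 - f)) + agg["llRA"],
        2 * np.log(f) + agg["llAA"],
    ], axis=1)
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    out = agg[["individual_id", "snp_id"]].copy()
    out["p_RR"], out["p_RA"], out["p_AA"] = post[:, 0], post[:, 1], post[:, 2]
    out["het"] = out["p_RA"] >= HET_POSTERIOR
    return out


# ---------------------------------------------------------------------------
# stage: per-sample ASE fits
# ---------------------------------------------------------------------------

ASE_COLUMNS = ["snp_id", "sample_id", "individual_id", "cell_type", "condition",
               "batch", "total_count", "beta", "se", "z", "p_value", "q_value",
               "corrected"]


def stage_ase(counts: pd.DataFrame, genotypes: pd.DataFrame, models: pd.DataFrame,
              params: PipelineParams) -> pd.DataFrame:
    """Beta-binomial ASE fit for every het SNP passing the coverage filter,
    with Benjamini-Hochberg q-values within each sample."""
    het = genotypes.loc[genotypes["het"], ["individual_id", "snp_id"]]
    df = counts.merge(het, on=["individual_id", "snp_id"])
    df = df.merge(models[["sample_id", "rho"]], on="sample_id")
    total = df["ref_count"] + df["alt_count"]
    df = df[total >= params.min_coverage].copy()
    df["total_count"] = (df["ref_count"] + df["alt_count"]).astype(np.int64)
    if df.empty:
        return pd.DataFrame(columns=ASE_COLUMNS)
    beta, se, corrected = ase_mle(df["ref_count"].to_numpy(),
                                  df["alt_count"].to_numpy(),
                                  df["rho"].to_numpy())
    df["beta"], df["se"], df["corrected"] = beta, se, corrected
    df["z"] = df["beta"] / df["se"]
    df["p_value"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
    df["q_value"] = np.nan
    for _, idx in df.groupby("sample_id", sort=False).groups.items():
        df.loc[idx, "q_value"] = bh_fdr(df.loc[idx, "p_value"])
    return df[ASE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def build_pairs(ase: pd.DataFrame, manifest: pd.DataFrame):
    """Assemble treatment-versus-control and CO1-versus-CO2 effect pairs.

    Both members of a pair must carry an ASE fit (i.e. both passed the
    coverage filter). The calibration stratum is cell type x batch.
    """
    man = manifest.set_index("sample_id")
    t_rows = ase[ase["sample_id"].map(man["role"]) == "treatment"].copy()
    t_rows["control_sample_id"] = t_rows["sample_id"].map(man["control_sample_id"])
    ctrl = ase.rename(columns={c: f"{c}_C" for c in
                               ("sample_id", "beta", "se", "z", "p_value",
                                "q_value", "total_count")})
    pairs = t_rows.merge(
        ctrl[["snp_id", "individual_id", "sample_id_C", "beta_C", "se_C", "z_C",
              "total_count_C"]],
        left_on=["snp_id", "individual_id", "control_sample_id"],
        right_on=["snp_id", "individual_id", "sample_id_C"])
    pairs = pairs.rename(columns={"beta": "beta_T", "se": "se_T", "z": "z_T",
                                  "total_count": "total_count_T"})
    pairs["stratum"] = pairs["cell_type"].astype(str) + "|" + pairs["batch"].astype(str)

    co = ase[ase["sample_id"].map(man["role"]).isin(["CO1", "CO2"])].copy()
    co["role"] = co["sample_id"].map(man["role"])
    co1 = co[co["role"] == "CO1"]
    co2 = co[co["role"] == "CO2"].rename(
        columns={"sample_id": "sample_id_C", "beta": "beta_C", "se": "se_C",
                 "z": "z_C", "total_count": "total_count_C"})
    null_pairs = co1.merge(
        co2[["snp_id", "individual_id", "batch", "sample_id_C", "beta_C", "se_C",
             "z_C", "total_count_C"]],
        on=["snp_id", "individual_id", "batch"])
    null_pairs = null_pairs.rename(
        columns={"beta": "beta_T", "se": "se_T", "z": "z_T",
                 "total_count": "total_count_T"})
    null_pairs["stratum"] = (null_pairs["cell_type"].astype(str) + "|"
                             + null_pairs["batch"].astype(str))
    keep = ["snp_id", "individual_id", "cell_type", "condition", "batch", "stratum",
            "sample_id", "sample_id_C", "beta_T", "se_T", "z_T", "total_count_T",
            "beta_C", "se_C", "z_C", "total_count_C"]
    return pairs[keep].reset_index(drop=True), null_pairs[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage: induced ASE
# ---------------------------------------------------------------------------

IASE_COLUMNS = ["snp_id", "individual_id", "cell_type", "condition", "batch",
                "sample_id", "control_sample_id", "treatment_total", "control_total",
                "q_value", "control_cutoff_reads", "log2_fold_change", "is_iase",
                "treatment_covered", "treatment_significant", "control_unexpressed",
                "fold_change_passed"]


def stage_iase(ase: pd.DataFrame, counts: pd.DataFrame, manifest: pd.DataFrame,
               params: PipelineParams) -> pd.DataFrame:
    """Induced-ASE calls for every fitted treatment-sample SNP.

    Control coverage comes from the raw counts (the control need not — and for
    a hit, must not — pass the ASE filter).
    """
    man = manifest.set_index("sample_id")
    t_rows = ase[ase["sample_id"].map(man["role"]) == "treatment"].copy()
    t_rows["control_sample_id"] = t_rows["sample_id"].map(man["control_sample_id"])
    ctotal = counts.assign(total=counts["ref_count"] + counts["alt_count"])
    ctotal = ctotal[["sample_id", "snp_id", "total"]].rename(
        columns={"sample_id": "control_sample_id", "total": "control_total"})
    df = t_rows.merge(ctotal, on=["control_sample_id", "snp_id"], how="left")
    df["control_total"] = df["control_total"].fillna(0).astype(np.int64)
    d_t = df["sample_id"].map(man["depth"]).to_numpy(float)
    d_c = df["control_sample_id"].map(man["depth"]).to_numpy(float)
    df = df.rename(columns={"total_count": "treatment_total"})
    df["control_cutoff_reads"] = CONTROL_COVERAGE_RATIO * (d_c / d_t)
    df["log2_fold_change"] = np.log2(((df["treatment_total"] + 1.0) / d_t)
                                     / ((df["control_total"] + 1.0) / d_c))
    df["treatment_covered"] = df["treatment_total"] >= params.min_coverage
    df["treatment_significant"] = df["q_value"] <= params.ase_fdr
    df["control_unexpressed"] = df["control_total"] < df["control_cutoff_reads"]
    df["fold_change_passed"] = df["log2_fold_change"] > np.log2(MIN_FOLD_CHANGE)
    df["is_iase"] = (df["treatment_covered"] & df["treatment_significant"]
                     & df["control_unexpressed"] & df["fold_change_passed"])
    return df[IASE_COLUMNS].reset_index(drop=True)


# ---------------------------------------------------------------------------
# stage: configuration Bayes factors
# ---------------------------------------------------------------------------

BFCASE_COLUMNS = ["snp_id", "individual_id", "condition", "bf_shared", "bf_treatment",
                  "bf_control", "case_stat_T", "case_stat_C", "call"]


def stage_bfcase(pairs: pd.DataFrame, params: PipelineParams,
                 grid: PriorGrid | None = None) -> pd.DataFrame:
    grid = grid or default_prior_grid()
    if pairs.empty:
        return pd.DataFrame(columns=BFCASE_COLUMNS)
    lbs, lbt, lbc = configuration_log_bfs_arrays(
        pairs["beta_T"], pairs["se_T"], pairs["beta_C"], pairs["se_C"], grid)
    calls, st, sc = call_case_arrays(lbs, lbt, lbc, params.bf_threshold,
                                     params.bf_scale)
    out = pairs[["snp_id", "individual_id", "condition"]].copy()
    cap = 700.0
    out["bf_shared"] = np.exp(np.minimum(lbs, cap))
    out["bf_treatment"] = np.exp(np.minimum(lbt, cap))
    out["bf_control"] = np.exp(np.minimum(lbc, cap))
    out["case_stat_T"], out["case_stat_C"], out["call"] = st, sc, calls
    return out[BFCASE_COLUMNS]


# ---------------------------------------------------------------------------
# stage: EDGE
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["cell_type", "condition", "r_null", "r_tc", "edge", "n_snps_null",
                "n_snps_tc", "defined"]


def stage_edge(pairs: pd.DataFrame, null_pairs: pd.DataFrame) -> pd.DataFrame:
    """EDGE index per cell type x treatment from the paired Z-scores."""
    rows = []
    for cell, nul in null_pairs.groupby("cell_type", sort=False):
        for cond, grp in pairs[pairs["cell_type"] == cell].groupby("condition",
                                                                   sort=False):
            try:
                res = edge(grp["z_T"], grp["z_C"], nul["z_T"], nul["z_C"],
                           cell_type=cell, condition=cond)
            except InsufficientDataError:
                continue
            rows.append(asdict(res))
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

RESULT_FILES = {"ase": "ase.tsv", "iase": "iase.tsv", "dast": "dast.tsv",
                "bfcase": "bfcase.tsv", "edge": "edge.tsv"}


def run_pipeline(manifest: pd.DataFrame, counts: pd.DataFrame,
                 params: PipelineParams | None = None,
                 out_dir: str | Path | None = None,
                 grid: PriorGrid | None = None) -> dict:
    """Run every stage and return the five result tables.

    Validates the manifest and the manifest/counts correspondence before any
    computation; with ``out_dir`` set, writes each table as TSV plus a
    ``run_log.json`` recording versions, parameters and per-stage row counts.
    Deterministic: identical inputs give byte-identical files.
    """
    params = params or PipelineParams()
    validate_manifest(manifest)
    missing = set(manifest["sample_id"]) - set(counts["sample_id"])
    if missing:
        raise ValidationError(f"counts lack manifest samples: {sorted(missing)}")

    models = stage_models(counts, params)
    # library depths in the manifest take precedence; fill from counts if absent
    if manifest["depth"].isna().any():
        manifest = manifest.drop(columns="depth").merge(
            models[["sample_id", "depth"]], on="sample_id")
    genotypes = stage_genotype(counts, models)
    ase = stage_ase(counts, genotypes, models, params)
    pairs, null_pairs = build_pairs(ase, manifest)
    iase = stage_iase(ase, counts, manifest, params)
    dast = delta_ast(pairs, null_pairs) if len(null_pairs) >= 30 else pd.DataFrame(
        columns=["snp_id", "individual_id", "condition", "z_delta", "p_delta",
                 "q_empirical", "is_null_pair"])
    bfcase = stage_bfcase(pairs, params, grid)
    edge_tab = stage_edge(pairs, null_pairs)

    results = {"models": models, "genotypes": genotypes, "ase": ase,
               "pairs": pairs, "null_pairs": null_pairs, "iase": iase,
               "dast": dast, "bfcase": bfcase, "edge": edge_tab}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, fname in RESULT_FILES.items():
            write_table(results[key], out / fname)
        log = {
            "casekit_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": params.seed,
            "params": {k: v for k, v in asdict(params).items()},
            "records": {k: int(len(v)) for k, v in results.items()},
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return results
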
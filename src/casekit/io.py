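"""Tab-delimited file formats and the samples manifest.

The count table is pre-tabulated from mpileup-style pileups upstream (1-based
positions, reference/alternate alleles as in VCF); alignment and mapping-bias
correction are out of scope here. Column orders are fixed so that re-written
tables are byte-identical, which the pipeline's determinism contract relies
on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

#: exact column order of the allele-count table
COUNT_COLUMNS = ["sample_id", "individual_id", "cell_type", "condition", "batch",
                 "chrom", "pos", "snp_id", "ref", "alt", "maf",
                 "ref_count", "alt_count", "other_count"]

_COUNT_INT = ["pos", "ref_count", "alt_count", "other_count"]

MANIFEST_COLUMNS = ["sample_id", "individual_id", "cell_type", "condition", "role",
                    "batch", "control_sample_id", "depth"]

ROLES = {"treatment", "CO1", "CO2"}


def read_counts_table(path) -> pd.DataFrame:
    """Read and validate an allele-count TSV.

    Raises :class:`ParseError` naming the 1-based file line for a missing
    column, malformed row, or negative count; row order is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                         dtype={"sample_id": str, "individual_id": str,
                                "snp_id": str, "chrom": str})
    except pd.errors.ParserError as exc:
        line = None
        msg = str(exc)
        if "line " in msg:
            try:
                line = int(msg.split("line ")[1].split(",")[0].split()[0])
            except (ValueError, IndexError):
                line = None
        raise ParseError(f"malformed count table {path}: {msg}", line) from exc
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"count table {path} is missing columns {missing}", line=1)
    for col in _COUNT_INT:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            raise ParseError(
                f"column {col!r} must be a non-negative integer",
                line=int(bad.idxmax()) + 2)  # +1 header, +1 one-based
        df[col] = vals.astype(np.int64)
    df["maf"] = pd.to_numeric(df["maf"], errors="coerce")
    if df["maf"].isna().any():
        raise ParseError("column 'maf' must be numeric",
                         line=int(df["maf"].isna().idxmax()) + 2)
    return df[COUNT_COLUMNS]


def write_counts_table(df: pd.DataFrame, path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual_id": str,
                                            "control_sample_id": str})
    df["control_sample_id"] = df["control_sample_id"].fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"manifest {path} is missing columns {missing}", line=1)
    return df[MANIFEST_COLUMNS]


def write_manifest(df: pd.DataFrame, path) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, sep="\t", index=False)


def validate_manifest(manifest: pd.DataFrame) -> None:
    """Check the pairing invariants of the experimental design.

    Every treatment row must reference an existing control sample of the same
    individual and batch, and every (individual, batch) cell that carries
    treatments must ship both vehicle-control sets CO1 and CO2.
    """
    bad_roles = set(manifest["role"]) - ROLES
    if bad_roles:
        raise ValidationError(f"unknown sample roles: {sorted(bad_roles)}")
    if manifest["sample_id"].duplicated().any():
        dup = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id {dup!r}")
    by_id = manifest.set_index("sample_id")
    treatments = manifest[manifest["role"] == "treatment"]
    for _, row in treatments.iterrows():
        ctrl = row["control_sample_id"]
        if not ctrl or ctrl not in by_id.index:
            raise ValidationError(
                f"treatment sample {row['sample_id']!r} references missing control "
                f"{ctrl!r}")
        crow = by_id.loc[ctrl]
        if crow["role"] not in ("CO1", "CO2"):
            raise ValidationError(f"control {ctrl!r} does not have a control role")
        if (crow["batch"] != row["batch"]
                or crow["individual_id"] != row["individual_id"]):
            raise ValidationError(
                f"treatment {row['sample_id']!r} is paired across batches or "
                f"individuals with {ctrl!r}")
    for (ind, batch), grp in treatments.groupby(["individual_id", "batch"]):
        cell = manifest[(manifest["individual_id"] == ind)
                        & (manifest["batch"] == batch)]
        roles = set(cell["role"])
        if not {"CO1", "CO2"} <= roles:
            raise ValidationError(
                f"individual {ind!r} batch {batch!r} has treatments but lacks both "
                f"vehicle controls (found roles {sorted(roles)})")


def write_table(df: pd.DataFrame, path, columns=None) -> None:
    """Write a result table with a stable column order."""
    if columns is not None:
        df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False)


def write_bed(df: pd.DataFrame, path) -> None:
    """Export called SNPs as BED (0-based half-open) for browser use."""
    bed = pd.DataFrame({
        "chrom": df["chrom"], "start": df["pos"].astype(np.int64) - 1,
        "end": df["pos"].astype(np.int64), "name": df["snp_id"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)
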
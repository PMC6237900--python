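"""Readers and writers for the package's plain-text table dialects.

Quant tables are long-format CSV with one row per measured transition per
run; clinical tables are TSV with one row per patient.  Both round-trip
through pandas with explicit dtypes so that re-reading a written table gives
back an identical frame.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

QUANT_COLUMNS = [
    "sample_id",
    "batch_id",
    "is_qc",
    "replicate_index",
    "protein_id",
    "peptide_id",
    "transition_id",
    "raw_peak_area",
    "panel",
]

CLINICAL_COLUMNS = ["patient_id", "stage", "arm", "dfs_months", "event"]

STAGE_CODES = {"1b": 1, "2": 2, "3": 3, "4": 4}


def validate_quant(quant: pd.DataFrame) -> pd.DataFrame:
    missing = set(QUANT_COLUMNS) - set(quant.columns)
    if missing:
        raise ValueError(f"quant table missing columns: {sorted(missing)}")
    if (quant["raw_peak_area"] < 0).any():
        raise ValueError("raw_peak_area must be nonnegative")
    key = ["sample_id", "peptide_id", "transition_id", "replicate_index"]
    if quant.duplicated(subset=key).any():
        raise ValueError("duplicate (sample, peptide, transition, replicate) rows")
    return quant


def read_quant(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "sample_id": str,
            "batch_id": str,
            "protein_id": str,
            "peptide_id": str,
            "transition_id": str,
            "panel": str,
        },
    )
    df["is_qc"] = df["is_qc"].astype(bool)
    df["replicate_index"] = df["replicate_index"].astype(int)
    return validate_quant(df)


def write_quant(quant: pd.DataFrame, path: str | Path) -> None:
    validate_quant(quant)
    out = quant.copy()
    out["is_qc"] = out["is_qc"].astype(int)
    out.to_csv(path, index=False)


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    missing = set(CLINICAL_COLUMNS) - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    bad = set(clinical["stage"].astype(str)) - set(STAGE_CODES)
    if bad:
        raise ValueError(f"unknown TNM stages: {sorted(bad)}")
    bad_arm = set(clinical["arm"]) - {"CTX", "CCRT"}
    if bad_arm:
        raise ValueError(f"unknown adjuvant arms: {sorted(bad_arm)}")
    return clinical


def stage_ordinal(stage: pd.Series) -> pd.Series:
    """Encode TNM stage 1b..4 as the ordinal covariate 1..4."""
    return stage.astype(str).map(STAGE_CODES).astype(int)


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "stage": str, "arm": str})
    df["dfs_months"] = df["dfs_months"].astype(float)
    df["event"] = df["event"].astype(int)
    return validate_clinical(df)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    validate_clinical(clinical)
    clinical.to_csv(path, sep="\t", index=False)
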
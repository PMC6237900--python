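"""Replicate-based QC filtering and representative-peptide selection.

Two samples per analytical batch are injected in triplicate; the coefficient
of variation of raw peak areas over those triplicates measures technical
repeatability peptide by peptide.  A peptide whose CV exceeds the threshold
in more than ``max_violations`` triplicated samples is excluded from all
downstream analysis.  Where several peptides of one protein survive, a
single representative is kept, preferring (in order) the least interference,
the lowest median replicate CV and the highest median peak area.
"""

from __future__ import annotations

import pandas as pd

DEFAULT_CV_THRESHOLD = 0.25
DEFAULT_MAX_VIOLATIONS = 5


def compute_replicate_cv(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide QC report from triplicated samples.

    Returns one row per monitored peptide with columns ``median_cv``
    (median over triplicated samples of sd/mean of the replicate raw peak
    areas, sample sd with n-1 denominator), ``n_violations`` placeholder
    counts per threshold are added by :func:`filter_peptides`, and
    ``assessable`` flagging peptides that have at least one sample with >=2
    replicate runs.  The per-(peptide, sample) CVs are attached as the
    ``cv_by_sample`` frame attribute for threshold counting.
    """
    reps = quant[quant["replicate_index"] > 0]
    peptides = quant["peptide_id"].unique()
    if len(reps) == 0:
        report = pd.DataFrame(
            {"peptide_id": peptides, "median_cv": float("nan"), "assessable": False}
        )
        report.attrs["cv_by_sample"] = pd.DataFrame(
            columns=["peptide_id", "sample_id", "cv"]
        )
        return report
    g = reps.groupby(["peptide_id", "sample_id"])["raw_peak_area"]
    agg = g.agg(["mean", "std", "count"])
    agg = agg[agg["count"] >= 2]
    cv = (agg["std"] / agg["mean"]).rename("cv").reset_index()
    med = cv.groupby("peptide_id")["cv"].median().rename("median_cv")
    report = pd.DataFrame({"peptide_id": peptides}).merge(
        med, on="peptide_id", how="left"
    )
    report["assessable"] = report["peptide_id"].isin(cv["peptide_id"])
    report.attrs["cv_by_sample"] = cv
    return report


def filter_peptides(
    report: pd.DataFrame,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    max_violations: int = DEFAULT_MAX_VIOLATIONS,
) -> set[str]:
    """Excluded peptides: CV above ``cv_threshold`` in more than
    ``max_violations`` triplicated samples (strictly more; a peptide with
    exactly ``max_violations`` offending samples is retained).  Peptides with
    no assessable triplicate are flagged in the report but never excluded.
    """
    cv = report.attrs.get("cv_by_sample")
    if cv is None:
        raise ValueError("report must come from compute_replicate_cv")
    viol = (
        cv[cv["cv"] > cv_threshold].groupby("peptide_id").size()
        if len(cv)
        else pd.Series(dtype=int)
    )
    report["n_violations"] = (
        report["peptide_id"].map(viol).fillna(0).astype(int)
    )
    report["excluded"] = report["n_violations"] > max_violations
    return set(report.loc[report["excluded"], "peptide_id"])


def select_representative_peptide(
    quant: pd.DataFrame,
    report: pd.DataFrame | None = None,
    interference: dict[str, float] | None = None,
    excluded: set[str] | None = None,
) -> tuple[dict[str, str], list[str]]:
    """One representative peptide per protein.

    Ordering is lexicographic over (interference score if supplied, median
    replicate CV, negative median peak area), ties broken by peptide id.
    Returns the protein -> peptide map and the list of proteins dropped
    because all their peptides were excluded.
    """
    excluded = excluded or set()
    if report is None:
        report = compute_replicate_cv(quant)
    med_cv = report.set_index("peptide_id")["median_cv"].to_dict()
    med_area = (
        quant.groupby("peptide_id")["raw_peak_area"].median().to_dict()
    )
    interference = interference or {}

    rep_map: dict[str, str] = {}
    dropped: list[str] = []
    for protein, sub in quant.groupby("protein_id"):
        candidates = sorted(set(sub["peptide_id"]) - excluded)
        if not candidates:
            dropped.append(protein)
            continue
        rep_map[protein] = min(
            candidates,
            key=lambda p: (
                interference.get(p, 0.0),
                med_cv.get(p, float("inf")),
                -med_area.get(p, 0.0),
                p,
            ),
        )
    return rep_map, dropped


def qc_pipeline(
    quant: pd.DataFrame,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    max_violations: int = DEFAULT_MAX_VIOLATIONS,
    interference: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str], list[str]]:
    """CV report -> exclusion -> representative selection -> filtered quant.

    Returns (filtered quant restricted to representative peptides, QC
    report, protein->peptide map, dropped proteins).
    """
    report = compute_replicate_cv(quant)
    excluded = filter_peptides(report, cv_threshold, max_violations)
    rep_map, dropped = select_representative_peptide(
        quant, report, interference, excluded
    )
    keep = set(rep_map.values())
    filtered = quant[quant["peptide_id"].isin(keep)].copy()
    return filtered, report, rep_map, dropped
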
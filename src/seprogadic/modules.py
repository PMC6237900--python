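"""Prognosis and adjuvant-therapy-selection modules.

The prognosis module (PM) predicts recurrence risk from the selected serum
proteins with TNM stage as a forced covariate.  Endpoints derive from
6-year disease-free survival: a patient recurring within 72 months has PM
endpoint 2 (event at the recurrence time), one censored earlier has
endpoint 1 (censored at the censoring time), and one event-free at 72
months has endpoint 0 (censored at the horizon).

The AT-selection module asks a different question: who benefits from which
adjuvant therapy.  For patients treated with combined chemoradiation (CCRT)
the AT endpoint equals the PM endpoint; for chemotherapy-only (CTX)
patients it is reversed (2 - PM), encoding the hypothesis that a CTX
patient who did well might have done equally well under the lighter regimen
while a CTX patient who relapsed might have been rescued by CCRT.  The
reversal maps a CTX non-recurrence to an event at the horizon and a CTX
recurrence to a censoring at the observed recurrence time.

Both modules are ordinary Cox fits on the selected features; a patient's
module score is the linear predictor, and the cohort median score splits
low- from high-risk (PM) or benefit groups (AT: CCRT patients below the
cutoff are "true CCRT", CTX patients below it "false CTX", and so on).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import stage_ordinal
from .survival import (
    CoxPH,
    CoxPHResults,
    cox_fit,
    km_estimate,
    logrank_test,
    survival_roc,
)
from .selection import SelectionResult

__all__ = [
    "assign_pm_endpoints",
    "assign_at_endpoints",
    "ModuleModel",
    "fit_module",
    "stratify",
]

HORIZON = 72.0


def assign_pm_endpoints(clinical: pd.DataFrame, horizon: float = HORIZON) -> pd.DataFrame:
    """Three-level prognosis endpoint with its derived (time, event) pair."""
    dfs = clinical["dfs_months"].to_numpy(float)
    ev = clinical["event"].to_numpy(int)
    pm = np.where((ev == 1) & (dfs <= horizon), 2, np.where(dfs < horizon, 1, 0))
    # recurrence after the horizon counts as "no recurrence within horizon"
    late = (ev == 1) & (dfs > horizon)
    pm[late] = 0
    d_time = np.where(pm == 0, horizon, dfs)
    d_event = (pm == 2).astype(int)
    return pd.DataFrame(
        {
            "patient_id": clinical["patient_id"].to_numpy(),
            "pm_endpoint": pm,
            "derived_time": d_time,
            "derived_event": d_event,
        }
    )


def assign_at_endpoints(
    endpoints: pd.DataFrame, clinical: pd.DataFrame, horizon: float = HORIZON
) -> pd.DataFrame:
    """Arm-dependent AT endpoint: identity on CCRT, reversal (2 - PM) on CTX.

    Derived pairs on the CTX arm: AT = 2 (originally event-free) becomes an
    event at the horizon; AT = 0 (originally recurred) is censored at the
    observed recurrence time; AT = 1 stays censored at the censoring time.
    """
    merged = endpoints.merge(
        clinical[["patient_id", "arm", "dfs_months"]], on="patient_id"
    )
    unknown = set(merged["arm"]) - {"CTX", "CCRT"}
    if unknown:
        raise ValueError(f"unknown treatment arms: {sorted(unknown)}")
    ctx = merged["arm"] == "CTX"
    at = np.where(ctx, 2 - merged["pm_endpoint"], merged["pm_endpoint"])
    at_time = merged["derived_time"].to_numpy(float).copy()
    at_event = merged["derived_event"].to_numpy(int).copy()
    at_time[ctx & (at == 2)] = horizon
    at_event[ctx & (at == 2)] = 1
    ctx_rev0 = ctx & (at == 0)
    at_time[ctx_rev0] = merged.loc[ctx_rev0, "dfs_months"]
    at_event[ctx_rev0] = 0
    at_event[ctx & (at == 1)] = 0
    out = endpoints.copy()
    out["at_endpoint"] = at
    out["at_time"] = at_time
    out["at_event"] = at_event
    return out


@dataclass
class ModuleModel:
    """A deployable PM or AT classifier: Cox fit, scores and median cutoff."""

    panel: str  # "MD" | "ND"
    purpose: str  # "prognosis" | "at_selection"
    features: list[str]
    fit: CoxPHResults
    scores: pd.Series  # subject -> linear predictor
    median_cutoff: float

    def score(self, X: pd.DataFrame) -> pd.Series:
        """Linear predictor for new subjects (columns must match features)."""
        return pd.Series(
            self.fit.predict_linear(X[self.fit.covariates].to_numpy()),
            index=X.index,
        )

    def summary(self) -> pd.DataFrame:
        return self.fit.summary()

    def to_tsv(self, path: str | Path) -> None:
        tab = self.summary().reset_index()
        with open(path, "w") as fh:
            fh.write(f"# panel={self.panel} purpose={self.purpose} "
                     f"median_cutoff={self.median_cutoff!r}\n")
            tab.to_csv(fh, sep="\t", index=False)


def fit_module(
    time,
    event,
    X: pd.DataFrame,
    selection: SelectionResult | list[str],
    panel: str,
    purpose: str,
    stage=None,
) -> ModuleModel:
    """Final full-data Cox fit on the selected features.

    For a prognosis module the ordinal stage covariate is prepended as the
    forced variable.  Scores are linear predictors (no baseline term); the
    median training score is stored as the classification cutoff.
    """
    selected = selection.selected if isinstance(selection, SelectionResult) else list(selection)
    design = pd.DataFrame(index=X.index)
    if stage is not None:
        design["Stage"] = np.asarray(stage, float)
    for f in selected:
        design[f] = X[f]
    if design.shape[1] == 0:
        raise ValueError("no features selected and no forced stage; nothing to fit")
    res = CoxPH(time, event, design).fit(raise_on_fail=True)
    scores = pd.Series(res.predict_linear(design.to_numpy()), index=X.index)
    return ModuleModel(
        panel=panel,
        purpose=purpose,
        features=selected,
        fit=res,
        scores=scores,
        median_cutoff=float(scores.median()),
    )


def _group_eval(time, event, low_mask) -> dict:
    """KM/log-rank/HR comparison of a low- vs high-risk split."""
    n_low, n_high = int(low_mask.sum()), int((~low_mask).sum())
    out = {
        "n_low": n_low,
        "n_high": n_high,
        "events_low": int(event[low_mask].sum()),
        "events_high": int(event[~low_mask].sum()),
        "logrank_p": np.nan,
        "hr_low_vs_high": np.nan,
    }
    if n_low == 0 or n_high == 0:
        return out
    stat, p = logrank_test(time[low_mask], event[low_mask],
                           time[~low_mask], event[~low_mask])
    out["logrank_p"] = p
    try:
        fit = cox_fit(time, event, low_mask.astype(float)[:, None], names=["low"])
        if fit.converged:
            out["hr_low_vs_high"] = float(fit.hazard_ratios[0])
    except (ValueError, np.linalg.LinAlgError):
        pass
    return out


def stratify(
    module: ModuleModel,
    clinical: pd.DataFrame,
    endpoints: pd.DataFrame,
    horizon: float = HORIZON,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-split risk assignment plus its survival evaluation.

    Prognosis modules split at the median PM score (low: score <= cutoff)
    and are evaluated overall and per TNM stage on the derived PM endpoint:
    Kaplan-Meier groups, log-rank p, low-vs-high hazard ratio, and the
    6-year time-dependent AUC of the score with sensitivity/specificity at
    the cutoff.  AT modules cross the median split with the actual arm into
    tCCRT/fCCRT/tCTX/fCTX and are evaluated on observed DFS.

    Returns (assignments, evaluation) tables.
    """
    merged = clinical.merge(endpoints, on="patient_id")
    scores = module.scores.to_numpy()
    if np.ptp(scores) == 0:
        raise ValueError("all module scores identical; median split degenerate")
    cutoff = module.median_cutoff

    if module.purpose == "prognosis":
        time = merged["derived_time"].to_numpy(float)
        event = merged["derived_event"].to_numpy(int)
        low = scores <= cutoff
        assignments = pd.DataFrame(
            {
                "patient_id": merged["patient_id"],
                "score": scores,
                "risk_group": np.where(low, "low", "high"),
            }
        )
        rows = []
        strata = [("all", np.ones(len(merged), bool))] + [
            (f"stage_{s}", (merged["stage"] == s).to_numpy()) for s in ["1b", "2", "3", "4"]
        ]
        for name, mask in strata:
            res = _group_eval(time[mask], event[mask], low[mask])
            res["stratum"] = name
            if name == "all":
                roc = survival_roc(scores, time, event, t=horizon)
                res["auc"] = roc.auc
                i = int(np.searchsorted(roc.cutoffs, cutoff, side="right") - 1)
                i = max(i, 0)
                res["sensitivity_at_cutoff"] = float(roc.sensitivity[i])
                res["specificity_at_cutoff"] = float(roc.specificity[i])
            rows.append(res)
        evaluation = pd.DataFrame(rows).set_index("stratum").reset_index()
        return assignments, evaluation

    if module.purpose != "at_selection":
        raise ValueError(f"unknown module purpose {module.purpose!r}")
    below = scores < cutoff
    ccrt = (merged["arm"] == "CCRT").to_numpy()
    group = np.where(
        ccrt,
        np.where(below, "tCCRT", "fCCRT"),
        np.where(below, "fCTX", "tCTX"),
    )
    assignments = pd.DataFrame(
        {
            "patient_id": merged["patient_id"],
            "score": scores,
            "treatment_group": group,
        }
    )
    # evaluation on observed DFS; fCTX is the poor-prognosis reference
    time = merged["dfs_months"].to_numpy(float)
    event = ((merged["event"] == 1) & (merged["dfs_months"] <= horizon)).astype(int).to_numpy()
    time = np.minimum(time, horizon)
    rows = []
    for g in ["tCCRT", "fCCRT", "tCTX", "fCTX"]:
        mask = group == g
        row = {
            "group": g,
            "n": int(mask.sum()),
            "events": int(event[mask].sum()),
            "logrank_p_vs_fCTX": np.nan,
            "hr_fCTX_vs_group": np.nan,
        }
        if g != "fCTX" and mask.sum() > 0 and (group == "fCTX").sum() > 0:
            ref = group == "fCTX"
            _, p = logrank_test(time[mask], event[mask], time[ref], event[ref])
            row["logrank_p_vs_fCTX"] = p
            both = mask | ref
            try:
                fit = cox_fit(
                    time[both], event[both], ref[both].astype(float)[:, None],
                    names=["fCTX"],
                )
                if fit.converged:
                    row["hr_fCTX_vs_group"] = float(fit.hazard_ratios[0])
            except (ValueError, np.linalg.LinAlgError):
                pass
        rows.append(row)
    evaluation = pd.DataFrame(rows)
    return assignments, evaluation
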
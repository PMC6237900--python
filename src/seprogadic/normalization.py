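"""Endogenous-protein normalization of MRM peak areas.

Instrument response drifts over a multi-batch LC-MRM-MS campaign.  The drift
is estimated per run from a set of endogenous normalizing peptides (NPs):
each NP's raw area is divided by its cohort-wide median, and the median of
those ratios is the run's normalization scaling factor (NSF).  Because
ionization response is not perfectly proportional for every peptide, a
per-peptide exponent beta is estimated as the slope of log2(peak area) on
log2(NSF) across the pooled QC runs (identical material, so any systematic
area change is pure drift), and the corrected abundance is

    corrected = raw_area / NSF ** beta

which reduces to plain NSF division at beta = 1 and inverts the generative
drift model exactly in the noise-free limit.

NP candidates are screened before selection: a candidate must be detected in
every sample, must not differ between the three prognostic outcome groups
(one-way ANOVA), must track the spiked exogenous control (Pearson r > 0.5 —
both respond to the same drift), and the survivors are ranked by a
NormFinder-style stability score (intra-group variance plus squared
inter-group deviation on the log scale; lower is more stable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizationModel",
    "outcome_groups",
    "screen_np_candidates",
    "compute_nsf",
    "normalize",
    "estimate_beta",
    "beta_correct",
]


def sample_peptide_areas(quant: pd.DataFrame) -> pd.DataFrame:
    """Wide matrix of raw peak areas, samples x peptides.

    Triplicate runs of a sample are averaged so every sample contributes one
    value per peptide.
    """
    return quant.pivot_table(
        index="sample_id", columns="peptide_id", values="raw_peak_area",
        aggfunc="mean",
    )


def outcome_groups(clinical: pd.DataFrame, horizon: float = 72.0) -> pd.Series:
    """Three prognostic outcome groups used by the NP screen.

    ``recurred``: recurrence within the horizon; ``censored``: censored
    before the horizon; ``no_recurrence``: event-free at the horizon.
    """
    rec = (clinical["event"] == 1) & (clinical["dfs_months"] <= horizon)
    cens = (clinical["event"] == 0) & (clinical["dfs_months"] < horizon)
    out = pd.Series("no_recurrence", index=clinical.index)
    out[rec] = "recurred"
    out[cens] = "censored"
    return out


@dataclass
class NormalizationModel:
    """Selected NPs with their cohort medians, per-sample NSFs and betas."""

    selected_nps: list[str]
    peptide_medians: dict[str, float]
    nsf: dict[str, float]
    beta: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        rows = [("np", p, self.peptide_medians[p]) for p in self.selected_nps]
        rows += [("nsf", s, v) for s, v in self.nsf.items()]
        rows += [("beta", p, v) for p, v in self.beta.items()]
        pd.DataFrame(rows, columns=["kind", "key", "value"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalizationModel":
        df = pd.read_csv(path, sep="\t", dtype={"key": str})
        nps = df[df["kind"] == "np"]
        return cls(
            selected_nps=list(nps["key"]),
            peptide_medians=dict(zip(nps["key"], nps["value"])),
            nsf=dict(zip(*df[df["kind"] == "nsf"][["key", "value"]].T.values)),
            beta=dict(zip(*df[df["kind"] == "beta"][["key", "value"]].T.values)),
        )


def stability_score(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """NormFinder-style stability on log2 areas; lower = more stable.

    score^2 = sum_g w_g [ (m_g - m)^2 + v_g ]  with group weights
    w_g = n_g / n, group means m_g and within-group variances v_g.
    """
    log_vals = np.log2(values)
    scores = {}
    n = len(log_vals)
    for pep in log_vals.columns:
        col = log_vals[pep]
        total = 0.0
        m = col.mean()
        for _, sub in col.groupby(groups):
            w = len(sub) / n
            v = sub.var(ddof=1) if len(sub) > 1 else 0.0
            total += w * ((sub.mean() - m) ** 2 + v)
        scores[pep] = float(np.sqrt(total))
    return pd.Series(scores, name="stability")


def screen_np_candidates(
    quant: pd.DataFrame,
    clinical: pd.DataFrame,
    candidates: list[str],
    spike_protein: str,
    anova_alpha: float = 0.05,
    min_pearson: float = 0.5,
    n_select: int = 5,
    horizon: float = 72.0,
) -> tuple[pd.DataFrame, list[str]]:
    """Screen and rank NP candidate peptides; return (report, selected).

    ``candidates`` are peptide ids.  A candidate passes when it is (1)
    detected (area > 0) in every clinical sample, (2) indistinguishable
    between the three outcome groups (ANOVA p >= ``anova_alpha``), and (3)
    correlated with the spiked exogenous control (Pearson r > ``min_pearson``).
    Survivors are ranked ascending by stability; the top ``n_select`` are
    selected.
    """
    clin_quant = quant[~quant["is_qc"]]
    areas = sample_peptide_areas(clin_quant)
    clin = clinical.set_index("patient_id").loc[areas.index]
    groups = outcome_groups(clin, horizon)

    spike_peps = quant.loc[quant["protein_id"] == spike_protein, "peptide_id"].unique()
    if len(spike_peps) == 0:
        raise ValueError(f"spiked control protein {spike_protein!r} not in quant table")
    spike_mean = areas[list(spike_peps)].mean(axis=1)

    rows = []
    for pep in candidates:
        present = pep in areas.columns
        vals = areas[pep] if present else None
        detected = bool(present and vals.notna().all() and (vals > 0).all())
        if detected:
            by_group = [vals[groups == g] for g in groups.unique()]
            anova_p = float(stats.f_oneway(*by_group).pvalue)
            pearson_r = float(stats.pearsonr(vals, spike_mean).statistic)
        else:
            anova_p, pearson_r = np.nan, np.nan
        passes = (
            detected and anova_p >= anova_alpha and pearson_r > min_pearson
        )
        rows.append(
            {
                "peptide_id": pep,
                "detected_in_all": detected,
                "anova_p": anova_p,
                "pearson_r": pearson_r,
                "passes": passes,
            }
        )
    report = pd.DataFrame(rows)
    survivors = report.loc[report["passes"], "peptide_id"].tolist()
    if len(survivors) < n_select:
        raise ValueError(
            f"only {len(survivors)} NP candidates pass the screen but "
            f"{n_select} are required; relax anova_alpha/min_pearson or "
            "provide more candidates"
        )
    stab = stability_score(areas[survivors], groups)
    report = report.merge(
        stab.rename("stability"), left_on="peptide_id", right_index=True, how="left"
    )
    ranked = stab.sort_values(kind="stable")
    selected = list(ranked.index[:n_select])
    report = report.sort_values(
        ["passes", "stability"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return report, selected


def compute_nsf(quant: pd.DataFrame, nps: list[str]) -> NormalizationModel:
    """Per-sample NSF: median over the selected NPs of area / cohort median.

    Every sample (clinical and QC alike) must carry all selected NPs; a
    missing measurement is an error, not an imputation target.
    """
    areas = sample_peptide_areas(quant)
    missing_pep = [p for p in nps if p not in areas.columns]
    if missing_pep:
        raise ValueError(f"NP peptides absent from quant table: {missing_pep}")
    sub = areas[nps]
    if sub.isna().any().any():
        bad = sub.index[sub.isna().any(axis=1)].tolist()
        raise ValueError(f"samples missing NP measurements: {bad[:5]}")
    medians = sub.median(axis=0)
    ratios = sub / medians
    nsf = ratios.median(axis=1)
    return NormalizationModel(
        selected_nps=list(nps),
        peptide_medians={p: float(medians[p]) for p in nps},
        nsf={s: float(v) for s, v in nsf.items()},
    )


def _nsf_series(quant: pd.DataFrame, model: NormalizationModel) -> pd.Series:
    nsf = quant["sample_id"].map(model.nsf)
    if nsf.isna().any():
        bad = quant.loc[nsf.isna(), "sample_id"].unique()
        raise ValueError(f"no NSF for samples: {list(bad)[:5]}")
    return nsf


def normalize(quant: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """Divide each raw peak area by its sample's NSF (``normalized_area``)."""
    out = quant.copy()
    out["normalized_area"] = out["raw_peak_area"] / _nsf_series(quant, model)
    return out


def estimate_beta(
    quant: pd.DataFrame,
    model: NormalizationModel,
    clamp: tuple[float, float] = (0.5, 2.0),
) -> NormalizationModel:
    """Per-peptide ionization exponent from the pooled QC runs.

    beta_j is the OLS slope of log2(peak area) on log2(NSF) across QC runs;
    the QC material is identical in every batch, so the slope isolates how
    strongly peptide j's response follows the overall drift.  Slopes are
    expected very close to one and are clamped to ``clamp`` (with a warning)
    to guard against degenerate fits on ten points.  If all QC NSFs coincide
    the slope is undefined and beta falls back to 1.
    """
    qc = quant[quant["is_qc"]]
    if qc.empty:
        raise ValueError("no QC runs in quant table")
    areas = sample_peptide_areas(qc)
    nsf = np.array([model.nsf[s] for s in areas.index])
    if len(nsf) < 3:
        raise ValueError("beta estimation needs at least 3 QC runs")
    x = np.log2(nsf)
    beta: dict[str, float] = {}
    degenerate = np.ptp(x) == 0
    if degenerate:
        warnings.warn("all QC NSFs identical; falling back to beta = 1")
    xc = x - x.mean()
    denom = float(xc @ xc)
    for pep in areas.columns:
        if degenerate:
            beta[pep] = 1.0
            continue
        y = np.log2(areas[pep].to_numpy())
        b = float(xc @ (y - y.mean()) / denom)
        if not clamp[0] <= b <= clamp[1]:
            warnings.warn(
                f"beta for {pep} = {b:.3f} outside {clamp}; clamped"
            )
            b = float(np.clip(b, *clamp))
        beta[pep] = b
    model.beta = beta
    return model


def beta_correct(quant: pd.DataFrame, model: NormalizationModel) -> pd.DataFrame:
    """Beta-corrected normalized areas: raw / NSF ** beta (``corrected_area``)."""
    nsf = _nsf_series(quant, model)
    if (nsf <= 0).any():
        raise ValueError("NSF must be positive for beta correction")
    beta = quant["peptide_id"].map(model.beta)
    if beta.isna().any():
        missing = quant.loc[beta.isna(), "peptide_id"].unique()
        raise ValueError(f"no beta for peptides: {list(missing)[:5]}")
    out = quant.copy()
    out["corrected_area"] = out["raw_peak_area"] / nsf ** beta
    return out
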
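"""End-to-end orchestration: QC -> normalization -> endpoints -> selection
-> module fitting -> stratification, with reproducible file outputs.

Every stage writes a plain-text table to the output directory; a
``run_info.yaml`` sidecar records the configuration, seed and package
version so a rerun with the same config reproduces every number.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_quant, read_clinical, stage_ordinal, write_quant
from .qc import qc_pipeline
from .normalization import (
    screen_np_candidates,
    compute_nsf,
    estimate_beta,
    beta_correct,
)
from .modules import assign_pm_endpoints, assign_at_endpoints, fit_module, stratify
from .selection import SelectionConfig, StabilitySelector
from .survival import survival_roc, optimal_cutoff, logrank_test

log = logging.getLogger("seprogadic")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "protein_matrix"]


@dataclass
class PipelineConfig:
    quant_path: str | None = None
    clinical_path: str | None = None
    outdir: str | None = None
    panels: tuple[str, ...] = ("MD", "ND")
    purposes: tuple[str, ...] = ("prognosis", "at_selection")
    spike_protein: str = "SPIKE_BGAL"
    np_prefix: str = "NP"  # protein-id prefix identifying NP candidates
    np_candidates: list[str] | None = None  # peptide ids; overrides prefix
    cv_threshold: float = 0.25
    max_violations: int = 5
    anova_alpha: float = 0.05
    min_pearson: float = 0.5
    n_nps: int = 5
    horizon: float = 72.0
    univariate_horizons: tuple[float, ...] = (24.0, 36.0, 48.0, 60.0, 72.0)
    n_folds: int = 8
    n_iterations: int = 500
    alpha: float = 0.05
    min_fold_hits: int = 4
    z_threshold: float = 1.96
    seed: int = 0

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: PipelineConfig
    qc_report: pd.DataFrame
    rep_map: dict[str, str]
    np_report: pd.DataFrame
    selected_nps: list[str]
    norm_model: object
    corrected: pd.DataFrame
    protein_matrix: pd.DataFrame  # patients x proteins, z-scored log2
    endpoints: pd.DataFrame
    univariate: pd.DataFrame
    selections: dict  # (panel, purpose) -> SelectionResult
    modules: dict  # (panel, purpose) -> ModuleModel
    stratifications: dict  # (panel, purpose) -> (assignments, evaluation)


def protein_matrix(
    corrected: pd.DataFrame,
    clinical: pd.DataFrame,
    standardize: bool = True,
) -> pd.DataFrame:
    """Patients x proteins matrix of log2 beta-corrected abundances.

    Replicate runs are averaged; values are log2-transformed and (by
    default) z-scored per protein so Cox coefficients read as log-hazard
    per standard deviation of log2 abundance.
    """
    clin = corrected[~corrected["is_qc"]]
    mat = clin.pivot_table(
        index="sample_id", columns="protein_id", values="corrected_area",
        aggfunc="mean",
    )
    mat = np.log2(mat)
    if standardize:
        mat = (mat - mat.mean()) / mat.std(ddof=1)
    return mat.loc[clinical["patient_id"]]


def run_pipeline(
    config: PipelineConfig,
    quant: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
) -> PipelineResult:
    """Execute the full analysis; stage failures raise stage-named errors.

    ``quant``/``clinical`` may be passed in memory; otherwise they are read
    from the configured paths.
    """
    if quant is None:
        if config.quant_path is None:
            raise ValueError("stage=load: no quant table or path given")
        quant = read_quant(config.quant_path)
    if clinical is None:
        if config.clinical_path is None:
            raise ValueError("stage=load: no clinical table or path given")
        clinical = read_clinical(config.clinical_path)

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "run_info.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "version": __version__,
                    "seed": config.seed,
                    "config_hash": config.config_hash(),
                    "config": asdict(config),
                },
                fh,
                sort_keys=True,
            )

    # --- QC ---------------------------------------------------------------
    log.info("stage=qc: replicate CV filter and representative selection")
    filtered, qc_report, rep_map, dropped = qc_pipeline(
        quant, config.cv_threshold, config.max_violations
    )
    if dropped:
        log.warning("stage=qc: dropped proteins with no retained peptide: %s", dropped)

    # --- normalization ----------------------------------------------------
    log.info("stage=normalization: NP screen, NSF, beta correction")
    if config.np_candidates is not None:
        candidates = list(config.np_candidates)
    else:
        candidates = sorted(
            quant.loc[
                quant["protein_id"].str.startswith(config.np_prefix), "peptide_id"
            ].unique()
        )
    if not candidates:
        raise ValueError("stage=normalization: no NP candidate peptides found")
    np_report, selected_nps = screen_np_candidates(
        quant,
        clinical,
        candidates,
        config.spike_protein,
        anova_alpha=config.anova_alpha,
        min_pearson=config.min_pearson,
        n_select=config.n_nps,
        horizon=config.horizon,
    )
    norm_model = compute_nsf(quant, selected_nps)
    norm_model = estimate_beta(quant, norm_model)
    biomarker_mask = filtered["panel"].isin(config.panels) & ~filtered[
        "protein_id"
    ].str.startswith(config.np_prefix) & (filtered["protein_id"] != config.spike_protein)
    corrected = beta_correct(filtered[biomarker_mask], norm_model)

    mat = protein_matrix(corrected, clinical)
    panel_of = corrected.drop_duplicates("protein_id").set_index("protein_id")["panel"]

    # --- endpoints --------------------------------------------------------
    log.info("stage=endpoints: PM and AT endpoint coding")
    endpoints = assign_pm_endpoints(clinical, config.horizon)
    endpoints = assign_at_endpoints(endpoints, clinical, config.horizon)
    stage = stage_ordinal(clinical["stage"]).to_numpy()

    # --- univariate screen ------------------------------------------------
    log.info("stage=univariate: per-protein time-dependent ROC")
    pm_time = endpoints["derived_time"].to_numpy()
    pm_event = endpoints["derived_event"].to_numpy()
    uni_rows = []
    for prot in mat.columns:
        marker = mat[prot].to_numpy()
        row = {"protein_id": prot, "panel": panel_of.get(prot, "")}
        for t in config.univariate_horizons:
            try:
                roc = survival_roc(marker, pm_time, pm_event, t)
                row[f"auc_{int(t)}m"] = roc.auc
            except ValueError:
                row[f"auc_{int(t)}m"] = np.nan
        try:
            roc72 = survival_roc(marker, pm_time, pm_event, config.horizon)
            cut = optimal_cutoff(roc72)
            lowm = marker <= cut
            if 0 < lowm.sum() < len(lowm):
                _, p = logrank_test(
                    pm_time[lowm], pm_event[lowm], pm_time[~lowm], pm_event[~lowm]
                )
                row["cutoff"] = cut
                row["logrank_p"] = p
        except ValueError:
            pass
        uni_rows.append(row)
    univariate = pd.DataFrame(uni_rows)

    # --- selection + modules + stratification -----------------------------
    selections, modules_, strats = {}, {}, {}
    for panel in config.panels:
        prots = [p for p in mat.columns if panel_of.get(p) == panel]
        X = mat[prots]
        for purpose in config.purposes:
            key = (panel, purpose)
            log.info("stage=selection: panel=%s purpose=%s", panel, purpose)
            if purpose == "prognosis":
                t_arr, e_arr = pm_time, pm_event
                force = True
            else:
                t_arr = endpoints["at_time"].to_numpy()
                e_arr = endpoints["at_event"].to_numpy()
                force = False
            sel_cfg = SelectionConfig(
                n_folds=config.n_folds,
                n_iterations=config.n_iterations,
                alpha=config.alpha,
                min_fold_hits=config.min_fold_hits,
                z_threshold=config.z_threshold,
                force_stage=force,
                seed=config.seed
                + 1000 * (config.panels.index(panel) + 1)
                + (0 if purpose == "prognosis" else 7),
            )
            selector = StabilitySelector(
                t_arr, e_arr, X, stage=stage if force else None
            )
            sel = selector.fit(sel_cfg)
            selections[key] = sel
            log.info(
                "stage=selection: panel=%s purpose=%s selected=%s",
                panel, purpose, sel.selected,
            )
            if not sel.selected and purpose != "prognosis":
                log.warning("stage=module: empty AT panel for %s; skipped", panel)
                continue
            module = fit_module(
                t_arr,
                e_arr,
                X,
                sel,
                panel=panel,
                purpose=purpose,
                stage=stage if purpose == "prognosis" else None,
            )
            modules_[key] = module
            strats[key] = stratify(module, clinical, endpoints, config.horizon)

    result = PipelineResult(
        config=config,
        qc_report=qc_report,
        rep_map=rep_map,
        np_report=np_report,
        selected_nps=selected_nps,
        norm_model=norm_model,
        corrected=corrected,
        protein_matrix=mat,
        endpoints=endpoints,
        univariate=univariate,
        selections=selections,
        modules=modules_,
        stratifications=strats,
    )
    if outdir:
        _write_outputs(result, outdir)
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    result.qc_report.drop(columns=[], errors="ignore").to_csv(
        outdir / "qc_report.tsv", sep="\t", index=False
    )
    result.np_report.to_csv(outdir / "np_screen.tsv", sep="\t", index=False)
    result.norm_model.to_tsv(outdir / "normalization_model.tsv")
    result.corrected.to_csv(outdir / "corrected_quant.csv", index=False)
    result.endpoints.to_csv(outdir / "endpoints.tsv", sep="\t", index=False)
    result.univariate.to_csv(outdir / "univariate_auc.tsv", sep="\t", index=False)
    for (panel, purpose), sel in result.selections.items():
        sel.table.to_csv(
            outdir / f"selection_{panel}_{purpose}.tsv", sep="\t", index=False
        )
    for (panel, purpose), module in result.modules.items():
        module.to_tsv(outdir / f"module_{panel}_{purpose}.tsv")
    for (panel, purpose), (assign, ev) in result.stratifications.items():
        assign.to_csv(
            outdir / f"assignments_{panel}_{purpose}.tsv", sep="\t", index=False
        )
        ev.to_csv(outdir / f"evaluation_{panel}_{purpose}.tsv", sep="\t", index=False)
        from .plotting import plot_km_groups

        merged = result.endpoints
        group_col = "risk_group" if purpose == "prognosis" else "treatment_group"
        plot_km_groups(
            merged["derived_time"],
            merged["derived_event"],
            assign[group_col],
            outdir / f"km_{panel}_{purpose}.svg",
            title=f"{panel} {purpose}",
        )
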
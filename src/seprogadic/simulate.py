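"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a 227-patient gastric-cancer serum cohort measured by
targeted MRM in 10 analytical batches.  Each batch carries one pooled QC run
(equal-volume mix of every patient serum) and 21-24 clinical runs; two
randomly chosen samples per batch are injected in triplicate.  Raw peak
areas follow

    PA_{j,s} = A_{p(j),s} * NSF_s ** beta_j * exp(technical noise)

where A is the lognormal biological abundance, NSF_s the multiplicative
instrument drift of run s (batch-level mean shift plus run-level jitter on
the log2 scale) and beta_j a per-peptide ionization response exponent.
Disease-free survival is exponential under a log-linear proportional-hazards
model driven by TNM stage and a handful of truly prognostic proteins, with
uniform random censoring and administrative censoring at 72 months.  The
ground truth (protein effects, per-run NSF, per-peptide beta) is recorded so
recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import validate_clinical, validate_quant, stage_ordinal

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_clinical",
    "generate_quant",
    "simulate_cohort",
]

SPIKE_PROTEIN = "SPIKE_BGAL"

STAGES = ["1b", "2", "3", "4"]
ARMS = ["CTX", "CCRT"]


@dataclass
class SimulationConfig:
    """Study-design and generative parameters of the synthetic cohort.

    Defaults mirror the emulated study: 227 patients in 10 batches, stage
    mix 1b/2/3/4 = 58/88/61/20, 107 CTX vs 120 CCRT, 73 MD-panel and 20
    ND-panel representative proteins, 15 NP candidates plus a constant
    exogenous spike.  Hazard parameters are chosen so that roughly 44
    patients recur within 72 months, 80 are censored earlier and the rest
    reach the horizon event-free.
    """

    n_patients: int = 227
    n_batches: int = 10
    stage_probs: tuple[float, ...] = (0.2555, 0.3877, 0.2687, 0.0881)
    arm_probs: tuple[float, float] = (0.4714, 0.5286)  # (CTX, CCRT)
    n_md_proteins: int = 73
    n_nd_proteins: int = 20
    n_np_candidates: int = 15
    n_true_prognostic: int = 3
    effect_sizes: tuple[float, ...] = (0.7, 0.6, -0.6)  # per sd of log2 abundance
    stage_coef: float = 0.5  # log-hazard per stage step
    baseline_hazard: float = 0.0009  # events/month at stage covariate 0
    admin_censor_months: float = 72.0
    censor_frac: float = 0.45  # fraction with uniform (0, 72] censoring time
    batch_drift_sd: float = 0.25  # log2 scale, batch-level mean shift
    beta_range: tuple[float, float] = (0.8, 1.2)
    technical_cv: float = 0.07
    biological_sd: float = 1.0  # log2 scale, biomarker proteins
    np_biological_sd: float = 0.15  # log2 scale, NP candidates
    n_np_confounded: int = 2  # NP candidates tied to disease severity
    np_confound_scale: float = 0.4
    spike_area: float = 1.0e6
    n_triplicate_per_batch: int = 2
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        for name, probs in (("stage_probs", self.stage_probs), ("arm_probs", self.arm_probs)):
            if abs(sum(probs) - 1.0) > 1e-8 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be nonnegative and sum to 1")
        if len(self.stage_probs) != 4 or len(self.arm_probs) != 2:
            raise ValueError("stage_probs needs 4 entries, arm_probs 2")
        if min(self.batch_drift_sd, self.technical_cv, self.biological_sd,
               self.np_biological_sd) < 0:
            raise ValueError("spreads and CVs must be nonnegative")
        if self.n_true_prognostic > self.n_md_proteins:
            raise ValueError("n_true_prognostic cannot exceed n_md_proteins")
        if len(self.effect_sizes) != self.n_true_prognostic:
            raise ValueError("effect_sizes must have n_true_prognostic entries")
        if self.admin_censor_months <= 0:
            raise ValueError("admin_censor_months must be positive")
        if self.n_np_confounded > self.n_np_candidates:
            raise ValueError("n_np_confounded cannot exceed n_np_candidates")
        return self


@dataclass
class SyntheticCohort:
    """Simulated quant + clinical tables plus the generative ground truth."""

    quant: pd.DataFrame
    clinical: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .io import write_quant, write_clinical

        write_quant(self.quant, outdir / "quant.csv")
        write_clinical(self.clinical, outdir / "clinical.tsv")
        truth = {
            "effects": self.truth["effects"],
            "beta": self.truth["beta"],
            "nsf": self.truth["nsf"],
            "np_candidates": self.truth["np_candidates"],
            "np_confounded": self.truth["np_confounded"],
            "spike_protein": self.truth["spike_protein"],
        }
        with open(outdir / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)


def _protein_ids(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    md = [f"MD{i:03d}" for i in range(1, config.n_md_proteins + 1)]
    nd = [f"ND{i:03d}" for i in range(1, config.n_nd_proteins + 1)]
    nps = [f"NP{i:02d}" for i in range(1, config.n_np_candidates + 1)]
    return md, nd, nps


def generate_clinical(config: SimulationConfig) -> pd.DataFrame:
    """Draw stage, arm and proportional-hazards survival outcomes.

    DFS times are exponential with hazard
    ``h0 * exp(stage_coef * stage + sum_k effect_k * z_k)`` where ``z_k`` is
    the standardized log2 abundance of the k-th truly prognostic protein
    (drawn here, reused by :func:`generate_quant`).  Treatment arm is
    assigned independently of everything, emulating a randomized trial.
    Uniform censoring on (0, 72] hits a ``censor_frac`` subset; everyone is
    administratively censored at the horizon.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_patients
    ids = [f"P{i:03d}" for i in range(1, n + 1)]
    stage = rng.choice(STAGES, size=n, p=np.asarray(config.stage_probs))
    arm = rng.choice(ARMS, size=n, p=np.asarray(config.arm_probs))
    z = rng.standard_normal((n, config.n_true_prognostic))
    stage_ord = pd.Series(stage).map({"1b": 1, "2": 2, "3": 3, "4": 4}).to_numpy()
    lp = config.stage_coef * stage_ord + z @ np.asarray(config.effect_sizes)
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    horizon = config.admin_censor_months
    c = np.where(
        rng.random(n) < config.censor_frac,
        rng.uniform(0.0, horizon, size=n),
        np.inf,
    )
    t_obs = np.minimum(np.minimum(t_event, c), horizon)
    event = (t_event <= np.minimum(c, horizon)).astype(int)
    clinical = pd.DataFrame(
        {
            "patient_id": ids,
            "stage": stage,
            "arm": arm,
            "dfs_months": t_obs,
            "event": event,
        }
    )
    # plain lists: DataFrame.attrs must stay comparable with ==
    clinical.attrs["latent_z"] = z.tolist()
    clinical.attrs["linear_predictor"] = lp.tolist()
    return validate_clinical(clinical)


def _batch_sizes(n: int, n_batches: int) -> list[int]:
    base, extra = divmod(n, n_batches)
    return [base + (1 if i < extra else 0) for i in range(n_batches)]


def generate_quant(config: SimulationConfig, clinical: pd.DataFrame) -> SyntheticCohort:
    """Raw MRM peak areas for every run of every batch, plus ground truth.

    One representative peptide and one quantitative transition per protein.
    The QC sample's biological abundance is the pooled (linear-scale) mean
    of all patients.  Replicate injections of a triplicated sample share the
    run drift and differ only by technical noise.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    md, nd, nps = _protein_ids(config)
    proteins = md + nd + nps + [SPIKE_PROTEIN]
    panels = (
        ["MD"] * len(md) + ["ND"] * len(nd) + ["ND"] * len(nps) + ["ND"]
    )
    n_prot = len(proteins)
    n = len(clinical)

    if "latent_z" not in clinical.attrs:
        raise ValueError("clinical table must come from generate_clinical")
    z_true = np.asarray(clinical.attrs["latent_z"], dtype=float)
    lp = np.asarray(clinical.attrs["linear_predictor"], dtype=float)

    # biological abundances on log2 scale
    mu = rng.uniform(14.0, 22.0, size=n_prot)
    log2_a = np.empty((n, n_prot))
    for k in range(n_prot):
        pid = proteins[k]
        if pid in md and md.index(pid) < config.n_true_prognostic:
            zk = z_true[:, md.index(pid)]
            sd = config.biological_sd
        elif pid in nps:
            zk = rng.standard_normal(n)
            sd = config.np_biological_sd
        elif pid == SPIKE_PROTEIN:
            log2_a[:, k] = np.log2(config.spike_area)
            continue
        else:
            zk = rng.standard_normal(n)
            sd = config.biological_sd
        log2_a[:, k] = mu[k] + sd * zk
    # a few NP candidates track disease severity and must fail the screen
    lp_c = lp - lp.mean()
    for j in range(config.n_np_confounded):
        k = proteins.index(nps[j])
        log2_a[:, k] += config.np_confound_scale * lp_c

    abundance = 2.0 ** log2_a
    qc_abundance = abundance.mean(axis=0)  # pooled equal-volume mix

    beta = rng.uniform(*config.beta_range, size=n_prot)
    peptides = [f"{p}_PEP1" for p in proteins]
    transitions = [f"{p}_PEP1.y7" for p in proteins]

    # assign patients to batches and pick triplicated samples
    order = rng.permutation(n)
    sizes = _batch_sizes(n, config.n_batches)
    pat_ids = clinical["patient_id"].to_numpy()
    sigma = np.sqrt(np.log1p(config.technical_cv**2))

    rows_sample, rows_batch, rows_qc, rows_rep, rows_nsf = [], [], [], [], []
    pos = 0
    nsf_truth: dict[str, float] = {}
    for b in range(config.n_batches):
        batch_id = f"B{b + 1:02d}"
        members = order[pos: pos + sizes[b]]
        pos += sizes[b]
        batch_shift = rng.normal(0.0, config.batch_drift_sd)
        trip = rng.choice(members, size=min(config.n_triplicate_per_batch, len(members)), replace=False)
        trip_set = set(trip.tolist())
        # QC run first, then clinical runs
        runs = [("QC", f"QC{b + 1:02d}", 0)]
        for m in members:
            reps = (1, 2, 3) if m in trip_set else (0,)
            runs.append(("S", pat_ids[m], reps))
        for kind, sid, reps in runs:
            run_shift = rng.normal(0.0, config.batch_drift_sd / 2.0)
            nsf = float(2.0 ** (batch_shift + run_shift))
            nsf_truth[sid] = nsf
            rep_list = (0,) if kind == "QC" else reps
            for r in rep_list:
                rows_sample.append(sid)
                rows_batch.append(batch_id)
                rows_qc.append(kind == "QC")
                rows_rep.append(r)
                rows_nsf.append(nsf)

    n_runs = len(rows_sample)
    sample_arr = np.array(rows_sample)
    nsf_arr = np.array(rows_nsf)
    # abundance rows per run
    pat_index = {p: i for i, p in enumerate(pat_ids)}
    ab_rows = np.empty((n_runs, n_prot))
    for i, sid in enumerate(rows_sample):
        ab_rows[i] = qc_abundance if sid.startswith("QC") else abundance[pat_index[sid]]
    noise = np.exp(rng.normal(0.0, sigma, size=(n_runs, n_prot))) if sigma > 0 else 1.0
    raw = ab_rows * nsf_arr[:, None] ** beta[None, :] * noise

    quant = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_arr, n_prot),
            "batch_id": np.repeat(np.array(rows_batch), n_prot),
            "is_qc": np.repeat(np.array(rows_qc), n_prot),
            "replicate_index": np.repeat(np.array(rows_rep), n_prot),
            "protein_id": np.tile(np.array(proteins), n_runs),
            "peptide_id": np.tile(np.array(peptides), n_runs),
            "transition_id": np.tile(np.array(transitions), n_runs),
            "raw_peak_area": raw.ravel(),
            "panel": np.tile(np.array(panels), n_runs),
        }
    )
    validate_quant(quant)

    effects = {
        md[k]: float(config.effect_sizes[k]) for k in range(config.n_true_prognostic)
    }
    truth = {
        "effects": effects,
        "stage_coef": float(config.stage_coef),
        "beta": {peptides[k]: float(beta[k]) for k in range(n_prot)},
        "nsf": nsf_truth,
        "abundance": pd.DataFrame(abundance, index=pat_ids, columns=proteins),
        "qc_abundance": pd.Series(qc_abundance, index=proteins),
        "np_candidates": [f"{p}_PEP1" for p in nps],
        "np_confounded": [f"{p}_PEP1" for p in nps[: config.n_np_confounded]],
        "spike_protein": SPIKE_PROTEIN,
        "md_proteins": md,
        "nd_proteins": nd,
    }
    return SyntheticCohort(quant=quant, clinical=clinical, truth=truth)


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> SyntheticCohort:
    """Convenience wrapper: clinical then quant from one config."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    clinical = generate_clinical(config)
    return generate_quant(config, clinical)
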
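"""Cross-validated Cox stability selection with a binomial stopping rule.

Candidate proteins are repeatedly subjected to 8-fold cross-validated Cox
backward elimination: in each of ``n_iterations`` random fold partitions,
every 7/8 training split is reduced by backward elimination (Wald p > 0.05),
and a protein scores an iteration-level observation (N.O.) when it survives
in at least ``min_fold_hits`` of the 8 folds.  Proteins are ranked by N.O.;
the size of the final panel is set by comparing each rank's N.O. against
what random feature draws would produce: if ``s`` of ``n`` features were
picked at random per fold, a given feature appears in four or more of eight
folds with probability

    p_s = sum_{i=4..8} C(8, i) (s/n)^i ((n-s)/n)^(8-i)

and across 500 iterations the normal-approximation statistic

    Z = (N.O.(s) - 500 p_s) / sqrt(500 p_s (1 - p_s))

must reach 1.96 (one-sided 97.5% confidence) for the rank-s feature to
enter the panel; the panel is the longest prefix of the ranking in which
every rank passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survival import backward_eliminate

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "StabilitySelector",
    "binomial_selection_prob",
    "z_statistic",
    "run_selection",
]


def binomial_selection_prob(s: int, n: int, n_folds: int = 8, min_hits: int = 4) -> float:
    """Probability a random size-``s``-of-``n`` draw repeats a given feature
    in at least ``min_hits`` of ``n_folds`` folds."""
    if not 1 <= s <= n:
        raise ValueError(f"rank s={s} must be in 1..n={n}")
    return float(stats.binom.sf(min_hits - 1, n_folds, s / n))


def z_statistic(observed: float, p_s: float, n_iterations: int = 500) -> float:
    """Normal-approximation excess of N.O. over the random-draw expectation."""
    if not 0.0 < p_s < 1.0:
        raise ValueError("p_s must be strictly between 0 and 1")
    mu = n_iterations * p_s
    sd = np.sqrt(n_iterations * p_s * (1.0 - p_s))
    return float((observed - mu) / sd)


@dataclass
class SelectionConfig:
    n_folds: int = 8
    n_iterations: int = 500
    alpha: float = 0.05
    min_fold_hits: int = 4
    z_threshold: float = 1.96
    force_stage: bool = True
    seed: int = 0

    def validate(self) -> "SelectionConfig":
        if self.min_fold_hits > self.n_folds:
            raise ValueError("min_fold_hits cannot exceed n_folds")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        return self


@dataclass
class SelectionResult:
    """Observation counts, ranking, per-rank p_s and Z, and the panel."""

    table: pd.DataFrame  # columns: feature, n_obs, rank, p_s, z
    selected: list[str]
    n_panel: int
    config: SelectionConfig
    n_nonconverged_folds: int = 0

    def summary(self) -> pd.DataFrame:
        return self.table.copy()


class StabilitySelector:
    """Model-style wrapper: construct with data, ``fit`` runs the selection.

    Parameters
    ----------
    time, event : array-like
        Derived survival endpoint (months, event flag).
    X : DataFrame, subjects x candidate proteins.
    stage : Series or None
        Ordinal stage covariate, forced into every fold model when the
        config says so and excluded from the protein ranking.
    """

    STAGE_COL = "stage"

    def __init__(self, time, event, X: pd.DataFrame, stage=None):
        self.time = np.asarray(time, float)
        self.event = np.asarray(event, int)
        self.X = X.reset_index(drop=True)
        self.stage = None if stage is None else np.asarray(stage, float)
        if self.STAGE_COL in self.X.columns:
            raise ValueError("X must not contain a 'stage' column; pass stage=")

    def _fold_assignment(self, rng: np.random.Generator, n_folds: int) -> np.ndarray:
        """Random partition stratified by the event indicator."""
        n = len(self.time)
        folds = np.empty(n, dtype=int)
        for flag in (0, 1):
            idx = np.flatnonzero(self.event == flag)
            rng.shuffle(idx)
            folds[idx] = np.arange(len(idx)) % n_folds
        return folds

    def fit(self, config: SelectionConfig | None = None, **overrides) -> SelectionResult:
        config = (config or SelectionConfig(**overrides)).validate()
        proteins = list(self.X.columns)
        n_panel = len(proteins)
        design = self.X.copy()
        forced: list[str] = []
        if config.force_stage:
            if self.stage is None:
                raise ValueError("force_stage=True but no stage covariate given")
            design[self.STAGE_COL] = self.stage
            forced = [self.STAGE_COL]
        n_obs = {p: 0 for p in proteins}
        bad_folds = 0
        for it in range(config.n_iterations):
            rng = np.random.default_rng([config.seed, 7919, it])
            folds = self._fold_assignment(rng, config.n_folds)
            hits = {p: 0 for p in proteins}
            for f in range(config.n_folds):
                train = folds != f
                if self.event[train].sum() == 0:
                    bad_folds += 1
                    continue
                retained, fit = backward_eliminate(
                    self.time[train],
                    self.event[train],
                    design.loc[train],
                    forced=forced,
                    alpha=config.alpha,
                )
                if fit is not None and not fit.converged:
                    bad_folds += 1  # counted as non-selection for every protein
                    continue
                for p in retained:
                    if p != self.STAGE_COL:
                        hits[p] += 1
            for p in proteins:
                if hits[p] >= config.min_fold_hits:
                    n_obs[p] += 1

        order = sorted(proteins, key=lambda p: (-n_obs[p], p))
        rows = []
        selected: list[str] = []
        still_prefix = True
        for rank, p in enumerate(order, start=1):
            p_s = binomial_selection_prob(
                rank, n_panel, config.n_folds, config.min_fold_hits
            )
            z = (
                z_statistic(n_obs[p], p_s, config.n_iterations)
                if 0.0 < p_s < 1.0
                else np.nan
            )
            if still_prefix and np.isfinite(z) and z >= config.z_threshold:
                selected.append(p)
            else:
                still_prefix = False
            rows.append(
                {"feature": p, "n_obs": n_obs[p], "rank": rank, "p_s": p_s, "z": z}
            )
        table = pd.DataFrame(rows)
        table["selected"] = table["feature"].isin(selected)
        return SelectionResult(
            table=table,
            selected=selected,
            n_panel=n_panel,
            config=config,
            n_nonconverged_folds=int(bad_folds),
        )


def run_selection(
    time,
    event,
    X: pd.DataFrame,
    stage=None,
    config: SelectionConfig | None = None,
    **overrides,
) -> SelectionResult:
    """Functional entry point over :class:`StabilitySelector`."""
    return StabilitySelector(time, event, X, stage=stage).fit(config, **overrides)
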
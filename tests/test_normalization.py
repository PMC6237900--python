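"""NP screening, NSF computation, beta estimation and correction."""

import numpy as np
import pandas as pd
import pytest

from seprogadic.normalization import (
    NormalizationModel,
    beta_correct,
    compute_nsf,
    estimate_beta,
    normalize,
    outcome_groups,
    sample_peptide_areas,
    screen_np_candidates,
    stability_score,
)
from seprogadic.simulate import SimulationConfig, simulate_cohort


def _quant(records):
    df = pd.DataFrame(records, columns=["sample_id", "peptide_id", "raw_peak_area"])
    df["batch_id"] = "B01"
    df["is_qc"] = df["sample_id"].str.startswith("QC")
    df["replicate_index"] = 0
    df["protein_id"] = df["peptide_id"].str.split("_").str[0]
    df["transition_id"] = df["peptide_id"] + ".y7"
    df["panel"] = "ND"
    return df


class TestNSF:
    def test_median_of_listed_ratios(self):
        # NP ratios (0.5, 0.8, 1.0, 1.2, 2.0) -> NSF = 1.0
        nps = [f"NP{i}_pep" for i in range(5)]
        ratios = [0.5, 0.8, 1.0, 1.2, 2.0]
        records = []
        # three reference samples at the median, one test sample at the ratios
        for s in ["S1", "S2", "S3"]:
            records += [(s, p, 1000.0) for p in nps]
        records += [("S4", p, 1000.0 * r) for p, r in zip(nps, ratios)]
        model = compute_nsf(_quant(records), nps)
        assert model.nsf["S4"] == pytest.approx(1.0)
        assert model.nsf["S1"] == pytest.approx(1.0)

    def test_identity_sample_has_unit_nsf(self):
        nps = [f"NP{i}_pep" for i in range(5)]
        rng = np.random.default_rng(0)
        records = []
        for s in range(7):
            for p in nps:
                records.append((f"S{s}", p, float(rng.uniform(500, 2000))))
        q = _quant(records)
        model = compute_nsf(q, nps)
        # a synthetic sample sitting exactly at each peptide's median
        extra = [(f"S99", p, model.peptide_medians[p]) for p in nps]
        model2 = compute_nsf(pd.concat([q, _quant(extra)]), nps)
        assert model2.nsf["S99"] == pytest.approx(1.0)

    def test_homogeneity_under_sample_rescaling(self):
        nps = [f"NP{i}_pep" for i in range(5)]
        rng = np.random.default_rng(1)
        records = [
            (f"S{s:03d}", p, float(rng.uniform(500, 2000)))
            for s in range(101)
            for p in nps
        ]
        q = _quant(records)
        base = compute_nsf(q, nps)
        c = 3.7
        q2 = q.copy()
        mask = q2["sample_id"] == "S000"
        q2.loc[mask, "raw_peak_area"] *= c
        scaled = compute_nsf(q2, nps)
        # the cohort medians barely move with 101 samples, so the rescaled
        # sample's NSF tracks the factor c almost exactly
        assert scaled.nsf["S000"] / base.nsf["S000"] == pytest.approx(c, rel=0.03)
        # and exactly when the reference medians are held fixed
        areas = sample_peptide_areas(q)
        ratios = (areas.loc["S000"] * c) / pd.Series(base.peptide_medians)
        assert np.median(ratios) == pytest.approx(c * base.nsf["S000"], rel=1e-12)

    def test_median_ratio_property_is_one(self, small_cohort):
        quant = small_cohort.quant
        nps = sorted(
            quant.loc[quant["protein_id"].str.startswith("NP"), "peptide_id"].unique()
        )[:5]
        model = compute_nsf(quant, nps)
        areas = sample_peptide_areas(quant)
        for p in nps:
            ratios = areas[p] / model.peptide_medians[p]
            assert np.median(ratios) == pytest.approx(1.0, abs=1e-12)

    def test_missing_np_measurement_is_an_error(self):
        nps = [f"NP{i}_pep" for i in range(5)]
        records = [("S1", p, 100.0) for p in nps]
        records += [("S2", p, 100.0) for p in nps[:4]]  # one NP missing
        with pytest.raises(ValueError, match="missing NP"):
            compute_nsf(_quant(records), nps)


class TestNormalize:
    def _model(self, nsf):
        return NormalizationModel(
            selected_nps=["NP_pep"], peptide_medians={"NP_pep": 1.0}, nsf=nsf
        )

    def test_unit_nsf_is_identity(self):
        q = _quant([("S1", "A_pep", 2000.0)])
        out = normalize(q, self._model({"S1": 1.0}))
        assert out["normalized_area"].iloc[0] == 2000.0

    def test_direct_division(self):
        q = _quant([("S1", "A_pep", 2000.0)])
        out = normalize(q, self._model({"S1": 2.0}))
        assert out["normalized_area"].iloc[0] == 1000.0

    def test_sample_wide_factor_cancels(self):
        nps = [f"NP{i}_pep" for i in range(5)]
        rng = np.random.default_rng(2)
        records = [
            (f"S{s}", p, float(rng.uniform(500, 2000)))
            for s in range(30)
            for p in nps
        ]
        records += [(f"S{s}", "A_pep", 1000.0) for s in range(30)]
        q = _quant(records)
        c = 2.5
        q2 = q.copy()
        q2.loc[q2["sample_id"] == "S3", "raw_peak_area"] *= c
        n1 = normalize(q, compute_nsf(q, nps))
        n2 = normalize(q2, compute_nsf(q2, nps))
        a1 = n1[(n1["sample_id"] == "S3") & (n1["peptide_id"] == "A_pep")]
        a2 = n2[(n2["sample_id"] == "S3") & (n2["peptide_id"] == "A_pep")]
        # with 30 samples one rescaled sample barely moves the medians
        assert a2["normalized_area"].iloc[0] == pytest.approx(
            a1["normalized_area"].iloc[0], rel=0.02
        )


class TestBeta:
    def _qc_quant(self, nsfs, law):
        records = []
        for i, nsf in enumerate(nsfs):
            records.append((f"QC{i:02d}", "A_pep", law(nsf)))
        q = _quant(records)
        model = NormalizationModel(
            selected_nps=[], peptide_medians={},
            nsf={f"QC{i:02d}": float(v) for i, v in enumerate(nsfs)},
        )
        return q, model

    def test_proportional_gives_unit_slope(self):
        nsfs = [0.7, 0.9, 1.0, 1.1, 1.4]
        q, model = self._qc_quant(nsfs, lambda v: 1000.0 * v)
        model = estimate_beta(q, model)
        assert model.beta["A_pep"] == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_law_gives_slope_two(self):
        nsfs = [0.7, 0.9, 1.0, 1.1, 1.4]
        q, model = self._qc_quant(nsfs, lambda v: 1000.0 * v**2)
        model = estimate_beta(q, model)
        assert model.beta["A_pep"] == pytest.approx(2.0, abs=1e-10)

    def test_identical_nsfs_fall_back_to_one(self):
        q, model = self._qc_quant([1.0, 1.0, 1.0], lambda v: 1000.0)
        with pytest.warns(UserWarning, match="identical"):
            model = estimate_beta(q, model)
        assert model.beta["A_pep"] == 1.0

    def test_outside_clamp_warns(self):
        nsfs = [0.5, 1.0, 2.0]
        q, model = self._qc_quant(nsfs, lambda v: 1000.0 * v**3)
        with pytest.warns(UserWarning, match="clamped"):
            model = estimate_beta(q, model)
        assert model.beta["A_pep"] == 2.0

    def test_recovery_on_generative_truth(self):
        cfg = SimulationConfig(
            n_patients=100, n_batches=10, n_md_proteins=20, n_nd_proteins=10,
            effect_sizes=(0.5,) * 3, technical_cv=0.01, seed=21,
        )
        cohort = simulate_cohort(cfg)
        quant = cohort.quant
        nsf_truth = cohort.truth["nsf"]
        model = NormalizationModel(
            selected_nps=[], peptide_medians={},
            nsf={s: nsf_truth[s] for s in quant.loc[quant["is_qc"], "sample_id"].unique()},
        )
        model = estimate_beta(quant[quant["is_qc"]], model)
        errs = [
            abs(model.beta[p] - cohort.truth["beta"][p]) for p in model.beta
        ]
        assert np.mean(np.array(errs) <= 0.05) >= 0.95


class TestBetaCorrect:
    def test_reduces_to_plain_normalization_at_unit_beta(self):
        q = _quant([("S1", "A_pep", 2000.0)])
        model = NormalizationModel(
            selected_nps=[], peptide_medians={}, nsf={"S1": 2.0},
            beta={"A_pep": 1.0},
        )
        out = beta_correct(q, model)
        assert out["corrected_area"].iloc[0] == 1000.0

    def test_square_root_beta_example(self):
        # 4000 / 4**0.5 = 2000
        q = _quant([("S1", "A_pep", 4000.0)])
        model = NormalizationModel(
            selected_nps=[], peptide_medians={}, nsf={"S1": 4.0},
            beta={"A_pep": 0.5},
        )
        assert beta_correct(q, model)["corrected_area"].iloc[0] == 2000.0

    def test_nonpositive_nsf_rejected(self):
        q = _quant([("S1", "A_pep", 4000.0)])
        model = NormalizationModel(
            selected_nps=[], peptide_medians={}, nsf={"S1": 0.0},
            beta={"A_pep": 1.0},
        )
        with pytest.raises(ValueError, match="positive"):
            beta_correct(q, model)

    def test_generative_round_trip_noise_free(self, noise_free_cohort):
        cohort = noise_free_cohort
        quant = cohort.quant[~cohort.quant["is_qc"]]
        model = NormalizationModel(
            selected_nps=[], peptide_medians={},
            nsf=cohort.truth["nsf"],
            beta=cohort.truth["beta"],
        )
        out = beta_correct(quant, model)
        truth_ab = cohort.truth["abundance"]
        got = out.pivot_table(
            index="sample_id", columns="protein_id", values="corrected_area",
            aggfunc="mean",
        )
        expect = truth_ab.loc[got.index, got.columns]
        assert np.allclose(got.to_numpy(), expect.to_numpy(), rtol=1e-9)

    def test_qc_variance_shrinks_after_correction(self, small_cohort):
        quant = small_cohort.quant
        nps = sorted(
            quant.loc[quant["protein_id"].str.startswith("NP"), "peptide_id"].unique()
        )[:5]
        model = estimate_beta(quant, compute_nsf(quant, nps))
        qc = beta_correct(quant[quant["is_qc"]], model)
        for pep, sub in qc.groupby("peptide_id"):
            raw_var = np.var(np.log2(sub["raw_peak_area"]))
            cor_var = np.var(np.log2(sub["corrected_area"]))
            if raw_var > 1e-6:
                assert cor_var < raw_var


class TestScreen:
    def test_screen_on_synthetic_cohort(self, small_cohort):
        quant, clinical = small_cohort.quant, small_cohort.clinical
        candidates = sorted(set(small_cohort.truth["np_candidates"]))
        report, selected = screen_np_candidates(
            quant, clinical, candidates, small_cohort.truth["spike_protein"]
        )
        assert len(selected) == 5
        # NPs planted with a disease-severity shift must not be selected
        confounded = set(small_cohort.truth["np_confounded"])
        assert not (set(selected) & confounded)

    def test_absent_candidate_fails_detection(self, small_cohort):
        quant = small_cohort.quant
        cand = small_cohort.truth["np_candidates"][0]
        # remove one clinical measurement of the candidate
        pat = small_cohort.clinical["patient_id"].iloc[0]
        drop = quant[(quant["peptide_id"] == cand) & (quant["sample_id"] == pat)]
        q2 = quant.drop(drop.index)
        report, _ = screen_np_candidates(
            q2, small_cohort.clinical,
            sorted(set(small_cohort.truth["np_candidates"])),
            small_cohort.truth["spike_protein"],
        )
        row = report.set_index("peptide_id").loc[cand]
        assert not row["detected_in_all"] and not row["passes"]

    def test_too_few_survivors_raises(self, small_cohort):
        with pytest.raises(ValueError, match="relax"):
            screen_np_candidates(
                small_cohort.quant, small_cohort.clinical,
                sorted(set(small_cohort.truth["np_candidates"]))[:4],
                small_cohort.truth["spike_protein"], min_pearson=0.999,
            )

    def test_stability_ranks_flat_np_above_shifted(self):
        rng = np.random.default_rng(3)
        n = 90
        groups = pd.Series(["recurred", "censored", "no_recurrence"] * 30)
        flat = 1000.0 * 2 ** rng.normal(0, 0.05, n)
        shifted = 1000.0 * 2 ** (
            rng.normal(0, 0.05, n) + groups.map(
                {"recurred": 0.5, "censored": 0.0, "no_recurrence": -0.5}
            ).to_numpy()
        )
        vals = pd.DataFrame({"flat_pep": flat, "shifted_pep": shifted})
        scores = stability_score(vals, groups)
        assert scores["flat_pep"] < scores["shifted_pep"]

    def test_outcome_grouping_definition(self):
        clin = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c", "d"],
                "stage": ["2"] * 4,
                "arm": ["CTX"] * 4,
                "dfs_months": [30.0, 50.0, 72.0, 72.0],
                "event": [1, 0, 0, 0],
            }
        )
        g = outcome_groups(clin)
        assert list(g) == ["recurred", "censored", "no_recurrence", "no_recurrence"]

    def test_model_tsv_round_trip(self, tmp_path, small_cohort):
        quant = small_cohort.quant
        nps = sorted(
            quant.loc[quant["protein_id"].str.startswith("NP"), "peptide_id"].unique()
        )[:5]
        model = estimate_beta(quant, compute_nsf(quant, nps))
        model.to_tsv(tmp_path / "m.tsv")
        back = NormalizationModel.from_tsv(tmp_path / "m.tsv")
        assert back.selected_nps == model.selected_nps
        assert back.nsf == pytest.approx(model.nsf)
        assert back.beta == pytest.approx(model.beta)
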
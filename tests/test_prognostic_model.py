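"""Published score model, stepwise AIC development, tertile grouping."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from immunoprog.prognostic_model import (
    ScoreModel,
    ScoreTerm,
    assign_groups,
    compute_score,
    cox_fit,
    derive_tertile_cutoffs,
    forward_stepwise_aic,
    load_model,
    null_cox_log_likelihood,
    published_her2event,
    save_model,
    score_frame,
    standardize_evenness,
)
from immunoprog.synthetic_data import CohortSimConfig, make_noise_features, simulate_cohort
from immunoprog.features import encode_clinical_frame


def patient(evenness_std=0.0, tils=0.0, pcr=0.0, hr=0.0, cn0=0.0):
    return {
        "bcr_evenness_std": evenness_std,
        "tils": tils,
        "pcr_breast": pcr,
        "hr": hr,
        "cn0": cn0,
    }


class TestPublishedModel:
    def test_frozen_constants(self):
        m = published_her2event()
        coefs = {t.variable: t.coefficient for t in m.terms}
        assert coefs == {
            "bcr_evenness_std": 0.300436587,
            "tils": -0.024107504,
            "pcr_breast": -0.568111234,
            "hr": -0.525011259,
            "cn0": -0.504914127,
        }
        assert (m.cutoff_good, m.cutoff_mid) == (-1.3763, -0.8143)
        assert (m.evenness_center, m.evenness_scale) == (0.7917893, 0.1004482)
        assert m.provenance == "published"

    @pytest.mark.parametrize("suffix", ["yaml", "json"])
    def test_serialization_roundtrip(self, tmp_path, suffix):
        m = published_her2event()
        path = tmp_path / f"model.{suffix}"
        save_model(m, path)
        assert load_model(path) == m

    def test_invalid_cutoff_order_rejected(self):
        with pytest.raises(ValueError):
            ScoreModel(terms=(ScoreTerm("x", 1.0),), cutoff_good=1.0, cutoff_mid=0.0)


class TestComputeScore:
    def test_all_zero_covariates(self):
        assert compute_score(patient(), published_her2event()) == 0.0

    def test_worked_example(self):
        score = compute_score(patient(tils=20.0, pcr=1.0, hr=1.0, cn0=1.0),
                              published_her2event())
        assert score == pytest.approx(-2.0801867, abs=1e-7)

    def test_single_covariate_differences(self):
        m = published_her2event()
        base = compute_score(patient(tils=10.0, hr=1.0), m)
        with_pcr = compute_score(patient(tils=10.0, hr=1.0, pcr=1.0), m)
        assert with_pcr - base == pytest.approx(-0.568111234, abs=1e-12)

    def test_missing_term_gives_nan(self):
        feats = patient()
        feats["tils"] = float("nan")
        assert np.isnan(compute_score(feats, published_her2event()))

    def test_score_frame_standardizes_raw_evenness(self):
        m = published_her2event()
        df = pd.DataFrame(
            [patient(tils=12.0, hr=1.0) | {"bcr_evenness": 0.7917893}]
        ).drop(columns="bcr_evenness_std")
        expected = compute_score(patient(tils=12.0, hr=1.0), m)
        assert score_frame(df, m).iloc[0] == pytest.approx(expected)

    def test_identical_patients_identical_scores(self):
        m = published_her2event()
        df = pd.DataFrame([patient(0.4, 22.0, 1.0, 0.0, 1.0)] * 2)
        scores = score_frame(df, m)
        assert scores.iloc[0] == scores.iloc[1]

    def test_standardize_evenness_constants(self):
        m = published_her2event()
        assert standardize_evenness(0.7917893, m) == pytest.approx(0.0, abs=1e-12)
        assert standardize_evenness(0.8922375, m) == pytest.approx(1.0, abs=1e-9)


class TestTertiles:
    def test_one_to_nine(self):
        lo, hi = derive_tertile_cutoffs(np.arange(1.0, 10.0))
        assert lo == pytest.approx(11.0 / 3.0)
        assert hi == pytest.approx(19.0 / 3.0)

    def test_degenerate_all_equal(self):
        lo, hi = derive_tertile_cutoffs([2.0, 2.0, 2.0, 2.0])
        assert lo == hi == 2.0
        groups = assign_groups(
            pd.Series([2.0, 2.0]),
            ScoreModel(terms=(ScoreTerm("x", 1.0),), cutoff_good=lo, cutoff_mid=hi),
        )
        assert (groups["group"] == "good").all()  # <= rule

    def test_boundary_scores(self):
        m = published_her2event()
        groups = assign_groups(
            pd.Series([-1.3763, -1.3762, -0.8143, -0.8142]), m
        )
        assert list(groups["group"]) == ["good", "poor", "poor", "poor"]
        assert list(groups["tertile"]) == [1, 2, 2, 3]

    def test_group_assignment_monotone_in_risk(self):
        """Raising the hazard-increasing evenness covariate can only move a
        patient toward the poor group, never out of it."""
        m = published_her2event()
        grid = np.linspace(-3, 3, 61)
        scores = score_frame(
            pd.DataFrame([patient(e, 15.0, 1.0, 1.0, 1.0) for e in grid]), m
        )
        labels = assign_groups(scores, m)["group"].to_list()
        first_poor = labels.index("poor") if "poor" in labels else len(labels)
        assert all(lab == "good" for lab in labels[:first_poor])
        assert all(lab == "poor" for lab in labels[first_poor:])


class TestCoxFit:
    def test_null_model_closed_form(self):
        # textbook: times 1,2,3 all events -> logPL = -(log3 + log2)
        ll = null_cox_log_likelihood([1.0, 2.0, 3.0], [1, 1, 1])
        assert ll == pytest.approx(-(np.log(3) + np.log(2)))
        fit = cox_fit(pd.DataFrame(index=range(3)), [1.0, 2.0, 3.0], [1, 1, 1])
        assert fit.aic == pytest.approx(-2.0 * ll)

    def test_matches_lifelines_oracle(self, rng):
        """Coefficients, SEs and log partial likelihood agree with an
        independent engine, with and without tied event times."""
        for tie in (False, True):
            X = pd.DataFrame(rng.normal(size=(250, 3)), columns=list("abc"))
            beta = np.array([0.5, -0.3, 0.0])
            t = rng.exponential(1.0 / np.exp(X.to_numpy() @ beta))
            if tie:
                t = np.ceil(t * 6) / 6
            t = np.maximum(t, 1e-9)
            e = (rng.random(250) < 0.7).astype(int)
            mine = cox_fit(X, t, e)
            df = X.copy()
            df["_t"], df["_e"] = t, e
            cph = CoxPHFitter()
            cph.fit(df, "_t", "_e")
            assert np.allclose(mine.coefficients, cph.params_, atol=1e-6)
            assert np.allclose(mine.standard_errors, cph.standard_errors_, atol=1e-6)
            assert mine.log_likelihood == pytest.approx(float(cph.log_likelihood_), abs=1e-6)

    def test_recovers_binary_log_hazard(self, rng):
        n, beta = 800, 0.8
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0 / (0.2 * np.exp(beta * x)))
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, dtype=int))
        est, se = fit.coefficients["x"], fit.standard_errors["x"]
        assert abs(est - beta) < 3 * se

    def test_constant_covariate_rejected(self, rng):
        X = pd.DataFrame({"x": np.ones(50)})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(X, rng.exponential(1, 50), np.ones(50, dtype=int))

    def test_separation_flagged_not_raised(self):
        # perfectly separating covariate: early deaths all x=1
        t = np.concatenate([np.arange(1, 21), np.arange(31, 51)]).astype(float)
        x = np.concatenate([np.ones(20), np.zeros(20)])
        fit = cox_fit(pd.DataFrame({"x": x}), t, np.ones(40, dtype=int))
        assert not fit.converged
        assert fit.aic == np.inf


class TestForwardStepwise:
    @staticmethod
    def _dev_data(seed, n=500, noise=3):
        clinical, _ = simulate_cohort(CohortSimConfig(seed=seed, n_patients=n))
        feats = encode_clinical_frame(clinical)
        m = published_her2event()
        feats["bcr_evenness_std"] = standardize_evenness(feats["bcr_evenness"], m)
        nz = make_noise_features(n, noise, seed=seed + 1)
        nz.index = feats.index
        return pd.concat([feats, nz], axis=1)

    def test_strong_variable_selected_first(self, rng):
        n = 400
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.3 * np.exp(1.2 * x)))
        X = pd.DataFrame({"noise_a": rng.normal(size=n), "signal": x,
                          "noise_b": rng.normal(size=n)})
        trace = forward_stepwise_aic(list(X.columns), X, t, np.ones(n, dtype=int))
        assert trace.steps[0][0] == "signal"

    def test_aic_strictly_decreasing_and_reproducible(self):
        X = self._dev_data(seed=11)
        pool = ["bcr_evenness_std", "tils", "pcr_breast", "hr", "cn0",
                "noise_01", "noise_02", "noise_03"]
        t1 = forward_stepwise_aic(pool, X, X["efs_time"], X["efs_event"])
        aics = [t1.null_aic] + [a for _, a in t1.steps]
        assert all(b < a for a, b in zip(aics, aics[1:]))
        t2 = forward_stepwise_aic(pool, X, X["efs_time"], X["efs_event"])
        assert t1.steps == t2.steps
        assert t1.final_aic == t2.final_aic

    def test_empty_pool_returns_null_trace(self, rng):
        t = rng.exponential(1, 50)
        trace = forward_stepwise_aic([], pd.DataFrame(index=range(50)), t,
                                     np.ones(50, dtype=int))
        assert trace.steps == [] and trace.final_variables == ()
        assert trace.final_aic == trace.null_aic

    def test_pure_noise_pool_selects_few(self):
        """Forward AIC on independent noise admits some false inclusions but
        the selected set stays small relative to the pool."""
        rng = np.random.default_rng(99)
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"noise_{i:02d}" for i in range(10)])
        t = rng.exponential(2.0, n)
        e = (rng.random(n) < 0.7).astype(int)
        trace = forward_stepwise_aic(list(X.columns), X, t, e)
        assert len(trace.final_variables) <= 4
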
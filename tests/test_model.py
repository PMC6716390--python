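import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lexacq import (GroundTruth, ModelSpec, build_design, category_contrasts,
                    compose_category_effects, fit_glmm,
                    fit_logistic_trajectory, generate_administrations,
                    generate_lexicon, latent_predictor_table,
                    summarize_coefficients)
from lexacq.model import CoefficientTable
from lexacq.simulate import CATEGORIES


def _study(n_items=60, n_children=300, seed=0, **truth_kw):
    items = generate_lexicon(n_items, seed=seed, languages=["L"])
    truth = GroundTruth.build(["L"], **truth_kw)
    adm = generate_administrations(items, truth, n_children, (8, 30),
                                   "production", "L", seed=seed + 1)
    return items, adm, latent_predictor_table(items, "L")


class TestContrasts:
    def test_deviation_columns_sum_to_zero_over_levels(self):
        cats = pd.Series(list(CATEGORIES))
        C = category_contrasts(cats, coding="deviation")
        assert C.shape == (4, 3)
        assert C.sum(axis=0).to_numpy() == pytest.approx(np.zeros(3))

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            category_contrasts(pd.Series(["Nouns", "Verbs"]))


class TestBuildDesign:
    def test_full_interaction_column_count(self):
        items, adm, table = _study(n_items=200, n_children=50)
        spec = ModelSpec(measure="production")
        d = build_design(adm, table, spec)
        # intercept + age + 9 + 9x age + 27 category interactions + 3 contrasts
        assert d.X.shape[1] == 50
        assert len(d.colnames) == 50

    def test_no_interaction_column_count(self):
        items, adm, table = _study(n_items=40, n_children=50)
        spec = ModelSpec(measure="production",
                         include_age_interactions=False,
                         include_category_interactions=False)
        d = build_design(adm, table, spec)
        assert d.colnames == ["(Intercept)", "age"] + list(table.data.columns[:9])

    def test_binomial_aggregation_preserves_totals(self):
        items, adm, table = _study(n_items=30, n_children=80)
        spec = ModelSpec(measure="production",
                         include_age_interactions=False,
                         include_category_interactions=False)
        d = build_design(adm, table, spec)
        prod = adm[adm["measure"] == "production"]
        assert d.trials.sum() == len(prod)
        assert d.successes.sum() == prod["value"].sum()

    def test_unscaled_table_rejected(self):
        items, adm, table = _study(n_items=20, n_children=20)
        table.scaling = {}
        with pytest.raises(ValueError):
            build_design(adm, table, ModelSpec(measure="production"))

    def test_thin_category_cells_rejected_for_interactions(self):
        items, adm, table = _study(n_items=30, n_children=20)
        with pytest.raises(ValueError, match="categor"):
            build_design(adm, table, ModelSpec(measure="production"))


class TestCodingInvariance:
    def test_fitted_probabilities_and_cell_effects_match(self):
        """Deviation and treatment coding are reparametrizations: plain
        logistic fits must give identical fitted probabilities and
        identical per-category cell slopes/intercepts."""
        items, adm, table = _study(n_items=250, n_children=60, seed=3)
        fits = {}
        for coding in ("deviation", "treatment"):
            spec = ModelSpec(measure="production", category_coding=coding,
                             include_age_interactions=False)
            d = build_design(adm, table, spec)
            res = sm.GLM(np.column_stack([d.successes,
                                          d.trials - d.successes]),
                         d.X, family=sm.families.Binomial()).fit()
            fits[coding] = (d, res)
        d_dev, r_dev = fits["deviation"]
        d_tr, r_tr = fits["treatment"]
        np.testing.assert_allclose(r_dev.predict(d_dev.X),
                                   r_tr.predict(d_tr.X), atol=1e-6)
        name = {n: i for i, n in enumerate(d_dev.colnames)}
        for cat in ("Nouns", "Predicates", "Function Words"):
            for p in ("frequency", "mlu_w"):
                slope_dev = (r_dev.params[name[p]]
                             + r_dev.params[name[f"{p}:cat_{cat}"]])
                slope_tr = (r_tr.params[name[p]]
                            + r_tr.params[name[f"{p}:cat_{cat}"]])
                assert slope_dev == pytest.approx(slope_tr, abs=1e-6)


class TestTrajectory:
    # noiseless proportions legitimately trigger statsmodels'
    # perfect-prediction warning; the MLE is still what we assert
    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings(
        "ignore:Perfect separation or prediction detected")
    def test_recovers_generating_curve(self):
        ages = np.arange(8, 31, dtype=float)
        p = 1 / (1 + np.exp(-(-6.0 + 0.4 * ages)))
        trials = np.full_like(ages, 1e6)
        b0, b1, _ = fit_logistic_trajectory(ages, p * trials, trials)
        assert b0 == pytest.approx(-6.0, abs=1e-3)
        assert b1 == pytest.approx(0.4, abs=1e-3)

    @pytest.mark.filterwarnings(
        "ignore:Perfect separation or prediction detected")
    def test_flat_data_zero_slope(self):
        ages = np.arange(10, 20, dtype=float)
        trials = np.full_like(ages, 1000.0)
        _, slope, _ = fit_logistic_trajectory(ages, 0.5 * trials, trials)
        assert slope == pytest.approx(0.0, abs=1e-8)

    def test_decreasing_proportions_negative_slope(self):
        ages = np.array([10.0, 15.0, 20.0, 25.0])
        succ = np.array([90.0, 70.0, 40.0, 20.0])
        trials = np.full(4, 100.0)
        _, slope, _ = fit_logistic_trajectory(ages, succ, trials)
        assert slope < 0

    def test_degenerate_responses_rejected(self):
        ages = np.array([10.0, 20.0])
        with pytest.raises(ValueError):
            fit_logistic_trajectory(ages, np.zeros(2), np.full(2, 50.0))


def _coef_table(estimates, language, sig=None):
    terms = [f"p{i}" for i in range(len(estimates))]
    sig = sig if sig is not None else [True] * len(estimates)
    df = pd.DataFrame({"term": terms, "term_type": "main",
                       "estimate": estimates, "se": 0.1, "z": 1.0,
                       "p": 0.01, "significant": sig})
    return CoefficientTable(df, language=language, measure="production")


class TestSummaries:
    def test_single_table_mean_is_itself(self):
        t = _coef_table([0.2, -0.1, 0.4], "en")
        out = summarize_coefficients([t])
        assert out["mean_estimate"].to_numpy() == pytest.approx([0.2, -0.1, 0.4])

    def test_mean_across_two_languages(self):
        out = summarize_coefficients([_coef_table([0.2], "a"),
                                      _coef_table([0.3], "b")])
        assert out["mean_estimate"].iloc[0] == pytest.approx(0.25)

    def test_sign_consistency_count(self):
        tables = [_coef_table([s], l) for s, l in
                  zip([0.5, 0.2, -0.1], "abc")]
        out = summarize_coefficients(tables)
        assert out["n_consistent"].iloc[0] == 2

    def test_mismatched_terms_rejected(self):
        with pytest.raises(ValueError):
            summarize_coefficients([_coef_table([0.1], "a"),
                                    _coef_table([0.1, 0.2], "b")])


class TestComposeCategoryEffects:
    @staticmethod
    def _table():
        rows = [("frequency", "main", 0.20),
                ("cat_Nouns", "category_main", 0.10),
                ("frequency:cat_Nouns", "category_interaction", 0.05),
                ("cat_Predicates", "category_main", 0.0),
                ("frequency:cat_Predicates", "category_interaction", 0.0)]
        df = pd.DataFrame(rows, columns=["term", "term_type", "estimate"])
        df["se"], df["z"], df["p"], df["significant"] = 0.1, 1.0, 0.5, False
        return CoefficientTable(df, language="en", measure="production")

    def test_stated_sum(self):
        assert compose_category_effects(self._table(), "frequency", "Nouns") \
            == pytest.approx(0.35)

    def test_zero_category_terms_reduce_to_main(self):
        assert compose_category_effects(self._table(), "frequency",
                                        "Predicates") == pytest.approx(0.20)

    def test_missing_term_rejected(self):
        with pytest.raises(KeyError):
            compose_category_effects(self._table(), "frequency",
                                     "Function Words")
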
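"""Simulation-based validation studies for the acquisition models.

These are the package's statistical quality checks, usable both from
the test suite and from reporting scripts:

* type-I error of the mixed-model Wald tests under a null generator,
* recovery and confidence-interval coverage of a known effect,
* calibration of the shuffled-baseline consistency interval,
* qualitative category-consistency ordering (shared content-word
  effects vs language-specific function-word effects) through the full
  file-based pipeline.

All studies derive per-replicate seeds from a single master seed.
"""

from __future__ import annotations

import tempfile

import numpy as np
import pandas as pd
from scipy import stats

from .consistency import shuffled_baseline
from .model import ModelSpec, build_design, fit_glmm
from .pipeline import RunConfig, run_pipeline
from .predictors import PREDICTORS
from .simulate import (GroundTruth, generate_administrations,
                       generate_lexicon, latent_predictor_table)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def _main_effect_spec() -> ModelSpec:
    return ModelSpec(measure="production", include_age_interactions=False,
                     include_category_interactions=False,
                     estimate_re_correlation=False)


def _simulate_and_fit(n_items, n_children, truth, seed):
    s1, s2 = _spawn_seeds(seed, 2)
    items = generate_lexicon(n_items, seed=s1, languages=["L"])
    adm = generate_administrations(items, truth, n_children, (8, 30),
                                   "production", "L", seed=s2)
    design = build_design(adm, latent_predictor_table(items, "L"),
                          _main_effect_spec())
    return fit_glmm(design, language="L")


def type_i_error_study(n_replicates: int = 50, n_children: int = 1000,
                       n_items: int = 50, seed: int = 0,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Null simulations: all predictor effects zero; per-predictor Wald
    rejection counts at the given alpha."""
    truth = GroundTruth.build(["L"], beta=np.zeros(len(PREDICTORS)))
    rejections = pd.Series(0, index=list(PREDICTORS))
    for rep_seed in _spawn_seeds(seed, n_replicates):
        fit = _simulate_and_fit(n_items, n_children, truth, rep_seed)
        main = fit.table[fit.table["term_type"] == "main"]
        for term, p in zip(main["term"], main["p"]):
            rejections[term] += p < alpha
    return pd.DataFrame({"rejections": rejections,
                         "n_replicates": n_replicates,
                         "rate": rejections / n_replicates})


def recovery_study(n_replicates: int = 50, beta_value: float = 0.4,
                   n_children: int = 1000, n_items: int = 100,
                   seed: int = 0, tolerance: float = 0.15) -> dict:
    """Recovery of a known frequency effect with random-effect SDs
    0.5 / 0.2: fraction of estimates within +-tolerance of truth and
    Wald 95% CI coverage."""
    beta = np.zeros(len(PREDICTORS))
    beta[0] = beta_value
    truth = GroundTruth.build(["L"], beta=beta, random_intercept_sd=0.5,
                              random_slope_sd=0.2)
    estimates, covered = [], 0
    for rep_seed in _spawn_seeds(seed, n_replicates):
        fit = _simulate_and_fit(n_items, n_children, truth, rep_seed)
        row = fit.table[fit.table["term"] == "frequency"].iloc[0]
        estimates.append(float(row["estimate"]))
        half = stats.t.ppf(0.975, fit.df_resid) * row["se"]
        covered += (row["estimate"] - half) <= beta_value <= (row["estimate"] + half)
    estimates = np.asarray(estimates)
    return {
        "n_replicates": n_replicates,
        "truth": beta_value,
        "mean_estimate": float(estimates.mean()),
        "frac_within_tolerance": float(
            np.mean(np.abs(estimates - beta_value) <= tolerance)),
        "ci_coverage": covered / n_replicates,
    }


def consistency_calibration_study(n_outer: int = 200, n_languages: int = 5,
                                  n_predictors: int = 9,
                                  n_bootstrap: int = 500,
                                  seed: int = 0) -> dict:
    """Calibration of the shuffled-baseline interval.

    Independent coefficient vectors: the observed mean pairwise r
    should fall inside the 95% interval about 95% of the time.  A
    single shared vector: the observed r (=1) should exceed the upper
    bound in every replicate.
    """
    seeds = _spawn_seeds(seed, 2 * n_outer)
    inside = 0
    for k in range(n_outer):
        rng = np.random.default_rng(seeds[k])
        v = pd.DataFrame(rng.normal(size=(n_languages, n_predictors)))
        res = shuffled_baseline(v, n_bootstrap=n_bootstrap, seed=seeds[k])
        lo, hi = res.overall_baseline_ci
        inside += lo <= res.overall_mean_r <= hi
    n_shared = max(n_outer // 10, 10)
    exceeds = 0
    for k in range(n_shared):
        rng = np.random.default_rng(seeds[n_outer + k])
        shared = rng.normal(size=n_predictors)
        v = pd.DataFrame(np.tile(shared, (n_languages, 1)))
        res = shuffled_baseline(v, n_bootstrap=n_bootstrap,
                                seed=seeds[n_outer + k])
        exceeds += res.overall_mean_r > res.overall_baseline_ci[1]
    return {"n_outer": n_outer,
            "inside_rate": inside / n_outer,
            "n_shared": n_shared,
            "shared_exceeds_rate": exceeds / n_shared}


def make_category_contrast_truth(languages: list[str], seed: int = 0,
                                 fw_sd: float = 0.5) -> GroundTruth:
    """Ground truth with shared content-word effects but language-specific
    function-word effect profiles (offsets drawn N(0, fw_sd) per language)."""
    rng = np.random.default_rng(seed)
    interactions = {
        lang: {"Function Words": rng.normal(0.0, fw_sd, len(PREDICTORS))}
        for lang in languages}
    return GroundTruth.build(languages, seed=seed,
                             category_interactions=interactions)


def category_ordering_study(n_runs: int = 20, n_languages: int = 5,
                            n_items: int = 300, n_children: int = 250,
                            n_utterances: int = 8000, seed: int = 0) -> dict:
    """End-to-end pipeline runs on studies whose content-word effects
    are shared across languages while function-word effects are
    language-specific; records how often the per-category consistency
    ordering (nouns above function words) is reproduced."""
    languages = [f"lang{i+1}" for i in range(n_languages)]
    noun_r, fw_r = [], []
    for run_seed in _spawn_seeds(seed, n_runs):
        truth = make_category_contrast_truth(languages, seed=run_seed)
        with tempfile.TemporaryDirectory() as tmp:
            cfg = RunConfig(
                out_dir=tmp, seed=run_seed, languages=languages,
                n_items=n_items, n_children=n_children,
                n_utterances=n_utterances, measures=("production",),
                include_age_interactions=False,
                include_category_interactions=True,
                n_bootstrap=200, truth=truth)
            run_pipeline(cfg)
            cat = pd.read_csv(f"{tmp}/consistency/category_production.csv",
                              index_col="category")["mean_pairwise_r"]
        noun_r.append(float(cat["Nouns"]))
        fw_r.append(float(cat["Function Words"]))
    noun_r, fw_r = np.asarray(noun_r), np.asarray(fw_r)
    return {"n_runs": n_runs,
            "ordering_rate": float(np.mean(noun_r > fw_r)),
            "mean_noun_r": float(noun_r.mean()),
            "mean_function_word_r": float(fw_r.mean())}
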
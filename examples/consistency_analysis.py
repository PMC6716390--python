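"""Quantify cross-language consistency of predictor effects.

Fits the acquisition model independently in several synthetic languages
that share the same generating effect profile, correlates the
coefficient vectors between languages, and compares the observed
agreement with a shuffled (within-language permutation) baseline.
"""

import pandas as pd

from lexacq import (GroundTruth, ModelSpec, build_design, cluster_languages,
                    fit_glmm, generate_administrations, generate_lexicon,
                    latent_predictor_table, shuffled_baseline)

languages = ["lang1", "lang2", "lang3", "lang4"]
truth = GroundTruth.build(languages)   # same betas everywhere
spec = ModelSpec(measure="production", include_age_interactions=False,
                 include_category_interactions=False,
                 estimate_re_correlation=False)

vectors = {}
for k, lang in enumerate(languages):
    items = generate_lexicon(100, seed=10 + k, languages=[lang])
    adm = generate_administrations(items, truth, 400, (8, 30),
                                   "production", lang, seed=20 + k)
    design = build_design(adm, latent_predictor_table(items, lang), spec)
    vectors[lang] = fit_glmm(design, language=lang).main_effects()

res = shuffled_baseline(pd.DataFrame(vectors).T, n_bootstrap=1000, seed=99)
print("Per-language mean pairwise correlation (observed vs null interval):")
for lang in languages:
    lo, hi = res.baseline_ci.loc[lang]
    obs = res.per_language_mean_r[lang]
    flag = "outside null" if obs > hi else "inside null"
    print(f"  {lang}: r = {obs:.3f}   null 95% [{lo:+.3f}, {hi:+.3f}]  ({flag})")
print(f"\nOverall mean r = {res.overall_mean_r:.3f}; languages sharing one")
print("generating profile agree far beyond the shuffled baseline.")

dend = cluster_languages(res.pairwise_r)
print(f"\nDendrogram (complete linkage on 1 - r), Newick:\n  {dend.newick}")
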
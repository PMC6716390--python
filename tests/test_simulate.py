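import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lexacq import (GroundTruth, TokenMapper, count_unigrams,
                    generate_administrations, generate_corpus,
                    generate_lexicon, generate_norms, generate_study,
                    inject_missingness, lexicon_maps,
                    log_normalized_frequency)
from lexacq.simulate import CATEGORIES


class TestLexicon:
    def test_degenerate_simplex_all_nouns(self):
        items = generate_lexicon(4, category_proportions=(1, 0, 0, 0), seed=0)
        assert (items["lexical_category"] == "Nouns").all()

    def test_category_counts_within_multinomial_band(self):
        # 99.9% multinomial band per cell: count ~ Binomial(400, p)
        props = (0.55, 0.25, 0.10, 0.10)
        items = generate_lexicon(400, category_proportions=props, seed=1)
        counts = items["lexical_category"].value_counts()
        for p, cat in zip(props, CATEGORIES):
            lo = stats.binom.ppf(0.0005, 400, p)
            hi = stats.binom.ppf(0.9995, 400, p)
            assert lo <= counts.get(cat, 0) <= hi

    def test_same_seed_identical_table(self):
        a = generate_lexicon(50, seed=7, languages=["x", "y"])
        b = generate_lexicon(50, seed=7, languages=["x", "y"])
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            generate_lexicon(10, category_proportions=(0.5, 0.5, 0.5, 0.5))

    def test_latent_correlation_structure(self):
        items = generate_lexicon(4000, seed=3)
        r = np.corrcoef(items["z_frequency"], items["z_concreteness"])[0, 1]
        assert r == pytest.approx(-0.35, abs=0.06)


class TestCorpusGeneration:
    def test_forced_single_item_composition(self):
        items = generate_lexicon(1, seed=0, n_polysemy_pairs=0)
        # pin latent MLU low so every utterance is the single word alone
        items.loc[:, "z_mlu_w"] = -10.0
        corpus = generate_corpus(items, "lang1", 200, seed=1,
                                 inflected_fraction=0.0)
        form = items["form_lang1"].iloc[0]
        assert all(u.tokens == (form,) for u in corpus)

    def test_frequency_roundtrip_correlation(self):
        items = generate_lexicon(80, seed=5, n_polysemy_pairs=0)
        corpus = generate_corpus(items, "lang1", 20_000, seed=6)
        f2i, infl, poly = lexicon_maps(items, "lang1")
        mapper = TokenMapper(f2i, infl, poly)
        counts, stats_ = count_unigrams(corpus, mapper, items.index)
        logf = log_normalized_frequency(counts, stats_["total_tokens"])
        rho = stats.spearmanr(logf, items["z_frequency"]).statistic
        assert rho >= 0.9

    def test_two_item_frequency_ratio(self):
        items = generate_lexicon(2, seed=2, n_polysemy_pairs=0)
        items.loc[:, "z_frequency"] = [np.log(10.0), 0.0]
        corpus = generate_corpus(items, "lang1", 50_000, seed=3,
                                 inflected_fraction=0.0)
        f2i, infl, poly = lexicon_maps(items, "lang1")
        counts, _ = count_unigrams(corpus, TokenMapper(f2i, infl, poly),
                                   items.index)
        ratio = counts.iloc[0] / counts.iloc[1]
        assert 8.0 <= ratio <= 12.0

    def test_same_seed_identical_corpus(self):
        items = generate_lexicon(20, seed=4)
        a = generate_corpus(items, "lang1", 500, seed=9)
        b = generate_corpus(items, "lang1", 500, seed=9)
        assert [u.tokens for u in a] == [u.tokens for u in b]

    def test_contains_single_and_multiword_utterances(self):
        items = generate_lexicon(50, seed=8)
        corpus = generate_corpus(items, "lang1", 2000, seed=10)
        lengths = {len(u) for u in corpus}
        assert 1 in lengths and any(l > 1 for l in lengths)


class TestAdministrations:
    def test_null_model_grand_mean_half(self):
        items = generate_lexicon(50, seed=0)
        truth = GroundTruth.build(["L"], beta=np.zeros(9), beta_age=0.0,
                                  intercept=0.0,
                                  measure_offsets={"production": 0.0},
                                  random_intercept_sd=0.0,
                                  random_slope_sd=0.0)
        adm = generate_administrations(items, truth, 1000, (8, 30),
                                       "production", "L", seed=1)
        phat = adm["value"].mean()
        se = 0.5 / np.sqrt(len(adm))
        assert abs(phat - 0.5) < 3 * se

    def test_frequency_effect_monotone_across_deciles(self):
        items = generate_lexicon(60, seed=2)
        beta = np.zeros(9)
        beta[0] = 0.5
        truth = GroundTruth.build(["L"], beta=beta, beta_age=0.0,
                                  random_intercept_sd=0.0,
                                  random_slope_sd=0.0)
        adm = generate_administrations(items, truth, 1000, (8, 30),
                                       "production", "L", seed=3)
        by_item = adm.groupby("item_id")["value"].mean()
        z = items["z_frequency"].reindex(by_item.index)
        rho = stats.spearmanr(by_item, z).statistic
        assert rho > 0

    def test_positive_age_effect_gives_rising_trajectory(self):
        items = generate_lexicon(40, seed=4)
        truth = GroundTruth.build(["L"], beta=np.zeros(9), beta_age=2.0)
        adm = generate_administrations(items, truth, 2000, (8, 30),
                                       "production", "L", seed=5)
        by_age = adm.groupby("age_months")["value"].mean()
        first, last = by_age.iloc[:5].mean(), by_age.iloc[-5:].mean()
        assert last > first + 0.2

    def test_unknown_measure_rejected(self):
        items = generate_lexicon(5, seed=0)
        truth = GroundTruth.build(["L"])
        with pytest.raises(ValueError):
            generate_administrations(items, truth, 10, (8, 30),
                                     "gestures", "L", seed=0)


class TestMissingness:
    def test_rate_zero_is_identity(self):
        items = generate_lexicon(30, seed=1)
        norms = generate_norms(items, seed=2)
        out = inject_missingness(norms, {"valence": 0.0}, seed=3)
        pd.testing.assert_frame_equal(out, norms)

    def test_rate_one_blanks_column(self):
        items = generate_lexicon(30, seed=1)
        norms = generate_norms(items, seed=2)
        out = inject_missingness(norms, {"babiness": 1.0}, seed=3)
        assert out["babiness"].isna().all()
        assert out["valence"].notna().all()

    def test_realized_rate_within_binomial_ci(self):
        items = generate_lexicon(400, seed=1)
        norms = generate_norms(items, seed=2)
        out = inject_missingness(norms, {"babiness": 0.3}, seed=5)
        n_missing = out["babiness"].isna().sum()
        lo = stats.binom.ppf(0.025, 400, 0.3)
        hi = stats.binom.ppf(0.975, 400, 0.3)
        assert lo <= n_missing <= hi

    def test_invalid_rate_rejected(self):
        items = generate_lexicon(10, seed=1)
        norms = generate_norms(items)
        with pytest.raises(ValueError):
            inject_missingness(norms, {"valence": 1.5})

    def test_phoneme_count_column_must_stay_complete(self):
        df = pd.DataFrame({"n_phonemes": [3.0, 4.0]})
        with pytest.raises(ValueError):
            inject_missingness(df, {"n_phonemes": 0.5})


class TestGroundTruthValidation:
    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth.build(["L"], random_intercept_sd=-1.0)

    def test_correlation_bound(self):
        with pytest.raises(ValueError):
            GroundTruth.build(["L"], random_effect_corr=1.5)

    def test_mismatched_beta_lengths_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(languages=["a", "b"],
                        beta={"a": np.zeros(9), "b": np.zeros(8)})


class TestStudy:
    def test_study_internally_consistent(self):
        study = generate_study(["l1", "l2"], n_items=30, n_children=20,
                               n_utterances=300, seed=11)
        adm = study.administrations
        assert set(adm["item_id"]) <= set(study.items.index)
        assert adm["age_months"].between(*study.age_range).all()
        assert set(adm["value"].unique()) <= {0, 1}
        assert set(adm["language"].unique()) == {"l1", "l2"}

    def test_study_deterministic(self):
        a = generate_study(["l1"], n_items=20, n_children=10,
                           n_utterances=200, seed=21)
        b = generate_study(["l1"], n_items=20, n_children=10,
                           n_utterances=200, seed=21)
        pd.testing.assert_frame_equal(a.administrations, b.administrations)
        assert [u.tokens for u in a.corpora["l1"]] == \
            [u.tokens for u in b.corpora["l1"]]
        pd.testing.assert_frame_equal(a.norms["l1"], b.norms["l1"])
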
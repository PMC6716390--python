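"""Synthetic multi-language word-learning studies with known ground truth.

Everything downstream — predictor extraction, imputation, mixed-model
fitting, consistency analysis — is exercised against data generated
here from an explicit generative model:

* a lexicon of items with latent standardized property values drawn
  from a multivariate normal whose correlation structure mimics
  naturalistic lexical statistics (frequency negatively correlated with
  concreteness and word length; utterance length with solo frequency);
* per-language child-directed-speech corpora whose empirical unigram
  statistics track the latent frequency / utterance-length targets;
* rating-norm tables (linear rescalings of the latent values onto
  conventional rating scales) with controllable MCAR missingness;
* checklist administrations in which child ``c`` knows item ``w`` with
  probability ``logistic(eta)``,

      eta = intercept + gamma[cat_w] + u_w
            + sum_p (beta_p + delta[cat_w, p]) x_pw
            + (beta_age + s_w + sum_p beta_age_p x_pw) * age_z,

  with per-word random intercepts and age slopes ``(u_w, s_w)`` drawn
  from a bivariate normal.

Ages are integer months; age is standardized as (age - midpoint) /
half-range of the configured instrument range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import ADULT, Corpus, Utterance
from .predictors import PREDICTORS, PredictorTable

CATEGORIES = ("Nouns", "Predicates", "Function Words", "Other")
MEASURES = ("comprehension", "production")

#: default standardized main effects, one per predictor in PREDICTORS
#: order (frequency, solo, final, mlu_w, n_phonemes, concreteness,
#: valence, arousal, babiness); magnitudes chosen to emulate the
#: typical cross-language profile of these predictors
DEFAULT_BETA = np.array([0.23, 0.17, 0.13, -0.14, -0.19, 0.18, 0.06, 0.003, 0.13])

_SYLLABLES = ["ba", "do", "ki", "mu", "ne", "po", "ra", "su", "ti", "vo",
              "ga", "le", "fi", "zo", "wa", "che", "dru", "sta", "mi", "ku"]
_PHONEME_INVENTORY = ["p", "b", "t", "d", "k", "g", "m", "n", "s", "z",
                      "l", "r", "f", "v", "a", "e", "i", "o", "u", "j"]


def _latent_cols() -> list[str]:
    return [f"z_{p}" for p in PREDICTORS]


def default_property_corr() -> np.ndarray:
    """Latent property correlation matrix (identity plus the naturalistic
    frequency–concreteness, frequency–length and MLU–solo correlations)."""
    p = len(PREDICTORS)
    R = np.eye(p)
    idx = {name: i for i, name in enumerate(PREDICTORS)}

    def set_corr(a, b, r):
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r

    set_corr("frequency", "concreteness", -0.35)
    set_corr("frequency", "n_phonemes", -0.33)
    set_corr("mlu_w", "solo_frequency", -0.44)
    return R


@dataclass
class GroundTruth:
    """Generative parameters for a multi-language synthetic study.

    ``beta`` maps each language to its vector of standardized main
    effects (logit scale), ordered as :data:`lexacq.predictors.PREDICTORS`.
    Category effects are parametrized as additive offsets: ``category_main``
    shifts the intercept for items of a category, ``category_interactions``
    shifts each predictor's slope within a category.
    """

    languages: list[str]
    beta: dict[str, np.ndarray]
    beta_age: float = 2.0
    beta_age_interactions: dict[str, np.ndarray] = field(default_factory=dict)
    category_main: dict[str, dict[str, float]] = field(default_factory=dict)
    category_interactions: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    intercept: float = 0.0
    measure_offsets: dict[str, float] = field(
        default_factory=lambda: {"comprehension": 0.5, "production": -0.5})
    random_intercept_sd: float = 0.5
    random_slope_sd: float = 0.2
    random_effect_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0 or self.random_slope_sd < 0:
            raise ValueError("random-effect SDs must be nonnegative")
        if abs(self.random_effect_corr) > 1:
            raise ValueError("|random_effect_corr| must be <= 1")
        lengths = set()
        for lang in self.languages:
            if lang not in self.beta:
                raise ValueError(f"no beta vector for language {lang!r}")
            self.beta[lang] = np.asarray(self.beta[lang], dtype=float)
            lengths.add(self.beta[lang].size)
        if len(lengths) > 1:
            raise ValueError("beta vectors must have the same length "
                             "across languages")

    @classmethod
    def build(cls, languages: list[str],
              beta: np.ndarray | dict[str, np.ndarray] | None = None,
              **kwargs) -> "GroundTruth":
        """Convenience constructor broadcasting a shared beta vector."""
        if beta is None:
            beta = DEFAULT_BETA
        if not isinstance(beta, dict):
            beta = {lang: np.asarray(beta, dtype=float) for lang in languages}
        return cls(languages=list(languages), beta=beta, **kwargs)

    def random_effect_cov(self) -> np.ndarray:
        s1, s2, r = (self.random_intercept_sd, self.random_slope_sd,
                     self.random_effect_corr)
        return np.array([[s1 * s1, r * s1 * s2],
                         [r * s1 * s2, s2 * s2]])


@dataclass
class SyntheticStudy:
    """One generated study: everything the analysis pipeline consumes."""

    items: pd.DataFrame
    administrations: pd.DataFrame
    corpora: dict[str, Corpus]
    norms: dict[str, pd.DataFrame]
    transcriptions: dict[str, pd.Series]
    mappings: dict
    truth: GroundTruth
    age_range: tuple[int, int]


def _unique_word(rng: np.random.Generator, used: set[str]) -> str:
    for _ in range(100):
        n_syll = int(rng.integers(1, 4))
        w = "".join(rng.choice(_SYLLABLES) for _ in range(n_syll))
        if w not in used:
            used.add(w)
            return w
    w = f"w{len(used)}"
    used.add(w)
    return w


def generate_lexicon(n_items: int,
                     category_proportions=(0.55, 0.25, 0.10, 0.10),
                     seed: int = 0,
                     languages: list[str] | None = None,
                     property_corr: np.ndarray | None = None,
                     n_polysemy_pairs: int = 2) -> pd.DataFrame:
    """Generate the item table: ids, per-language word forms, lexical
    category and latent standardized property values.

    Categories are drawn i.i.d. from ``category_proportions`` over
    (Nouns, Predicates, Function Words, Other).  Latent properties are
    multivariate normal with the configured correlation matrix.  A few
    pairs of items per language share a written form (polysemy).
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    props = np.asarray(category_proportions, dtype=float)
    if props.size != len(CATEGORIES) or np.any(props < 0) or \
            not np.isclose(props.sum(), 1.0):
        raise ValueError("category_proportions must be a simplex over "
                         f"{len(CATEGORIES)} categories")
    languages = languages or ["lang1"]
    rng = np.random.default_rng(seed)

    cats = rng.choice(len(CATEGORIES), size=n_items, p=props)
    R = default_property_corr() if property_corr is None else np.asarray(property_corr)
    Z = rng.multivariate_normal(np.zeros(len(PREDICTORS)), R, size=n_items,
                                method="cholesky")

    items = pd.DataFrame(index=pd.Index(
        [f"item{i:04d}" for i in range(n_items)], name="item_id"))
    items["lexical_category"] = [CATEGORIES[c] for c in cats]
    for j, col in enumerate(_latent_cols()):
        items[col] = Z[:, j]

    for lang in languages:
        used: set[str] = set()
        forms = [_unique_word(rng, used) for _ in range(n_items)]
        # polysemy: later item of each chosen pair reuses the former's form
        n_pairs = min(n_polysemy_pairs, n_items // 2)
        if n_pairs > 0:
            chosen = rng.choice(n_items, size=2 * n_pairs, replace=False)
            for k in range(n_pairs):
                forms[chosen[2 * k + 1]] = forms[chosen[2 * k]]
        items[f"form_{lang}"] = forms
        items[f"variant_{lang}"] = [f + "s" for f in forms]
    return items


def lexicon_maps(items: pd.DataFrame, language: str
                 ) -> tuple[dict[str, str], dict[str, str], dict[str, list[str]]]:
    """Derive (form_to_item, inflection_map, polysemy_map) for one language."""
    forms = items[f"form_{language}"]
    counts = forms.value_counts()
    poly_forms = set(counts[counts > 1].index)
    form_to_item = {f: i for i, f in forms.items() if f not in poly_forms}
    polysemy = {f: list(forms[forms == f].index) for f in poly_forms}
    inflection = {}
    for item, variant in items[f"variant_{language}"].items():
        if variant not in forms.values and variant not in inflection:
            inflection[variant] = item
    return form_to_item, inflection, polysemy


def generate_corpus(items: pd.DataFrame, language: str, n_utterances: int,
                    seed: int = 0, frequency_spread: float = 1.0,
                    inflected_fraction: float = 0.2) -> Corpus:
    """Generate an adult-speech corpus realizing the lexicon's latent targets.

    Each utterance draws a head item with probability proportional to
    ``exp(frequency_spread * z_frequency)``; its length is ``1 +
    Poisson(target_mlu - 1)`` with the head's target MLU derived from
    ``z_mlu_w``.  The head lands in final position with probability
    ``logistic(z_final_frequency)`` (for multi-word utterances), other
    slots are filled by frequency-weighted draws.  A fraction of tokens
    surface as the item's inflected variant.
    """
    if n_utterances < 1:
        raise ValueError("n_utterances must be >= 1")
    rng = np.random.default_rng(seed)
    z_freq = items["z_frequency"].to_numpy()
    z_mlu = items["z_mlu_w"].to_numpy()
    z_final = items["z_final_frequency"].to_numpy()
    forms = items[f"form_{language}"].to_numpy()
    variants = items[f"variant_{language}"].to_numpy()
    p = np.exp(frequency_spread * z_freq)
    p /= p.sum()
    target_mlu = np.clip(4.0 + 1.5 * z_mlu, 1.0, 12.0)
    p_final = 1.0 / (1.0 + np.exp(-z_final))

    n_items = len(items)
    heads = rng.choice(n_items, size=n_utterances, p=p)
    lengths = 1 + rng.poisson(np.maximum(target_mlu[heads] - 1.0, 0.0))

    utterances = []
    for h, L in zip(heads, lengths):
        slots = rng.choice(n_items, size=L, p=p)
        if L == 1:
            slots[0] = h
        elif rng.random() < p_final[h]:
            slots[-1] = h
        else:
            slots[int(rng.integers(0, L - 1))] = h
        inflect = rng.random(L) < inflected_fraction
        tokens = tuple(variants[i] if f else forms[i]
                       for i, f in zip(slots, inflect))
        utterances.append(Utterance(ADULT, tokens))
    return Corpus(utterances, language=language)


def latent_predictor_table(items: pd.DataFrame,
                           language: str | None = None) -> PredictorTable:
    """Predictor table built directly from the latent property values
    (already standardized); bypasses corpus extraction for model tests."""
    data = items[_latent_cols()].copy()
    data.columns = list(PREDICTORS)
    data["lexical_category"] = items["lexical_category"]
    scaling = {p: (0.0, 1.0) for p in PREDICTORS}
    return PredictorTable(data, language=language, scaling=scaling)


def _age_z(age: np.ndarray, age_range: tuple[int, int]) -> np.ndarray:
    lo, hi = age_range
    mid = (lo + hi) / 2.0
    half = (hi - lo) / 2.0
    return (np.asarray(age, dtype=float) - mid) / half


def item_linear_predictors(items: pd.DataFrame, truth: GroundTruth,
                           language: str, measure: str,
                           rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-item constant term ``a_w`` and age coefficient ``c_w`` of eta,
    including freshly drawn per-word random effects."""
    X = items[_latent_cols()].to_numpy()
    cats = items["lexical_category"].to_numpy()
    n_items = len(items)

    beta = truth.beta[language]
    slopes = np.tile(beta, (n_items, 1))
    delta = truth.category_interactions.get(language, {})
    gamma = truth.category_main.get(language, {})
    cat_offset = np.zeros(n_items)
    for c in CATEGORIES:
        mask = cats == c
        if c in delta:
            slopes[mask] += np.asarray(delta[c], dtype=float)
        cat_offset[mask] += gamma.get(c, 0.0)

    beta_age_int = truth.beta_age_interactions.get(
        language, np.zeros(len(PREDICTORS)))
    # explicit Cholesky factor so zero SDs (degenerate covariance) work
    s1, s2, r = (truth.random_intercept_sd, truth.random_slope_sd,
                 truth.random_effect_corr)
    L = np.array([[s1, 0.0], [r * s2, s2 * np.sqrt(max(1.0 - r * r, 0.0))]])
    re = rng.standard_normal((n_items, 2)) @ L.T
    a = (truth.intercept + truth.measure_offsets.get(measure, 0.0)
         + cat_offset + (slopes * X).sum(axis=1) + re[:, 0])
    c = truth.beta_age + X @ np.asarray(beta_age_int, dtype=float) + re[:, 1]
    return a, c


def generate_administrations(items: pd.DataFrame, truth: GroundTruth,
                             n_children: int, age_range: tuple[int, int],
                             measure: str, language: str,
                             seed: int = 0) -> pd.DataFrame:
    """Simulate one language x measure block of checklist administrations.

    Returns a long-format frame with columns child_id, language,
    age_months, measure, item_id, value (0/1).
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    rng = np.random.default_rng(seed)
    ages = rng.integers(age_range[0], age_range[1] + 1, size=n_children)
    age_z = _age_z(ages, age_range)
    a, c = item_linear_predictors(items, truth, language, measure, rng)

    eta = a[None, :] + np.outer(age_z, c)  # children x items
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(prob.shape) < prob).astype(np.int8)

    n_items = len(items)
    child_ids = np.repeat(
        [f"{language}_{measure[:4]}_c{i:05d}" for i in range(n_children)],
        n_items)
    return pd.DataFrame({
        "child_id": child_ids,
        "language": language,
        "age_months": np.repeat(ages, n_items),
        "measure": measure,
        "item_id": np.tile(items.index.to_numpy(), n_children),
        "value": y.ravel(),
    })


def generate_norms(items: pd.DataFrame, seed: int = 0,
                   noise_sd: float = 0.3) -> pd.DataFrame:
    """Rating-norm table on conventional scales (concreteness 1-5,
    valence/arousal 1-9, babiness 1-10), a noisy linear map of latents."""
    rng = np.random.default_rng(seed)
    n = len(items)

    def scale(z, center, spread, lo, hi):
        vals = center + spread * (z + noise_sd * rng.standard_normal(n))
        return np.clip(vals, lo, hi)

    return pd.DataFrame({
        "concreteness": scale(items["z_concreteness"], 3.0, 0.8, 1, 5),
        "valence": scale(items["z_valence"], 5.0, 1.5, 1, 9),
        "arousal": scale(items["z_arousal"], 5.0, 1.5, 1, 9),
        "babiness": scale(items["z_babiness"], 5.5, 1.8, 1, 10),
    }, index=items.index)


def generate_transcriptions(items: pd.DataFrame, seed: int = 0) -> pd.Series:
    """Space-delimited phonemic transcriptions whose length tracks the
    latent word-length value (1 to 12 phonemes)."""
    rng = np.random.default_rng(seed)
    k = np.clip(np.round(5.0 + 2.0 * items["z_n_phonemes"]), 1, 12).astype(int)
    out = {}
    for item, n_ph in zip(items.index, k):
        out[item] = " ".join(rng.choice(_PHONEME_INVENTORY) for _ in range(n_ph))
    return pd.Series(out, index=items.index, name="phonemes")


def inject_missingness(norm_table: pd.DataFrame, rates: dict[str, float],
                       mechanism: str = "MCAR", seed: int = 0) -> pd.DataFrame:
    """Blank out a fraction of each column completely at random.

    The word-length column, when present, must stay complete (its rate
    must be 0): phoneme counts are derivable for every word.
    """
    if mechanism != "MCAR":
        raise ValueError("only MCAR missingness is supported")
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col!r} must be in [0, 1]")
        if col == "n_phonemes" and rate > 0:
            raise ValueError("n_phonemes must remain complete (rate 0)")
    rng = np.random.default_rng(seed)
    out = norm_table.copy()
    for col, rate in rates.items():
        if col not in out.columns or rate == 0.0:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, col] = np.nan
    return out


#: per-column missingness rates emulating typical resource availability
DEFAULT_MISSING_RATES = {"concreteness": 0.01, "valence": 0.10,
                         "arousal": 0.10, "babiness": 0.20}


def generate_study(languages: list[str] | None = None,
                   n_items: int = 100, n_children: int = 500,
                   n_utterances: int = 10_000,
                   age_range: tuple[int, int] = (8, 30),
                   measures: tuple[str, ...] = MEASURES,
                   truth: GroundTruth | None = None,
                   missing_rates: dict[str, float] | None = None,
                   seed: int = 0) -> SyntheticStudy:
    """Generate a complete study: lexicon, corpora, norms, transcriptions,
    mappings and administrations for every language x measure."""
    languages = languages or ["lang1", "lang2", "lang3"]
    if truth is None:
        truth = GroundTruth.build(languages, seed=seed)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in ss.spawn(3 + 3 * len(languages) * (1 + len(measures)))]
    seed_iter = iter(seeds)

    items = generate_lexicon(n_items, seed=next(seed_iter),
                             languages=languages)
    norms_clean = generate_norms(items, seed=next(seed_iter))
    rates = DEFAULT_MISSING_RATES if missing_rates is None else missing_rates

    corpora, norms, transcriptions = {}, {}, {}
    mappings: dict = {"form_to_item": {}, "inflection": {}, "polysemy": {},
                      "categories": items["lexical_category"].to_dict(),
                      "translations": {
                          lang: items[f"form_{lang}"].to_dict()
                          for lang in languages}}
    admin_frames = []
    for lang in languages:
        corpora[lang] = generate_corpus(items, lang, n_utterances,
                                        seed=next(seed_iter))
        norms[lang] = inject_missingness(norms_clean, rates,
                                         seed=next(seed_iter))
        transcriptions[lang] = generate_transcriptions(items,
                                                       seed=next(seed_iter))
        f2i, infl, poly = lexicon_maps(items, lang)
        mappings["form_to_item"][lang] = f2i
        mappings["inflection"][lang] = infl
        mappings["polysemy"][lang] = poly
        for measure in measures:
            admin_frames.append(generate_administrations(
                items, truth, n_children, age_range, measure, lang,
                seed=next(seed_iter)))

    return SyntheticStudy(
        items=items,
        administrations=pd.concat(admin_frames, ignore_index=True),
        corpora=corpora, norms=norms, transcriptions=transcriptions,
        mappings=mappings, truth=truth, age_range=age_range)
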
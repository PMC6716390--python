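"""Word-level predictors of acquisition from corpora and rating norms.

Environmental predictors are extracted from adult utterances in a
child-directed-speech corpus:

* ``frequency`` — per-item unigram count, collapsed across inflected
  variants and synonyms, with polysemous forms split uniformly across
  their senses; normalized per million tokens, Laplace smoothed
  (0 -> 1) and natural-log transformed.
* ``solo_frequency`` / ``final_frequency`` — counts of occurrences as
  the sole word of an utterance, and as the final word of a multi-word
  utterance; same normalization, then residualized against frequency
  (so they measure variance beyond plain frequency).
* ``mlu_w`` — mean length in words of the utterances containing the
  item; items occurring fewer than ``min_occurrences`` (default 10)
  times are marked missing.
* ``n_phonemes`` — symbol count of a supplied phonemic transcription.

Meaning-based predictors (concreteness, valence, arousal, babiness) are
supplied as rating-norm columns and merged in unchanged.  All numeric
predictors are finally centered and scaled within language.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import ADULT, Corpus

#: canonical predictor order used throughout the package
PREDICTORS = (
    "frequency",
    "solo_frequency",
    "final_frequency",
    "mlu_w",
    "n_phonemes",
    "concreteness",
    "valence",
    "arousal",
    "babiness",
)

CORPUS_PREDICTORS = ("frequency", "solo_frequency", "final_frequency", "mlu_w")
NORM_PREDICTORS = ("concreteness", "valence", "arousal", "babiness")

PER_MILLION = 1e6


@dataclass
class PredictorTable:
    """Per-item predictor values for one language.

    ``data`` is indexed by item id and carries the nine predictor
    columns plus ``lexical_category``; missing cells are NaN.
    ``scaling`` maps each scaled column to its (mean, sd); ``meta``
    records corpus totals and unmapped-token tallies.
    """

    data: pd.DataFrame
    language: str | None = None
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def is_scaled(self) -> bool:
        return bool(self.scaling)

    def copy(self) -> "PredictorTable":
        return PredictorTable(self.data.copy(), self.language,
                              dict(self.scaling), dict(self.meta))


class TokenMapper:
    """Resolve a corpus token to item mass.

    Resolution order: case-fold; inflection/synonym collapsing takes
    precedence (a variant form contributes its full mass to its
    canonical item); otherwise a polysemous form splits its mass
    uniformly across its sense items; otherwise an exact word-form
    match contributes to its item; otherwise the token is unmapped.
    """

    def __init__(self, form_to_item: dict[str, str],
                 inflection_map: dict[str, str] | None = None,
                 polysemy_map: dict[str, list[str]] | None = None):
        self.form_to_item = {k.casefold(): v for k, v in form_to_item.items()}
        self.inflection_map = {k.casefold(): v
                               for k, v in (inflection_map or {}).items()}
        self.polysemy_map = {k.casefold(): list(v)
                             for k, v in (polysemy_map or {}).items()}

    def __call__(self, token: str) -> list[tuple[str, float]]:
        """Return ``[(item_id, mass), ...]``; empty if unmapped."""
        t = token.casefold()
        if t in self.inflection_map:
            return [(self.inflection_map[t], 1.0)]
        if t in self.polysemy_map:
            senses = self.polysemy_map[t]
            return [(s, 1.0 / len(senses)) for s in senses]
        if t in self.form_to_item:
            return [(self.form_to_item[t], 1.0)]
        return []


def _counts_series(acc: dict[str, float], items: pd.Index) -> pd.Series:
    s = pd.Series(0.0, index=items)
    for item, mass in acc.items():
        if item in s.index:
            s[item] += mass
    return s


def count_unigrams(corpus: Corpus, mapper: TokenMapper, items: pd.Index,
                   speaker_filter: str = ADULT) -> tuple[pd.Series, dict]:
    """Per-item (possibly fractional) unigram counts over one speaker role.

    Every counted token contributes total mass 1, split uniformly when
    polysemous.  Returns the counts and a stats dict with the total
    token count and the unmapped-token count (mass conservation:
    ``counts.sum() + unmapped == total``).
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    acc: dict[str, float] = {}
    total = 0
    unmapped = 0.0
    for utt in corpus:
        if utt.speaker_role != speaker_filter:
            continue
        for token in utt.tokens:
            total += 1
            hits = mapper(token)
            if not hits:
                unmapped += 1.0
                continue
            for item, mass in hits:
                acc[item] = acc.get(item, 0.0) + mass
    counts = _counts_series(acc, items)
    return counts, {"total_tokens": total, "unmapped_tokens": unmapped}


def log_normalized_frequency(raw_counts: pd.Series | np.ndarray,
                             corpus_token_total: int,
                             per: float = PER_MILLION) -> pd.Series | np.ndarray:
    """Laplace-smoothed, length-normalized log frequency.

    ``ln(max(count, 1) / total * per)`` with ``per`` defaulting to one
    million tokens (zero counts are replaced with counts of 1 before
    normalizing and taking logs).
    """
    if corpus_token_total < 1:
        raise ValueError("corpus_token_total must be >= 1")
    arr = np.asarray(raw_counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative counts")
    out = np.log(np.maximum(arr, 1.0) / corpus_token_total * per)
    if isinstance(raw_counts, pd.Series):
        return pd.Series(out, index=raw_counts.index)
    return out


def solo_and_final_counts(corpus: Corpus, mapper: TokenMapper, items: pd.Index,
                          speaker_filter: str = ADULT
                          ) -> tuple[pd.Series, pd.Series]:
    """Counts of sole-constituent and utterance-final occurrences.

    Final counts exclude single-word utterances; solo counts require the
    utterance to consist of exactly one token.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    solo: dict[str, float] = {}
    final: dict[str, float] = {}
    for utt in corpus:
        if utt.speaker_role != speaker_filter:
            continue
        if len(utt) == 1:
            for item, mass in mapper(utt.tokens[0]):
                solo[item] = solo.get(item, 0.0) + mass
        else:
            for item, mass in mapper(utt.tokens[-1]):
                final[item] = final.get(item, 0.0) + mass
    return _counts_series(solo, items), _counts_series(final, items)


def residualize(target: pd.Series | np.ndarray,
                covariate: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Residuals of a least-squares simple regression of target on covariate."""
    y = np.asarray(target, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("target and covariate must have matching items")
    if y.size < 3:
        raise ValueError("need at least 3 items to residualize")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; residualization undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    if isinstance(target, pd.Series):
        return pd.Series(resid, index=target.index)
    return resid


def compute_mlu_w(corpus: Corpus, mapper: TokenMapper, items: pd.Index,
                  speaker_filter: str = ADULT,
                  min_occurrences: float = 10) -> pd.Series:
    """Mean length in words of the utterances in which each item appears.

    One contribution per occurrence, weighted by the same fractional
    polysemy mass as frequency counting.  Items whose total occurrence
    mass is below ``min_occurrences`` are returned as NaN (missing).
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    mass_sum: dict[str, float] = {}
    len_sum: dict[str, float] = {}
    for utt in corpus:
        if utt.speaker_role != speaker_filter:
            continue
        length = len(utt)
        for token in utt.tokens:
            for item, mass in mapper(token):
                mass_sum[item] = mass_sum.get(item, 0.0) + mass
                len_sum[item] = len_sum.get(item, 0.0) + mass * length
    out = pd.Series(np.nan, index=items)
    for item in mass_sum:
        if item in out.index and mass_sum[item] >= min_occurrences:
            out[item] = len_sum[item] / mass_sum[item]
    return out


def count_phonemes(transcriptions: pd.Series, delimiter: str = " ") -> pd.Series:
    """Number of phonemes per item from delimiter-separated transcriptions."""
    counts = {}
    for item, trans in transcriptions.items():
        symbols = [s for s in str(trans).split(delimiter) if s]
        if not symbols:
            raise ValueError(f"empty phonemic transcription for item {item!r}")
        counts[item] = len(symbols)
    return pd.Series(counts, index=transcriptions.index, dtype=float)


def scale_predictors(table: PredictorTable,
                     columns: tuple[str, ...] = PREDICTORS) -> PredictorTable:
    """Center and scale each numeric predictor within language.

    Mean and sample SD are computed on non-missing values; missing
    cells stay missing.  Raises on constant columns (scaling undefined).
    """
    out = table.copy()
    for col in columns:
        vals = out.data[col].astype(float)
        obs = vals.dropna()
        if obs.nunique() < 2:
            raise ValueError(f"column {col!r} is constant; cannot scale")
        mean, sd = obs.mean(), obs.std(ddof=1)
        out.data[col] = (vals - mean) / sd
        out.scaling[col] = (float(mean), float(sd))
    return out


def collinearity_diagnostics(table: PredictorTable,
                             columns: tuple[str, ...] = PREDICTORS
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise Pearson correlations and variance inflation factors.

    VIF_p = 1 / (1 - R^2) from an intercept-augmented OLS of predictor p
    on all other predictors; requires a complete (post-imputation) table.
    """
    X = table.data[list(columns)].astype(float)
    if X.isna().any().any():
        raise ValueError("collinearity diagnostics require a complete table")
    if len(X) < len(columns) + 1:
        raise ValueError("need more items than predictors")
    corr = X.corr(method="pearson")
    vifs = {}
    arr = X.to_numpy()
    n, p = arr.shape
    for j, col in enumerate(columns):
        others = np.column_stack([np.ones(n), np.delete(arr, j, axis=1)])
        y = arr[:, j]
        coef, _, rank, _ = np.linalg.lstsq(others, y, rcond=None)
        if rank < others.shape[1]:
            raise ValueError(f"singular design when regressing {col!r} on others")
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        if r2 >= 1.0 - 1e-12:
            raise ValueError(f"predictor {col!r} is perfectly collinear")
        vifs[col] = 1.0 / (1.0 - r2)
    return corr, pd.Series(vifs)


def build_predictor_table(corpus: Corpus, items: pd.DataFrame,
                          mapper: TokenMapper,
                          norms: pd.DataFrame,
                          transcriptions: pd.Series,
                          language: str | None = None,
                          min_occurrences: float = 10,
                          scale: bool = False) -> PredictorTable:
    """Assemble the full per-item predictor table for one language.

    ``items`` must be indexed by item id and carry ``lexical_category``;
    ``norms`` carries the four rating columns (NaN where missing).
    Residualization of solo/final frequencies against frequency runs
    before any scaling.
    """
    idx = items.index
    raw, stats = count_unigrams(corpus, mapper, idx)
    total = stats["total_tokens"]
    freq = log_normalized_frequency(raw, total)
    solo_raw, final_raw = solo_and_final_counts(corpus, mapper, idx)
    solo = residualize(log_normalized_frequency(solo_raw, total), freq)
    final = residualize(log_normalized_frequency(final_raw, total), freq)
    mlu = compute_mlu_w(corpus, mapper, idx, min_occurrences=min_occurrences)

    data = pd.DataFrame({
        "frequency": freq,
        "solo_frequency": solo,
        "final_frequency": final,
        "mlu_w": mlu,
        "n_phonemes": count_phonemes(transcriptions.reindex(idx)),
        "concreteness": norms.reindex(idx)["concreteness"],
        "valence": norms.reindex(idx)["valence"],
        "arousal": norms.reindex(idx)["arousal"],
        "babiness": norms.reindex(idx)["babiness"],
        "lexical_category": items["lexical_category"],
    }, index=idx)
    table = PredictorTable(data, language=language, meta={
        "corpus_token_total": total,
        "unmapped_tokens": stats["unmapped_tokens"],
        "normalization_per": PER_MILLION,
        "mlu_min_occurrences": min_occurrences,
    })
    if scale:
        table = scale_predictors(table)
    return table
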
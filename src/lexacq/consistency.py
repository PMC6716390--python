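"""Cross-language consistency of predictor effects.

The coefficient profile of each language (its vector of standardized
main effects) is compared across languages by Pearson correlation.  How
much agreement would arise by chance is calibrated with a shuffled
bootstrap baseline: each replicate independently permutes every
language's coefficient vector and recomputes the per-language mean
pairwise correlation; the 2.5–97.5 percentile band of those replicates
is the null interval.  The similarity structure is summarized by
agglomerative clustering on the correlation distance 1 - r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class ConsistencyResult:
    pairwise_r: pd.DataFrame
    per_language_mean_r: pd.Series
    baseline_ci: pd.DataFrame        # per language: ci_low, ci_high
    overall_mean_r: float
    overall_baseline_ci: tuple[float, float]
    n_bootstrap: int
    seed: int
    measure: str | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class LanguageDendrogram:
    linkage: np.ndarray              # scipy linkage matrix
    labels: list[str]
    newick: str
    method: str


def _as_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    if len(vectors) < 2:
        raise ValueError("need at least 2 languages")
    if vectors.shape[1] < 2:
        raise ValueError("coefficient vectors must have length >= 2")
    sds = vectors.std(axis=1, ddof=0)
    if (sds == 0).any():
        bad = list(vectors.index[sds == 0])
        raise ValueError(f"constant coefficient vector(s): {bad}; "
                         "correlation undefined")
    return vectors


def pairwise_correlations(vectors: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Language x language Pearson correlations of coefficient vectors.

    ``vectors`` is languages x predictors, identically ordered columns.
    Returns the correlation matrix and each language's mean correlation
    with the others (self excluded).
    """
    vectors = _as_matrix(vectors)
    R = np.corrcoef(vectors.to_numpy())
    langs = list(vectors.index)
    mat = pd.DataFrame(R, index=langs, columns=langs)
    n = len(langs)
    mean_r = (mat.sum(axis=1) - 1.0) / (n - 1)
    return mat, mean_r


def shuffled_baseline(vectors: pd.DataFrame, n_bootstrap: int = 1000,
                      seed: int = 0, measure: str | None = None
                      ) -> ConsistencyResult:
    """Consistency result with a within-language shuffled null interval.

    Each bootstrap replicate applies an independent uniform-random
    permutation to every language's coefficient vector, then records
    the per-language mean pairwise correlation.
    """
    vectors = _as_matrix(vectors)
    mat, observed = pairwise_correlations(vectors)
    warns = []
    if n_bootstrap < 100:
        msg = f"n_bootstrap={n_bootstrap} < 100; baseline CI is unstable"
        warns.append(msg)
        warnings.warn(msg, stacklevel=2)

    rng = np.random.default_rng(seed)
    V = vectors.to_numpy()
    n_lang, n_pred = V.shape
    per_lang = np.empty((n_bootstrap, n_lang))
    overall = np.empty(n_bootstrap)
    for t in range(n_bootstrap):
        shuffled = np.take_along_axis(
            V, rng.permuted(np.tile(np.arange(n_pred), (n_lang, 1)), axis=1),
            axis=1)
        R = np.corrcoef(shuffled)
        means = (R.sum(axis=1) - 1.0) / (n_lang - 1)
        per_lang[t] = means
        overall[t] = means.mean()

    lo, hi = np.percentile(per_lang, [2.5, 97.5], axis=0)
    ci = pd.DataFrame({"ci_low": lo, "ci_high": hi}, index=vectors.index)
    olo, ohi = np.percentile(overall, [2.5, 97.5])
    return ConsistencyResult(
        pairwise_r=mat, per_language_mean_r=observed, baseline_ci=ci,
        overall_mean_r=float(observed.mean()),
        overall_baseline_ci=(float(olo), float(ohi)),
        n_bootstrap=n_bootstrap, seed=seed, measure=measure, warnings=warns)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as Newick; branch lengths are
    merge-height differences."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, h, _ = Z[i - n]
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        return f"({node(a)}:{la:.6g},{node(b)}:{lb:.6g})"

    for i, row in enumerate(Z):
        heights[n + i] = row[2]
    return node(n + len(Z) - 1) + ";"


def cluster_languages(pairwise_r: pd.DataFrame,
                      method: str = "complete") -> LanguageDendrogram:
    """Agglomerative clustering of languages on distance 1 - r."""
    R = pairwise_r.to_numpy()
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    labels = list(pairwise_r.index)
    return LanguageDendrogram(linkage=Z, labels=labels,
                              newick=_linkage_to_newick(Z, labels),
                              method=method)


def category_consistency(category_vectors: dict[str, pd.DataFrame]
                         ) -> pd.Series:
    """Mean pairwise between-language correlation per lexical category.

    ``category_vectors`` maps category name to a languages x predictors
    frame of composed per-category effects.
    """
    out = {}
    for cat, vectors in category_vectors.items():
        mat, _ = pairwise_correlations(vectors)
        vals = mat.to_numpy()[np.triu_indices(len(mat), k=1)]
        out[cat] = float(vals.mean())
    return pd.Series(out)
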
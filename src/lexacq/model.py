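"""Per-language acquisition models.

For each language and measure, a mixed-effects logistic regression
predicts whether a child knows a word from the child's (standardized)
age, the word's nine predictor values, predictor x age interactions,
and predictor x lexical-category interactions (contrast coded), with a
random intercept and a random age slope per word.  Word-level logistic
trajectory fits and cross-language coefficient summaries live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glmm import GLMMResult, fit_logistic_glmm
from .predictors import PREDICTORS, PredictorTable
from .simulate import CATEGORIES, MEASURES, _age_z

#: the contrast reference level (deviation coding drops this one)
REFERENCE_CATEGORY = "Other"


@dataclass
class ModelSpec:
    measure: str = "production"
    predictors: tuple[str, ...] = PREDICTORS
    include_age_interactions: bool = True
    include_category_interactions: bool = True
    category_coding: str = "deviation"  # or "treatment"
    random_age_slope: bool = True
    estimate_re_correlation: bool = True
    age_range: tuple[int, int] = (8, 30)

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        if not self.predictors:
            raise ValueError("predictors must be nonempty")
        if self.category_coding not in ("deviation", "treatment"):
            raise ValueError(f"unknown coding {self.category_coding!r}")


@dataclass
class DesignMatrices:
    X: np.ndarray
    colnames: list[str]
    successes: np.ndarray
    trials: np.ndarray
    group: np.ndarray           # dense word codes per row
    group_labels: list[str]     # item id per code
    age_z: np.ndarray           # per row
    spec: ModelSpec


@dataclass
class CoefficientTable:
    """Fitted standardized effects for one language x measure."""

    table: pd.DataFrame         # term, term_type, estimate, se, z, p, significant
    language: str
    measure: str
    random_sd: np.ndarray = field(default_factory=lambda: np.zeros(2))
    random_corr: float = 0.0
    loglik: float = float("nan")
    df_resid: int = 10 ** 9

    def estimate(self, term: str) -> float:
        rows = self.table.loc[self.table["term"] == term, "estimate"]
        if rows.empty:
            raise KeyError(f"no term {term!r} in coefficient table")
        return float(rows.iloc[0])

    def main_effects(self, predictors: tuple[str, ...] = PREDICTORS) -> pd.Series:
        sub = self.table[self.table["term_type"] == "main"]
        return sub.set_index("term")["estimate"].reindex(list(predictors))


def category_contrasts(categories: pd.Series, coding: str = "deviation"
                       ) -> pd.DataFrame:
    """Contrast-code lexical category.

    Deviation (sum-to-zero) coding over the four categories with
    ``Other`` as the dropped level: one column per non-reference
    category, 1 for that category, -1 for ``Other``, 0 elsewhere — each
    column sums to zero across the four levels.  Treatment coding is
    available for coding-invariance checks.
    """
    unknown = set(categories.unique()) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown lexical categories: {sorted(unknown)}")
    cols = {}
    for cat in CATEGORIES:
        if cat == REFERENCE_CATEGORY:
            continue
        col = (categories == cat).astype(float)
        if coding == "deviation":
            col = col - (categories == REFERENCE_CATEGORY).astype(float)
        cols[f"cat_{cat}"] = col
    return pd.DataFrame(cols, index=categories.index)


def build_design(administrations: pd.DataFrame, table: PredictorTable,
                 spec: ModelSpec) -> DesignMatrices:
    """Assemble the fixed-effect design for one language x measure.

    Bernoulli responses are aggregated into binomial (item, age) cells
    — exact, since every fixed effect is a function of item and age
    only — which keeps the likelihood identical while shrinking the row
    count to n_items x n_ages.
    """
    if not table.is_scaled:
        raise ValueError("predictor table must be scaled before modeling")
    preds = table.data[list(spec.predictors)]
    if preds.isna().any().any():
        raise ValueError("predictor table has missing cells; impute first")

    adm = administrations[administrations["measure"] == spec.measure]
    if adm.empty:
        raise ValueError(f"no administrations for measure {spec.measure!r}")
    unknown_items = set(adm["item_id"]) - set(table.data.index)
    if unknown_items:
        raise ValueError(f"administrations reference unknown items: "
                         f"{sorted(unknown_items)[:5]}")

    cells = (adm.groupby(["item_id", "age_months"], sort=True)["value"]
             .agg(successes="sum", trials="count").reset_index())
    age_z = _age_z(cells["age_months"].to_numpy(), spec.age_range)

    item_order = sorted(cells["item_id"].unique())
    code_of = {it: i for i, it in enumerate(item_order)}
    group = cells["item_id"].map(code_of).to_numpy()

    P = preds.loc[cells["item_id"]].to_numpy()
    cols: list[np.ndarray] = [np.ones(len(cells)), age_z]
    names: list[str] = ["(Intercept)", "age"]
    for j, p in enumerate(spec.predictors):
        cols.append(P[:, j])
        names.append(p)
    if spec.include_age_interactions:
        for j, p in enumerate(spec.predictors):
            cols.append(P[:, j] * age_z)
            names.append(f"{p}:age")
    if spec.include_category_interactions:
        # per-category slopes are identified only if every category cell
        # has comfortably more items than predictors
        counts = table.data["lexical_category"].value_counts()
        thin = counts[counts < len(spec.predictors) + 2]
        if not thin.empty:
            raise ValueError(
                "category interactions unidentifiable: categories "
                f"{thin.to_dict()} have fewer than "
                f"{len(spec.predictors) + 2} items")
        contrasts = category_contrasts(
            table.data["lexical_category"], coding=spec.category_coding)
        C = contrasts.loc[cells["item_id"]].to_numpy()
        for j, p in enumerate(spec.predictors):
            for k, cname in enumerate(contrasts.columns):
                cols.append(P[:, j] * C[:, k])
                names.append(f"{p}:{cname}")
        for k, cname in enumerate(contrasts.columns):
            cols.append(C[:, k])
            names.append(cname)

    Xmat = np.column_stack(cols)
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError("singular fixed-effect design matrix")
    return DesignMatrices(
        X=Xmat, colnames=names,
        successes=cells["successes"].to_numpy(dtype=float),
        trials=cells["trials"].to_numpy(dtype=float),
        group=group, group_labels=item_order, age_z=age_z, spec=spec)


def _term_type(name: str) -> str:
    if name == "(Intercept)":
        return "intercept"
    if name == "age":
        return "age"
    if name.startswith("cat_"):
        return "category_main"
    if ":age" in name:
        return "age_interaction"
    if ":cat_" in name:
        return "category_interaction"
    return "main"


def fit_glmm(design: DesignMatrices, language: str = "",
             **fit_kwargs) -> CoefficientTable:
    """Fit the mixed logistic model for one design; Wald SEs/p-values."""
    spec = design.spec
    Z = (np.column_stack([np.ones_like(design.age_z), design.age_z])
         if spec.random_age_slope else None)
    res: GLMMResult = fit_logistic_glmm(
        design.X, design.successes, design.trials, design.group, Z=Z,
        estimate_corr=spec.estimate_re_correlation and spec.random_age_slope,
        colnames=design.colnames, **fit_kwargs)
    pvals = res.pvalues
    df = pd.DataFrame({
        "term": design.colnames,
        "term_type": [_term_type(t) for t in design.colnames],
        "estimate": res.beta,
        "se": res.se,
        "z": res.zvalues,
        "p": pvals,
        "significant": pvals < 0.05,
    })
    return CoefficientTable(df, language=language, measure=spec.measure,
                            random_sd=res.random_sd,
                            random_corr=res.random_corr,
                            loglik=res.loglik, df_resid=res.df_resid)


def fit_logistic_trajectory(ages: np.ndarray, successes: np.ndarray,
                            trials: np.ndarray) -> tuple[float, float, pd.DataFrame]:
    """ML logistic fit of the proportion knowing a word versus age.

    Returns (intercept, slope) on the logit scale plus a frame with the
    fitted curve at the observed ages.  All-known or all-unknown data
    have no finite MLE and raise.
    """
    ages = np.asarray(ages, dtype=float)
    successes = np.asarray(successes, dtype=float)
    trials = np.asarray(trials, dtype=float)
    if ages.size < 2:
        raise ValueError("need at least 2 age groups")
    total_s, total_n = successes.sum(), trials.sum()
    if total_s == 0 or total_s == total_n:
        raise ValueError("all responses identical; logistic MLE undefined")
    X = sm.add_constant(ages)
    model = sm.GLM(np.column_stack([successes, trials - successes]), X,
                   family=sm.families.Binomial())
    fit = model.fit()
    intercept, slope = fit.params
    curve = pd.DataFrame({"age": ages,
                          "fitted": fit.predict(X),
                          "observed": successes / trials})
    return float(intercept), float(slope), curve


def summarize_coefficients(tables: list[CoefficientTable],
                           term_types: tuple[str, ...] = ("main",)
                           ) -> pd.DataFrame:
    """Mean estimate per term across fitted models, with significance
    and sign-consistency counts.

    ``n_consistent`` counts models whose estimate shares the majority
    sign for that term.
    """
    if not tables:
        raise ValueError("need at least one coefficient table")
    ref_terms = None
    frames = []
    for t in tables:
        sub = t.table[t.table["term_type"].isin(term_types)]
        terms = tuple(sub["term"])
        if ref_terms is None:
            ref_terms = terms
        elif terms != ref_terms:
            raise ValueError("coefficient tables have mismatched term sets")
        frames.append(sub.assign(language=t.language, measure=t.measure))
    allc = pd.concat(frames, ignore_index=True)

    def _summary(g: pd.DataFrame) -> pd.Series:
        signs = np.sign(g["estimate"])
        majority = 1.0 if (signs > 0).sum() >= (signs < 0).sum() else -1.0
        return pd.Series({
            "mean_estimate": g["estimate"].mean(),
            "n_models": len(g),
            "n_significant": int(g["significant"].sum()),
            "n_consistent": int((signs == majority).sum()),
        })
    out = allc.groupby("term", sort=False).apply(_summary, include_groups=False)
    return out.reindex(list(ref_terms))


def compose_category_effects(table: CoefficientTable, predictor: str,
                             category: str) -> float:
    """Combined per-category effect of a predictor: main effect of the
    predictor + main effect of the category + their interaction."""
    if category == REFERENCE_CATEGORY:
        raise ValueError(f"{REFERENCE_CATEGORY!r} is the contrast reference; "
                         "no composed effect is reported for it")
    main = table.estimate(predictor)
    cat_main = table.estimate(f"cat_{category}")
    interaction = table.estimate(f"{predictor}:cat_{category}")
    return main + cat_main + interaction


def category_effect_vectors(table: CoefficientTable,
                            predictors: tuple[str, ...] = PREDICTORS
                            ) -> dict[str, np.ndarray]:
    """Per-category composed effect vector over the predictors."""
    return {cat: np.array([compose_category_effects(table, p, cat)
                           for p in predictors])
            for cat in CATEGORIES if cat != REFERENCE_CATEGORY}
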
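"""Configuration-driven end-to-end orchestration.

Stages communicate through plain files under the run's output
directory, so each stage can be run standalone (the CLI exposes them as
subcommands) or chained by :func:`run_pipeline`:

    inputs/        simulated (or user-supplied) study files
    predictors/    per-language extracted predictor tables + metadata
    imputed/       completed predictor tables + convergence reports
    models/        coefficients.csv across languages and measures
    consistency/   pairwise matrices, shuffled baselines, dendrograms,
                   per-category consistency
    manifest.json  file checksums, stage timings, warnings, config echo

Identical config and seeds reproduce byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consistency as cons
from .corpus import read_corpus, write_corpus
from .impute import impute
from .model import (CoefficientTable, ModelSpec, build_design,
                    category_effect_vectors, fit_glmm)
from .model import summarize_coefficients
from .predictors import (PREDICTORS, PredictorTable, TokenMapper,
                         build_predictor_table, collinearity_diagnostics,
                         scale_predictors)
from .simulate import MEASURES, GroundTruth, SyntheticStudy, generate_study

log = logging.getLogger("lexacq.pipeline")


@dataclass
class RunConfig:
    out_dir: str = "lexacq_run"
    seed: int = 0
    languages: list[str] = field(
        default_factory=lambda: ["lang1", "lang2", "lang3"])
    n_items: int = 100
    n_children: int = 500
    n_utterances: int = 10_000
    age_range: tuple[int, int] = (8, 30)
    measures: tuple[str, ...] = MEASURES
    missing_rates: dict[str, float] | None = None
    mlu_min_occurrences: float = 10
    imputation_max_iterations: int = 20
    imputation_tolerance: float = 1e-6
    include_age_interactions: bool = True
    # per-category slopes need >> 9 items per category cell; the light
    # demo scale (100 items) fits the main + age-interaction model
    include_category_interactions: bool = False
    category_coding: str = "deviation"
    random_age_slope: bool = True
    estimate_re_correlation: bool = False
    n_bootstrap: int = 1000
    linkage: str = "complete"
    truth: GroundTruth | None = None   # programmatic override only

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "age_range" in raw:
            raw["age_range"] = tuple(raw["age_range"])
        if "measures" in raw:
            raw["measures"] = tuple(raw["measures"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("truth")
        d["age_range"] = list(self.age_range)
        d["measures"] = list(self.measures)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


class _Stage:
    """Context manager collecting emitted files and timing for one stage."""

    def __init__(self, manifest: dict, name: str):
        self.manifest, self.name = manifest, name
        self.files: list[Path] = []

    def emit(self, path: Path) -> Path:
        self.files.append(path)
        return path

    def __enter__(self):
        log.info("[%s] start", self.name)
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc_type is not None:
            raise RuntimeError(f"stage {self.name!r} failed: {exc}") from exc
        dt = time.perf_counter() - self._t0
        self.manifest["stages"][self.name] = {
            "seconds": round(dt, 3),
            "files": {str(p): _sha256(p) for p in self.files},
        }
        log.info("[%s] done in %.2fs", self.name, dt)


def simulate_stage(cfg: RunConfig, manifest: dict) -> SyntheticStudy:
    """Generate the synthetic study and write every input family."""
    inputs = Path(cfg.out_dir) / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    study = generate_study(
        languages=cfg.languages, n_items=cfg.n_items,
        n_children=cfg.n_children, n_utterances=cfg.n_utterances,
        age_range=cfg.age_range, measures=cfg.measures,
        truth=cfg.truth, missing_rates=cfg.missing_rates, seed=cfg.seed)
    with _Stage(manifest, "simulate") as st:
        study.administrations.to_csv(
            st.emit(inputs / "administrations.csv"), index=False)
        cats = study.items[["lexical_category"]]
        cats.to_csv(st.emit(inputs / "categories.csv"))
        trans = study.items[[f"form_{l}" for l in cfg.languages]]
        trans.to_csv(st.emit(inputs / "translations.csv"))
        for lang in cfg.languages:
            write_corpus(study.corpora[lang],
                         st.emit(inputs / f"corpus_{lang}.txt"))
            study.norms[lang].to_csv(st.emit(inputs / f"norms_{lang}.csv"))
            study.transcriptions[lang].rename("phonemes").to_csv(
                st.emit(inputs / f"transcriptions_{lang}.csv"))
            pd.Series(study.mappings["form_to_item"][lang],
                      name="item_id").rename_axis("word_form").to_csv(
                st.emit(inputs / f"form_to_item_{lang}.csv"))
            infl = pd.Series(study.mappings["inflection"][lang],
                             name="canonical_item").rename_axis("variant_form")
            infl.to_csv(st.emit(inputs / f"inflection_{lang}.csv"))
            poly_rows = [{"word_form": f, **{f"sense_item_{i+1}": s
                                             for i, s in enumerate(senses)}}
                         for f, senses in
                         study.mappings["polysemy"][lang].items()]
            pd.DataFrame(poly_rows).to_csv(
                st.emit(inputs / f"polysemy_{lang}.csv"), index=False)
    return study


def _load_mapper(inputs: Path, lang: str) -> TokenMapper:
    f2i = pd.read_csv(inputs / f"form_to_item_{lang}.csv",
                      index_col="word_form")["item_id"].to_dict()
    infl_path = inputs / f"inflection_{lang}.csv"
    infl = (pd.read_csv(infl_path, index_col="variant_form")
            ["canonical_item"].to_dict()) if infl_path.exists() else {}
    poly_path = inputs / f"polysemy_{lang}.csv"
    poly = {}
    if poly_path.exists() and poly_path.stat().st_size > 1:
        pdf = pd.read_csv(poly_path)
        if len(pdf):
            sense_cols = [c for c in pdf.columns if c.startswith("sense_item_")]
            for _, row in pdf.iterrows():
                senses = [row[c] for c in sense_cols if pd.notna(row[c])]
                poly[row["word_form"]] = senses
    return TokenMapper(f2i, infl, poly)


def predictors_stage(cfg: RunConfig, manifest: dict) -> dict[str, PredictorTable]:
    """Extract per-language predictor tables from the input files."""
    inputs = Path(cfg.out_dir) / "inputs"
    outdir = Path(cfg.out_dir) / "predictors"
    outdir.mkdir(parents=True, exist_ok=True)
    cats = pd.read_csv(inputs / "categories.csv", index_col="item_id")
    tables = {}
    with _Stage(manifest, "predictors") as st:
        for lang in cfg.languages:
            corpus = read_corpus(inputs / f"corpus_{lang}.txt", language=lang)
            norms = pd.read_csv(inputs / f"norms_{lang}.csv",
                                index_col="item_id")
            trans = pd.read_csv(inputs / f"transcriptions_{lang}.csv",
                                index_col="item_id")["phonemes"]
            table = build_predictor_table(
                corpus, cats, _load_mapper(inputs, lang), norms, trans,
                language=lang, min_occurrences=cfg.mlu_min_occurrences)
            table.data.to_csv(st.emit(outdir / f"predictors_{lang}.csv"))
            _write_json(table.meta, st.emit(outdir / f"meta_{lang}.json"))
            tables[lang] = table
    return tables


def impute_stage(cfg: RunConfig, manifest: dict) -> dict[str, PredictorTable]:
    """Impute missing cells and scale, per language."""
    pdir = Path(cfg.out_dir) / "predictors"
    outdir = Path(cfg.out_dir) / "imputed"
    outdir.mkdir(parents=True, exist_ok=True)
    cats = pd.read_csv(Path(cfg.out_dir) / "inputs" / "categories.csv",
                       index_col="item_id")
    tables = {}
    with _Stage(manifest, "impute") as st:
        for i, lang in enumerate(cfg.languages):
            data = pd.read_csv(pdir / f"predictors_{lang}.csv",
                               index_col="item_id")
            data["lexical_category"] = cats["lexical_category"]
            table = PredictorTable(data, language=lang)
            completed, report = impute(
                table, seed=cfg.seed + 1000 + i,
                max_iterations=cfg.imputation_max_iterations,
                tolerance=cfg.imputation_tolerance)
            scaled = scale_predictors(completed)
            scaled.data.to_csv(st.emit(outdir / f"imputed_{lang}.csv"))
            corr, vif = collinearity_diagnostics(scaled)
            corr.round(6).to_csv(
                st.emit(outdir / f"collinearity_{lang}.csv"))
            vif.round(6).rename("vif").rename_axis("predictor").to_csv(
                st.emit(outdir / f"vif_{lang}.csv"))
            _write_json({
                "iterations": report.iterations,
                "max_change": report.max_change,
                "converged": report.converged,
                "imputed_counts": report.imputed_counts,
                "column_order": list(report.column_order),
                "scaling": {k: list(v) for k, v in scaled.scaling.items()},
            }, st.emit(outdir / f"report_{lang}.json"))
            tables[lang] = scaled
    return tables


def fit_stage(cfg: RunConfig, manifest: dict,
              tables: dict[str, PredictorTable] | None = None
              ) -> list[CoefficientTable]:
    """Fit one mixed model per language x measure."""
    outdir = Path(cfg.out_dir) / "models"
    outdir.mkdir(parents=True, exist_ok=True)
    adm = pd.read_csv(Path(cfg.out_dir) / "inputs" / "administrations.csv")
    if tables is None:
        idir = Path(cfg.out_dir) / "imputed"
        tables = {}
        for lang in cfg.languages:
            data = pd.read_csv(idir / f"imputed_{lang}.csv",
                               index_col="item_id")
            scaling = json.loads(
                (idir / f"report_{lang}.json").read_text())["scaling"]
            tables[lang] = PredictorTable(
                data, language=lang,
                scaling={k: tuple(v) for k, v in scaling.items()})
    fits = []
    with _Stage(manifest, "fit") as st:
        for lang in cfg.languages:
            for measure in cfg.measures:
                spec = ModelSpec(
                    measure=measure,
                    include_age_interactions=cfg.include_age_interactions,
                    include_category_interactions=cfg.include_category_interactions,
                    category_coding=cfg.category_coding,
                    random_age_slope=cfg.random_age_slope,
                    estimate_re_correlation=cfg.estimate_re_correlation,
                    age_range=cfg.age_range)
                design = build_design(adm[adm["language"] == lang],
                                      tables[lang], spec)
                fits.append(fit_glmm(design, language=lang))
                log.info("fitted %s/%s (loglik %.1f)", lang, measure,
                         fits[-1].loglik)
        rows = []
        for fit in fits:
            rows.append(fit.table.assign(language=fit.language,
                                         measure=fit.measure))
        pd.concat(rows, ignore_index=True).to_csv(
            st.emit(outdir / "coefficients.csv"), index=False)
        for measure in cfg.measures:
            mfits = [f for f in fits if f.measure == measure]
            summarize_coefficients(mfits).round(6).to_csv(
                st.emit(outdir / f"summary_{measure}.csv"))
    return fits


def consistency_stage(cfg: RunConfig, manifest: dict,
                      fits: list[CoefficientTable] | None = None) -> dict:
    """Pairwise correlations, shuffled baselines, clustering, category
    consistency — per measure."""
    outdir = Path(cfg.out_dir) / "consistency"
    outdir.mkdir(parents=True, exist_ok=True)
    if fits is None:
        coef = pd.read_csv(Path(cfg.out_dir) / "models" / "coefficients.csv")
        fits = []
        for (lang, measure), g in coef.groupby(["language", "measure"]):
            fits.append(CoefficientTable(g.reset_index(drop=True),
                                         language=lang, measure=measure))
    results = {}
    with _Stage(manifest, "consistency") as st:
        for measure in cfg.measures:
            mfits = [f for f in fits if f.measure == measure]
            vectors = pd.DataFrame(
                {f.language: f.main_effects() for f in mfits}).T
            res = cons.shuffled_baseline(vectors, n_bootstrap=cfg.n_bootstrap,
                                         seed=cfg.seed + 77, measure=measure)
            res.pairwise_r.to_csv(st.emit(outdir / f"pairwise_{measure}.csv"))
            base = res.baseline_ci.copy()
            base.insert(0, "observed_mean_r", res.per_language_mean_r)
            base["n_bootstrap"] = res.n_bootstrap
            base["seed"] = res.seed
            base.to_csv(st.emit(outdir / f"baseline_{measure}.csv"))
            dend = cons.cluster_languages(res.pairwise_r, method=cfg.linkage)
            st.emit(outdir / f"dendrogram_{measure}.nwk").write_text(
                dend.newick + "\n")
            if cfg.include_category_interactions:
                cat_vectors = {}
                for f in mfits:
                    for cat, vec in category_effect_vectors(f).items():
                        cat_vectors.setdefault(cat, {})[f.language] = vec
                cat_frames = {c: pd.DataFrame(v).T
                              for c, v in cat_vectors.items()}
                cat_r = cons.category_consistency(cat_frames)
                cat_r.rename("mean_pairwise_r").rename_axis("category").to_csv(
                    st.emit(outdir / f"category_{measure}.csv"))
                results[(measure, "category_consistency")] = cat_r
            results[(measure, "consistency")] = res
            for w in res.warnings:
                manifest["warnings"].append(w)
    return results


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict(),
                                                    sort_keys=True))
    manifest: dict = {"config": cfg.to_dict(), "stages": {}, "warnings": []}
    simulate_stage(cfg, manifest)
    tables = predictors_stage(cfg, manifest)
    scaled = impute_stage(cfg, manifest)
    fits = fit_stage(cfg, manifest, scaled)
    consistency_stage(cfg, manifest, fits)
    manifest["checksums"] = {
        name: info["files"] for name, info in manifest["stages"].items()}
    _write_json(manifest, out / "manifest.json")
    return manifest
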
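"""Run the whole file-based pipeline on a synthetic demo study.

Equivalent to the CLI:  lexacq run-all --seed 1 --out-dir demo_out
Stages: simulate -> predictors -> impute -> fit -> consistency, with a
manifest of checksums making the run verifiably reproducible.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from lexacq import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(out_dir=tmp, seed=1, languages=["lang1", "lang2", "lang3"],
                    n_items=100, n_children=500, n_utterances=10_000)
    manifest = run_pipeline(cfg)

    print("Stage timings and file counts:")
    for stage, info in manifest["stages"].items():
        print(f"  {stage:12} {info['seconds']:6.2f}s  {len(info['files'])} files")

    coef = pd.read_csv(Path(tmp) / "models" / "coefficients.csv")
    main = coef[coef["term_type"] == "main"]
    print("\nMean standardized main effect across languages and measures")
    print("(frequency should be strongest, mirroring the generator):")
    print(main.groupby("term", sort=False)["estimate"].mean()
          .round(3).to_string())

    base = pd.read_csv(Path(tmp) / "consistency" / "baseline_production.csv",
                       index_col=0)
    print("\nProduction consistency (observed vs shuffled baseline):")
    print(base.round(3).to_string())
    print("\nObserved per-language mean r above ci_high means the languages")
    print("agree more than chance — the generator gave them shared effects.")
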
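"""Iterative regression imputation of missing predictor values.

Missing cells are first filled by sampling with replacement from the
observed values of the same column; the table is then swept repeatedly,
re-imputing each column's missing cells as the deterministic prediction
of an intercept-augmented linear regression of that column on all other
columns, until the largest absolute change of any imputed cell falls
below a tolerance (or a sweep cap is hit).  Observed cells are never
modified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .predictors import PREDICTORS, PredictorTable


@dataclass
class ImputationReport:
    iterations: int
    max_change: float
    converged: bool
    imputed_counts: dict[str, int]
    column_order: tuple[str, ...]


def impute(table: PredictorTable, seed: int, max_iterations: int = 20,
           tolerance: float = 1e-6,
           columns: tuple[str, ...] = PREDICTORS
           ) -> tuple[PredictorTable, ImputationReport]:
    """Fill all missing predictor cells; returns table + convergence report.

    Columns are updated in declared predictor order each sweep.  The
    initialization is the only stochastic step; given a seed the result
    is deterministic.
    """
    out = table.copy()
    X = out.data[list(columns)].astype(float).to_numpy()
    n, p = X.shape
    miss = np.isnan(X)
    if n < p + 2:
        raise ValueError("need at least predictors+2 rows to impute")
    for j, col in enumerate(columns):
        if miss[:, j].all():
            raise ValueError(f"column {col!r} has no observed values")
        if (~miss[:, j]).sum() < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")

    imputed_counts = {col: int(miss[:, j].sum())
                      for j, col in enumerate(columns)}
    if not miss.any():
        report = ImputationReport(0, 0.0, True, imputed_counts, tuple(columns))
        return out, report

    rng = np.random.default_rng(seed)
    for j in range(p):
        m = miss[:, j]
        if m.any():
            observed = X[~m, j]
            X[m, j] = rng.choice(observed, size=m.sum(), replace=True)

    max_change = np.inf
    iteration = 0
    while iteration < max_iterations and max_change >= tolerance:
        iteration += 1
        max_change = 0.0
        for j, col in enumerate(columns):
            m = miss[:, j]
            if not m.any():
                continue
            others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            # regression trained on originally-observed rows of column j
            coef, _, rank, _ = np.linalg.lstsq(others[~m], X[~m, j], rcond=None)
            if rank < others.shape[1]:
                raise ValueError(
                    f"singular regression while imputing column {col!r}")
            pred = others[m] @ coef
            max_change = max(max_change, float(np.abs(pred - X[m, j]).max()))
            X[m, j] = pred

    out.data[list(columns)] = X
    report = ImputationReport(
        iterations=iteration,
        max_change=float(max_change),
        converged=bool(max_change < tolerance),
        imputed_counts=imputed_counts,
        column_order=tuple(columns),
    )
    return out, report
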
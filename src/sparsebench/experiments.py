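"""The benchmarking grid: subsampled training sets scored against full-data
gold standards.

Each experiment draws a response column and a fixed number of predictor
columns from one (preprocessed) dataset, trains all five penalty families on
a small random subset of rows with one shared fold assignment, and scores
them on the held-out rows against the gold standard fitted on *all* rows of
that (response, predictors) draw.  Gold standards are cached and reused
across the cross-validation routines sharing a draw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .gold import GoldStandard, fit_gold_standard
from .metrics import TestSet, compute_metrics
from .solvers import PenaltySpec, fit_all_methods, make_folds

logger = logging.getLogger(__name__)

DESIGN_COLUMNS = ["experiment_id", "dataset_id", "n_train", "cv_k", "replicate"]
METRIC_COLUMNS = [
    "pve", "rr", "rte", "coef_similarity",
    "precision", "recall", "f1", "nonzero_count",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """One benchmarking cell: which columns, which training rows, which CV."""

    experiment_id: str
    dataset_id: str
    response_column: str
    predictor_columns: tuple[str, ...]
    train_indices: tuple[int, ...]
    n_train: int
    cv_k: int
    replicate: int
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.predictor_columns)) != len(self.predictor_columns):
            raise ValueError("duplicate predictor columns")
        if self.response_column in self.predictor_columns:
            raise ValueError("response column cannot be a predictor")
        if len(self.train_indices) != self.n_train:
            raise ValueError("train_indices length differs from n_train")


def build_grid(
    datasets: dict[str, ExpressionDataset],
    n_train_values: tuple[int, ...] = (25, 75, 150),
    replicates: int = 100,
    cv_routines: tuple[int, ...] = (5, 10),
    n_predictors: int = 500,
    seed: int = 0,
) -> list[ExperimentDesign]:
    """Enumerate every experiment design.

    Per (dataset, replicate, sample size) one random draw of response +
    predictors + training rows is made and shared by the cross-validation
    routines, isolating the routine effect.  All randomness derives
    deterministically from ``seed`` and the cell coordinates, so any single
    design can be regenerated in isolation.
    """
    for dataset_id, ds in datasets.items():
        if ds.n_variables < n_predictors + 1:
            raise ValueError(
                f"dataset {dataset_id!r} has {ds.n_variables} variables; "
                f"need more than {n_predictors} (predictors) + 1 (response)"
            )
        if ds.n_samples <= max(n_train_values):
            raise ValueError(
                f"dataset {dataset_id!r} has {ds.n_samples} samples; needs "
                f"more than max n_train = {max(n_train_values)} to hold out"
            )
    designs: list[ExperimentDesign] = []
    for d_idx, (dataset_id, ds) in enumerate(sorted(datasets.items())):
        for nt_idx, n_train in enumerate(n_train_values):
            for rep in range(1, replicates + 1):
                rng = np.random.default_rng([seed, d_idx, nt_idx, rep])
                cols = rng.permutation(ds.n_variables)
                response = ds.variable_ids[cols[0]]
                predictors = tuple(ds.variable_ids[j] for j in np.sort(cols[1:n_predictors + 1]))
                train = tuple(
                    int(i) for i in np.sort(
                        rng.choice(ds.n_samples, size=n_train, replace=False)
                    )
                )
                fold_seed = int(rng.integers(2**31))
                for cv_k in cv_routines:
                    designs.append(
                        ExperimentDesign(
                            experiment_id=(
                                f"{dataset_id}|n{n_train}|rep{rep:03d}|cv{cv_k}"
                            ),
                            dataset_id=dataset_id,
                            response_column=response,
                            predictor_columns=predictors,
                            train_indices=train,
                            n_train=n_train,
                            cv_k=cv_k,
                            replicate=rep,
                            seed=fold_seed,
                        )
                    )
    return designs


def gold_standard_for(
    design: ExperimentDesign,
    dataset: ExpressionDataset,
    gs_cache: dict | None = None,
    alpha: float = 0.05,
) -> GoldStandard:
    """Gold standard for the design's (response, predictors) draw, fitted on
    all dataset rows; cached under the draw so both CV routines reuse it."""
    key = (design.dataset_id, design.response_column, design.predictor_columns)
    if gs_cache is not None and key in gs_cache:
        return gs_cache[key]
    pred_idx = [dataset.column_index(v) for v in design.predictor_columns]
    resp_idx = dataset.column_index(design.response_column)
    gs = fit_gold_standard(
        dataset.values[:, pred_idx],
        dataset.values[:, resp_idx],
        alpha=alpha,
        variable_ids=list(design.predictor_columns),
    )
    if gs_cache is not None:
        gs_cache[key] = gs
    return gs


def run_experiment(
    design: ExperimentDesign,
    dataset: ExpressionDataset,
    gs_cache: dict | None = None,
    alpha: float = 0.05,
    specs: list[PenaltySpec] | None = None,
) -> list[dict]:
    """Fit all five families for one design and score them on the held-out
    rows.  Returns one record per family; a solver failure is recorded on its
    row (metrics NaN) without aborting the rest."""
    pred_idx = [dataset.column_index(v) for v in design.predictor_columns]
    resp_idx = dataset.column_index(design.response_column)
    x_full = dataset.values[:, pred_idx]
    y_full = dataset.values[:, resp_idx]

    gs = gold_standard_for(design, dataset, gs_cache, alpha=alpha)

    train = np.asarray(design.train_indices)
    test_mask = np.ones(dataset.n_samples, dtype=bool)
    test_mask[train] = False
    test = TestSet(x_full[test_mask], y_full[test_mask])

    folds = make_folds(design.n_train, design.cv_k, design.seed)
    fits = fit_all_methods(x_full[train], y_full[train], folds, specs=specs)

    meta = {
        "experiment_id": design.experiment_id,
        "dataset_id": design.dataset_id,
        "n_train": design.n_train,
        "cv_k": design.cv_k,
        "replicate": design.replicate,
        "gs_snr": gs.snr,
        "gs_active_count": gs.active_count,
    }
    records = []
    for fit in fits:
        if fit.error is not None:
            logger.warning(
                "%s %s failed: %s", design.experiment_id, fit.penalty, fit.error
            )
            rec = {
                **meta,
                "penalty": fit.penalty,
                **{m: float("nan") for m in METRIC_COLUMNS},
                "cv_mse": float("nan"),
                "error": fit.error,
            }
        else:
            metric = compute_metrics(
                design.experiment_id, fit.penalty, fit.beta_hat, gs, test
            )
            rec = {
                **meta,
                **metric.as_dict(),
                "cv_mse": fit.cv_mse,
                "error": "",
            }
        records.append(rec)
    return records


def run_grid(
    designs: list[ExperimentDesign],
    datasets: dict[str, ExpressionDataset],
    alpha: float = 0.05,
    specs: list[PenaltySpec] | None = None,
) -> pd.DataFrame:
    """Execute every design serially (experiments are independent, so the
    result is identical under any execution order) and return the long-format
    results table: one row per (experiment, penalty)."""
    gs_cache: dict = {}
    rows: list[dict] = []
    for i, design in enumerate(designs):
        rows.extend(
            run_experiment(design, datasets[design.dataset_id], gs_cache, alpha, specs)
        )
        if (i + 1) % 50 == 0 or i + 1 == len(designs):
            logger.info("completed %d/%d experiments", i + 1, len(designs))
    frame = pd.DataFrame(rows)
    ordered = (
        DESIGN_COLUMNS
        + ["gs_snr", "gs_active_count", "penalty"]
        + METRIC_COLUMNS
        + ["cv_mse", "error"]
    )
    return frame[ordered]


def summarise(
    results: pd.DataFrame,
    group_by: tuple[str, ...] = ("penalty", "n_train"),
    metrics: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Median and interquartile range per group, long format: one row per
    (group, metric).  Quantiles use linear interpolation."""
    if results.empty:
        raise ValueError("empty results table")
    if metrics is None:
        metrics = tuple(METRIC_COLUMNS)
    rows = []
    for keys, chunk in results.groupby(list(group_by), sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for metric in metrics:
            values = chunk[metric].dropna()
            if values.empty:
                logger.warning("no values for %s in group %s", metric, keys)
                continue
            rows.append(
                {
                    **dict(zip(group_by, keys)),
                    "metric": metric,
                    "median": values.median(),
                    "q1": values.quantile(0.25),
                    "q3": values.quantile(0.75),
                    "n": len(values),
                }
            )
    return pd.DataFrame(rows)
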
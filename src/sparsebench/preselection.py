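"""External rank-aggregation penalty preselection versus internal CV.

For a target experiment, the preselected penalty family is the one with the
lowest rank-sum of test performance across all experiments of the same
training-sample size in the *other* datasets (rank 1 = best, average ranks
on ties).  Its realised performance is compared, experiment by experiment,
with that of the family minimising the internal cross-validation MSE, via a
two-sided paired t-test per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .solvers import METHOD_ORDER, FittedModel

#: Metrics used for preselection, all oriented so larger is better.
COMPARISON_METRICS: tuple[str, ...] = ("pve", "f1", "coef_similarity")


@dataclass
class SelectionComparison:
    """Preselected vs internally selected performance for one experiment."""

    experiment_id: str
    metric: str
    preselected_method: str
    internal_method: str
    preselected_value: float
    internal_value: float

    @property
    def improvement(self) -> float:
        return self.preselected_value - self.internal_value


@dataclass
class PairedTestSummary:
    """Two-sided paired t-test of the preselection improvement."""

    metric: str
    t_score: float
    df: int
    mean_gain: float
    ci95: tuple[float, float]
    p_value: float


def _first_in_method_order(methods: list[str]) -> str:
    for name in METHOD_ORDER:
        if name in methods:
            return name
    raise ValueError(f"no known method among {methods}")


def rank_sums(external: pd.DataFrame, metric: str) -> pd.Series:
    """Per-method rank sums over the external experiments (rank 1 = best,
    ties get average ranks)."""
    table = external.pivot(index="experiment_id", columns="penalty", values=metric)
    ranks = table.rank(axis=1, ascending=False, method="average")
    return ranks.sum(axis=0)


def preselect_method(
    results: pd.DataFrame, target_dataset: str, n_train: int, metric: str
) -> str:
    """Rank-aggregation choice of penalty family for every experiment of the
    target dataset at this sample size, using only the other datasets."""
    external = results[
        (results["n_train"] == n_train) & (results["dataset_id"] != target_dataset)
    ]
    if external.empty:
        raise ValueError(
            f"no external experiments for dataset {target_dataset!r} at "
            f"n_train={n_train}; preselection needs other datasets"
        )
    sums = rank_sums(external, metric)
    best = sums[sums == sums.min()].index.tolist()
    return _first_in_method_order(best)


def preselect(results: pd.DataFrame, target_experiment, metric: str) -> str:
    """Preselected method label for one target experiment (leave the target's
    dataset out entirely)."""
    return preselect_method(
        results, target_experiment.dataset_id, target_experiment.n_train, metric
    )


def internal_select(fits: list[FittedModel]) -> str:
    """Method with the lowest internal CV MSE; ties break by the fixed
    method order."""
    for fit in fits:
        if fit.cv_mse is None or np.isnan(fit.cv_mse):
            raise ValueError(f"method {fit.penalty} has no cv_mse")
    best = min(fit.cv_mse for fit in fits)
    return _first_in_method_order([f.penalty for f in fits if f.cv_mse == best])


def _internal_select_rows(chunk: pd.DataFrame) -> str:
    if chunk["cv_mse"].isna().any():
        missing = chunk.loc[chunk["cv_mse"].isna(), "penalty"].tolist()
        raise ValueError(f"missing cv_mse for {missing}")
    best = chunk["cv_mse"].min()
    return _first_in_method_order(
        chunk.loc[chunk["cv_mse"] == best, "penalty"].tolist()
    )


def paired_t(differences: np.ndarray, metric: str) -> PairedTestSummary:
    """Closed-form two-sided paired t-test on the per-experiment improvement.
    Zero variance of the differences returns t=0, p=1 (degenerate guard)."""
    d = np.asarray(differences, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("paired t-test needs at least 2 paired observations")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        return PairedTestSummary(metric, 0.0, df, mean, (mean, mean), 1.0)
    se = sd / np.sqrt(n)
    t_score = mean / se
    p = 2.0 * float(t_dist.sf(abs(t_score), df))
    half = float(t_dist.ppf(0.975, df)) * se
    return PairedTestSummary(metric, float(t_score), df, mean, (mean - half, mean + half), p)


def compare_selection(
    results: pd.DataFrame,
) -> tuple[list[SelectionComparison], list[PairedTestSummary]]:
    """Per-experiment preselection-vs-internal comparison and the per-metric
    paired t-tests.

    The preselected method depends only on (target dataset, sample size,
    metric), so it is computed once per cell; the internal choice minimises
    each experiment's own CV MSE.  The output is invariant to the row order
    of ``results``.
    """
    results = results.sort_values(["experiment_id", "penalty"], kind="stable")
    cells = results[["dataset_id", "n_train"]].drop_duplicates()
    pre_choice: dict[tuple[str, int, str], str] = {}
    for _, cell in cells.iterrows():
        for metric in COMPARISON_METRICS:
            pre_choice[(cell.dataset_id, cell.n_train, metric)] = preselect_method(
                results, cell.dataset_id, cell.n_train, metric
            )

    comparisons: list[SelectionComparison] = []
    for experiment_id, chunk in results.groupby("experiment_id", sort=True):
        internal = _internal_select_rows(chunk)
        values = chunk.set_index("penalty")
        dataset_id = chunk["dataset_id"].iloc[0]
        n_train = int(chunk["n_train"].iloc[0])
        for metric in COMPARISON_METRICS:
            pre = pre_choice[(dataset_id, n_train, metric)]
            comparisons.append(
                SelectionComparison(
                    experiment_id=experiment_id,
                    metric=metric,
                    preselected_method=pre,
                    internal_method=internal,
                    preselected_value=float(values.loc[pre, metric]),
                    internal_value=float(values.loc[internal, metric]),
                )
            )

    summaries = [
        paired_t(
            np.array([c.improvement for c in comparisons if c.metric == metric]),
            metric,
        )
        for metric in COMPARISON_METRICS
    ]
    return comparisons, summaries


def comparisons_frame(comparisons: list[SelectionComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "experiment_id": c.experiment_id,
            "metric": c.metric,
            "preselected_method": c.preselected_method,
            "internal_method": c.internal_method,
            "preselected_value": c.preselected_value,
            "internal_value": c.internal_value,
            "improvement": c.improvement,
        }
        for c in comparisons
    )


def summaries_frame(summaries: list[PairedTestSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "metric": s.metric,
            "t": s.t_score,
            "df": s.df,
            "mean_gain": s.mean_gain,
            "ci95_low": s.ci95[0],
            "ci95_high": s.ci95[1],
            "p_value": s.p_value,
        }
        for s in summaries
    )


def improvement_cdf(
    comparisons: list[SelectionComparison], metric: str
) -> pd.DataFrame:
    """Empirical CDF points (x, F(x)) of the improvement for one metric."""
    values = np.sort(
        [c.improvement for c in comparisons if c.metric == metric]
    )
    if values.size == 0:
        raise ValueError(f"no comparisons for metric {metric!r}")
    frac = np.arange(1, values.size + 1) / values.size
    return pd.DataFrame({"metric": metric, "improvement": values, "cdf": frac})
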
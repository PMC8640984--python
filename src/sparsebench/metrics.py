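"""Predictive and structural validation metrics against the gold standard.

All expectations are empirical means over the held-out test rows.  The
division-by-zero convention for the discrete selection metrics is zero
replacement: any undefined precision / recall / F1 is reported as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np

from .gold import GoldStandard


@dataclass
class TestSet:
    """Held-out design rows and responses, disjoint from training."""

    __test__ = False  # not a pytest item, despite the name

    x_test: np.ndarray
    y_test: np.ndarray

    def __post_init__(self) -> None:
        self.x_test = np.asarray(self.x_test, dtype=float)
        self.y_test = np.asarray(self.y_test, dtype=float).ravel()
        if self.x_test.shape[0] != self.y_test.shape[0]:
            raise ValueError("x_test and y_test row counts differ")
        if self.x_test.shape[0] == 0:
            raise ValueError("empty test set")


@dataclass
class MetricRecord:
    """All metrics for one (experiment, penalty) pair."""

    experiment_id: str
    penalty: str
    pve: float
    rr: float
    rte: float
    coef_similarity: float
    precision: float
    recall: float
    f1: float
    nonzero_count: int

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def pve(beta_hat: np.ndarray, test: TestSet) -> float:
    """Proportion of variance explained on the test rows:
    1 - mean((y0 - x0'b)^2) / Var(y0), with the unbiased sample variance of
    the test response.  Negative values mean worse-than-null prediction."""
    var_y = float(np.var(test.y_test, ddof=1))
    if var_y <= 0.0:
        raise ValueError("test response has zero variance; PVE is undefined")
    resid = test.y_test - test.x_test @ beta_hat
    return 1.0 - float(np.mean(resid**2)) / var_y


def relative_risk(beta_hat: np.ndarray, gs: GoldStandard, test: TestSet) -> float:
    """Mean squared difference between the estimated and gold-standard linear
    predictors, normalised by the gold-standard predictor's mean square.
    0 is optimal; the all-zero model scores exactly 1."""
    ref = test.x_test @ gs.beta_star
    denom = float(np.mean(ref**2))
    if denom <= 0.0:
        raise ValueError(
            "gold-standard linear predictor is zero on the test set; "
            "relative risk is undefined"
        )
    diff = ref - test.x_test @ beta_hat
    return float(np.mean(diff**2)) / denom


def relative_test_error(beta_hat: np.ndarray, gs: GoldStandard, test: TestSet) -> float:
    """Test MSE of the estimate over test MSE of the gold standard; the gold
    standard itself scores exactly 1.  A zero denominator (noiseless gold
    standard) returns an infinite sentinel with a warning."""
    ref_err = float(np.mean((test.y_test - test.x_test @ gs.beta_star) ** 2))
    est_err = float(np.mean((test.y_test - test.x_test @ beta_hat) ** 2))
    if ref_err <= 0.0:
        warnings.warn(
            "gold-standard test error is zero; relative test error is unbounded",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return est_err / ref_err


def coefficient_similarity(beta_hat: np.ndarray, gs: GoldStandard) -> float:
    """Cosine similarity between the estimated and gold-standard coefficient
    vectors; an all-zero vector scores 0 (zero-replacement convention)."""
    nh = float(np.linalg.norm(beta_hat))
    ns = float(np.linalg.norm(gs.beta_star))
    if nh == 0.0 or ns == 0.0:
        return 0.0
    return float(np.dot(beta_hat, gs.beta_star) / (nh * ns))


def selection_scores(
    beta_hat: np.ndarray, gs: GoldStandard
) -> tuple[float, float, float, int]:
    """Precision / recall / F1 of the nonzero support against the
    FDR-significant gold-standard active set, plus the nonzero count.
    Division by zero yields 0."""
    predicted = np.asarray(beta_hat) != 0
    truth = np.asarray(gs.active, dtype=bool)
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1, int(predicted.sum())


def compute_metrics(
    experiment_id: str,
    penalty: str,
    beta_hat: np.ndarray,
    gs: GoldStandard,
    test: TestSet,
) -> MetricRecord:
    """All eight metrics for one fitted model."""
    precision, recall, f1, nnz = selection_scores(beta_hat, gs)
    return MetricRecord(
        experiment_id=experiment_id,
        penalty=penalty,
        pve=pve(beta_hat, test),
        rr=relative_risk(beta_hat, gs, test),
        rte=relative_test_error(beta_hat, gs, test),
        coef_similarity=coefficient_similarity(beta_hat, gs),
        precision=precision,
        recall=recall,
        f1=f1,
        nonzero_count=nnz,
    )
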
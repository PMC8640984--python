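"""Full-data OLS gold-standard models.

With the true coefficient vector unknown on real data, the benchmark treats
the ordinary-least-squares fit on the *whole* dataset (large n, no intercept)
as a noisy gold standard: its coefficient vector is the reference for
structural metrics, and its FDR-significant coefficients define the "true"
active set for variable-selection scoring.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import qr, solve_triangular
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests


@dataclass
class GoldStandard:
    """OLS fit on all observations plus the derived significance calls.

    ``active`` marks coefficients whose Benjamini-Hochberg q-value is below
    ``alpha``; ``snr`` is the empirical variance of the fitted linear
    predictor divided by the unbiased residual variance (n - p degrees of
    freedom).
    """

    beta_star: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    active: np.ndarray
    alpha: float
    residual_variance: float
    snr: float
    n_obs: int
    p_vars: int
    variable_ids: list[str] = field(default_factory=list)

    @property
    def active_count(self) -> int:
        return int(self.active.sum())

    def to_frame(self) -> pd.DataFrame:
        ids = self.variable_ids or [f"v{j}" for j in range(self.p_vars)]
        return pd.DataFrame(
            {
                "variable_id": ids,
                "beta": self.beta_star,
                "se": self.se,
                "t": self.t_stat,
                "p": self.p_value,
                "q": self.q_value,
                "active": self.active,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha": self.alpha,
            "residual_variance": self.residual_variance,
            "snr": self.snr,
            "n_obs": self.n_obs,
            "p_vars": self.p_vars,
            "variable_ids": self.variable_ids,
            "beta_star": self.beta_star.tolist(),
            "se": self.se.tolist(),
            "t_stat": self.t_stat.tolist(),
            "p_value": self.p_value.tolist(),
            "q_value": self.q_value.tolist(),
            "active": self.active.astype(bool).tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def fit_gold_standard(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    variable_ids: list[str] | None = None,
) -> GoldStandard:
    """Fit the no-intercept OLS gold standard and its FDR-controlled active set.

    The solve is QR-based (numerically equivalent to the normal-equations
    definition ``(X'X)^-1 X'y`` on full-rank inputs).  Standard errors use
    the classical OLS covariance with the unbiased residual variance on
    ``n - p`` degrees of freedom; two-sided p-values come from the t
    distribution with ``n - p`` df and are Benjamini-Hochberg adjusted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if y.shape[0] != n:
        raise ValueError(f"y has {y.shape[0]} entries for {n} rows of X")
    if n <= p:
        raise ValueError(
            f"gold standard requires n > p (got n={n}, p={p}); the t reference "
            "and the Gram inverse need positive residual degrees of freedom"
        )
    q_mat, r_mat = qr(x, mode="economic")
    diag = np.abs(np.diag(r_mat))
    if diag.min() <= 1e-10 * max(diag.max(), 1e-300):
        raise ValueError(
            "design matrix is rank deficient; remove collinear columns with "
            "preprocessing.full_rank_subspace first"
        )
    beta = solve_triangular(r_mat, q_mat.T @ y)
    residuals = y - x @ beta
    df_resid = n - p
    residual_variance = float(residuals @ residuals) / df_resid
    # diag((X'X)^-1) equals the squared row norms of R^-1
    r_inv = solve_triangular(r_mat, np.eye(p))
    gram_inv_diag = np.sum(r_inv**2, axis=1)
    se = np.sqrt(residual_variance * gram_inv_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p_value = 2.0 * t_dist.sf(np.abs(t_stat), df_resid)
    q_value = multipletests(p_value, method="fdr_bh")[1]
    active = q_value < alpha

    gs = GoldStandard(
        beta_star=beta,
        se=se,
        t_stat=t_stat,
        p_value=p_value,
        q_value=q_value,
        active=active,
        alpha=alpha,
        residual_variance=residual_variance,
        snr=0.0,
        n_obs=n,
        p_vars=p,
        variable_ids=list(variable_ids) if variable_ids is not None else [],
    )
    gs.snr = estimate_snr(gs, x, y)
    return gs


def estimate_snr(gs: GoldStandard, x: np.ndarray, y: np.ndarray) -> float:
    """Signal-to-noise ratio estimated from the gold standard's residuals:
    empirical variance of the fitted linear predictor over the unbiased
    residual variance.  A zero residual variance (noiseless construction)
    returns an infinite sentinel with a warning."""
    fitted = np.asarray(x, dtype=float) @ gs.beta_star
    signal_var = float(np.var(fitted, ddof=1))
    if signal_var == 0.0:
        return 0.0
    # residual variance at floating-point noise level counts as noiseless
    if gs.residual_variance <= 1e-12 * signal_var:
        warnings.warn(
            "zero residual variance: SNR is unbounded (noiseless fit)",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("inf")
    return signal_var / gs.residual_variance
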
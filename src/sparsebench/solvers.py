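"""The five penalised-regression families and their shared-fold CV selection.

Families combine an L0 (cardinality), L1 (absolute) and L2 (squared) penalty
on a squared-error loss without intercept:

    L0    : lam0 only          (best-subset surrogate, coordinate descent)
    L0L1  : lam0 + lam1
    L0L2  : lam0 + lam2
    L1    : lam1 only          (LASSO)
    L1L2  : lam1 + lam2        (elastic net, mixing grid)

The L0 family is solved by the in-package coordinate-descent kernels with
hard-threshold closed forms and bounded swap moves (see ``_cd``).  The L1
family delegates to scikit-learn's coordinate descent (``enet_path``), with
the pure-ridge mixing value handled in closed form via SVD.  Hyperparameters
are selected by minimising mean held-out MSE over cross-validation folds that
are *shared* across all five families within an experiment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import enet_path

from . import _cd

#: Fixed method order, used everywhere ties must break deterministically.
METHOD_ORDER: tuple[str, ...] = ("L0", "L0L1", "L0L2", "L1", "L1L2")

#: Elastic-net mixing grid (the L1 share of the combined L1+L2 penalty).
DEFAULT_MIXING_GRID: tuple[float, ...] = (
    0.0, 0.11, 0.22, 0.33, 0.44, 0.56, 0.67, 0.78, 0.89, 1.0,
)

# glmnet-style floor when computing the lambda path for tiny mixing values
_MIXING_FLOOR = 1e-3


@dataclass(frozen=True)
class PenaltySpec:
    """One penalty family plus its hyperparameter grid.

    Defaults mirror the conventional library grids: a 100-value log-spaced
    primary-penalty path with min/max ratio 1e-4, 10 log-spaced secondary
    penalties in [1e-4, 10] for the L0 combinations, the 10-value mixing
    grid for the elastic net, convergence tolerance 1e-6 with at most 200
    cycles, and a 1000-move swap cap.  No intercept is fitted: inputs are
    rank-Gaussianised and near zero mean, and disabling the intercept keeps
    all five families on the identical objective.
    """

    name: str
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    n_gamma: int = 10
    gamma_min: float = 1e-4
    gamma_max: float = 10.0
    mixing_grid: tuple[float, ...] = DEFAULT_MIXING_GRID
    tol: float = 1e-6
    max_iter: int = 200
    max_swaps: int = 1000
    swaps_in_cv: bool = False
    fit_intercept: bool = False

    def __post_init__(self) -> None:
        if self.name not in METHOD_ORDER:
            raise ValueError(f"unknown penalty {self.name!r}; expected one of {METHOD_ORDER}")
        if self.fit_intercept:
            raise ValueError("intercepts are disabled for all families")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")

    @property
    def lambda0_active(self) -> bool:
        return self.name.startswith("L0")

    @property
    def lambda1_active(self) -> bool:
        return "L1" in self.name

    @property
    def lambda2_active(self) -> bool:
        return self.name.endswith("L2") and self.name != "L2"

    @property
    def is_l0_family(self) -> bool:
        return self.lambda0_active


def default_specs() -> list[PenaltySpec]:
    return [PenaltySpec(name) for name in METHOD_ORDER]


@dataclass(frozen=True)
class FoldAssignment:
    """A balanced k-fold partition of the training rows."""

    fold_id: np.ndarray
    k: int
    seed: int

    @property
    def n(self) -> int:
        return self.fold_id.shape[0]


@dataclass
class FittedModel:
    """One cross-validated fit of one penalty family."""

    penalty: str
    beta_hat: np.ndarray
    intercept: float = 0.0
    selected_hyperparams: dict = field(default_factory=dict)
    cv_mse: float = float("nan")
    nonzero_count: int = 0
    error: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "penalty": self.penalty,
            "intercept": self.intercept,
            "selected_hyperparams": self.selected_hyperparams,
            "cv_mse": self.cv_mse,
            "nonzero_count": self.nonzero_count,
            "error": self.error,
            "beta_hat": self.beta_hat.tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def make_folds(n: int, k: int, seed: int) -> FoldAssignment:
    """Deterministic balanced k-fold assignment (fold sizes differ by <= 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} observations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=np.int64)
    fold_id[perm] = np.arange(n) % k
    return FoldAssignment(fold_id=fold_id, k=k, seed=seed)


# ---------------------------------------------------------------------------
# path grids


@dataclass
class _PathGroup:
    """One warm-start group: fixed secondary penalties plus a descending
    primary path."""

    kind: str                    # "l0" or "l1"
    lam1: float = 0.0            # l0 kind: fixed L1 penalty
    lam2: float = 0.0            # l0 kind: fixed L2 penalty
    mixing: float = 0.0          # l1 kind: elastic-net mixing value
    primary: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _validate_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.ascontiguousarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2 or y.shape[0] != x.shape[0]:
        raise ValueError("X must be 2-D with one y entry per row")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in X or y")
    return x, y


def _secondary_values(spec: PenaltySpec) -> np.ndarray:
    if spec.name == "L0":
        return np.array([0.0])
    return np.geomspace(spec.gamma_min, spec.gamma_max, spec.n_gamma)


def _lam0_path(x, y, spec, lam1, lam2) -> np.ndarray:
    """Data-driven descending lam0 path.  The first value is the smallest
    lam0 at which the null model is a coordinate-wise minimum (the strict
    hard-threshold keeps the path's head at exactly the null model)."""
    c = np.abs(x.T @ y)
    m = np.maximum(c - lam1, 0.0)
    colsq = np.einsum("ij,ij->j", x, x)
    den = colsq + 2.0 * lam2
    ok = den > 0
    lam0_max = float(np.max(m[ok] ** 2 / (2.0 * den[ok]))) if ok.any() else 0.0
    if lam0_max <= 0.0:
        return np.array([1.0])
    # nudge above the exact threshold so the path head is the null model
    # despite floating-point rounding
    lam0_max *= 1.0 + 1e-9
    return np.geomspace(lam0_max, lam0_max * spec.lambda_min_ratio, spec.n_lambda)


def _alpha_path(x, y, spec, mixing) -> np.ndarray:
    """Descending elastic-net alpha path on scikit-learn's per-sample scale."""
    n = x.shape[0]
    m_eff = max(mixing, _MIXING_FLOOR)
    alpha_max = float(np.max(np.abs(x.T @ y))) / (n * m_eff)
    if alpha_max <= 0.0:
        return np.array([1.0])
    alpha_max *= 1.0 + 1e-9  # keep the path head strictly at the null model
    return np.geomspace(alpha_max, alpha_max * spec.lambda_min_ratio, spec.n_lambda)


def make_grid(x: np.ndarray, y: np.ndarray, spec: PenaltySpec) -> list[_PathGroup]:
    """Build the hyperparameter grid on the (full) training data.  The same
    explicit grid is reused in every CV fold so fold MSEs are comparable
    point by point."""
    x, y = _validate_xy(x, y)
    groups: list[_PathGroup] = []
    if spec.is_l0_family:
        for gamma in _secondary_values(spec):
            lam1 = gamma if spec.name == "L0L1" else 0.0
            lam2 = gamma if spec.name == "L0L2" else 0.0
            groups.append(
                _PathGroup(kind="l0", lam1=lam1, lam2=lam2,
                           primary=_lam0_path(x, y, spec, lam1, lam2))
            )
    else:
        mixings = spec.mixing_grid if spec.name == "L1L2" else (1.0,)
        for m in mixings:
            groups.append(
                _PathGroup(kind="l1", mixing=m,
                           primary=_alpha_path(x, y, spec, m))
            )
    if not groups or not any(g.primary.size for g in groups):
        raise ValueError("empty hyperparameter grid")
    return groups


def _ridge_path_betas(x, y, alphas) -> np.ndarray:
    """Closed-form ridge solutions for all alphas at once (p x n_alphas)."""
    n = x.shape[0]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    uty = u.T @ y
    lam2s = n * np.asarray(alphas) / 2.0
    shrink = s[:, None] / (s[:, None] ** 2 + 2.0 * lam2s[None, :])
    return vt.T @ (shrink * uty[:, None])


def _fit_group(
    x, y, spec: PenaltySpec, group: _PathGroup, in_cv: bool = False,
    gram: np.ndarray | None = None, xy: np.ndarray | None = None,
) -> np.ndarray:
    """Fit one warm-start group; returns betas with shape (p, len(primary)).

    ``x`` must be Fortran-ordered float64.  Within CV folds the L0 family
    runs plain coordinate descent (the swap polish is applied to the
    full-training fits whose coefficients are actually reported) and the
    elastic-net solver uses a looser duality tolerance; hyperparameter
    scoring only needs fold MSEs that are comparable across grid points.
    """
    p = x.shape[1]
    out = np.empty((p, group.primary.size))
    if group.kind == "l0":
        max_swaps = spec.max_swaps if (not in_cv or spec.swaps_in_cv) else 0
        out[:] = _cd.solve_l0_path(
            x, y, group.primary, group.lam1, group.lam2,
            spec.tol, spec.max_iter, max_swaps,
        )
    elif group.mixing == 0.0:
        out[:] = _ridge_path_betas(x, y, group.primary)
    else:
        with warnings.catch_warnings():
            # fold fits deliberately run at a loose duality tolerance
            warnings.simplefilter("ignore", ConvergenceWarning)
            extra = {}
            if gram is not None:
                extra = {"precompute": gram, "Xy": xy}
            _, coefs, _ = enet_path(
                x, y, l1_ratio=group.mixing, alphas=group.primary,
                tol=1e-4 if in_cv else 1e-7, max_iter=100_000,
                check_input=False, **extra,
            )
        out[:] = coefs
    return out


def _fit_grid(
    x, y, spec: PenaltySpec, grid: list[_PathGroup], in_cv: bool = False
) -> list[np.ndarray]:
    xf = np.asfortranarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    gram = xy = None
    if any(g.kind == "l1" and g.mixing > 0.0 for g in grid):
        gram = np.ascontiguousarray(xf.T @ xf)
        xy = xf.T @ y
    return [_fit_group(xf, y, spec, g, in_cv=in_cv, gram=gram, xy=xy) for g in grid]


def _point_hyperparams(spec: PenaltySpec, group: _PathGroup, value: float, n: int) -> dict:
    if group.kind == "l0":
        return {"lambda0": float(value), "lambda1": group.lam1, "lambda2": group.lam2}
    # translate sklearn's per-sample alpha to the objective scale used here
    return {
        "lambda0": 0.0,
        "lambda1": n * value * group.mixing,
        "lambda2": n * value * (1.0 - group.mixing) / 2.0,
        "mixing": group.mixing,
        "alpha": float(value),
    }


def fit_path(
    x: np.ndarray, y: np.ndarray, spec: PenaltySpec
) -> list[tuple[dict, np.ndarray]]:
    """Fit the full regularisation path; returns (hyperparams, beta) pairs in
    grid order."""
    x, y = _validate_xy(x, y)
    grid = make_grid(x, y, spec)
    path: list[tuple[dict, np.ndarray]] = []
    n = x.shape[0]
    for group, betas in zip(grid, _fit_grid(x, y, spec, grid)):
        for i, value in enumerate(group.primary):
            path.append((_point_hyperparams(spec, group, value, n), betas[:, i].copy()))
    return path


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    folds: FoldAssignment,
) -> FittedModel:
    """Select hyperparameters by mean held-out MSE over the shared folds.

    The grid is built once on the full training data and re-fitted within
    each fold; the winning point's full-training solution is returned.  Ties
    in CV MSE break toward the sparser full-training solution, then toward
    the larger primary penalty.
    """
    x, y = _validate_xy(x, y)
    if folds.n != x.shape[0]:
        raise ValueError(
            f"fold assignment covers {folds.n} rows but X has {x.shape[0]}"
        )
    n = x.shape[0]
    grid = make_grid(x, y, spec)

    full_betas = _fit_grid(x, y, spec, grid)
    n_points = sum(g.primary.size for g in grid)
    fold_mse = np.zeros((folds.k, n_points))
    for f in range(folds.k):
        tr = folds.fold_id != f
        va = ~tr
        fold_betas = _fit_grid(x[tr], y[tr], spec, grid, in_cv=True)
        offset = 0
        for g, betas in zip(grid, fold_betas):
            pred = x[va] @ betas
            fold_mse[f, offset:offset + g.primary.size] = np.mean(
                (y[va, None] - pred) ** 2, axis=0
            )
            offset += g.primary.size
    mean_mse = fold_mse.mean(axis=0)

    best_mse = float(mean_mse.min())
    candidates = np.flatnonzero(mean_mse == best_mse)

    def tiebreak_key(flat_idx: int):
        g_idx, within = _locate(grid, flat_idx)
        beta = full_betas[g_idx][:, within]
        primary = grid[g_idx].primary[within]
        return (int(np.count_nonzero(beta)), -primary, flat_idx)

    best_flat = min(candidates, key=tiebreak_key)
    g_idx, within = _locate(grid, best_flat)
    group = grid[g_idx]
    beta = full_betas[g_idx][:, within].copy()
    return FittedModel(
        penalty=spec.name,
        beta_hat=beta,
        selected_hyperparams=_point_hyperparams(spec, group, group.primary[within], n),
        cv_mse=best_mse,
        nonzero_count=int(np.count_nonzero(beta)),
    )


def _locate(grid: list[_PathGroup], flat_idx: int) -> tuple[int, int]:
    offset = 0
    for g_idx, g in enumerate(grid):
        if flat_idx < offset + g.primary.size:
            return g_idx, flat_idx - offset
        offset += g.primary.size
    raise IndexError(flat_idx)


def fit_all_methods(
    x: np.ndarray,
    y: np.ndarray,
    folds: FoldAssignment,
    specs: Sequence[PenaltySpec] | None = None,
) -> list[FittedModel]:
    """Fit all five families with the identical fold assignment, in the fixed
    order L0, L0L1, L0L2, L1, L1L2.  A failure in one family is recorded on
    its ``FittedModel`` without aborting the batch."""
    if specs is None:
        specs = default_specs()
    fits: list[FittedModel] = []
    p = np.asarray(x).shape[1]
    for spec in specs:
        try:
            fits.append(cross_validate(x, y, spec, folds))
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            fits.append(
                FittedModel(
                    penalty=spec.name,
                    beta_hat=np.zeros(p),
                    cv_mse=float("nan"),
                    nonzero_count=0,
                    error=f"{type(exc).__name__}: {exc}",
                )
            )
    return fits
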
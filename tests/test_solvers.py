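"""Penalised-regression solvers: fold construction, path correctness,
oracle equivalence, KKT conditions, and CV selection."""

import itertools
from collections import Counter

import numpy as np
import pytest

from sparsebench import _cd
from sparsebench.solvers import (
    METHOD_ORDER,
    PenaltySpec,
    cross_validate,
    default_specs,
    fit_all_methods,
    fit_path,
    make_folds,
)


class TestFolds:
    def test_exact_division(self):
        folds = make_folds(25, 5, seed=0)
        assert Counter(Counter(folds.fold_id).values()) == {5: 5}

    def test_balanced_sizes(self):
        folds = make_folds(75, 10, seed=1)
        sizes = sorted(Counter(folds.fold_id).values())
        assert sum(sizes) == 75
        assert max(sizes) - min(sizes) <= 1
        assert Counter(sizes) == {7: 5, 8: 5}

    def test_deterministic(self):
        a = make_folds(40, 5, seed=9)
        b = make_folds(40, 5, seed=9)
        np.testing.assert_array_equal(a.fold_id, b.fold_id)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            make_folds(4, 5, seed=0)


@pytest.fixture(scope="module")
def small_instance():
    rng = np.random.default_rng(100)
    n, p = 50, 12
    x = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[[1, 4]] = [1.5, -1.0]
    y = x @ beta + rng.normal(0, 0.5, n)
    return x, y


@pytest.mark.parametrize("name", METHOD_ORDER)
def test_path_head_is_null_model(small_instance, name):
    """The largest primary penalty on each sparsity-inducing path segment
    fully shrinks the model.  (The elastic net's mixing value 0 is pure
    ridge, which shrinks without selecting, so it is exempt.)"""
    x, y = small_instance
    path = fit_path(x, y, PenaltySpec(name))
    seen_groups = set()
    for hp, beta in path:
        if "mixing" in hp:
            key = hp["mixing"]
        else:
            key = (hp["lambda1"], hp["lambda2"])
        if key in seen_groups:
            continue
        seen_groups.add(key)  # first (largest-penalty) point of each group
        if hp.get("mixing") == 0.0:
            continue  # pure ridge shrinks without selecting
        assert np.count_nonzero(beta) == 0, hp


def test_l1_on_orthonormal_design_is_soft_thresholding():
    rng = np.random.default_rng(3)
    q, _ = np.linalg.qr(rng.standard_normal((60, 10)))
    x = q  # orthonormal columns
    y = rng.standard_normal(60)
    c = x.T @ y
    path = fit_path(x, y, PenaltySpec("L1"))
    for hp, beta in path[:: len(path) // 10]:
        lam1 = hp["lambda1"]
        expected = np.sign(c) * np.maximum(np.abs(c) - lam1, 0.0)
        np.testing.assert_allclose(beta, expected, atol=1e-6)


def test_l0_path_matches_exhaustive_best_subset():
    """On p<=8 instances, every support size visited by the L0 path attains
    the exhaustive best-subset residual sum of squares (small sample of the
    larger oracle suite)."""
    spec = PenaltySpec("L0")
    failures = 0
    for inst in range(25):
        rng = np.random.default_rng(7000 + inst)
        n, p = 30, 6
        x = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[rng.choice(p, 2, replace=False)] = rng.uniform(0.5, 1.5, 2)
        y = x @ beta + rng.normal(0, 1.0, n)
        best_rss = {}
        for _, b in fit_path(x, y, spec):
            k = int(np.count_nonzero(b))
            rss = float(np.sum((y - x @ b) ** 2))
            best_rss[k] = min(best_rss.get(k, np.inf), rss)
        for k, rss in best_rss.items():
            opt = float(y @ y)
            for subset in itertools.combinations(range(p), k):
                if not subset:
                    continue
                bs, *_ = np.linalg.lstsq(x[:, subset], y, rcond=None)
                rv = y - x[:, subset] @ bs
                opt = min(opt, float(rv @ rv))
            if rss > opt + 1e-6:
                failures += 1
                break
    assert failures == 0


def test_l1_kkt_conditions(small_instance):
    """Stationarity of the LASSO solutions: per-sample gradient bounded by
    the penalty for zero coefficients and equal to it (with sign) for
    active ones."""
    x, y = small_instance
    n = x.shape[0]
    path = fit_path(x, y, PenaltySpec("L1"))
    for hp, beta in path:
        alpha = hp["alpha"]
        grad = x.T @ (y - x @ beta) / n
        zero = beta == 0
        assert np.all(np.abs(grad[zero]) <= alpha + 1e-5)
        active = ~zero
        np.testing.assert_allclose(
            grad[active], alpha * np.sign(beta[active]), atol=1e-5
        )


@pytest.mark.parametrize("name", ["L0", "L1"])
def test_objective_monotone_along_path(small_instance, name):
    """The penalised objective at the solution never increases as the
    primary penalty decreases (all else fixed)."""
    x, y = small_instance
    path = fit_path(x, y, PenaltySpec(name))
    if name == "L0":
        objs = [
            _cd.objective(np.asfortranarray(x), y, b, hp["lambda0"], 0.0, 0.0)
            for hp, b in path
        ]
    else:
        objs = [
            0.5 * np.sum((y - x @ b) ** 2) + hp["lambda1"] * np.abs(b).sum()
            for hp, b in path
        ]
    assert all(b <= a + 1e-8 for a, b in zip(objs, objs[1:]))


def test_coordinate_descent_fixed_point(small_instance):
    """One extra full sweep at the solution moves no coefficient by more
    than the convergence tolerance."""
    x, y = small_instance
    spec = PenaltySpec("L0L2")
    path = fit_path(x, y, spec)
    hp, beta = path[len(path) // 2]
    xf = np.asfortranarray(x)
    colsq = np.einsum("ij,ij->j", x, x)
    r = y - x @ beta
    beta_after = beta.copy()
    delta = _cd._sweep(
        xf, r, beta_after, colsq, hp["lambda0"], hp["lambda1"], hp["lambda2"], False
    )
    assert delta <= spec.tol * 10


class TestCrossValidate:
    def test_single_path_point_selected_trivially(self, small_instance):
        x, y = small_instance
        spec = PenaltySpec("L1", n_lambda=1)
        folds = make_folds(x.shape[0], 5, seed=0)
        fit = cross_validate(x, y, spec, folds)
        assert fit.nonzero_count == 0  # the single point is the null head

    def test_pure_noise_often_selects_null_l0(self):
        """With no signal at n=25, the L0 family usually keeps the null
        model."""
        nulls = 0
        reps = 12
        for s in range(reps):
            rng = np.random.default_rng(9000 + s)
            x = rng.standard_normal((25, 40))
            y = rng.standard_normal(25)
            folds = make_folds(25, 5, seed=s)
            fit = cross_validate(x, y, PenaltySpec("L0"), folds)
            nulls += fit.nonzero_count == 0
        assert nulls >= reps // 2

    def test_strong_signal_recovered_by_l0l2(self):
        hits = 0
        reps = 15
        for s in range(reps):
            rng = np.random.default_rng(500 + s)
            x = rng.standard_normal((100, 20))
            beta = np.zeros(20)
            beta[[3, 15]] = [1.0, -1.0]
            y = x @ beta + rng.normal(0, 0.1, 100)
            folds = make_folds(100, 5, seed=s)
            fit = cross_validate(x, y, PenaltySpec("L0L2"), folds)
            hits += {3, 15} <= set(np.flatnonzero(fit.beta_hat))
        assert hits >= reps - 1

    def test_ties_prefer_sparser_then_larger_penalty(self):
        """With a constant-zero response every grid point scores the same CV
        MSE; the null model at the largest penalty must win."""
        rng = np.random.default_rng(11)
        x = rng.standard_normal((30, 8))
        y = np.zeros(30)
        folds = make_folds(30, 5, seed=2)
        fit = cross_validate(x, y, PenaltySpec("L0"), folds)
        assert fit.nonzero_count == 0
        assert fit.cv_mse == 0.0


class TestFitAllMethods:
    def test_returns_five_records_in_fixed_order(self, small_instance):
        x, y = small_instance
        folds = make_folds(x.shape[0], 5, seed=4)
        fits = fit_all_methods(x, y, folds)
        assert [f.penalty for f in fits] == list(METHOD_ORDER)
        assert all(f.error is None for f in fits)

    def test_deterministic_hyperparameters(self, small_instance):
        x, y = small_instance
        folds = make_folds(x.shape[0], 5, seed=4)
        fits1 = fit_all_methods(x, y, folds)
        fits2 = fit_all_methods(x, y, folds)
        for f1, f2 in zip(fits1, fits2):
            assert f1.selected_hyperparams == f2.selected_hyperparams
            np.testing.assert_array_equal(f1.beta_hat, f2.beta_hat)

    def test_failures_recorded_without_aborting(self):
        x = np.full((20, 5), np.nan)
        y = np.zeros(20)
        folds = make_folds(20, 5, seed=0)
        fits = fit_all_methods(x, y, folds)
        assert len(fits) == 5
        assert all(f.error is not None for f in fits)
        assert all("non-finite" in f.error for f in fits)

    def test_hardest_cell_completes(self):
        """n=25 training rows against 500 predictors runs to completion for
        all five families."""
        rng = np.random.default_rng(77)
        x = rng.standard_normal((25, 500))
        beta = np.zeros(500)
        beta[:3] = [1.0, -1.0, 0.5]
        y = x @ beta + rng.normal(0, 1.0, 25)
        folds = make_folds(25, 5, seed=1)
        fits = fit_all_methods(x, y, folds)
        assert [f.penalty for f in fits] == list(METHOD_ORDER)
        assert all(f.error is None for f in fits)
        assert all(np.isfinite(f.cv_mse) for f in fits)


def test_penalty_spec_flags():
    flags = {
        "L0": (True, False, False),
        "L0L1": (True, True, False),
        "L0L2": (True, False, True),
        "L1": (False, True, False),
        "L1L2": (False, True, True),
    }
    for name, (l0, l1, l2) in flags.items():
        spec = PenaltySpec(name)
        assert (spec.lambda0_active, spec.lambda1_active, spec.lambda2_active) == (
            l0, l1, l2,
        )
    with pytest.raises(ValueError):
        PenaltySpec("L2")


def test_default_specs_order():
    assert [s.name for s in default_specs()] == list(METHOD_ORDER)
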
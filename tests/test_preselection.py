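"""Rank-aggregation preselection, internal CV selection, and the paired
comparison."""

import numpy as np
import pandas as pd
import pytest

from sparsebench.preselection import (
    COMPARISON_METRICS,
    compare_selection,
    comparisons_frame,
    improvement_cdf,
    internal_select,
    paired_t,
    preselect_method,
    rank_sums,
)
from sparsebench.solvers import METHOD_ORDER, FittedModel


def _results_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "experiment_id", "dataset_id", "n_train", "penalty",
            "pve", "f1", "coef_similarity", "cv_mse",
        ],
    )


def _full_table(rng, n_datasets=3, reps=4, n_train=25, favourite="L0L2"):
    """Synthetic results table; ``favourite`` gets a bump on every metric."""
    rows = []
    for d in range(n_datasets):
        for rep in range(reps):
            for m in METHOD_ORDER:
                bump = 0.3 if m == favourite else 0.0
                rows.append(
                    {
                        "experiment_id": f"d{d}|rep{rep}",
                        "dataset_id": f"d{d}",
                        "n_train": n_train,
                        "penalty": m,
                        "pve": rng.random() * 0.2 + bump,
                        "f1": rng.random() * 0.2 + bump,
                        "coef_similarity": rng.random() * 0.2 + bump,
                        "cv_mse": rng.random(),
                    }
                )
    return _results_frame(rows)


class TestPreselect:
    def test_dominant_method_selected(self):
        table = _full_table(np.random.default_rng(0))
        assert preselect_method(table, "d0", 25, "pve") == "L0L2"

    def test_leave_one_dataset_out(self):
        """The target dataset's own experiments never influence the choice:
        make L1 dominant everywhere except in the target."""
        rng = np.random.default_rng(1)
        external = _full_table(rng, n_datasets=2, favourite="L1")
        target = _full_table(rng, n_datasets=1, favourite="L0")
        target["dataset_id"] = "target"
        target["experiment_id"] = "t|" + target["experiment_id"]
        table = pd.concat([external, target], ignore_index=True)
        assert preselect_method(table, "target", 25, "pve") == "L1"

    def test_rank_sum_tie_broken_by_method_order(self):
        # two external experiments; L0 ranks (1,2), L0L1 ranks (2,1),
        # L0L2 ranks (3,3): tie between L0 and L0L1 resolves to L0
        rows = [
            ("e1", "d1", 25, "L0", 0.9, 0, 0, 0),
            ("e1", "d1", 25, "L0L1", 0.8, 0, 0, 0),
            ("e1", "d1", 25, "L0L2", 0.1, 0, 0, 0),
            ("e2", "d1", 25, "L0", 0.5, 0, 0, 0),
            ("e2", "d1", 25, "L0L1", 0.6, 0, 0, 0),
            ("e2", "d1", 25, "L0L2", 0.2, 0, 0, 0),
        ]
        table = _results_frame(rows)
        sums = rank_sums(table, "pve")
        assert sums["L0"] == sums["L0L1"] == 3.0
        assert preselect_method(table, "d0", 25, "pve") == "L0"

    def test_rank_sum_conservation(self):
        """With 5 methods the per-experiment ranks always total 15, so the
        rank sums over E external experiments total 15E (even with ties)."""
        table = _full_table(np.random.default_rng(2), n_datasets=3, reps=5)
        tied = table.copy()
        tied.loc[tied["penalty"].isin(["L0", "L1"]), "pve"] = 0.5
        for t in (table, tied):
            external = t[t["dataset_id"] != "d0"]
            n_experiments = external["experiment_id"].nunique()
            assert rank_sums(external, "pve").sum() == pytest.approx(
                15 * n_experiments
            )

    def test_no_external_experiments_raises(self):
        table = _full_table(np.random.default_rng(3), n_datasets=1)
        with pytest.raises(ValueError, match="external"):
            preselect_method(table, "d0", 25, "pve")


class TestInternalSelect:
    def _fits(self, mses):
        return [
            FittedModel(penalty=m, beta_hat=np.zeros(2), cv_mse=v)
            for m, v in zip(METHOD_ORDER, mses)
        ]

    def test_argmin(self):
        assert internal_select(self._fits([5, 4, 3, 2, 1])) == "L1L2"

    def test_tie_broken_by_method_order(self):
        assert internal_select(self._fits([1, 1, 1, 1, 1])) == "L0"

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            mses = rng.random(5)
            expected = METHOD_ORDER[int(np.argmin(mses))]
            assert internal_select(self._fits(mses)) == expected

    def test_missing_cv_mse_named(self):
        fits = self._fits([1, 2, 3, 4, float("nan")])
        with pytest.raises(ValueError, match="L1L2"):
            internal_select(fits)


class TestPairedT:
    def test_matches_closed_form_on_fixture(self):
        d = np.array([0.1, -0.05, 0.2, 0.0, 0.15, -0.1, 0.05, 0.3, -0.2, 0.12])
        out = paired_t(d, "pve")
        n = d.size
        mean, sd = d.mean(), d.std(ddof=1)
        t_expected = mean / (sd / np.sqrt(n))
        assert out.t_score == pytest.approx(t_expected, abs=1e-10)
        assert out.df == n - 1
        assert out.mean_gain == pytest.approx(mean, abs=1e-12)
        assert 0 <= out.p_value <= 1
        assert out.ci95[0] < mean < out.ci95[1]

    def test_degenerate_zero_variance(self):
        out = paired_t(np.zeros(8), "f1")
        assert out.t_score == 0.0
        assert out.p_value == 1.0
        assert out.mean_gain == 0.0

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            paired_t(np.array([0.1]), "pve")


class TestCompareSelection:
    def test_identical_selections_give_zero_gain(self):
        """When the internally selected method is also the rank-aggregation
        winner everywhere, every paired test is degenerate (t=0, p=1)."""
        table = _full_table(np.random.default_rng(5), favourite="L0L2")
        table.loc[table["penalty"] == "L0L2", "cv_mse"] = 0.0
        comparisons, summaries = compare_selection(table)
        for s in summaries:
            assert s.mean_gain == 0.0
            assert s.t_score == 0.0
            assert s.p_value == 1.0

    def test_three_summaries_one_per_metric(self):
        table = _full_table(np.random.default_rng(6))
        comparisons, summaries = compare_selection(table)
        assert [s.metric for s in summaries] == list(COMPARISON_METRICS)
        n_experiments = table["experiment_id"].nunique()
        assert len(comparisons) == n_experiments * 3
        for s in summaries:
            assert s.df == n_experiments - 1

    def test_row_order_invariance(self):
        table = _full_table(np.random.default_rng(7))
        shuffled = table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        _, s1 = compare_selection(table)
        _, s2 = compare_selection(shuffled)
        for a, b in zip(s1, s2):
            assert a.t_score == pytest.approx(b.t_score, abs=1e-12)
            assert a.mean_gain == pytest.approx(b.mean_gain, abs=1e-12)

    def test_dominant_method_yields_nonnegative_gain(self):
        """If one method dominates every dataset on every metric,
        preselection can never do worse on average than internal CV."""
        rng = np.random.default_rng(8)
        table = _full_table(rng, n_datasets=4, reps=6, favourite="L0L1")
        comparisons, summaries = compare_selection(table)
        for s in summaries:
            assert s.mean_gain >= 0.0

    def test_improvement_cdf_points(self):
        table = _full_table(np.random.default_rng(9))
        comparisons, _ = compare_selection(table)
        cdf = improvement_cdf(comparisons, "pve")
        assert cdf["cdf"].iloc[-1] == 1.0
        assert cdf["improvement"].is_monotonic_increasing
        frame = comparisons_frame(comparisons)
        assert (frame["improvement"] ==
                frame["preselected_value"] - frame["internal_value"]).all()
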
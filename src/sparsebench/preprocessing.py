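"""Dataset preparation: sparse-variable subspace, Gaussian rank transform,
and pivoted-QR removal of collinear variables.

The three steps run in a fixed order — subspace selection, then the
rank-based inverse-normal transform, then the full-rank extraction — which
guarantees the Gram matrix downstream OLS needs is invertible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.linalg import qr
from scipy.special import ndtri
from scipy.stats import rankdata

from .datasets import ExpressionDataset

#: Boundary rule applied inside the inverse-normal transform: the tie-aware
#: <=-counting rank r is mapped through Phi^-1(r / (n + 1)), keeping every
#: output finite (the naive r / n rule sends each column maximum to +inf).
ECDF_BOUNDARY_RULE = "rank/(n+1)"


@dataclass
class PreprocessReport:
    """What preprocessing kept and dropped."""

    retained_variable_ids: list[str]
    dropped_collinear_ids: list[str]
    rank: int
    ecdf_boundary_rule: str = ECDF_BOUNDARY_RULE
    constant_variable_ids: list[str] = field(default_factory=list)
    subspace_selected: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def select_sparse_subspace(
    data: ExpressionDataset, k: int = 1000, threshold_p: int = 5000
) -> ExpressionDataset:
    """Keep the ``k`` variables with the fewest nonzero entries when the
    dataset is very wide (more than ``threshold_p`` variables); otherwise
    return the input unchanged.

    Ties in the nonzero count are broken by original column order, so the
    selection is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if data.n_variables <= threshold_p:
        return data
    nonzero_counts = np.count_nonzero(data.values, axis=0)
    order = np.argsort(nonzero_counts, kind="stable")[:k]
    keep = np.sort(order)
    return replace(
        data,
        values=data.values[:, keep].copy(),
        variable_ids=[data.variable_ids[j] for j in keep],
        sample_ids=list(data.sample_ids),
    )


def gaussian_ecdf_transform(data: ExpressionDataset) -> ExpressionDataset:
    """Per-column rank-based inverse-normal transform.

    Each value is replaced by Phi^-1 of its tie-aware empirical CDF, where
    the CDF counts entries ``<=`` the value; the ``rank/(n+1)`` boundary
    rule keeps all outputs finite.  Ties map to identical outputs and the
    within-column ordering is preserved.  A constant column maps to the
    single finite value Phi^-1(n/(n+1)).
    """
    if data.n_samples < 2:
        raise ValueError("need at least 2 samples to rank-transform")
    n = data.n_samples
    out = np.empty_like(data.values)
    for j in range(data.n_variables):
        ranks = rankdata(data.values[:, j], method="max")
        out[:, j] = ndtri(ranks / (n + 1.0))
    return replace(data, values=out, sample_ids=list(data.sample_ids),
                   variable_ids=list(data.variable_ids))


def full_rank_subspace(
    data: ExpressionDataset, rel_tol: float = 1e-9
) -> tuple[ExpressionDataset, PreprocessReport]:
    """Drop (near-)perfectly collinear columns via column-pivoted QR.

    Columns whose pivoted diagonal magnitude satisfies
    ``|R_ii| <= rel_tol * |R_11|`` are removed; of a collinear group the
    pivot order keeps the larger-norm member.  Retained columns keep their
    original order.
    """
    values = data.values
    _, r, piv = qr(values, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0.0:
        rank = 0
    else:
        rank = int(np.sum(diag > rel_tol * diag[0]))
    keep = np.sort(piv[:rank])
    dropped = [data.variable_ids[j] for j in sorted(piv[rank:])]
    reduced = replace(
        data,
        values=values[:, keep].copy(),
        variable_ids=[data.variable_ids[j] for j in keep],
        sample_ids=list(data.sample_ids),
    )
    report = PreprocessReport(
        retained_variable_ids=list(reduced.variable_ids),
        dropped_collinear_ids=dropped,
        rank=rank,
    )
    return reduced, report


def preprocess(
    data: ExpressionDataset,
    k: int = 1000,
    threshold_p: int = 5000,
    rel_tol: float = 1e-9,
) -> tuple[ExpressionDataset, PreprocessReport]:
    """Full preparation pipeline: subspace selection -> inverse-normal
    transform -> full-rank extraction."""
    subset = select_sparse_subspace(data, k=k, threshold_p=threshold_p)
    constant = [
        subset.variable_ids[j]
        for j in range(subset.n_variables)
        if np.all(subset.values[:, j] == subset.values[0, j])
    ]
    transformed = gaussian_ecdf_transform(subset)
    reduced, report = full_rank_subspace(transformed, rel_tol=rel_tol)
    report.constant_variable_ids = constant
    report.subspace_selected = subset.n_variables != data.n_variables
    return reduced, report
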
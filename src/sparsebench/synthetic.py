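"""Synthetic expression-like datasets with known sparse linear structure.

The generator emulates the statistical features of the large-n genomic
matrices the benchmark was designed around: thousands of samples, hundreds of
variables, a response that is itself one column of the matrix, a small
right-skewed active set of true predictors (scale-free-like connectivity),
modest inter-predictor correlation, and one of three signal-to-noise regimes
(high / intermediate / low).  Optional perfectly duplicated columns and
mostly-zero count columns exercise the preprocessing stages.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .datasets import ExpressionDataset

#: Target SNR medians per regime, matching the empirical medians of the three
#: kinds of source datasets the benchmark was characterised on.
SNR_TARGETS: dict[str, float] = {"high": 12.03, "intermediate": 1.58, "low": 0.44}

#: Dataset-suite regime profile: one high-, one intermediate- and three
#: low-SNR datasets.
DEFAULT_SUITE_REGIMES: tuple[str, ...] = (
    "high",
    "intermediate",
    "low",
    "low",
    "low",
)

# Discrete log-normal law for the number of true predictors per response.
# exp(mu) = 7 pins the median at 7; sigma = ln(40/7)/z_0.95 pins the 95th
# quantile at 40.  The implied quartiles (~3.4, ~14.4) bracket the observed
# right-skewed spread, and draws are truncated below at 1.
ACTIVE_SIZE_MEDIAN = 7.0
ACTIVE_SIZE_SIGMA = math.log(40.0 / 7.0) / 1.6448536269514722


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic dataset.

    ``active_set_size`` overrides the log-normal draw with a fixed size
    (0 is allowed and produces a pure-noise response).  ``snr_target``
    overrides the regime's median target.
    """

    n_samples: int = 4000
    n_variables: int = 500
    snr_regime: str = "intermediate"
    snr_target: float | None = None
    active_size_median: float = ACTIVE_SIZE_MEDIAN
    active_size_sigma: float = ACTIVE_SIZE_SIGMA
    active_set_size: int | None = None
    coef_low: float = 0.5
    coef_high: float = 2.0
    predictor_correlation: float = 0.3
    correlation_block_size: int = 10
    n_duplicate_columns: int = 0
    n_sparse_count_columns: int = 0
    sparse_nonzero_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_variables < 2:
            raise ValueError("need n_samples >= 2 and n_variables >= 2")
        if self.snr_regime not in SNR_TARGETS:
            raise ValueError(
                f"snr_regime must be one of {sorted(SNR_TARGETS)}, "
                f"got {self.snr_regime!r}"
            )
        if self.snr_target is not None and self.snr_target <= 0:
            raise ValueError("snr_target must be positive")
        if not 0 <= self.predictor_correlation < 1:
            raise ValueError("predictor_correlation must lie in [0, 1)")
        if self.active_set_size is not None and self.active_set_size < 0:
            raise ValueError("active_set_size must be >= 0")

    @property
    def target_snr(self) -> float:
        return self.snr_target if self.snr_target is not None else SNR_TARGETS[self.snr_regime]


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic dataset.

    ``beta_true`` has one entry per emitted column (appended duplicate and
    sparse-count columns carry zeros); ``realized_snr`` is the empirical
    variance of the noiseless linear predictor divided by ``noise_variance``.
    """

    beta_true: np.ndarray
    response_index: int
    response_id: str
    noise_variance: float
    realized_snr: float
    active_ids: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["beta_true"] = [float(b) for b in self.beta_true]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["beta_true"] = np.asarray(payload["beta_true"], dtype=float)
        return cls(**payload)


def draw_active_set_size(config: SyntheticConfig, rng: np.random.Generator) -> int:
    """Draw the number of true predictors from the zero-truncated discrete
    log-normal law (median ~7, 95th quantile ~40)."""
    if config.active_set_size is not None:
        k = config.active_set_size
        if k > config.n_variables - 1:
            raise ValueError(
                f"active_set_size {k} exceeds the {config.n_variables - 1} "
                "available predictor columns"
            )
        return k
    mu = math.log(config.active_size_median)
    for _ in range(1000):
        k = int(round(rng.lognormal(mu, config.active_size_sigma)))
        k = max(k, 1)
        if k <= config.n_variables - 1:
            return k
    raise ValueError(
        "could not draw an active-set size <= n_variables - 1 after 1000 "
        "attempts; increase n_variables or fix active_set_size"
    )


def _correlated_gaussian(
    n: int, p: int, rho: float, block: int, rng: np.random.Generator
) -> np.ndarray:
    """Equicorrelated Gaussian blocks: within a block of ``block`` columns the
    pairwise correlation is ``rho``; blocks are independent."""
    x = rng.standard_normal((n, p))
    if rho <= 0:
        return x
    for start in range(0, p, block):
        stop = min(start + block, p)
        shared = rng.standard_normal(n)
        x[:, start:stop] = (
            math.sqrt(rho) * shared[:, None]
            + math.sqrt(1.0 - rho) * x[:, start:stop]
        )
    return x


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate one dataset plus its ground-truth record.

    One designated column of the emitted matrix is the response
    ``y = X_active @ beta + noise``; the Gaussian noise variance is solved
    analytically from the target SNR given the realized empirical variance of
    the noiseless predictor, so the realized SNR equals the regime target
    exactly (except in the null-signal case, where it is 0).
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_variables

    x = _correlated_gaussian(
        n, p, config.predictor_correlation, config.correlation_block_size, rng
    )
    response_index = int(rng.integers(p))
    candidates = np.delete(np.arange(p), response_index)

    k = draw_active_set_size(config, rng)
    active = np.sort(rng.choice(candidates, size=k, replace=False))
    magnitudes = rng.uniform(config.coef_low, config.coef_high, size=k)
    signs = rng.choice([-1.0, 1.0], size=k)

    beta_core = np.zeros(p)
    beta_core[active] = signs * magnitudes

    signal = x @ beta_core
    signal_var = float(np.var(signal, ddof=1))
    if signal_var > 0:
        noise_variance = signal_var / config.target_snr
        realized_snr = signal_var / noise_variance
    else:  # null-signal case: unit noise, zero SNR
        noise_variance = 1.0
        realized_snr = 0.0
    y = signal + rng.normal(0.0, math.sqrt(noise_variance), size=n)
    x[:, response_index] = y

    variable_ids = [f"g{j:04d}" for j in range(p)]
    columns = [x]
    beta_parts = [beta_core]

    if config.n_duplicate_columns > 0:
        src = rng.choice(candidates, size=config.n_duplicate_columns, replace=True)
        columns.append(x[:, src].copy())
        variable_ids += [
            f"dup{i:03d}_of_{variable_ids[j]}" for i, j in enumerate(src)
        ]
        beta_parts.append(np.zeros(config.n_duplicate_columns))

    if config.n_sparse_count_columns > 0:
        m = config.n_sparse_count_columns
        counts = rng.poisson(3.0, size=(n, m)) + 1.0
        mask = rng.random((n, m)) < config.sparse_nonzero_fraction
        columns.append(counts * mask)
        variable_ids += [f"sparse{i:03d}" for i in range(m)]
        beta_parts.append(np.zeros(m))

    values = np.hstack(columns)
    beta_true = np.concatenate(beta_parts)
    dataset = ExpressionDataset(
        values=values,
        sample_ids=[f"s{i:04d}" for i in range(n)],
        variable_ids=variable_ids,
        provenance=f"synthetic(regime={config.snr_regime}, seed={config.seed})",
    )
    truth = SyntheticTruth(
        beta_true=beta_true,
        response_index=response_index,
        response_id=dataset.variable_ids[response_index],
        noise_variance=noise_variance,
        realized_snr=realized_snr,
        active_ids=[dataset.variable_ids[j] for j in active],
    )
    return dataset, truth


def generate_dataset_suite(
    n_datasets: int,
    regimes: list[str] | tuple[str, ...] | None = None,
    seed: int = 0,
    **config_overrides,
) -> list[tuple[ExpressionDataset, SyntheticTruth]]:
    """Generate a suite of datasets with per-dataset seeds derived from
    ``seed``.  Regimes are assigned in the order given (cycled if fewer than
    ``n_datasets``); the default profile mirrors one high-, one intermediate-
    and three low-SNR datasets.

    At least two datasets are required because rank-aggregation preselection
    scores each target dataset using experiments from the *other* datasets.
    """
    if n_datasets < 2:
        raise ValueError(
            "n_datasets must be >= 2: penalty preselection requires external "
            "datasets to rank methods on"
        )
    if regimes is None:
        regimes = DEFAULT_SUITE_REGIMES
    if not regimes:
        raise ValueError("regimes must be nonempty")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_datasets) >> 1
    suite = []
    for i in range(n_datasets):
        config = SyntheticConfig(
            snr_regime=regimes[i % len(regimes)],
            seed=int(child_seeds[i]),
            **config_overrides,
        )
        suite.append(generate_dataset(config))
    return suite


def write_dataset(
    dataset: ExpressionDataset, truth: SyntheticTruth, out_dir: str | Path, name: str
) -> None:
    """Write the matrix as TSV (first column sample ids) with a JSON truth
    sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.to_frame().to_csv(out / f"{name}.tsv", sep="\t", index_label="sample_id")
    truth.to_json(out / f"{name}.truth.json")
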
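"""End-to-end orchestration: (synthesise) -> preprocess -> grid -> run ->
summarise -> preselection comparison, with every stage's outputs archived."""

from __future__ import annotations

import logging
import time
from pathlib import Path

from .config import RunConfig
from .datasets import ExpressionDataset
from .experiments import build_grid, run_grid, summarise
from .io import read_dataset_dir, write_expression_matrix
from .preprocessing import preprocess
from .preselection import (
    COMPARISON_METRICS,
    compare_selection,
    comparisons_frame,
    improvement_cdf,
    summaries_frame,
)
from .synthetic import generate_dataset_suite

logger = logging.getLogger(__name__)


def _load_or_generate(config: RunConfig, out: Path) -> dict[str, ExpressionDataset]:
    if config.datasets_dir is not None:
        return read_dataset_dir(config.datasets_dir, config.orientation)
    params = dict(config.synthetic or {})
    n_datasets = params.pop("n_datasets", 5)
    regimes = params.pop("regimes", None)
    suite = generate_dataset_suite(
        n_datasets, regimes=regimes, seed=config.seed, **params
    )
    datasets = {}
    data_dir = out / "datasets"
    data_dir.mkdir(parents=True, exist_ok=True)
    for i, (ds, truth) in enumerate(suite):
        name = f"synthetic{i}"
        datasets[name] = ds
        write_expression_matrix(ds, data_dir / f"{name}.tsv")
        truth.to_json(data_dir / f"{name}.truth.json")
    return datasets


def run_pipeline(config: RunConfig) -> int:
    """Run all stages; returns 0 on success, 1 on stage failure (partial
    outputs are kept and the failing stage is named in the log)."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    stage = "setup"
    try:
        stage = "load/generate datasets"
        t0 = time.perf_counter()
        raw = _load_or_generate(config, out)
        logger.info("%s: %d datasets (%.1fs)", stage, len(raw), time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        datasets = {}
        for name, ds in raw.items():
            prepped, report = preprocess(
                ds,
                k=config.subspace_k,
                threshold_p=config.subspace_threshold_p,
                rel_tol=config.qr_rel_tol,
            )
            report.to_json(out / f"preprocess_{name}.json")
            datasets[name] = prepped
        logger.info("%s done (%.1fs)", stage, time.perf_counter() - t0)

        stage = "build grid"
        designs = build_grid(
            datasets,
            n_train_values=tuple(config.n_train_values),
            replicates=config.replicates,
            cv_routines=tuple(config.cv_routines),
            n_predictors=config.n_predictors,
            seed=config.seed,
        )
        logger.info("%s: %d experiment designs", stage, len(designs))

        stage = "run experiments"
        t0 = time.perf_counter()
        results = run_grid(designs, datasets, alpha=config.alpha)
        results.to_csv(out / "results.csv", index=False)
        logger.info("%s done (%.1fs)", stage, time.perf_counter() - t0)

        stage = "summarise"
        summarise(results).to_csv(out / "summary.csv", index=False)

        stage = "preselection"
        comparisons, summaries = compare_selection(results)
        comparisons_frame(comparisons).to_csv(out / "preselection_comparisons.csv", index=False)
        summaries_frame(summaries).to_csv(out / "preselection_tests.csv", index=False)
        cdf_frames = [improvement_cdf(comparisons, m) for m in COMPARISON_METRICS]
        import pandas as pd

        pd.concat(cdf_frames, ignore_index=True).to_csv(
            out / "preselection_cdf.csv", index=False
        )
    except Exception:
        logger.exception("pipeline failed during stage: %s", stage)
        return 1
    logger.info("pipeline complete; outputs in %s", out)
    return 0
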
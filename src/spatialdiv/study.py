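"""Headline bias/accuracy study: run the experiment suite and aggregate.

The full printed design (100 demes, N = 10,000 haploids, mu = 2e-8,
20 replicates, sample sizes 10-50) is expensive; the package's standard
desk-scale study runs every experiment at a proportionally shrunk
configuration (25 demes, N = 1,000, mu = 2e-7, 10 replicates, migration
rates {0.001, 0.01, 0.1, 0.5}, sample sizes {10, 20, 30}) chosen to
keep per-site diversity at the full design's order of magnitude while
fitting a single-CPU run.  Experiment #5 (random sampling from one
panmictic deme) additionally supports the full printed scale, where it
is cheap.

Aggregation convention: a *cell* is one (experiment, structure,
migration rate, sample size, measure) combination; grand means average
cell values with equal weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from spatialdiv.experiment import ExperimentConfig, run_experiment

__all__ = ["run_scaled_suite", "run_full_scale_random_sampling", "headline_metrics"]


def run_scaled_suite(
    seed: int, experiments: tuple[int, ...] = (1, 2, 3, 4, 5)
) -> pd.DataFrame:
    """Run the desk-scale experiments and return the combined cell table."""
    tables = []
    for exp in experiments:
        cfg = ExperimentConfig.scaled(exp, seed=seed)
        tables.append(run_experiment(cfg).table)
    return pd.concat(tables, ignore_index=True)


def run_full_scale_random_sampling(seed: int) -> pd.DataFrame:
    """Experiment #5 at the full printed scale.

    Single panmictic deme of 10,000 haploids, 1,000-bp sequences at
    mu = 2e-8, 20 replicates, random samples of sizes 10-50;
    mutation-free populations excluded.
    """
    cfg = ExperimentConfig(experiment=5, seed=seed)
    return run_experiment(cfg).table


def _cells(
    table: pd.DataFrame,
    measure: str,
    experiments: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    sel = table[table["measure"] == measure]
    if experiments is not None:
        sel = sel[sel["experiment"].isin(experiments)]
    return sel


def headline_metrics(table: pd.DataFrame) -> dict[str, float]:
    """Grand-mean bias/accuracy figures (percent) from a cell table.

    Spatial-sampling figures aggregate experiments #1-4; Watterson's
    theta figures aggregate every experiment present.
    """
    spatial = (1, 2, 3, 4)
    out: dict[str, float] = {}
    for measure in ("pi_tilde", "He_hat", "sigma_hat"):
        cells = _cells(table, measure, spatial)
        out[f"mean_abs_sme_{measure}"] = 100 * float(cells["sme"].abs().mean())
        out[f"mean_srmse_{measure}"] = 100 * float(cells["srmse"].mean())
        out[f"grand_sme_{measure}"] = 100 * float(cells["sme"].mean())
    theta = _cells(table, "theta_w_site")
    out["grand_sme_theta_w"] = 100 * float(theta["sme"].mean())
    out["grand_srmse_theta_w"] = 100 * float(theta["srmse"].mean())
    exp1_low = theta[(theta["experiment"] == 1) & (theta["migration"] == theta[theta["experiment"] == 1]["migration"].min())]
    if not exp1_low.empty:
        out["min_theta_sme_exp1_lowest_migration"] = 100 * float(
            exp1_low["sme"].min()
        )
    exp5 = _cells(table, "pi_tilde", (5,))
    if not exp5.empty:
        out["grand_sme_pi_tilde_random_sampling"] = 100 * float(exp5["sme"].mean())
    return out
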
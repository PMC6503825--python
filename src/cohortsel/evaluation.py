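"""Performance metrics for the inference methods on simulated cohorts.

Summarizes replicate tables produced by :func:`cohortsel.simulate.run_replicates`
into the quantities a method-evaluation study reports: bias and RMSE of the
selection-coefficient point estimates (for both the posterior mean and the
posterior median), the noncoverage rate (NCR) of credible intervals, and the
rejection rate of the neutrality test — the type-I error under a neutral
scenario, the power otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import SimulationScenario, run_replicates

__all__ = ["MetricReport", "compute_metrics", "run_grid", "plot_grid"]


@dataclass(frozen=True)
class MetricReport:
    """Replicate-level performance summary for one simulation scenario."""

    true_s: float
    n_effective_replicates: int
    bias_mean: float | None = None
    bias_median: float | None = None
    rmse_mean: float | None = None
    rmse_median: float | None = None
    ncr: float | None = None
    rejection_rate: float | None = None  # type-I error if true_s == 0, power otherwise
    bayes_rejection_rate: float | None = None  # 95% CI excludes 0
    n_flagged: int = 0


def compute_metrics(
    replicates: pd.DataFrame,
    true_s: float,
    alpha: float = 0.05,
) -> MetricReport:
    """Reduce a replicate table to bias/RMSE/NCR and rejection rates.

    Flagged replicates (e.g. too few survivors) are excluded from every
    metric and counted in ``n_flagged``.  Metrics whose inputs are absent
    from the table (no test, or no posterior summaries) are ``None``.
    """
    if len(replicates) == 0:
        raise ValueError("empty replicate table")
    flagged = replicates["flag"].fillna("").astype(str) != "" if "flag" in replicates else (
        pd.Series(False, index=replicates.index)
    )
    ok = replicates[~flagged]
    n_eff = len(ok)
    if n_eff == 0:
        raise ValueError("no effective replicates (all flagged)")

    kw: dict = {}
    if "s_mean" in ok and ok["s_mean"].notna().any():
        err_mean = ok["s_mean"].to_numpy() - true_s
        err_median = ok["s_median"].to_numpy() - true_s
        kw["bias_mean"] = float(err_mean.mean())
        kw["bias_median"] = float(err_median.mean())
        kw["rmse_mean"] = float(np.sqrt(np.mean(err_mean**2)))
        kw["rmse_median"] = float(np.sqrt(np.mean(err_median**2)))
    if "ci_low" in ok and ok["ci_low"].notna().any():
        miss = (ok["ci_low"].to_numpy() > true_s) | (ok["ci_high"].to_numpy() < true_s)
        kw["ncr"] = float(miss.mean())
        excl0 = (ok["ci_low"].to_numpy() > 0.0) | (ok["ci_high"].to_numpy() < 0.0)
        kw["bayes_rejection_rate"] = float(excl0.mean())
    if "p_value" in ok and ok["p_value"].notna().any():
        kw["rejection_rate"] = float((ok["p_value"].to_numpy() <= alpha).mean())
    return MetricReport(
        true_s=true_s,
        n_effective_replicates=n_eff,
        n_flagged=int(flagged.sum()),
        **kw,
    )


def run_grid(
    scenarios: Sequence[SimulationScenario],
    alpha: float = 0.05,
    **analysis_kwargs,
) -> pd.DataFrame:
    """Evaluate a grid of scenarios; one metrics row per scenario.

    ``analysis_kwargs`` are forwarded to
    :func:`cohortsel.simulate.run_replicates` (which tests and/or estimators
    to run, MCMC settings, ...).  Per-scenario failures are recorded in an
    ``error`` column; the rest of the grid still completes.
    """
    rows = []
    for sc in scenarios:
        key = {
            "N": sc.N,
            "n": max(sc.sample_sizes),
            "maf": sc.maf,
            "s": sc.s[0] if len(sc.s) == 1 else str(sc.s),
            "exhaustive": sc.exhaustive,
            "replicates": sc.replicates,
        }
        try:
            table = run_replicates(sc, **analysis_kwargs)
            report = compute_metrics(table, true_s=sc.s[0], alpha=alpha)
            rows.append({**key, **asdict(report), "error": ""})
        except Exception as exc:  # keep the rest of the grid alive
            rows.append({**key, "error": str(exc)})
    return pd.DataFrame(rows)


def plot_grid(
    grid: pd.DataFrame,
    metric: str,
    by: str = "maf",
    panel: str = "n",
    ax=None,
):
    """Bar panels of one metric across the grid (one group of bars per panel value)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    panels = sorted(grid[panel].unique())
    width = 0.8 / max(len(panels), 1)
    xs = sorted(grid[by].unique())
    for i, pv in enumerate(panels):
        sub = grid[grid[panel] == pv].sort_values(by)
        pos = [xs.index(v) + i * width for v in sub[by]]
        ax.bar(pos, sub[metric], width=width, label=f"{panel}={pv}")
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(xs))])
    ax.set_xticklabels([str(v) for v in xs])
    ax.set_xlabel(by)
    ax.set_ylabel(metric)
    ax.legend()
    return ax
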
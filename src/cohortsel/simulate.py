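"""Synthetic cohort-mortality studies with genotype-dependent survival.

Generates the data the inference modules are designed for: a single cohort of
N diploids founded at Hardy-Weinberg proportions for a chosen minor allele
frequency, thinned by one or more episodes of viability selection, and
sampled at T+1 time steps.  Survival is individual and stochastic: a genotype
g individual survives an episode with probability w_g / w_max, where w_g is
its relative fitness (1+2s, 1+2hs, 1) — under neutrality (s = 0) everyone
survives, so exhaustive sampling of a neutral cohort shows exactly zero
allele-frequency change.  An optional baseline survival multiplier adds
genotype-independent mortality for sensitivity analyses.

Samples are drawn without replacement from the currently alive cohort
(multivariate hypergeometric), so the inference model's multinomial
approximation is itself exercised, as in a real field study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import PriorSpec, sample_posterior, summarize_posterior
from .core import GenotypeCounts, GenotypeFrequencies, TemporalLocusData
from .neutrality import estimate_initial_frequencies, monte_carlo_pvalue, quasi_exact_pvalue

__all__ = [
    "SimulationScenario",
    "InsufficientSurvivorsError",
    "simulate_cohort_study",
    "run_replicates",
]


class InsufficientSurvivorsError(RuntimeError):
    """Fewer survivors than the requested sample size at some time step."""

    def __init__(self, time_step: int, survivors: int, requested: int):
        self.time_step = time_step
        self.survivors = survivors
        self.requested = requested
        super().__init__(
            f"time step {time_step}: only {survivors} survivors for a requested "
            f"sample of {requested}"
        )


@dataclass(frozen=True)
class SimulationScenario:
    """One cell of a simulation study design.

    ``sample_sizes`` has one entry per time step (T+1 entries for T selective
    periods); ``s`` has one selection coefficient per period.  ``exhaustive``
    replaces every sample by the full set of currently alive individuals
    (n = N reference mode).  ``initial_frequencies`` overrides the
    Hardy-Weinberg zygote pool implied by ``maf``.
    """

    N: int
    sample_sizes: tuple[int, ...]
    maf: float
    s: tuple[float, ...]
    h: float = 0.5
    exhaustive: bool = False
    replicates: int = 1000
    seed: int | None = None
    baseline_survival: float = 1.0
    initial_frequencies: GenotypeFrequencies | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in self.sample_sizes))
        ss = self.s if isinstance(self.s, (tuple, list, np.ndarray)) else (self.s,)
        object.__setattr__(self, "s", tuple(float(x) for x in ss))
        if self.N < 1:
            raise ValueError("cohort size N must be >= 1")
        if len(self.sample_sizes) != len(self.s) + 1:
            raise ValueError("need one sample size per time step (periods + 1)")
        if not self.exhaustive and any(n > self.N for n in self.sample_sizes):
            raise ValueError("sample sizes cannot exceed the cohort size N")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("minor allele frequency must be in (0, 0.5]")
        for st in self.s:
            if st <= -0.5:
                raise ValueError("selection coefficients must exceed -0.5")
        if not 0.0 < self.baseline_survival <= 1.0:
            raise ValueError("baseline_survival must be in (0, 1]")

    @property
    def n_periods(self) -> int:
        return len(self.s)

    def zygote_pool(self) -> GenotypeFrequencies:
        if self.initial_frequencies is not None:
            return self.initial_frequencies
        return GenotypeFrequencies.hardy_weinberg(self.maf)


def simulate_cohort_study(
    scenario: SimulationScenario,
    rng: np.random.Generator | None = None,
    locus_id: str = "sim",
) -> TemporalLocusData:
    """Simulate one cohort mortality study and return its temporal counts.

    Steps: (1) found a cohort of N genotypes multinomially from the zygote
    pool; (2) record the t = 0 sample (hypergeometric without replacement, or
    the whole cohort in exhaustive mode); (3) for each period apply stochastic
    viability selection, each individual surviving with probability
    ``baseline * w_g / w_max``; (4) sample the survivors.

    Raises
    ------
    InsufficientSurvivorsError
        If a requested sample exceeds the number of survivors.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    pool = scenario.zygote_pool().as_array()
    alive = rng.multinomial(scenario.N, pool)

    samples: list[GenotypeCounts] = []
    for t in range(len(scenario.sample_sizes)):
        if t > 0:
            st = scenario.s[t - 1]
            w = np.array([1.0 + 2.0 * st, 1.0 + 2.0 * scenario.h * st, 1.0])
            surv_p = scenario.baseline_survival * w / w.max()
            alive = rng.binomial(alive, surv_p)
        if scenario.exhaustive:
            draw = alive
        else:
            n_t = scenario.sample_sizes[t]
            if alive.sum() < n_t:
                raise InsufficientSurvivorsError(t, int(alive.sum()), n_t)
            draw = rng.multivariate_hypergeometric(alive, n_t)
        samples.append(GenotypeCounts(*(int(x) for x in draw)))
    return TemporalLocusData(locus_id=locus_id, samples=tuple(samples))


def run_replicates(
    scenario: SimulationScenario,
    neutrality: str | None = "monte_carlo",
    B: int = 10_000,
    bayes: bool = False,
    prior: PriorSpec | None = None,
    iterations: int = 8_000,
    burn_in: int = 2_000,
    thin: int = 5,
    exact_cutoff: int = 500,
) -> pd.DataFrame:
    """Run a scenario's replicates through the requested analyses.

    Returns a tidy table with one row per replicate per period: the
    standardized change and its p-value (when ``neutrality`` is
    ``"quasi_exact"``, ``"monte_carlo"`` or ``"auto"``), posterior summaries
    (when ``bayes=True``; dominance is fixed at the scenario's h unless a
    custom ``prior`` estimates it), the true s, and a ``flag`` column noting
    replicates excluded for lack of survivors.  Per-replicate seeds derive
    deterministically from the scenario's master seed.
    """
    if neutrality not in (None, "quasi_exact", "monte_carlo", "auto"):
        raise ValueError(f"unknown neutrality method {neutrality!r}")
    if bayes and prior is None:
        prior = PriorSpec(h_fixed=scenario.h)
    master = np.random.SeedSequence(scenario.seed)
    children = master.spawn(scenario.replicates)

    rows: list[dict] = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        try:
            data = simulate_cohort_study(scenario, rng=rng, locus_id=f"rep{rep}")
        except InsufficientSurvivorsError as exc:
            rows.append(
                {"replicate": rep, "seed": rep_seed, "period": np.nan,
                 "true_s": np.nan, "flag": str(exc)}
            )
            continue
        p0 = estimate_initial_frequencies(data.pooled()) if neutrality else None
        summary = None
        if bayes:
            post = sample_posterior(
                data, prior=prior, iterations=iterations, burn_in=burn_in,
                thin=thin, seed=rep_seed,
            )
            summary = summarize_posterior(post)
        for t in range(1, data.T + 1):
            row: dict = {
                "replicate": rep,
                "seed": rep_seed,
                "period": t,
                "true_s": scenario.s[t - 1],
                "flag": "",
            }
            if neutrality:
                prev, curr = data.samples[t - 1], data.samples[t]
                use_exact = neutrality == "quasi_exact" or (
                    neutrality == "auto" and max(prev.n, curr.n) <= exact_cutoff
                )
                if use_exact:
                    res = quasi_exact_pvalue(prev, curr, p0)
                else:
                    res = monte_carlo_pvalue(prev, curr, p0, B=B, seed=rng)
                row["delta_obs"] = res.delta_obs
                row["p_value"] = res.p_value
            if summary is not None:
                i = t - 1
                row.update(
                    s_median=float(summary.s_median[i]),
                    s_mean=float(summary.s_mean[i]),
                    ci_low=float(summary.ci_low[i]),
                    ci_high=float(summary.ci_high[i]),
                )
            rows.append(row)
    return pd.DataFrame(rows)
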
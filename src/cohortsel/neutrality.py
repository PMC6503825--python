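"""Neutrality tests for temporal genotype samples from a cohort mortality study.

The null hypothesis is genotype-independent mortality: all temporal samples
are independent multinomial draws from the cohort's initial zygote-pool
genotype frequencies.  Allele-frequency change between two samples is measured
by the standardized variance

    delta = (f_t - f_{t-1})^2 / (z - z^2),   z = (f_t + f_{t-1}) / 2,

and the test asks how often two random draws from the (estimated) common pool
produce a change at least as large as the observed one.  The quasi-exact test
sums the tail probability over the full outcome space; the Monte Carlo test
estimates it from simulated draws.

The exact enumeration exploits the fact that delta depends on a genotype-count
outcome (i, j, k) only through the allele count a = 2i + j, so the quadruple
sum over genotype-count pairs collapses to a double sum over allele-count
marginals, computable in O(n^2) instead of O(n^4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln, xlogy
from statsmodels.stats.multitest import multipletests

from .core import (
    GenotypeCounts,
    GenotypeFrequencies,
    LocusScanResult,
    TemporalLocusData,
    allele_frequency,
    validate_dataset,
)

__all__ = [
    "NeutralityTestResult",
    "ScanOutput",
    "delta_stat",
    "estimate_initial_frequencies",
    "allele_count_pmf",
    "quasi_exact_pvalue",
    "monte_carlo_pvalue",
    "scan",
]

#: Above this per-sample size the quasi-exact enumeration is refused.
DEFAULT_EXACT_LIMIT = 2000

#: In ``method="auto"`` scans, samples larger than this use Monte Carlo.
AUTO_EXACT_CUTOFF = 500


@dataclass(frozen=True)
class NeutralityTestResult:
    """Outcome of a single two-sample neutrality test."""

    delta_obs: float
    p_value: float
    method: Literal["quasi_exact", "monte_carlo"]
    n_replicates: int | None = None


def delta_stat(f_prev: float, f_curr: float) -> float:
    """Standardized variance of the allele-frequency change between two samples.

    Returns ``(f_curr - f_prev)**2 / (z - z**2)`` with ``z`` the mean of the
    two frequencies; defined as 0 when both samples are fixed for the same
    allele (z = 0 or 1), where no change has occurred.
    """
    if not (0.0 <= f_prev <= 1.0 and 0.0 <= f_curr <= 1.0):
        raise ValueError(f"allele frequencies must be in [0, 1], got {f_prev!r}, {f_curr!r}")
    z = 0.5 * (f_curr + f_prev)
    den = z - z * z
    if den <= 0.0:
        return 0.0
    return (f_curr - f_prev) ** 2 / den


def estimate_initial_frequencies(pooled: GenotypeCounts) -> GenotypeFrequencies:
    """Estimate zygote-pool genotype frequencies from the total pooled sample.

    Adds a 1/3 pseudo-count to each genotype class (so that all three classes
    are assumed present in the cohort even when undetected):
    ``p_hat = (y + 1/3) / (n + 1)``.  The three components sum to 1 exactly
    and are strictly positive.
    """
    n = pooled.n
    if n == 0:
        raise ValueError("empty pooled sample: cannot estimate initial frequencies")
    denom = n + 1.0
    return GenotypeFrequencies(
        (pooled.y11 + 1.0 / 3.0) / denom,
        (pooled.y12 + 1.0 / 3.0) / denom,
        (pooled.y22 + 1.0 / 3.0) / denom,
    )


def allele_count_pmf(p0: GenotypeFrequencies, n: int) -> np.ndarray:
    """Distribution of the allele-1 count in a multinomial genotype sample.

    For a sample of ``n`` genotypes drawn from pool frequencies ``p0``, the
    allele count a = 2*y11 + y12 takes values 0..2n.  Returns the length
    ``2n + 1`` probability vector P(a), marginalizing the trinomial over all
    genotype-count outcomes compatible with each a.
    """
    if n < 1:
        raise ValueError(f"sample size must be >= 1, got {n}")
    p11, p12, p22 = p0.p11, p0.p12, p0.p22
    logfact = gammaln(np.arange(n + 1) + 1.0)
    log_n_fact = logfact[n]
    out = np.zeros(2 * n + 1)
    for i in range(n + 1):
        j = np.arange(n - i + 1)
        k = n - i - j
        logpmf = (
            log_n_fact
            - logfact[i]
            - logfact[j]
            - logfact[k]
            + xlogy(i, p11)
            + xlogy(j, p12)
            + xlogy(k, p22)
        )
        out[2 * i : 2 * i + n - i + 1] += np.exp(logpmf)
    return out


def quasi_exact_pvalue(
    prev: GenotypeCounts,
    curr: GenotypeCounts,
    p0: GenotypeFrequencies,
    max_n: int = DEFAULT_EXACT_LIMIT,
) -> NeutralityTestResult:
    """Quasi-exact neutrality test between two temporal samples.

    Sums, over every pair of possible multinomial outcomes of the two sample
    sizes drawn from ``p0``, the probability of those with standardized change
    at least as large as observed (inclusive tail).  Exact up to the
    estimation of ``p0``; cost O(n^2).

    Raises
    ------
    ValueError
        If either sample exceeds ``max_n`` (use :func:`monte_carlo_pvalue`).
    """
    n_prev, n_curr = prev.n, curr.n
    if n_prev == 0 or n_curr == 0:
        raise ValueError("empty sample: both temporal samples must be non-empty")
    if max(n_prev, n_curr) > max_n:
        raise ValueError(
            f"sample size {max(n_prev, n_curr)} exceeds the exact-enumeration limit "
            f"{max_n}; use monte_carlo_pvalue for large samples"
        )

    delta_obs = delta_stat(allele_frequency(prev), allele_frequency(curr))

    pmf_prev = allele_count_pmf(p0, n_prev)
    pmf_curr = allele_count_pmf(p0, n_curr)
    f_prev = np.arange(2 * n_prev + 1) / (2.0 * n_prev)
    f_curr = np.arange(2 * n_curr + 1) / (2.0 * n_curr)

    # Row-wise over the previous sample's allele counts to keep memory flat.
    thresh = delta_obs * (1.0 - 1e-12)  # inclusive tail, guard float jitter
    p_value = 0.0
    for ap, w in enumerate(pmf_prev):
        z = 0.5 * (f_curr + f_prev[ap])
        den = z - z * z
        num = (f_curr - f_prev[ap]) ** 2
        delta = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
        p_value += w * pmf_curr[delta >= thresh].sum()
    p_value = min(p_value, 1.0)
    return NeutralityTestResult(delta_obs=delta_obs, p_value=p_value, method="quasi_exact")


def monte_carlo_pvalue(
    prev: GenotypeCounts,
    curr: GenotypeCounts,
    p0: GenotypeFrequencies,
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
    add_one: bool = False,
) -> NeutralityTestResult:
    """Monte Carlo approximation to the quasi-exact neutrality test.

    Simulates ``B`` pairs of multinomial genotype samples of the observed
    sizes from ``p0`` and reports the proportion with a standardized change at
    least as large as observed.  ``add_one=True`` uses (k+1)/(B+1) instead of
    the plain proportion, guaranteeing a strictly positive p-value.
    """
    if B < 1:
        raise ValueError(f"replicate count B must be >= 1, got {B}")
    n_prev, n_curr = prev.n, curr.n
    if n_prev == 0 or n_curr == 0:
        raise ValueError("empty sample: both temporal samples must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    delta_obs = delta_stat(allele_frequency(prev), allele_frequency(curr))
    pvals = p0.as_array()
    sim_prev = rng.multinomial(n_prev, pvals, size=B)
    sim_curr = rng.multinomial(n_curr, pvals, size=B)
    f_prev = (2 * sim_prev[:, 0] + sim_prev[:, 1]) / (2.0 * n_prev)
    f_curr = (2 * sim_curr[:, 0] + sim_curr[:, 1]) / (2.0 * n_curr)
    z = 0.5 * (f_curr + f_prev)
    den = z - z * z
    num = (f_curr - f_prev) ** 2
    delta_sim = np.where(den > 0.0, num / np.where(den > 0.0, den, 1.0), 0.0)
    k = int(np.count_nonzero(delta_sim >= delta_obs * (1.0 - 1e-12)))
    p_value = (k + 1) / (B + 1) if add_one else k / B
    return NeutralityTestResult(
        delta_obs=delta_obs, p_value=p_value, method="monte_carlo", n_replicates=B
    )


@dataclass
class ScanOutput:
    """Multi-locus scan results plus loci excluded or failed, with reasons."""

    results: list[LocusScanResult]
    excluded: dict[str, str]
    flagged: dict[str, str]

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)


def scan(
    data: Sequence[TemporalLocusData],
    method: Literal["quasi_exact", "monte_carlo", "auto"] = "auto",
    maf_threshold: float = 0.05,
    fdr_level: float = 0.05,
    B: int = 10_000,
    seed: int | None = None,
    fdr_family: Literal["joint", "per_period"] = "joint",
) -> ScanOutput:
    """Genome scan: test every retained locus over every consecutive period.

    For each locus passing the pooled-MAF filter and each period (t-1, t),
    computes the standardized change and its neutrality p-value using the
    pool frequencies estimated from the locus's *total* pooled sample (all
    time steps), then applies Benjamini-Hochberg FDR control at ``fdr_level``.
    ``method="auto"`` uses the quasi-exact test for samples up to
    ``AUTO_EXACT_CUTOFF`` individuals and Monte Carlo above.  Per-locus
    failures are flagged, never abort the scan.

    ``fdr_family="joint"`` corrects across all locus-by-period tests as one
    family (default); ``"per_period"`` corrects each period separately.
    """
    report = validate_dataset(data, maf_threshold=maf_threshold)
    ss = np.random.SeedSequence(seed)

    rows: list[tuple[str, int, float, float]] = []
    flagged: dict[str, str] = {}
    for locus in report.retained:
        child_rng = np.random.default_rng(ss.spawn(1)[0])
        try:
            p0 = estimate_initial_frequencies(locus.pooled())
            for t in range(1, locus.T + 1):
                prev, curr = locus.samples[t - 1], locus.samples[t]
                use_exact = method == "quasi_exact" or (
                    method == "auto" and max(prev.n, curr.n) <= AUTO_EXACT_CUTOFF
                )
                if use_exact:
                    res = quasi_exact_pvalue(prev, curr, p0)
                else:
                    res = monte_carlo_pvalue(prev, curr, p0, B=B, seed=child_rng, add_one=True)
                rows.append((locus.locus_id, t, res.delta_obs, res.p_value))
        except ValueError as exc:
            flagged[locus.locus_id] = str(exc)

    results: list[LocusScanResult] = []
    if rows:
        pvals = np.array([r[3] for r in rows])
        reject = np.zeros(len(rows), dtype=bool)
        qvals = np.ones(len(rows))
        if fdr_family == "joint":
            reject, qvals = multipletests(pvals, alpha=fdr_level, method="fdr_bh")[:2]
        else:
            periods = np.array([r[1] for r in rows])
            for t in np.unique(periods):
                idx = periods == t
                reject[idx], qvals[idx] = multipletests(
                    pvals[idx], alpha=fdr_level, method="fdr_bh"
                )[:2]
        for (locus_id, period, delta_obs, p), q, sig in zip(rows, qvals, reject):
            results.append(
                LocusScanResult(
                    locus_id=locus_id,
                    period=period,
                    delta_obs=delta_obs,
                    p_value=p,
                    q_value=float(min(q, 1.0)),
                    significant=bool(sig),
                )
            )
    return ScanOutput(results=results, excluded=report.excluded, flagged=flagged)
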
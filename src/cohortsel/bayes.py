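"""Bayesian estimation of per-period viability selection coefficients.

Model: genotype relative fitnesses in period t are w11 = 1+2*s_t,
w12 = 1+2*h*s_t, w22 = 1.  Expected genotype frequencies after one episode of
selective mortality are p * w / wbar with wbar the mean fitness.  Each
temporal sample is an independent multinomial draw — the t = 0 sample from the
initial zygote-pool frequencies p0, the sample at time t from p0 pushed
sequentially through the selection map for periods 1..t.  Priors are
uninformative: flat Dirichlet on p0, uniform on (-0.5, 1e6) for each s_t,
uniform on (0, 1) for h (optionally fixed, e.g. h = 0.5 for codominance).

The posterior is sampled by Metropolis-within-Gibbs with random-walk blocks on
unconstrained transforms: additive log-ratio coordinates for p0,
log(s_t + 0.5) for each selection coefficient, logit(h) for dominance.  Step
sizes adapt during burn-in toward a 20-40% acceptance rate and are frozen
afterwards, keeping the chain a valid Markov chain on the retained draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import gammaln

from .core import GenotypeCounts, GenotypeFrequencies, TemporalLocusData

__all__ = [
    "PriorSpec",
    "PosteriorSample",
    "PosteriorSummary",
    "post_selection_frequencies",
    "log_likelihood",
    "sample_posterior",
    "summarize_posterior",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyper-parameters for the selection model."""

    p0_dirichlet_alpha: float = 1.0
    s_low: float = -0.5
    s_high: float = 1e6
    h_low: float = 0.0
    h_high: float = 1.0
    h_fixed: float | None = None

    def __post_init__(self) -> None:
        if self.s_low < -0.5:
            raise ValueError("s_low must be >= -0.5 (fitness 1+2s must stay positive)")
        if not self.s_low < self.s_high:
            raise ValueError("require s_low < s_high")
        if not (0.0 <= self.h_low < self.h_high <= 1.0):
            raise ValueError("require 0 <= h_low < h_high <= 1")
        if self.h_fixed is not None and not (0.0 <= self.h_fixed <= 1.0):
            raise ValueError("h_fixed must be in [0, 1]")


@dataclass
class PosteriorSample:
    """Retained MCMC draws (one or more chains) for one locus."""

    p0: np.ndarray  # (n_chains, n_draws, 3)
    s: np.ndarray  # (n_chains, n_draws, T)
    h: np.ndarray  # (n_chains, n_draws)
    acceptance: dict[str, float]
    seed: int | None
    h_estimated: bool
    rhat_s: np.ndarray | None = None  # split-Rhat per period when multi-chain

    @property
    def n_periods(self) -> int:
        return self.s.shape[2]

    def s_draws(self, period: int = 0) -> np.ndarray:
        """Pooled draws of s for one period (all chains concatenated)."""
        return self.s[:, :, period].ravel()


@dataclass
class PosteriorSummary:
    """Per-period posterior point estimates and credible intervals."""

    s_mean: np.ndarray
    s_median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # CI excludes 0, per period
    ci_level: float
    h_mean: float | None = None
    h_median: float | None = None
    h_ci: tuple[float, float] | None = None


def post_selection_frequencies(
    p: GenotypeFrequencies, s: float, h: float
) -> GenotypeFrequencies:
    """Expected genotype frequencies after one episode of viability selection."""
    if s <= -0.5:
        raise ValueError(f"selection coefficient must exceed -0.5, got {s}")
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"dominance h must be in [0, 1], got {h}")
    w11 = 1.0 + 2.0 * s
    w12 = 1.0 + 2.0 * h * s
    wbar = w11 * p.p11 + w12 * p.p12 + p.p22
    if wbar <= 0.0:
        raise ValueError("mean fitness must be positive")
    return GenotypeFrequencies(p.p11 * w11 / wbar, p.p12 * w12 / wbar, p.p22 / wbar)


def _sample_list(data: TemporalLocusData | Sequence[GenotypeCounts]) -> list[GenotypeCounts]:
    if isinstance(data, TemporalLocusData):
        return list(data.samples)
    return list(data)


def log_likelihood(
    data: TemporalLocusData | Sequence[GenotypeCounts],
    p0: GenotypeFrequencies,
    s: Sequence[float],
    h: float,
) -> float:
    """Log-probability of the full temporal count series under the model.

    The t = 0 sample is multinomial at ``p0``; the sample at time t is
    multinomial at the frequencies obtained by applying the selection map
    sequentially with s[0..t-1].  Expected class frequency 0 with a positive
    observed count yields ``-inf`` (a valid log-probability, not an error).
    """
    samples = _sample_list(data)
    s = [float(x) for x in s]
    if len(s) != len(samples) - 1:
        raise ValueError(
            f"need one selection coefficient per period: got {len(s)} for "
            f"{len(samples) - 1} period(s)"
        )
    total = 0.0
    p = p0
    for t, counts in enumerate(samples):
        if t > 0:
            p = post_selection_frequencies(p, s[t - 1], h)
        y = counts.as_array()
        n = counts.n
        logcoef = gammaln(n + 1) - gammaln(y + 1.0).sum()
        ll = logcoef
        for yc, pc in zip(y, p.as_array()):
            if yc > 0:
                if pc <= 0.0:
                    return float("-inf")
                ll += yc * math.log(pc)
        total += ll
    return float(total)


# ---------------------------------------------------------------------------
# MCMC internals: scalar math on unconstrained coordinates, constants dropped.
# ---------------------------------------------------------------------------


def _loglik_fast(counts: list[tuple[float, float, float]], p11: float, p12: float,
                 p22: float, s: list[float], h: float) -> float:
    """Log-likelihood up to additive constants (multinomial coefficients)."""
    y11, y12, y22 = counts[0]
    ll = y11 * math.log(p11) + y12 * math.log(p12) + y22 * math.log(p22)
    for t in range(1, len(counts)):
        st = s[t - 1]
        w11 = 1.0 + 2.0 * st
        w12 = 1.0 + 2.0 * h * st
        wbar = w11 * p11 + w12 * p12 + p22
        p11 = p11 * w11 / wbar
        p12 = p12 * w12 / wbar
        p22 = p22 / wbar
        y11, y12, y22 = counts[t]
        ll += y11 * math.log(p11) + y12 * math.log(p12) + y22 * math.log(p22)
    return ll


def _alr_inv(x1: float, x2: float) -> tuple[float, float, float]:
    """Additive log-ratio inverse: (x1, x2) -> simplex point, p22 reference."""
    m = max(x1, x2, 0.0)
    e1 = math.exp(x1 - m)
    e2 = math.exp(x2 - m)
    e3 = math.exp(-m)
    tot = e1 + e2 + e3
    return e1 / tot, e2 / tot, e3 / tot


def sample_posterior(
    data: TemporalLocusData | Sequence[GenotypeCounts],
    prior: PriorSpec | None = None,
    iterations: int = 60_000,
    burn_in: int = 10_000,
    thin: int = 10,
    seed: int | None = None,
    n_chains: int = 1,
) -> PosteriorSample:
    """Sample the joint posterior of (p0, s_1..s_T, h) for one locus.

    Deterministic given ``seed``.  ``n_chains > 1`` runs independent chains
    from jittered starting points and reports split-Rhat for each s_t.
    Acceptance rates per block are reported; a block whose post-burn-in
    acceptance is 0 triggers a divergence warning.
    """
    prior = prior or PriorSpec()
    samples = _sample_list(data)
    if len(samples) < 2:
        raise ValueError("need at least two temporal samples (T >= 1)")
    if all(c.n == 0 for c in samples):
        raise ValueError("all temporal samples are empty")
    if not iterations > burn_in:
        raise ValueError("iterations must exceed burn_in")
    T = len(samples) - 1
    counts = [(float(c.y11), float(c.y12), float(c.y22)) for c in samples]
    estimate_h = prior.h_fixed is None
    alpha = prior.p0_dirichlet_alpha

    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(n_chains)
    n_kept = (iterations - burn_in + thin - 1) // thin

    all_p0 = np.empty((n_chains, n_kept, 3))
    all_s = np.empty((n_chains, n_kept, T))
    all_h = np.empty((n_chains, n_kept))
    acc_totals: dict[str, float] = {}

    # Starting point: pooled-count frequencies (pseudo-counts keep it interior).
    pool = np.sum([[c.y11, c.y12, c.y22] for c in samples], axis=0, dtype=float)
    p_start = (pool + 1.0 / 3.0) / (pool.sum() + 1.0)

    for ci, cs in enumerate(chain_seeds):
        rng = np.random.default_rng(cs)
        x1 = math.log(p_start[0] / p_start[2])
        x2 = math.log(p_start[1] / p_start[2])
        if ci > 0:  # jitter extra chains for a meaningful Rhat
            x1 += rng.normal(0.0, 0.5)
            x2 += rng.normal(0.0, 0.5)
        u = [math.log(0.5) + (rng.normal(0.0, 0.3) if ci > 0 else 0.0) for _ in range(T)]
        h = prior.h_fixed if not estimate_h else 0.5
        v = 0.0  # logit(0.5)

        def logtarget(p11: float, p12: float, p22: float, svec: list[float], hh: float) -> float:
            lt = _loglik_fast(counts, p11, p12, p22, svec, hh)
            lt += alpha * (math.log(p11) + math.log(p12) + math.log(p22))
            for st in svec:
                lt += math.log(st + 0.5)
            if estimate_h:
                lt += math.log(hh) + math.log(1.0 - hh)
            return lt

        s_vec = [math.exp(ui) - 0.5 for ui in u]
        p11, p12, p22 = _alr_inv(x1, x2)
        cur = logtarget(p11, p12, p22, s_vec, h)

        step_p = 0.2
        step_s = [0.2] * T
        step_h = 0.5
        n_blocks = 1 + T + (1 if estimate_h else 0)
        normals = rng.normal(size=(iterations, 2 + T + 1))
        logu = np.log(rng.uniform(size=(iterations, n_blocks)))

        acc = {"p0": 0, **{f"s{t}": 0 for t in range(T)}, "h": 0}
        win = {"p0": 0, **{f"s{t}": 0 for t in range(T)}, "h": 0}
        window = 50
        kept = 0
        for it in range(iterations):
            adapt = it < burn_in
            block = 0
            # --- p0 block ---
            nx1 = x1 + step_p * normals[it, 0]
            nx2 = x2 + step_p * normals[it, 1]
            q11, q12, q22 = _alr_inv(nx1, nx2)
            if q11 > 0.0 and q12 > 0.0 and q22 > 0.0:
                new = logtarget(q11, q12, q22, s_vec, h)
                if logu[it, block] < new - cur:
                    x1, x2, p11, p12, p22, cur = nx1, nx2, q11, q12, q22, new
                    acc["p0"] += 0 if adapt else 1
                    win["p0"] += 1
            block += 1
            # --- s blocks ---
            for t in range(T):
                nu = u[t] + step_s[t] * normals[it, 2 + t]
                ns = math.exp(nu) - 0.5
                if prior.s_low < ns < prior.s_high:
                    trial = list(s_vec)
                    trial[t] = ns
                    new = logtarget(p11, p12, p22, trial, h)
                    if logu[it, block] < new - cur:
                        u[t] = nu
                        s_vec = trial
                        cur = new
                        acc[f"s{t}"] += 0 if adapt else 1
                        win[f"s{t}"] += 1
                block += 1
            # --- h block ---
            if estimate_h:
                nv = v + step_h * normals[it, 2 + T]
                nh = 1.0 / (1.0 + math.exp(-nv))
                if prior.h_low < nh < prior.h_high:
                    new = logtarget(p11, p12, p22, s_vec, nh)
                    if logu[it, block] < new - cur:
                        v, h, cur = nv, nh, new
                        acc["h"] += 0 if adapt else 1
                        win["h"] += 1
            # --- adapt step sizes during burn-in ---
            if adapt and (it + 1) % window == 0:
                rate = win["p0"] / window
                step_p *= math.exp(min(max(rate - 0.3, -0.5), 0.5))
                for t in range(T):
                    rate = win[f"s{t}"] / window
                    step_s[t] *= math.exp(min(max(rate - 0.3, -0.5), 0.5))
                if estimate_h:
                    rate = win["h"] / window
                    step_h *= math.exp(min(max(rate - 0.3, -0.5), 0.5))
                for k in win:
                    win[k] = 0
            # --- record ---
            if it >= burn_in and (it - burn_in) % thin == 0:
                all_p0[ci, kept] = (p11, p12, p22)
                all_s[ci, kept] = s_vec
                all_h[ci, kept] = h
                kept += 1

        post = iterations - burn_in
        for k, v_ in acc.items():
            if k == "h" and not estimate_h:
                continue
            acc_totals[k] = acc_totals.get(k, 0.0) + v_ / post / n_chains
            if v_ == 0:
                warnings.warn(
                    f"MCMC block {k!r} accepted no proposals after burn-in "
                    f"(chain {ci}); the chain may be stuck",
                    RuntimeWarning,
                )

    rhat = _split_rhat(all_s) if n_chains > 1 else None
    return PosteriorSample(
        p0=all_p0,
        s=all_s,
        h=all_h,
        acceptance=acc_totals,
        seed=seed,
        h_estimated=estimate_h,
        rhat_s=rhat,
    )


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-Rhat per parameter for draws of shape (chains, iters, params)."""
    c, n, p = draws.shape
    half = n // 2
    segs = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, nn = segs.shape[0], segs.shape[1]
    chain_means = segs.mean(axis=1)  # (m, p)
    chain_vars = segs.var(axis=1, ddof=1)  # (m, p)
    W = chain_vars.mean(axis=0)
    B = nn * chain_means.var(axis=0, ddof=1)
    var_plus = (nn - 1) / nn * W + B / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(var_plus / W)


def _hpd_interval(draws: np.ndarray, level: float) -> tuple[float, float]:
    x = np.sort(draws)
    m = len(x)
    k = max(int(math.ceil(level * m)), 2)
    widths = x[k - 1 :] - x[: m - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def summarize_posterior(
    sample: PosteriorSample,
    ci_level: float = 0.95,
    interval: Literal["equal-tailed", "hpd"] = "equal-tailed",
) -> PosteriorSummary:
    """Per-period posterior mean, median and credible interval.

    ``significant`` flags periods whose credible interval excludes 0 — the
    Bayesian analogue of a rejection at level 1 - ci_level.
    """
    if sample.s.size == 0:
        raise ValueError("empty posterior sample")
    T = sample.n_periods
    lo_q = (1.0 - ci_level) / 2.0
    s_mean = np.empty(T)
    s_median = np.empty(T)
    ci_low = np.empty(T)
    ci_high = np.empty(T)
    for t in range(T):
        d = sample.s_draws(t)
        s_mean[t] = d.mean()
        s_median[t] = np.median(d)
        if interval == "hpd":
            ci_low[t], ci_high[t] = _hpd_interval(d, ci_level)
        else:
            ci_low[t], ci_high[t] = np.quantile(d, [lo_q, 1.0 - lo_q])
    significant = (ci_low > 0.0) | (ci_high < 0.0)
    out = PosteriorSummary(
        s_mean=s_mean,
        s_median=s_median,
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        ci_level=ci_level,
    )
    if sample.h_estimated:
        hd = sample.h.ravel()
        out.h_mean = float(hd.mean())
        out.h_median = float(np.median(hd))
        if interval == "hpd":
            out.h_ci = _hpd_interval(hd, ci_level)
        else:
            q = np.quantile(hd, [lo_q, 1.0 - lo_q])
            out.h_ci = (float(q[0]), float(q[1]))
    return out
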
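"""Domain types and elementary conversions for cohort mortality studies.

A cohort mortality study genotypes sequential random samples drawn from a
single same-age cohort as it dies.  Every quantity downstream works on
per-locus, per-time-step genotype counts at biallelic loci: ``y11`` copies of
the 11 homozygote, ``y12`` heterozygotes, ``y22`` copies of the 22 homozygote.
Sample sizes may differ across loci at the same time step because of
locus-specific missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenotypeCounts",
    "TemporalLocusData",
    "GenotypeFrequencies",
    "SelectionParams",
    "LocusScanResult",
    "ValidationReport",
    "allele_frequency",
    "validate_dataset",
]

_SIMPLEX_TOL = 1e-12


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for one locus in one temporal sample."""

    y11: int
    y12: int
    y22: int

    def __post_init__(self) -> None:
        for name in ("y11", "y12", "y22"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        """Sample size (number of genotyped individuals)."""
        return self.y11 + self.y12 + self.y22

    @property
    def allele1_count(self) -> int:
        """Copies of allele 1 in the sample (2*y11 + y12)."""
        return 2 * self.y11 + self.y12

    def as_array(self) -> np.ndarray:
        return np.array([self.y11, self.y12, self.y22], dtype=np.int64)

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(self.y11 + other.y11, self.y12 + other.y12, self.y22 + other.y22)


@dataclass(frozen=True)
class TemporalLocusData:
    """A locus's full time series of genotype counts, t = 0..T contiguous."""

    locus_id: str
    samples: tuple[GenotypeCounts, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        if len(self.samples) < 2:
            raise ValueError(
                f"locus {self.locus_id!r}: need at least two temporal samples, got {len(self.samples)}"
            )

    @property
    def T(self) -> int:
        """Number of selective periods (time steps minus one)."""
        return len(self.samples) - 1

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(s.n for s in self.samples)

    def pooled(self) -> GenotypeCounts:
        """Counts summed over all temporal samples (the total pooled sample)."""
        tot = GenotypeCounts(0, 0, 0)
        for s in self.samples:
            tot = tot + s
        return tot

    def pooled_maf(self) -> float:
        """Minor allele frequency in the total pooled sample."""
        pool = self.pooled()
        if pool.n == 0:
            raise ValueError(f"locus {self.locus_id!r}: empty pooled sample")
        f1 = allele_frequency(pool)
        return min(f1, 1.0 - f1)


@dataclass(frozen=True)
class GenotypeFrequencies:
    """A point on the 3-simplex of genotype frequencies (p11, p12, p22)."""

    p11: float
    p12: float
    p22: float

    def __post_init__(self) -> None:
        for name in ("p11", "p12", "p22"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        s = self.p11 + self.p12 + self.p22
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"genotype frequencies must sum to 1, got {s!r}")

    @property
    def allele1_frequency(self) -> float:
        return self.p11 + 0.5 * self.p12

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p22], dtype=float)

    @classmethod
    def from_array(cls, p: Iterable[float]) -> "GenotypeFrequencies":
        p11, p12, p22 = (float(x) for x in p)
        return cls(p11, p12, p22)

    @classmethod
    def hardy_weinberg(cls, allele1_freq: float) -> "GenotypeFrequencies":
        """Hardy-Weinberg genotype frequencies at a given allele-1 frequency."""
        q = float(allele1_freq)
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"allele frequency must be in [0, 1], got {q!r}")
        return cls(q * q, 2.0 * q * (1.0 - q), (1.0 - q) * (1.0 - q))


@dataclass(frozen=True)
class SelectionParams:
    """Per-period selection coefficients and dominance for one locus.

    Relative fitnesses in period t are 1+2*s[t] (11 homozygote),
    1+2*h*s[t] (heterozygote) and 1 (22 homozygote); h = 0.5 is codominance.
    """

    s: tuple[float, ...]
    h: float = 0.5

    def __post_init__(self) -> None:
        s = tuple(float(x) for x in (self.s if isinstance(self.s, (tuple, list, np.ndarray)) else (self.s,)))
        object.__setattr__(self, "s", s)
        for st in s:
            if st <= -0.5:
                raise ValueError(f"selection coefficient must exceed -0.5, got {st}")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError(f"dominance h must be in [0, 1], got {self.h}")


@dataclass(frozen=True)
class LocusScanResult:
    """One row of a multi-locus scan: one locus, one sampling period."""

    locus_id: str
    period: int  # test of the change between samples (period-1, period), period >= 1
    delta_obs: float
    p_value: float
    q_value: float | None = None
    significant: bool | None = None
    s_median: float | None = None
    s_mean: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")
        if self.q_value is not None and self.q_value < self.p_value - 1e-12:
            raise ValueError("BH q-value cannot be smaller than the p-value")
        if self.s_median is not None and self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.s_median <= self.ci_high:
                raise ValueError("credible interval must bracket the posterior median")


@dataclass
class ValidationReport:
    """Outcome of dataset validation: retained loci plus per-locus flags."""

    retained: list[TemporalLocusData] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # locus_id -> reason
    maf: dict[str, float] = field(default_factory=dict)  # pooled MAF per inspected locus

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of allele 1 in a sample: (2*y11 + y12) / (2n).

    Raises
    ------
    ValueError
        If the sample is empty (n = 0).
    """
    n = counts.n
    if n == 0:
        raise ValueError("empty sample: cannot compute an allele frequency from n = 0")
    return counts.allele1_count / (2.0 * n)


def validate_dataset(
    data: Sequence[TemporalLocusData],
    maf_threshold: float = 0.05,
) -> ValidationReport:
    """Screen loci for a scan: drop empty-sample and monomorphic loci, apply MAF filter.

    A locus is retained when every temporal sample is non-empty, the pooled
    sample is polymorphic, and the pooled minor allele frequency exceeds
    ``maf_threshold``.  Exclusion reasons are itemized per locus.
    """
    report = ValidationReport()
    for locus in data:
        if any(s.n == 0 for s in locus.samples):
            report.excluded[locus.locus_id] = "empty sample at one or more time steps"
            continue
        maf = locus.pooled_maf()
        report.maf[locus.locus_id] = maf
        if maf == 0.0:
            report.excluded[locus.locus_id] = "monomorphic in pooled sample"
        elif maf <= maf_threshold:
            report.excluded[locus.locus_id] = f"pooled MAF {maf:.4g} <= threshold {maf_threshold:g}"
        else:
            report.retained.append(locus)
    return report
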
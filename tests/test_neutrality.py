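"""Tests of the standardized-change statistic and the neutrality tests.

Exact results are checked against brute-force enumeration over the full
multinomial outcome space at tiny sample sizes, and the Monte Carlo test
against its exact counterpart.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import multinomial as sp_multinomial

from cohortsel import (
    GenotypeCounts,
    GenotypeFrequencies,
    TemporalLocusData,
    allele_count_pmf,
    allele_frequency,
    delta_stat,
    estimate_initial_frequencies,
    monte_carlo_pvalue,
    quasi_exact_pvalue,
    scan,
)


def _all_outcomes(n):
    """Every genotype-count outcome (i, j, k) with i + j + k = n."""
    return [(i, j, n - i - j) for i in range(n + 1) for j in range(n - i + 1)]


class TestDeltaStat:
    @pytest.mark.parametrize(
        "f_prev, f_curr, expected",
        [
            (0.3, 0.3, 0.0),
            (0.5, 0.4722, (0.5 - 0.4722) ** 2 / (0.48611 - 0.48611**2)),
            (0.0, 0.0, 0.0),  # both fixed for allele 2: no change by convention
            (1.0, 1.0, 0.0),  # both fixed for allele 1
        ],
    )
    def test_known_values(self, f_prev, f_curr, expected):
        assert delta_stat(f_prev, f_curr) == pytest.approx(expected, rel=1e-4)

    def test_value_matches_hand_arithmetic(self):
        assert delta_stat(0.5, 0.4722) == pytest.approx(0.003094, abs=1e-6)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            delta_stat(*bad)

    @given(f1=st.floats(0, 1), f2=st.floats(0, 1))
    def test_nonnegative_and_symmetric(self, f1, f2):
        d = delta_stat(f1, f2)
        assert d >= 0.0
        assert d == delta_stat(f2, f1)


class TestInitialFrequencyEstimator:
    def test_symmetric_counts(self):
        p = estimate_initial_frequencies(GenotypeCounts(1, 1, 1))
        assert (p.p11, p.p12, p.p22) == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_undetected_classes_get_pseudocounts(self):
        p = estimate_initial_frequencies(GenotypeCounts(0, 0, 10))
        assert (p.p11, p.p12, p.p22) == pytest.approx((1 / 33, 1 / 33, 31 / 33))

    @given(
        y11=st.integers(0, 50), y12=st.integers(0, 50), y22=st.integers(0, 50)
    )
    def test_simplex_and_positivity(self, y11, y12, y22):
        if y11 + y12 + y22 == 0:
            with pytest.raises(ValueError):
                estimate_initial_frequencies(GenotypeCounts(y11, y12, y22))
            return
        p = estimate_initial_frequencies(GenotypeCounts(y11, y12, y22))
        assert p.p11 > 0 and p.p12 > 0 and p.p22 > 0
        assert p.p11 + p.p12 + p.p22 == pytest.approx(1.0, abs=1e-12)


class TestAlleleCountPmf:
    def test_single_draw(self):
        pmf = allele_count_pmf(GenotypeFrequencies(0.25, 0.5, 0.25), 1)
        assert pmf == pytest.approx([0.25, 0.5, 0.25])

    def test_two_draws_top_count(self):
        pmf = allele_count_pmf(GenotypeFrequencies(0.25, 0.5, 0.25), 2)
        assert pmf[4] == pytest.approx(0.0625)  # both draws 11-homozygous

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_matches_brute_force_enumeration(self, n):
        p = GenotypeFrequencies(0.2, 0.35, 0.45)
        expected = np.zeros(2 * n + 1)
        for i, j, k in _all_outcomes(n):
            expected[2 * i + j] += sp_multinomial.pmf(
                [i, j, k], n, [p.p11, p.p12, p.p22]
            )
        assert allele_count_pmf(p, n) == pytest.approx(list(expected), abs=1e-12)

    def test_sums_to_one(self):
        pmf = allele_count_pmf(GenotypeFrequencies(0.1, 0.2, 0.7), 200)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)


class TestQuasiExact:
    def test_no_observed_change_gives_p_one(self):
        prev = curr = GenotypeCounts(5, 10, 5)
        p0 = estimate_initial_frequencies(prev + curr)
        res = quasi_exact_pvalue(prev, curr, p0)
        assert res.delta_obs == 0.0
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "prev, curr",
        [((2, 0, 0), (0, 1, 1)), ((1, 1, 0), (0, 0, 2)), ((0, 2, 0), (1, 0, 1))],
    )
    def test_matches_brute_force_over_all_outcome_pairs(self, prev, curr):
        prev, curr = GenotypeCounts(*prev), GenotypeCounts(*curr)
        p0 = estimate_initial_frequencies(prev + curr)
        d_obs = delta_stat(allele_frequency(prev), allele_frequency(curr))
        pv = p0.as_array()
        expected = 0.0
        for a in _all_outcomes(prev.n):
            for b in _all_outcomes(curr.n):
                f_prev = (2 * a[0] + a[1]) / (2 * prev.n)
                f_curr = (2 * b[0] + b[1]) / (2 * curr.n)
                if delta_stat(f_prev, f_curr) >= d_obs - 1e-12:
                    expected += sp_multinomial.pmf(a, prev.n, pv) * sp_multinomial.pmf(
                        b, curr.n, pv
                    )
        res = quasi_exact_pvalue(prev, curr, p0)
        assert res.p_value == pytest.approx(expected, abs=1e-10)

    def test_complexity_guard_suggests_monte_carlo(self):
        big = GenotypeCounts(2000, 1000, 50)
        p0 = GenotypeFrequencies(0.3, 0.4, 0.3)
        with pytest.raises(ValueError, match="monte_carlo"):
            quasi_exact_pvalue(big, big, p0)

    def test_null_pvalues_not_anticonservative(self, rng):
        """Under one common pool, P(p <= alpha) should not exceed alpha by
        more than the Kolmogorov-Smirnov band (discrete tests are
        conservative, so the empirical CDF may sit well below uniform)."""
        n_rep = 400
        pool = GenotypeFrequencies.hardy_weinberg(0.3)
        pvals = []
        for _ in range(n_rep):
            prev = GenotypeCounts(*rng.multinomial(60, pool.as_array()))
            curr = GenotypeCounts(*rng.multinomial(60, pool.as_array()))
            p0 = estimate_initial_frequencies(prev + curr)
            pvals.append(quasi_exact_pvalue(prev, curr, p0).p_value)
        pvals = np.array(pvals)
        band = 1.36 / np.sqrt(n_rep)  # 95% KS band
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            assert (pvals <= alpha).mean() <= alpha + band


class TestMonteCarlo:
    def test_no_observed_change_gives_p_one(self):
        prev = curr = GenotypeCounts(5, 10, 5)
        p0 = estimate_initial_frequencies(prev + curr)
        assert monte_carlo_pvalue(prev, curr, p0, B=200, seed=0).p_value == 1.0

    def test_seed_reproducibility(self, two_sample_locus):
        prev, curr = two_sample_locus.samples
        p0 = estimate_initial_frequencies(two_sample_locus.pooled())
        r1 = monte_carlo_pvalue(prev, curr, p0, B=5000, seed=42)
        r2 = monte_carlo_pvalue(prev, curr, p0, B=5000, seed=42)
        assert r1.p_value == r2.p_value

    def test_add_one_variant_strictly_positive(self):
        prev = GenotypeCounts(50, 0, 0)
        curr = GenotypeCounts(0, 0, 50)
        p0 = estimate_initial_frequencies(prev + curr)
        res = monte_carlo_pvalue(prev, curr, p0, B=100, seed=1, add_one=True)
        assert res.p_value > 0.0

    def test_converges_to_quasi_exact(self):
        prev = GenotypeCounts(20, 20, 10)
        curr = GenotypeCounts(10, 25, 15)
        p0 = estimate_initial_frequencies(prev + curr)
        exact = quasi_exact_pvalue(prev, curr, p0).p_value
        mc = monte_carlo_pvalue(prev, curr, p0, B=200_000, seed=7).p_value
        se = np.sqrt(exact * (1 - exact) / 200_000)
        assert abs(mc - exact) <= 4 * se

    def test_agreement_with_exact_across_random_cases(self, rng):
        """MC with B = 10,000 tracks the exact tail probability within
        Monte Carlo error across a spread of pools and sample sizes."""
        for _ in range(25):
            maf = rng.uniform(0.05, 0.5)
            n = int(rng.integers(20, 120))
            pool = GenotypeFrequencies.hardy_weinberg(maf)
            prev = GenotypeCounts(*rng.multinomial(n, pool.as_array()))
            curr = GenotypeCounts(*rng.multinomial(n, pool.as_array()))
            p0 = estimate_initial_frequencies(prev + curr)
            exact = quasi_exact_pvalue(prev, curr, p0).p_value
            mc = monte_carlo_pvalue(prev, curr, p0, B=10_000, seed=rng).p_value
            se = max(np.sqrt(exact * (1 - exact) / 10_000), 1e-4)
            assert abs(mc - exact) <= 4 * se


class TestScan:
    def _dataset(self, rng, n_loci=20, sizes=(80, 80, 60)):
        from cohortsel import SimulationScenario, simulate_cohort_study

        loci = []
        for i in range(n_loci):
            sc = SimulationScenario(
                N=5000,
                sample_sizes=sizes,
                maf=float(rng.uniform(0.15, 0.5)),
                s=(0.0,) * (len(sizes) - 1),
                replicates=1,
            )
            loci.append(simulate_cohort_study(sc, rng=rng, locus_id=f"L{i}"))
        return loci

    def test_two_period_dataset_yields_two_rows_per_locus(self, rng):
        data = self._dataset(rng)
        out = scan(data, method="quasi_exact", seed=0)
        per_locus = {}
        for r in out.results:
            per_locus.setdefault(r.locus_id, []).append(r.period)
        assert all(sorted(v) == [1, 2] for v in per_locus.values())

    def test_bh_qvalues_match_stepup_oracle(self, rng):
        """q-values agree with an independent Benjamini-Hochberg step-up
        computed directly from the scan's own p-values."""
        data = self._dataset(rng)
        out = scan(data, method="quasi_exact", seed=0)
        p = np.array([r.p_value for r in out.results])
        m = len(p)
        order = np.argsort(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        q = np.array([r.q_value for r in out.results])
        assert q == pytest.approx(expected, abs=1e-12)

    def test_bh_handworked_example(self):
        """Step-up on p = (0.001, 0.01, 0.02, 0.9) gives
        q = (0.004, 0.02, 0.0267, 0.9) with the first three significant,
        and the scan's q-values are monotone in the ranked p-values."""
        from statsmodels.stats.multitest import multipletests

        reject, q = multipletests(
            [0.001, 0.01, 0.02, 0.9], alpha=0.05, method="fdr_bh"
        )[:2]
        assert q == pytest.approx([0.004, 0.02, 0.02 * 4 / 3, 0.9])
        assert reject.sum() == 3

    def test_qvalues_dominate_pvalues_and_are_monotone(self, rng):
        data = self._dataset(rng)
        out = scan(data, method="quasi_exact", seed=0)
        rows = sorted(out.results, key=lambda r: r.p_value)
        assert all(r.q_value >= r.p_value - 1e-12 for r in rows)
        qs = [r.q_value for r in rows]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_flagged_locus_does_not_abort(self, rng):
        data = self._dataset(rng, n_loci=5)
        mono = TemporalLocusData(
            "allsame", (GenotypeCounts(0, 0, 30), GenotypeCounts(0, 0, 30))
        )
        out = scan(data + [mono], method="quasi_exact", seed=0)
        assert "allsame" in out.excluded
        assert len(out.results) == 5 * 2

    def test_seed_reproducible_with_monte_carlo(self, rng):
        data = self._dataset(rng, n_loci=6, sizes=(90, 90))
        a = scan(data, method="monte_carlo", B=2000, seed=5)
        b = scan(data, method="monte_carlo", B=2000, seed=5)
        assert [r.p_value for r in a.results] == [r.p_value for r in b.results]
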
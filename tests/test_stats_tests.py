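"""Exact-test oracles, invariances and the per-year paired comparison."""

import itertools

import numpy as np
import pytest

from dendromort.stats_tests import (
    mann_whitney_u,
    pearson_correlation,
    per_year_paired_comparison,
    significant_periods,
    wilcoxon_signed_rank,
)
from test_growth import bai_from_values


# ---------------------------------------------------------------------------
# Brute-force enumeration oracles (independent of scipy)
# ---------------------------------------------------------------------------

def mw_exact_p(x, y):
    """Two-sided Mann-Whitney p by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, len(x)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        return sum((xs[:, None] > ys[None, :]).sum() for _ in [0])

    observed = u_of(range(n1))
    us = np.array([u_of(c) for c in itertools.combinations(range(n), n1)])
    p_low = np.mean(us <= observed)
    p_high = np.mean(us >= observed)
    return min(1.0, 2 * min(p_low, p_high))


def wilcoxon_exact_p(diffs):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    observed = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=d.size)
    ]
    ws = np.array(ws)
    p = 2 * min(np.mean(ws <= observed), np.mean(ws >= observed))
    return min(1.0, p)


class TestMannWhitney:
    def test_disjoint_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.exact

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n1*n2/2 under symmetry
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_n(self, rng):
        """Exact p equals exhaustive enumeration for every n1+n2 <= 10."""
        for n1 in range(1, 10):
            for n2 in range(1, 11 - n1):
                for _ in range(3):
                    vals = rng.permutation(
                        np.linspace(0, 1, n1 + n2) + rng.uniform(0, 1e-6, n1 + n2)
                    )
                    x, y = vals[:n1], vals[n1:]
                    res = mann_whitney_u(x, y)
                    assert res.exact
                    assert res.p_value == pytest.approx(mw_exact_p(x, y), abs=1e-12)

    def test_order_and_monotone_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=7)
        base = mann_whitney_u(x, y)
        shuffled = mann_whitney_u(rng.permutation(x), rng.permutation(y))
        transformed = mann_whitney_u(np.exp(x), np.exp(y))
        assert shuffled.p_value == pytest.approx(base.p_value)
        assert transformed.p_value == pytest.approx(base.p_value)
        assert transformed.statistic == base.statistic

    def test_null_rejection_rate(self, rng):
        rejections = 0
        reps = 2000
        for _ in range(reps):
            p = mann_whitney_u(rng.normal(size=30), rng.normal(size=30)).p_value
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestWilcoxon:
    def test_all_positive_diffs(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.statistic == 6  # W+ at its maximum
        assert res.p_value == pytest.approx(0.25)
        assert res.exact

    def test_antisymmetric_pair(self):
        assert wilcoxon_signed_rank([-1.0, 1.0]).p_value == pytest.approx(1.0)

    def test_zeros_dropped_and_counted(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0])
        assert res.n == (2,)
        assert res.extra["n_zero_dropped"] == 2

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_matches_enumeration_oracle_small_n(self, rng):
        for n in range(2, 11):
            for _ in range(3):
                d = rng.normal(size=n)
                d += np.sign(d) * 1e-9  # no zeros
                res = wilcoxon_signed_rank(d)
                assert res.exact
                assert res.p_value == pytest.approx(wilcoxon_exact_p(d), abs=1e-12)

    def test_null_rejection_rate(self, rng):
        reps = 2000
        rej = sum(
            wilcoxon_signed_rank(rng.normal(size=25)).p_value < 0.05
            for _ in range(reps)
        )
        rate = rej / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 2 * x).statistic == pytest.approx(1.0)
        assert pearson_correlation(x, -x).statistic == pytest.approx(-1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_monte_carlo_recovery(self, rng):
        rho, n, reps = 0.5, 32, 1000
        cov = [[1, rho], [rho, 1]]
        rs = []
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            rs.append(pearson_correlation(xy[:, 0], xy[:, 1]).statistic)
        assert np.mean(rs) == pytest.approx(rho, abs=0.03)


class TestPerYearPairedComparison:
    def _groups(self, rng, n_couples=12, onset=None, effect=0.4):
        years = np.arange(1990, 2015)
        living, dead, couples = [], [], []
        for i in range(n_couples):
            base = np.exp(rng.normal(1.0, 0.2)) * np.ones(years.size)
            lnoise = rng.normal(0, 0.15, years.size)
            dnoise = rng.normal(0, 0.15, years.size)
            lv = base * np.exp(lnoise)
            dv = base * np.exp(dnoise)
            if onset is not None:
                dv = dv * np.exp(-effect * np.clip(years - onset, 0, None) / 5.0)
            living.append(bai_from_values(lv, start=1990, tid=f"L{i}"))
            dead.append(bai_from_values(dv, start=1990, tid=f"D{i}"))
            couples.append((f"L{i}", f"D{i}"))
        return living, dead, couples

    def test_null_has_few_flags(self, rng):
        living, dead, couples = self._groups(rng)
        out = per_year_paired_comparison(living, dead, couples)
        assert out["significant"].mean() <= 0.15  # nominal false positives only

    def test_onset_detected_near_divergence(self, rng):
        first_flags = []
        for _ in range(10):
            living, dead, couples = self._groups(rng, onset=2005, effect=1.2)
            out = per_year_paired_comparison(living, dead, couples)
            flagged = out.loc[out["significant"], "year"]
            assert not flagged.empty
            first_flags.append(int(flagged.iloc[0]))
        assert np.median(first_flags) == pytest.approx(2005.5, abs=2)

    def test_single_couple_unassessable(self):
        living = [bai_from_values([1, 2, 3.0], start=2000, tid="L0")]
        dead = [bai_from_values([1, 1, 1.0], start=2000, tid="D0")]
        out = per_year_paired_comparison(living, dead, [("L0", "D0")])
        assert not out["assessable"].any()
        assert not out["significant"].any()

    def test_no_couples_error(self):
        with pytest.raises(ValueError):
            per_year_paired_comparison([], [], [])

    def test_significant_periods_contiguity(self, rng):
        living, dead, couples = self._groups(rng, onset=2000, effect=2.0)
        out = per_year_paired_comparison(living, dead, couples)
        periods = significant_periods(out)
        years = set()
        for a, b in periods:
            assert a <= b
            years.update(range(a, b + 1))
        assert years == set(out.loc[out["significant"], "year"].astype(int))
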
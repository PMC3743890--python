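"""Statistical layer: signed-rank exactness, reliability, correlation, power."""

from itertools import product

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from dixonquant import (
    bland_altman,
    change_correlation,
    default_cohort_spec,
    grade_agreement,
    power_comparison,
    shapiro_wilk,
    wilcoxon_signed_rank,
)
from dixonquant.cohort import CohortSpec, FunctionalTestSpec, MuscleSpec
from dixonquant.stats import holm_adjust


def brute_force_wilcoxon_p(diffs):
    """Independent oracle: two-sided p by full enumeration of sign flips.

    For each of the 2^n sign assignments to |d| the positive-rank sum is
    computed; p is twice the smaller tail of the observed W+, capped at 1.
    """
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(n_le, n_ge) / 2.0**n)


class TestWilcoxon:
    def test_all_positive_n5(self):
        res = wilcoxon_signed_rank(np.zeros(5), np.array([1.0, 2, 3, 4, 5]))
        assert res.pvalue == 0.0625  # 2 / 2^5, the one-sided extreme doubled
        assert res.method == "exact"

    def test_plus_minus_one(self):
        res = wilcoxon_signed_rank(np.array([1.0, -1.0]))
        assert res.pvalue == 1.0
        assert res.method == "exact"

    def test_identical_vectors_degenerate(self):
        res = wilcoxon_signed_rank(np.ones(6), np.ones(6))
        assert res.pvalue == 1.0
        assert res.method == "degenerate"
        assert res.n_zero == 6

    def test_zero_differences_dropped_and_counted(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -3.0])
        res = wilcoxon_signed_rank(d)
        assert res.n_used == 3
        assert res.n_zero == 2
        assert res.pvalue == brute_force_wilcoxon_p(d)

    @settings(max_examples=250, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.integers(min_value=1, max_value=10_000), min_size=1, max_size=10,
            unique=True,
        ),
        st.data(),
    )
    def test_exact_path_equals_enumeration(self, magnitudes, data):
        # tie-free property sweep: exact p must equal brute-force enumeration
        signs = [
            data.draw(st.sampled_from([-1.0, 1.0])) for _ in magnitudes
        ]
        d = np.array(magnitudes, float) * np.array(signs)
        res = wilcoxon_signed_rank(d)
        assert res.method == "exact"
        assert res.pvalue == brute_force_wilcoxon_p(d)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=-5, max_value=5), min_size=2, max_size=10)
    )
    def test_tied_small_samples_match_enumeration(self, diffs):
        d = np.array(diffs, float)
        if np.all(d == 0):
            return
        res = wilcoxon_signed_rank(d)
        assert res.pvalue == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(
                min_value=-50, max_value=50, allow_nan=False,
                allow_subnormal=False,
            ),
            min_size=1, max_size=12,
        )
    )
    def test_sign_flip_invariance(self, diffs):
        d = np.asarray(diffs)
        r1 = wilcoxon_signed_rank(d)
        r2 = wilcoxon_signed_rank(-d)
        assert r1.pvalue == pytest.approx(r2.pvalue, rel=1e-12)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = x + rng.normal(0.3, 1.0, size=40)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "approx"
        ref = sps.wilcoxon(y - x, correction=True, mode="approx")
        assert res.pvalue == pytest.approx(float(ref.pvalue), rel=1e-6)

    def test_exact_matches_scipy_exact(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=14)
        y = x + rng.normal(0.5, 1.0, size=14)
        res = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(y - x, mode="exact")
        assert res.pvalue == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_infinite_values_use_largest_ranks(self):
        b = np.array([5.0, 6.0, 7.0, np.inf])
        f = np.array([6.0, 8.0, np.inf, np.inf])
        res = wilcoxon_signed_rank(b, f)
        assert res.n_used == 3
        assert res.n_zero == 1  # the inf -> inf pair
        assert res.statistic == 6.0  # all three differences positive


class TestShapiro:
    def test_detects_uniform_non_normality(self):
        rng = np.random.default_rng(3)
        _, p = shapiro_wilk(rng.uniform(0, 100, 5000))
        assert p < 0.05

    def test_no_false_catastrophe_on_normal(self):
        rng = np.random.default_rng(4)
        _, p = shapiro_wilk(rng.normal(size=5000))
        assert p > 1e-6

    def test_preconditions(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([3.0, 3.0, 3.0])


class TestBlandAltman:
    def test_identical_observers(self):
        a = np.array([1.0, 5.0, 9.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert res.repeatability_coefficient == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 5.0, 9.0])
        res = bland_altman(a + 0.5, a)
        assert res.bias == pytest.approx(0.5)
        assert res.repeatability_coefficient == pytest.approx(0.0)
        assert res.limits == pytest.approx((0.5, 0.5))

    def test_recovery_of_known_difference_sd(self):
        # differences iid N(0, 0.73): true RC = 1.96*0.73 = 1.4308
        rng = np.random.default_rng(12)
        base = rng.uniform(0, 100, 448)
        a = base + rng.normal(0, 0.73, 448)
        res = bland_altman(a, base)
        assert abs(res.bias) < 3 * 0.73 / np.sqrt(448)
        assert res.repeatability_coefficient == pytest.approx(1.4308, rel=0.10)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestAgreement:
    def test_identical_vectors(self):
        g = ["0", "1", "2a", "2b", "3", "4"] * 3
        res = grade_agreement(g, g)
        assert res.overall == 1.0
        assert all(v == 1.0 for v in res.per_grade.values())

    def test_disjoint_vectors(self):
        res = grade_agreement(["0", "1", "2a"], ["1", "2a", "2b"])
        assert res.overall == 0.0

    def test_confusion_table_row_sums(self):
        rng = np.random.default_rng(5)
        grades = np.array(["0", "1", "2a", "2b", "3", "4"], dtype=object)
        a = grades[rng.integers(0, 6, 200)]
        b = grades[rng.integers(0, 6, 200)]
        res = grade_agreement(a, b)
        for g in grades:
            assert res.confusion.loc[g].sum() == np.sum(a == g)

    def test_unknown_symbol_named(self):
        with pytest.raises(ValueError, match="2c"):
            grade_agreement(["2c"], ["0"])


class TestCorrelation:
    def test_monotone_pairings(self):
        assert change_correlation([1, 2, 3, 4], [10, 20, 30, 40]).rho == 1.0
        assert change_correlation([1, 2, 3, 4], [40, 30, 20, 10]).rho == -1.0

    def test_constant_vector_flagged(self):
        res = change_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert np.isnan(res.rho)

    def test_exact_small_sample_type_one(self):
        # independent changes, n=8 exact permutation p: rejection ~ alpha
        rng = np.random.default_rng(6)
        rej = 0
        n_rep = 400
        for _ in range(n_rep):
            r = change_correlation(rng.normal(size=8), rng.normal(size=8))
            rej += r.pvalue < 0.05
        rate = rej / n_rep
        assert abs(rate - 0.05) < 0.035

    def test_asymptotic_type_one_n32(self):
        rng = np.random.default_rng(7)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            r = change_correlation(rng.normal(size=32), rng.normal(size=32))
            rej += r.pvalue < 0.05
        assert abs(rej / n_rep - 0.05) < 0.025


class TestHolm:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.2, 0.9])
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.005)


def small_power_spec(effect, n=16, measurement_sd=3.0, seed=0):
    return CohortSpec(
        n_subjects=n,
        muscles={"A": MuscleSpec(25.0, progression_median=effect)},
        measurement_sd=measurement_sd,
        functional_tests={
            "walk": FunctionalTestSpec(300.0, 100.0, drift=0.0, noise_sd=40.0)
        },
        seed=seed,
    )


class TestPower:
    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            power_comparison(small_power_spec(0.0), alpha=1.5, replications=100)
        with pytest.raises(ValueError):
            power_comparison(small_power_spec(0.0), replications=10)

    def test_power_monotone_in_effect_and_n(self):
        margin = 0.08  # Monte-Carlo slack at 250 replications
        powers_eff = []
        for effect in (0.0, 2.0, 4.0):
            res = power_comparison(
                small_power_spec(effect), replications=250, seed=20,
                endpoints=("ff",),
            )
            powers_eff.append(res[0].power)
        assert powers_eff[1] >= powers_eff[0] - margin
        assert powers_eff[2] >= powers_eff[1] - margin
        powers_n = []
        for n in (8, 32):
            res = power_comparison(
                small_power_spec(3.0, n=n), replications=250, seed=21,
                endpoints=("ff",),
            )
            powers_n.append(res[0].power)
        assert powers_n[1] >= powers_n[0] - margin

    def test_continuous_dominates_ordinal_coarsening(self):
        # the grade endpoint observes a deterministic coarsening of the same
        # latent FF plus observer noise: it cannot be more powerful
        res = power_comparison(
            small_power_spec(4.0, n=32), replications=300, seed=22,
            endpoints=("ff", "grade"),
        )
        by_ep = {r.endpoint: r.power for r in res if r.name == "A"}
        assert by_ep["ff"] >= by_ep["grade"] - 0.05

    def test_large_latent_change_within_one_grade_band(self):
        # muscle mid-way through the 30-60% volume band (FF ~31%) with a
        # +4-point change that stays inside the band: continuous power near
        # 1, ordinal power near alpha (driven only by observer confusion)
        spec = CohortSpec(
            n_subjects=32,
            muscles={"A": MuscleSpec(31.0, concentration=400.0,
                                     progression_median=4.0)},
            measurement_sd=1.0,
            grader=default_cohort_spec().grader,
            seed=0,
        )
        res = power_comparison(
            spec, replications=300, seed=23, endpoints=("ff", "grade")
        )
        by_ep = {r.endpoint: r.power for r in res}
        assert by_ep["ff"] > 0.95
        assert by_ep["grade"] < 0.25
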
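"""Unit and property tests for the circular-statistics primitives."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, special, stats

from tentacular import circstats as cs
from tentacular.circstats import VectorSample
from tentacular.errors import EmptySampleError, InsufficientSampleError


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_moore(angles_deg, weights):
    """Rank-weighted resultant evaluated with plain Python loops.

    Ranks are assigned by explicit sorting with average ranks for ties —
    written independently of the library implementation.
    """
    n = len(angles_deg)
    order = sorted(range(n), key=lambda i: weights[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and weights[order[j + 1]] == weights[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    dx = sum(r * math.cos(math.radians(a)) for r, a in zip(ranks, angles_deg))
    dy = sum(r * math.sin(math.radians(a)) for r, a in zip(ranks, angles_deg))
    r_star = math.sqrt(dx * dx + dy * dy) / n ** 1.5
    phi = math.degrees(math.atan2(dy, dx)) % 360.0
    return r_star, phi


def kappa_root_oracle(rbar):
    return optimize.brentq(
        lambda k: special.i1e(k) / special.i0e(k) - rbar,
        1e-10, 600.0, xtol=1e-12, rtol=8.9e-16,
    )


# ---------------------------------------------------------------------------
# Moore's modified Rayleigh test
# ---------------------------------------------------------------------------

class TestMooreRayleigh:
    def test_aligned_vectors_hit_rank_sum_bound(self):
        # all headings identical: R* = (sum of ranks) / n^1.5 = (n+1)/(2 sqrt n)
        s = VectorSample(np.full(4, 90.0), np.array([1.0, 2.0, 3.0, 4.0]))
        r, phi = cs.moore_rayleigh(s)
        assert r == pytest.approx(1.25, abs=1e-12)
        assert phi == pytest.approx(90.0, abs=1e-9)

    def test_two_opposed_vectors(self):
        # ranks 1 and 2 at 0 and 180 degrees: D = (-1, 0)
        s = VectorSample(np.array([0.0, 180.0]), np.array([1.0, 2.0]))
        r, phi = cs.moore_rayleigh(s)
        assert r == pytest.approx(1.0 / 2.0 ** 1.5, abs=1e-12)
        assert phi == pytest.approx(180.0, abs=1e-9)

    def test_balanced_sample_has_zero_resultant_and_undefined_phi(self):
        s = VectorSample(np.array([0.0, 90.0, 180.0, 270.0]), np.ones(4))
        r, phi = cs.moore_rayleigh(s)
        assert r == 0.0
        assert math.isnan(phi)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            cs.moore_rayleigh(VectorSample(np.empty(0)))

    def test_matches_brute_force_oracle(self, rng):
        # random small samples, including ties in the weights
        for _ in range(300):
            n = int(rng.integers(1, 9))
            angles = rng.uniform(0, 360, n)
            weights = np.round(rng.uniform(0.5, 3.0, n), 1)  # forces ties
            r1, p1 = cs.moore_rayleigh(VectorSample(angles, weights))
            r2, p2 = brute_force_moore(list(angles), list(weights))
            assert r1 == pytest.approx(r2, abs=1e-12)
            if not math.isnan(p1):
                assert p1 == pytest.approx(p2, abs=1e-9)

    @given(rotation=st.floats(0.0, 360.0), seed=st.integers(0, 10 ** 6))
    def test_rotation_equivariance(self, rotation, seed):
        g = np.random.default_rng(seed)
        angles = g.uniform(0, 360, 6)
        weights = g.uniform(0.5, 2.0, 6)
        r0, p0 = cs.moore_rayleigh(VectorSample(angles, weights))
        r1, p1 = cs.moore_rayleigh(VectorSample(angles + rotation, weights))
        assert r1 == pytest.approx(r0, abs=1e-9)
        circ_diff = ((p1 - p0 - rotation) + 180.0) % 360.0 - 180.0
        assert circ_diff == pytest.approx(0.0, abs=1e-6)

    @given(scale=st.floats(0.1, 100.0))
    def test_weights_enter_only_through_ranks(self, scale):
        g = np.random.default_rng(1)
        angles = g.uniform(0, 360, 8)
        weights = g.uniform(0.5, 2.0, 8)
        r0, p0 = cs.moore_rayleigh(VectorSample(angles, weights))
        r1, p1 = cs.moore_rayleigh(VectorSample(angles, weights * scale))
        assert (r0, p0) == (r1, p1)


class TestMooreCriticalValue:
    def test_deterministic_given_seed(self):
        a = cs.moore_critical_value(7, reps=2000, seed=11)
        b = cs.moore_critical_value(7, reps=2000, seed=11)
        assert a == b

    def test_alpha_one_gives_zero(self):
        assert cs.moore_critical_value(5, alpha=1.0, reps=1000) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            cs.moore_critical_value(1)

    def test_large_n_matches_asymptotic_quantile(self):
        # R*^2 is asymptotically exponential with mean 1/3, so the 95%
        # quantile tends to sqrt(ln(20) / 3) ~ 0.9993
        crit = cs.moore_critical_value(500, alpha=0.05, reps=100_000)
        assert crit == pytest.approx(math.sqrt(math.log(20.0) / 3.0),
                                     abs=0.01)

    def test_small_n_matches_independent_simulation(self):
        # brute-force null simulation written without the library helper
        g = np.random.default_rng(99)
        n, reps = 10, 20_000
        vals = np.empty(reps)
        for i in range(reps):
            theta = g.uniform(0, 2 * np.pi, n)
            ranks = np.arange(1, n + 1)
            dx = np.sum(ranks * np.cos(theta))
            dy = np.sum(ranks * np.sin(theta))
            vals[i] = np.hypot(dx, dy) / n ** 1.5
        expected = np.quantile(vals, 0.95)
        crit = cs.moore_critical_value(10, alpha=0.05, reps=100_000)
        assert crit == pytest.approx(expected, abs=0.015)

    def test_persistent_cache_round_trip(self, tmp_path):
        path = tmp_path / "crit.tsv"
        a = cs.moore_critical_value(6, reps=1500, seed=3, cache_path=path)
        cs._CRIT_CACHE.pop((6, 0.05, 1500, 3))
        b = cs.moore_critical_value(6, reps=1500, seed=3, cache_path=path)
        assert a == b
        assert path.exists()


# ---------------------------------------------------------------------------
# von Mises fitting
# ---------------------------------------------------------------------------

class TestVonMisesFit:
    def test_symmetric_sample_mean_is_axis(self):
        fit = cs.vonmises_fit(VectorSample(np.array([30.0, 330.0])),
                              weighted=False)
        assert fit.mu_deg == pytest.approx(0.0, abs=1e-9) \
            or fit.mu_deg == pytest.approx(360.0, abs=1e-9)

    def test_identical_angles_cap_kappa(self):
        fit = cs.vonmises_fit(VectorSample(np.full(5, 123.0)), weighted=False)
        assert fit.kappa == cs.KAPPA_MAX
        assert fit.degenerate

    def test_parameter_recovery_from_simulation(self, rng):
        draws = np.degrees(rng.vonmises(np.pi / 4, 2.0, 1000)) % 360.0
        fit = cs.vonmises_fit(VectorSample(draws), weighted=False)
        assert abs((fit.mu_deg - 45.0 + 180.0) % 360.0 - 180.0) < 5.0
        assert 1.7 < fit.kappa < 2.3

    def test_kappa_inversion_agrees_with_root_finding(self):
        for rbar in np.linspace(0.01, 0.99, 99):
            assert cs.kappa_from_rbar(rbar) == pytest.approx(
                kappa_root_oracle(rbar), abs=1e-6)

    def test_weights_shift_the_mean(self):
        s = VectorSample(np.array([0.0, 90.0]), np.array([3.0, 1.0]))
        fit = cs.vonmises_fit(s, weighted=True)
        assert 0.0 < fit.mu_deg < 45.0

    def test_zero_weights_rejected(self):
        s = VectorSample(np.array([0.0, 90.0]), np.zeros(2))
        with pytest.raises(ValueError):
            cs.vonmises_fit(s, weighted=True)

    def test_loglik_matches_scipy_vonmises(self, rng):
        draws = np.degrees(rng.vonmises(1.0, 3.0, 50)) % 360.0
        fit = cs.vonmises_fit(VectorSample(draws), weighted=False)
        ref = np.sum(stats.vonmises.logpdf(
            np.deg2rad(draws), fit.kappa, loc=np.deg2rad(fit.mu_deg)))
        assert fit.loglik == pytest.approx(float(ref), rel=1e-9)


class TestUniformLoglik:
    @pytest.mark.parametrize("n,expected", [
        (1, -math.log(2 * math.pi)),
        (18, -18 * math.log(2 * math.pi)),
        (0, 0.0),
    ])
    def test_values(self, n, expected):
        assert cs.uniform_loglik(n) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

class TestModelSelect:
    def test_aicc_penalty_arithmetic(self):
        # equal log-likelihoods at n=18 leave the unimodal model penalised
        # by 2k + 2k(k+1)/(n-k-1) = 4 + 12/15 = 4.8
        n = 18
        penalty = 2 * 2 + 2 * 2 * 3 / (n - 2 - 1)
        assert penalty == pytest.approx(4.8)
        res = cs.model_select(np.degrees(
            np.random.default_rng(2).vonmises(0, 0.0, n)) % 360)
        gap = (res.aicc_unimodal - res.aicc_uniform) \
            - (-2 * res.loglik_unimodal + 2 * res.loglik_uniform)
        assert gap == pytest.approx(4.8, abs=1e-9)

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientSampleError):
            cs.model_select([0.0, 10.0, 20.0])

    def test_weights_sum_to_one_and_min_delta_zero(self, rng):
        res = cs.model_select(rng.uniform(0, 360, 12))
        assert sum(res.aicc_weights.values()) == pytest.approx(1.0)
        assert min(res.delta_aicc.values()) == 0.0

    def test_concentrated_data_prefer_unimodal(self, rng):
        wins = 0
        for _ in range(100):
            a = np.degrees(rng.vonmises(0.0, 4.0, 18)) % 360
            res = cs.model_select(a)
            wins += res.best == "unimodal" and res.delta_aicc["uniform"] > 2
        assert wins >= 80

    def test_uniform_data_retain_uniform_support(self, rng):
        kept = 0
        for _ in range(100):
            res = cs.model_select(rng.uniform(0, 360, 18))
            kept += res.delta_aicc["uniform"] < 2
        assert kept >= 80


# ---------------------------------------------------------------------------
# Equal-kappa test
# ---------------------------------------------------------------------------

class TestEqualKappa:
    def test_identical_samples_are_homogeneous(self, rng):
        g = np.degrees(rng.vonmises(0, 2.0, 40)) % 360
        res = cs.equal_kappa_test([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_separated_concentrations_detected(self, rng):
        a = np.degrees(rng.vonmises(0, 10.0, 50)) % 360
        b = np.degrees(rng.vonmises(0, 0.5, 50)) % 360
        res = cs.equal_kappa_test([a, b])
        assert res.p_value < 0.05

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            cs.equal_kappa_test([[0.0, 10.0], [5.0]])

    def test_matches_permutation_oracle_on_small_instances(self, rng):
        # compare the chi-square p with a permutation null of the same
        # statistic: they should agree in their accept/reject calls at
        # a generous margin
        a = np.degrees(rng.vonmises(0, 8.0, 25)) % 360
        b = np.degrees(rng.vonmises(1.0, 0.8, 25)) % 360
        obs = cs.equal_kappa_test([a, b])
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 400
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            stat = cs.equal_kappa_test([perm[:25], perm[25:]]).statistic
            count += stat >= obs.statistic
        p_perm = (count + 1) / (n_perm + 1)
        assert (obs.p_value < 0.05) == (p_perm < 0.05)


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

class TestFriedman:
    def test_all_tied_rows_give_zero_statistic(self):
        table = np.full((4, 3), 7.0)
        res = cs.friedman_test(table)
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_hand_worked_example(self):
        # three subjects all ranking treatments (1, 2, 3): rank sums
        # (3, 6, 9), chi2 = 6, df = 2
        table = np.array([[1, 2, 3], [1, 2, 3], [1, 2, 3]], dtype=float)
        res = cs.friedman_test(table)
        assert res.chi2 == pytest.approx(6.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.049787, abs=1e-5)

    def test_matches_scipy_cross_check(self, rng):
        table = rng.poisson(8.0, size=(12, 4)).astype(float)
        res = cs.friedman_test(table)
        ref = stats.friedmanchisquare(*table.T)
        assert res.chi2 == pytest.approx(ref.statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_two_treatments_supported(self):
        table = np.array([[1.0, 2.0], [1.0, 3.0], [2.0, 5.0], [0.0, 4.0]])
        res = cs.friedman_test(table)
        assert res.df == 1
        assert 0.0 <= res.p_value <= 1.0

    def test_missing_cells_rejected(self):
        table = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            cs.friedman_test(table)


# ---------------------------------------------------------------------------
# Directedness regression
# ---------------------------------------------------------------------------

class TestDirectednessRegression:
    def test_noiseless_recovery_is_exact(self, rng):
        z = rng.uniform(0, 2, 40)
        r_star = 1.21 - 0.23 * z
        res = cs.directedness_regression(r_star, z)
        assert res.beta1 == pytest.approx(1.21, abs=1e-9)
        assert res.beta2 == pytest.approx(-0.23, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_reports_f_test_and_cis(self, rng):
        z = rng.uniform(0, 2, 70)
        y = 1.2 - 0.3 * z + rng.normal(0, 0.1, 70)
        res = cs.directedness_regression(y, z)
        assert res.f_df == (1, 68)
        lo, hi = res.conf_int["beta2"]
        assert lo < res.beta2 < hi
        assert 0.0 <= res.shapiro_p <= 1.0

    def test_constant_z_rejected(self):
        with pytest.raises(ValueError):
            cs.directedness_regression([1.0, 1.1, 0.9], [0.5, 0.5, 0.5])

    def test_null_slope_false_positive_rate(self, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            z = rng.uniform(0, 2, 30)
            y = rng.normal(1.0, 0.2, 30)
            res = cs.directedness_regression(y, z)
            rejections += res.p_value < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.035)


# ---------------------------------------------------------------------------
# Fisher-Lee correlation
# ---------------------------------------------------------------------------

class TestFisherLee:
    def test_identity_series_fully_correlated(self):
        t = np.linspace(0, 350, 36)
        assert cs.fisher_lee_correlation(t, t) == pytest.approx(1.0)

    def test_reversed_series_anticorrelated(self):
        t = np.linspace(0, 350, 36)
        assert cs.fisher_lee_correlation(t, -t) == pytest.approx(-1.0)

    def test_constant_series_has_no_correlation(self):
        t = np.linspace(0, 350, 36)
        assert math.isnan(cs.fisher_lee_correlation(np.full(36, 10.0), t))

    def test_rotation_invariance(self, rng):
        a = rng.uniform(0, 360, 20)
        b = rng.uniform(0, 360, 20)
        r0 = cs.fisher_lee_correlation(a, b)
        r1 = cs.fisher_lee_correlation((a + 123.0) % 360, b)
        assert r0 == pytest.approx(r1, abs=1e-9)
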
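"""Statistics: exact Wilcoxon, Friedman/Conover, JZS Bayes factor, Spearman."""

import itertools

import numpy as np
import pytest
import scipy.stats as ss
from scipy import integrate

import oddphot as op
from oddphot.stats import wilcoxon_exact_p_batch


def brute_force_wilcoxon_p(d):
    """Independent oracle: enumerate all 2^n sign assignments directly."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = ss.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(ranks[np.array(signs, dtype=bool)].sum())
    ws = np.array(ws)
    eps = 1e-9
    cdf = np.mean(ws <= w_obs + eps)
    sf = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(cdf, sf))


def rouder_bf10(t, n, r=0.707):
    """Independent oracle: the g-integral form of the JZS Bayes factor
    (Cauchy prior as a scale mixture with inverse-gamma mixing)."""
    df = n - 1

    def num_integrand(g):
        return (
            (1 + n * g) ** -0.5
            * (1 + t * t / ((1 + n * g) * df)) ** (-(df + 1) / 2.0)
            * (r * r / 2.0) ** 0.5
            / np.sqrt(np.pi)
            * g ** -1.5
            * np.exp(-r * r / (2 * g))
        )

    num, _ = integrate.quad(num_integrand, 0, np.inf, epsabs=1e-14, epsrel=1e-10)
    den = (1 + t * t / df) ** (-(df + 1) / 2.0)
    return num / den


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        r = op.wilcoxon_signed_rank(np.arange(1.0, 6.0), np.zeros(5))
        assert r.p_value == pytest.approx(2.0 / 32.0)
        assert r.method == "wilcoxon_signed_rank_exact"

    def test_identical_samples_degenerate(self):
        with pytest.raises(op.DegenerateDataError):
            op.wilcoxon_signed_rank(np.ones(5), np.ones(5))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        if seed % 3 == 0:  # provoke midrank ties in |d|
            x = np.round(x - y, 1) + y
        d = x - y
        if np.all(d == 0) or (d != 0).sum() < 2:
            return
        r = op.wilcoxon_signed_rank(x, y)
        assert r.p_value == pytest.approx(brute_force_wilcoxon_p(d), abs=1e-12)

    def test_zero_differences_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([1.0, 0.0, 1.0, 6.0, 1.0, 2.0])
        r = op.wilcoxon_signed_rank(x, y)
        assert r.n == 5

    def test_exact_and_approximate_agree_at_boundary(self):
        """Normal approximation with continuity correction tracks the exact
        p to < 0.01 at n = 25."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.standard_normal(25)
            y = rng.standard_normal(25)
            exact = op.wilcoxon_signed_rank(x, y, exact_threshold=25)
            approx = op.wilcoxon_signed_rank(x, y, exact_threshold=0)
            assert abs(exact.p_value - approx.p_value) < 0.01

    def test_batch_exact_matches_scalar(self):
        rng = np.random.default_rng(4)
        n = 21
        x = rng.standard_normal((50, n))
        ranks = ss.rankdata(np.abs(x), axis=1)
        w = np.where(x > 0, ranks, 0.0).sum(axis=1)
        ps = wilcoxon_exact_p_batch(w, n)
        for i in range(50):
            r = op.wilcoxon_signed_rank(x[i], np.zeros(n))
            assert ps[i] == pytest.approx(r.p_value, abs=1e-12)

    def test_type_one_error_calibration(self):
        """Under the null (i.i.d. paired normals, n = 21), the exact test
        rejects at alpha = 0.05 in 5% +/- 1% of 10,000 replicates."""
        rng = np.random.default_rng(2024)
        n, reps = 21, 10_000
        d = rng.standard_normal((reps, n))
        ranks = ss.rankdata(np.abs(d), axis=1)
        w = np.where(d > 0, ranks, 0.0).sum(axis=1)
        rate = float(np.mean(wilcoxon_exact_p_batch(w, n) < 0.05))
        assert 0.04 <= rate <= 0.06


class TestFriedman:
    def test_identical_rankings_maximal_statistic(self):
        """k = 4, n = 12, all subjects rank identically: chi2 = n(k-1)."""
        base = np.array([10.0, 20.0, 30.0, 40.0])
        table = np.tile(base, (12, 1)) + np.arange(12)[:, None]
        r = op.friedman(table)
        assert r.statistic == pytest.approx(12 * 3, abs=1e-9)

    def test_identical_columns_zero(self):
        table = np.tile(np.arange(5.0)[:, None], (1, 3))
        with pytest.raises(op.DegenerateDataError):
            op.friedman(table)  # all within-subject ranks tie flat

    def test_textbook_rank_computation(self):
        table = np.array(
            [[1.0, 2, 3], [1, 2, 3], [2, 1, 3], [1, 3, 2], [1, 2, 3]]
        )
        r = op.friedman(table)
        # hand computation: R = (6, 10, 14), chi2 = 12/(5*3*4)*sum(R^2) - 3*5*4
        expected = 12.0 / (5 * 3 * 4) * (36 + 100 + 196) - 3 * 5 * 4
        assert r.statistic == pytest.approx(expected)
        assert r.statistic == pytest.approx(
            ss.friedmanchisquare(*table.T).statistic
        )

    def test_tie_correction_on_tied_table(self):
        table = np.array([[1.0, 1.0, 2.0], [3.0, 1.0, 2.0], [1.0, 2.0, 2.0],
                          [2.0, 3.0, 1.0]])
        r = op.friedman(table)
        # independent oracle: tie-corrected rank formula evaluated explicitly
        ranks = np.apply_along_axis(ss.rankdata, 1, table)
        n, k = table.shape
        a1 = (ranks**2).sum()
        c1 = n * k * (k + 1) ** 2 / 4.0
        tt = ((ranks.sum(axis=0) - n * (k + 1) / 2.0) ** 2).sum()
        assert r.statistic == pytest.approx((k - 1) * tt / (a1 - c1))


class TestConover:
    def test_identical_columns_all_one(self):
        table = np.array([[1.0, 2.0], [2.0, 1.0], [1.0, 2.0], [2.0, 1.0]])
        p = op.conover_posthoc(table)
        assert np.all(p == 1.0)

    def test_two_conditions_no_correction_factor(self):
        rng = np.random.default_rng(5)
        table = rng.standard_normal((8, 2))
        assert np.array_equal(
            op.conover_posthoc(table, bonferroni=True),
            op.conover_posthoc(table, bonferroni=False),
        )

    def test_toy_table_matches_published_formula(self):
        """6 x 4 table against Conover's t formula evaluated step by step."""
        rng = np.random.default_rng(6)
        table = rng.standard_normal((6, 4)) + np.array([0.0, 0.2, 0.5, 1.0])
        p = op.conover_posthoc(table, bonferroni=False)

        ranks = np.apply_along_axis(ss.rankdata, 1, table)
        n, k = table.shape
        R = ranks.sum(axis=0)
        A1 = (ranks**2).sum()
        C1 = n * k * (k + 1) ** 2 / 4.0
        TT = ((R - n * (k + 1) / 2.0) ** 2).sum()
        T1 = (k - 1) * TT / (A1 - C1)
        df = (n - 1) * (k - 1)
        denom = np.sqrt(2 * n * (A1 - C1) / df * (1 - T1 / (n * (k - 1))))
        for i, j in itertools.combinations(range(k), 2):
            t = abs(R[i] - R[j]) / denom
            assert p[i, j] == pytest.approx(2 * ss.t.sf(t, df), abs=1e-12)

    def test_bonferroni_clipping(self):
        rng = np.random.default_rng(7)
        table = rng.standard_normal((5, 4))
        p = op.conover_posthoc(table, bonferroni=True)
        assert np.all(p <= 1.0) and np.all(p >= 0.0)
        assert np.allclose(p, p.T)


class TestBayesFactor:
    def test_null_t_gives_evidence_toward_null(self):
        for n in (5, 21, 40):
            bf = op.bayes_factor_from_t(0.0, n)
            assert bf < 1.0
            assert bf == pytest.approx(rouder_bf10(0.0, n), rel=1e-6)

    def test_monotone_in_t_magnitude(self):
        bfs = [op.bayes_factor_from_t(t, 21) for t in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(bfs) > 0)

    @pytest.mark.parametrize("t,n", [(2.5, 21), (-1.7, 12), (4.0, 37), (0.3, 8)])
    def test_dual_oracle_agreement(self, t, n):
        """Noncentral-t route vs the g-integral route to 1e-6 relative."""
        assert op.bayes_factor_from_t(t, n) == pytest.approx(
            rouder_bf10(t, n), rel=1e-6
        )

    def test_matches_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in [(2.5, 21), (0.0, 10), (3.3, 15)]:
            ref = float(pingouin.bayesfactor_ttest(t, n, paired=True))
            assert op.bayes_factor_from_t(t, n) == pytest.approx(ref, rel=1e-6)

    def test_paired_interface_and_degenerate(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(21) + 0.8
        y = rng.standard_normal(21)
        r = op.bayes_paired_t(x, y)
        assert r.bf10 > 0 and r.n == 21
        with pytest.raises(op.DegenerateDataError):
            op.bayes_paired_t(np.ones(5), np.zeros(5))

    def test_bf_consistency_under_true_and_null_effects(self):
        """Median BF10 > 3 under d = 0.8 (n = 21); < 1 under d = 0."""
        rng = np.random.default_rng(9)
        reps = 200
        bf_alt, bf_null = [], []
        for _ in range(reps):
            d = rng.standard_normal(21)
            bf_null.append(op.bayes_paired_t(d, np.zeros(21)).bf10)
            bf_alt.append(op.bayes_paired_t(d + 0.8, np.zeros(21)).bf10)
        assert np.median(bf_alt) > 3.0
        assert np.median(bf_null) < 1.0


class TestInterpretBf:
    @pytest.mark.parametrize(
        "bf,label",
        [(0.179, "null"), (1.0, "inconclusive"), (3.0001, "alternative"),
         (3.0, "inconclusive"), (1.0 / 3.0, "inconclusive")],
    )
    def test_threshold_labels(self, bf, label):
        assert op.interpret_bf(bf) == label

    def test_invalid_bf_rejected(self):
        with pytest.raises(op.ParameterError):
            op.interpret_bf(0.0)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert op.spearman(x, np.exp(x))[0] == 1.0
        assert op.spearman(x, -np.exp(x))[0] == -1.0

    def test_tied_data_matches_rank_then_pearson_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([2.0, 1.0, 3.0, 3.0, 5.0, 4.0, 6.0, 5.0, 8.0, 7.0])
        r, _ = op.spearman(x, y)
        oracle = np.corrcoef(ss.rankdata(x), ss.rankdata(y))[0, 1]
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        r, p = op.spearman(x, y)
        # enumerate all 120 permutations directly
        rx = ss.rankdata(x)
        robs = abs(np.corrcoef(rx, ss.rankdata(y))[0, 1])
        count = 0
        for perm in itertools.permutations(ss.rankdata(y)):
            if abs(np.corrcoef(rx, perm)[0, 1]) >= robs - 1e-12:
                count += 1
        assert p == pytest.approx(count / 120.0)

    def test_large_n_t_approximation_close_to_scipy(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(40)
        y = x + rng.standard_normal(40)
        r, p = op.spearman(x, y)
        r_sp, p_sp = ss.spearmanr(x, y)
        assert r == pytest.approx(r_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(op.DegenerateDataError):
            op.spearman(np.ones(5), np.arange(5.0))
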
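"""Nonparametric and Bayesian paired statistics.

Provides the tests used throughout the analysis chain:

* Wilcoxon signed-rank with an *exact* two-sided p (full enumeration of the
  signed-rank distribution, midrank ties supported) below a configurable n,
  and a tie-corrected normal approximation with continuity correction above;
* tie-corrected Friedman test and Conover post hoc pairwise comparisons with
  Bonferroni correction;
* the JZS Bayes factor for a paired t-test (Cauchy prior on the
  standardized effect size, default scale r = 0.707), by adaptive numerical
  integration;
* Bayes-factor interpretation at the 3 / 0.33 evidence thresholds;
* Spearman rank correlation with midranks, exact permutation p for small n
  and the t approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as ss

from .exceptions import DegenerateDataError, ParameterError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    bf10: float | None = None
    correction: str | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ParameterError(f"p-value outside [0, 1]: {self.p_value}")
        if self.bf10 is not None and self.bf10 <= 0:
            raise ParameterError("BF10 must be positive")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def signed_rank_null_counts(ranks2: np.ndarray) -> np.ndarray:
    """Exact null distribution of W+ (sum of positive-signed ranks).

    ``ranks2`` are the doubled (hence integer) midranks of |differences|.
    Returns counts over W+ on the doubled scale: counts[w] of the 2^n sign
    assignments give that doubled rank sum.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: counts.size - r]
        counts = new
    return counts


def _exact_two_sided_p(w2: int, counts: np.ndarray) -> float:
    total = counts.sum()
    cdf = counts[: w2 + 1].sum() / total
    sf = counts[w2:].sum() / total
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray, exact_threshold: int = 25
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (all-zero raises).  For n (after dropping)
    up to ``exact_threshold`` the p-value is exact by full enumeration of the
    signed-rank null distribution; above, a tie-corrected normal
    approximation with continuity correction is used.  The statistic is W+,
    the sum of the midranks of positive differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n < 2:
        raise DegenerateDataError(
            "fewer than 2 non-zero differences; test undefined"
        )
    ranks = ss.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    ranks2 = np.round(2.0 * ranks).astype(int)

    if n <= exact_threshold:
        counts = signed_rank_null_counts(ranks2)
        p = _exact_two_sided_p(int(round(2.0 * w_plus)), counts)
        method = "wilcoxon_signed_rank_exact"
    else:
        mu = ranks.sum() / 2.0
        sd = np.sqrt((ranks**2).sum() / 4.0)
        delta = w_plus - mu
        z = (delta - 0.5 * np.sign(delta)) / sd if delta != 0 else 0.0
        p = float(min(1.0, 2.0 * ss.norm.sf(abs(z))))
        method = "wilcoxon_signed_rank_normal_cc"
    return TestResult(statistic=w_plus, p_value=p, n=n, method=method)


def wilcoxon_exact_p_batch(w_plus: np.ndarray, n: int) -> np.ndarray:
    """Vectorized exact two-sided p for tie-free samples of size n.

    For continuous data the signed-rank null depends only on n; this
    precomputes it once and evaluates many statistics (used for type-I
    calibration at scale).
    """
    ranks2 = 2 * np.arange(1, n + 1)
    counts = signed_rank_null_counts(ranks2)
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    sf = np.cumsum(counts[::-1])[::-1] / total
    w2 = np.round(2.0 * np.asarray(w_plus, dtype=float)).astype(int)
    return np.minimum(1.0, 2.0 * np.minimum(cdf[w2], sf[w2]))


# ---------------------------------------------------------------------------
# Friedman and Conover post hoc
# ---------------------------------------------------------------------------


def _friedman_parts(table: np.ndarray):
    tbl = np.asarray(table, dtype=float)
    if tbl.ndim != 2:
        raise ParameterError("table must be subjects x conditions")
    n, k = tbl.shape
    if n < 2 or k < 2:
        raise ParameterError("need >= 2 subjects and >= 2 conditions")
    ranks = np.apply_along_axis(ss.rankdata, 1, tbl)
    col_sums = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    if a1 - c1 <= 0:
        raise DegenerateDataError(
            "all subjects rank conditions identically flat; test undefined"
        )
    tt = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    stat = (k - 1) * tt / (a1 - c1)
    return n, k, ranks, col_sums, a1, c1, stat


def friedman(table: np.ndarray) -> TestResult:
    """Tie-corrected Friedman chi-square test on a subjects x conditions table.

    Within-subject midrank ties are supported; the statistic has k-1 degrees
    of freedom.
    """
    n, k, _, _, _, _, stat = _friedman_parts(table)
    p = float(ss.chi2.sf(stat, k - 1))
    return TestResult(statistic=float(stat), p_value=p, n=n, method="friedman")


def conover_posthoc(
    table: np.ndarray, bonferroni: bool = True
) -> np.ndarray:
    """Conover's all-pairs post hoc comparisons after a Friedman test.

    Returns a symmetric (k x k) matrix of two-sided p-values (diagonal 1),
    multiplied by the number of pairs and clipped at 1 when ``bonferroni``.
    Uses the Friedman-conditional t statistic with tie correction:
    t = (R_i - R_j) / sqrt([2n(A - C)/df] * [1 - chi2/(n(k-1))]),
    df = (n-1)(k-1).
    """
    n, k, _, col_sums, a1, c1, stat = _friedman_parts(table)
    df = (n - 1) * (k - 1)
    factor = 1.0 - stat / (n * (k - 1))
    factor = max(factor, 1e-12)  # chi2 at its maximum -> zero denominator
    denom = np.sqrt(2.0 * n * (a1 - c1) / df * factor)
    n_pairs = k * (k - 1) // 2
    p = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        t = abs(col_sums[i] - col_sums[j]) / denom
        pij = 2.0 * ss.t.sf(t, df)
        if bonferroni:
            pij = min(1.0, pij * n_pairs)
        p[i, j] = p[j, i] = pij
    return p


# ---------------------------------------------------------------------------
# JZS Bayes factor (paired t)
# ---------------------------------------------------------------------------


def bayes_factor_from_t(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """JZS BF10 for a one-sample (paired-difference) t statistic.

    BF10 = integral over the Cauchy(0, r) prior on the standardized effect
    size of the noncentral-t likelihood, divided by the central-t likelihood,
    computed by adaptive quadrature (relative tolerance 1e-8).
    """
    if n < 2:
        raise ParameterError("need n >= 2")
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        return ss.nct.pdf(t, df, delta * sqrt_n) * ss.cauchy.pdf(
            delta, scale=cauchy_scale
        )

    # split at 0 and near the maximum-likelihood effect size for stability
    d_hat = t / sqrt_n
    pts = sorted({0.0, d_hat})
    num = 0.0
    bounds = [-np.inf] + pts + [np.inf]
    for a, b in zip(bounds, bounds[1:]):
        val, _ = integrate.quad(integrand, a, b, epsabs=1e-14, epsrel=1e-8)
        num += val
    den = ss.t.pdf(t, df)
    return float(num / den)


def bayes_paired_t(
    x: np.ndarray, y: np.ndarray, cauchy_scale: float = 0.707
) -> TestResult:
    """Bayesian paired-samples t-test (JZS, Cauchy prior scale 0.707).

    Returns the frequentist t statistic with the BF10 attached; the p-value
    field carries the two-sided classical p for reference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    d = x - y
    n = d.size
    if n < 2:
        raise DegenerateDataError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateDataError("zero variance of differences")
    t = float(d.mean() / (sd / np.sqrt(n)))
    bf = bayes_factor_from_t(t, n, cauchy_scale)
    p = float(2.0 * ss.t.sf(abs(t), n - 1))
    return TestResult(
        statistic=t, p_value=p, n=n, bf10=bf, method="bayes_paired_t_jzs"
    )


def interpret_bf(bf10: float) -> str:
    """Evidence label at the BF > 3 / BF < 1/3 thresholds."""
    if bf10 <= 0:
        raise ParameterError("BF10 must be positive")
    if bf10 > 3.0:
        return "alternative"
    if bf10 < 1.0 / 3.0:
        return "null"
    return "inconclusive"


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(
    x: np.ndarray, y: np.ndarray, exact_threshold: int = 9
) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    p-value by exact permutation enumeration for n <= ``exact_threshold``,
    else by the t approximation.  Returns (r, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    n = x.size
    if n < 3:
        raise ParameterError("need n >= 3")
    rx = ss.rankdata(x)
    ry = ss.rankdata(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    sx = np.sqrt((cx**2).sum())
    sy = np.sqrt((cy**2).sum())
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDataError("constant input; correlation undefined")
    r = float((cx * cy).sum() / (sx * sy))

    if n <= exact_threshold:
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = (cy[perms] @ cx) / (sx * sy)
        p = float(np.mean(np.abs(r_perm) >= abs(r) - 1e-12))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * ss.t.sf(abs(t), n - 2))
    return r, p
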
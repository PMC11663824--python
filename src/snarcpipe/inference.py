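"""Group-level frequentist and default-prior Bayesian tests.

t-tests carry a JZS Bayes factor: the marginal likelihood of the observed t
under a Cauchy(0, rscale) prior on the standardized effect size (numerically
integrated against the noncentral-t sampling density) divided by the central-t
likelihood at the null. Default rscale is 0.707. One-sided Bayes factors
truncate the Cauchy prior to the hypothesized direction.

Pearson correlations carry a default Bayes factor under a stretched-beta
prior on the population correlation. The default width is 1/3, which is the
convention of the widely used default-Bayes-factor software for correlations;
width 1 (uniform prior) is available via the ``width`` argument.

The Jonckheere-Terpstra trend statistic sums, over ordered group pairs
(i < j), the number of cross-group pairs with x_i < x_j plus half the ties.
Significance comes from label permutation with the add-one estimator
p = (1 + #{T* >= T}) / (B + 1), so a permutation p-value is never zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, special, stats

DEFAULT_RSCALE = 0.707
DEFAULT_COR_WIDTH = 1.0 / 3.0

SIDES = ("two", "less", "greater")


@dataclass
class TestResult:
    test_kind: str
    statistic: float
    p_value: float
    df: float | None = None
    sidedness: str = "two"
    bf10: float | None = None
    n: object = None
    extra: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p_value outside [0, 1]")
        if self.bf10 is not None and self.bf10 <= 0:
            raise ValueError("bf10 must be positive")


@dataclass
class TrendTestResult:
    t_jt: float
    n_permutations: int
    p_value: float
    direction: tuple


def _p_from_t(t: float, df: float, sidedness: str) -> float:
    if sidedness == "two":
        return float(2.0 * stats.t.sf(abs(t), df))
    if sidedness == "less":
        return float(stats.t.cdf(t, df))
    if sidedness == "greater":
        return float(stats.t.sf(t, df))
    raise ValueError(f"sidedness must be one of {SIDES}")


def jzs_bf(
    t: float,
    n1: int,
    n2: int | None = None,
    rscale: float = DEFAULT_RSCALE,
    sidedness: str = "two",
) -> float:
    """JZS Bayes factor BF10 for a one- or two-sample t statistic.

    Two-sample designs use effective n = n1*n2/(n1+n2) and df = n1+n2-2.
    ``sidedness='less'``/``'greater'`` truncates the Cauchy prior to negative/
    positive effects respectively.
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if sidedness not in SIDES:
        raise ValueError(f"sidedness must be one of {SIDES}")
    if n2 is None:
        if n1 < 2:
            raise ValueError("n must be >= 2")
        df = n1 - 1
        n_eff = float(n1)
    else:
        if n1 < 2 or n2 < 2:
            raise ValueError("both group sizes must be >= 2")
        df = n1 + n2 - 2
        n_eff = n1 * n2 / (n1 + n2)

    sqrt_n = math.sqrt(n_eff)

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(delta, 0.0, rscale)

    d_hat = t / sqrt_n  # where the likelihood peaks
    if sidedness == "two":
        cuts = sorted({0.0, d_hat})
        segments = [(-np.inf, cuts[0])] + list(zip(cuts[:-1], cuts[1:])) + [(cuts[-1], np.inf)]
        scale = 1.0
    elif sidedness == "less":
        cuts = sorted({0.0, min(d_hat, 0.0)})
        segments = [(-np.inf, cuts[0])] + list(zip(cuts[:-1], cuts[1:]))
        scale = 2.0  # renormalize the half-Cauchy
    else:
        cuts = sorted({0.0, max(d_hat, 0.0)})
        segments = list(zip(cuts[:-1], cuts[1:])) + [(cuts[-1], np.inf)]
        scale = 2.0

    marginal = 0.0
    total_err = 0.0
    for lo, hi in segments:
        if lo == hi:
            continue
        val, err = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-9, limit=300)
        marginal += val
        total_err += err
    marginal *= scale
    if marginal <= 0 or not math.isfinite(marginal):
        raise RuntimeError("JZS quadrature did not converge to a positive marginal")
    if marginal > 0 and total_err / marginal > 1e-6:
        raise RuntimeError(
            f"JZS quadrature relative error {total_err / marginal:.2e} too large"
        )
    null_like = stats.t.pdf(t, df)
    return float(marginal / null_like)


def one_sample_t_from_summary(
    mean: float,
    sd: float,
    n: int,
    mu0: float = 0.0,
    sidedness: str = "two",
    rscale: float = DEFAULT_RSCALE,
    compute_bf: bool = True,
) -> TestResult:
    """One-sample t-test from summary statistics (mean, SD, n)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    df = n - 1
    if sd == 0.0:
        if mean == mu0:
            t, p = 0.0, 1.0
        else:
            t = math.inf if mean > mu0 else -math.inf
            p = 0.0
        return TestResult("one_sample_t", t, p, df=df, sidedness=sidedness, n=n)
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = _p_from_t(t, df, sidedness)
    bf = jzs_bf(t, n, rscale=rscale, sidedness=sidedness) if compute_bf else None
    return TestResult("one_sample_t", float(t), p, df=df, sidedness=sidedness, bf10=bf, n=n)


def one_sample_t(
    values: Sequence[float],
    mu0: float = 0.0,
    sidedness: str = "two",
    rscale: float = DEFAULT_RSCALE,
    compute_bf: bool = True,
) -> TestResult:
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return one_sample_t_from_summary(
        float(x.mean()), float(x.std(ddof=1)), int(x.size),
        mu0=mu0, sidedness=sidedness, rscale=rscale, compute_bf=compute_bf,
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    sidedness: str = "two",
    rscale: float = DEFAULT_RSCALE,
    compute_bf: bool = True,
) -> TestResult:
    """Welch two-sample t-test from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both group sizes must be >= 2")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        if mean1 == mean2:
            return TestResult("welch_t", 0.0, 1.0, df=n1 + n2 - 2,
                              sidedness=sidedness, n=(n1, n2))
        t = math.inf if mean1 > mean2 else -math.inf
        return TestResult("welch_t", t, 0.0, df=n1 + n2 - 2,
                          sidedness=sidedness, n=(n1, n2))
    t = (mean1 - mean2) / math.sqrt(se2)
    denom = v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
    # denom can underflow to 0 for near-degenerate variances; cap at pooled df
    df = se2**2 / denom if denom > 0 else float(n1 + n2 - 2)
    df = min(df, n1 + n2 - 2)
    p = _p_from_t(t, df, sidedness)
    bf = jzs_bf(t, n1, n2, rscale=rscale, sidedness=sidedness) if compute_bf else None
    return TestResult("welch_t", float(t), p, df=float(df),
                      sidedness=sidedness, bf10=bf, n=(n1, n2))


def welch_t(
    a: Sequence[float],
    b: Sequence[float],
    sidedness: str = "two",
    rscale: float = DEFAULT_RSCALE,
    compute_bf: bool = True,
) -> TestResult:
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least 2 observations")
    return welch_t_from_summary(
        float(x.mean()), float(x.std(ddof=1)), int(x.size),
        float(y.mean()), float(y.std(ddof=1)), int(y.size),
        sidedness=sidedness, rscale=rscale, compute_bf=compute_bf,
    )


def paired_t(
    a: Sequence[float],
    b: Sequence[float],
    sidedness: str = "two",
    rscale: float = DEFAULT_RSCALE,
    compute_bf: bool = True,
) -> TestResult:
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    res = one_sample_t(x - y, sidedness=sidedness, rscale=rscale, compute_bf=compute_bf)
    return TestResult("paired_t", res.statistic, res.p_value, df=res.df,
                      sidedness=sidedness, bf10=res.bf10, n=int(x.size))


def _cor_bf10(r: float, n: int, width: float) -> float:
    """Default Bayes factor for a Pearson correlation, stretched-beta prior.

    The prior on rho is a Beta(1/width, 1/width) stretched to (-1, 1). The
    likelihood ratio f(r|rho)/f(r|0) uses the exact sampling density of r
    (rho-free factors cancel).
    """
    a = 1.0 / width
    lognorm = (2 * a - 1) * math.log(2.0) + special.betaln(a, a)
    log_h0 = math.log(special.hyp2f1(0.5, 0.5, n - 0.5, 0.5))

    def integrand(rho: float) -> float:
        logk = (
            (n - 1) / 2.0 * math.log1p(-rho * rho)
            - (n - 1.5) * math.log1p(-rho * r)
            + math.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0))
            + (a - 1.0) * math.log1p(-rho * rho)
            - lognorm
        )
        return math.exp(logk - log_h0)

    bf, err = integrate.quad(integrand, -1.0, 1.0, epsabs=0.0, epsrel=1e-9, limit=400)
    if bf <= 0 or not math.isfinite(bf):
        raise RuntimeError("correlation BF quadrature failed")
    return float(bf)


def pearson_cor(
    x: Sequence[float],
    y: Sequence[float],
    width: float = DEFAULT_COR_WIDTH,
    compute_bf: bool = True,
) -> TestResult:
    """Pearson correlation with two-sided t-based p and default BF10."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    n = int(xv.size)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if xv.std(ddof=1) == 0.0 or yv.std(ddof=1) == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(xv, yv)[0, 1])
    df = n - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    bf = _cor_bf10(r, n, width) if (compute_bf and abs(r) < 1.0) else None
    return TestResult("correlation", r, p, df=df, sidedness="two", bf10=bf, n=n)


def jt_statistic(groups: Sequence[Sequence[float]]) -> float:
    """Jonckheere-Terpstra statistic for groups in hypothesized increasing order."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    t = 0.0
    for i, j in itertools.combinations(range(len(arrays)), 2):
        xi = arrays[i][:, None]
        yj = arrays[j][None, :]
        t += float((xi < yj).sum()) + 0.5 * float((xi == yj).sum())
    return t


def jonckheere_terpstra(
    groups: Sequence[Sequence[float]],
    n_perm: int = 2000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TrendTestResult:
    """One-sided permutation JT test for an increasing trend across groups.

    Pass the groups in the order of the alternative hypothesis (values
    expected to increase along the sequence). For a decreasing alternative,
    reverse the group order.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least 1 observation")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = jt_statistic(arrays)
    pooled = np.concatenate(arrays)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum(sizes)[:-1]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        perm_groups = np.split(perm, bounds)
        if jt_statistic(perm_groups) >= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TrendTestResult(
        t_jt=observed,
        n_permutations=n_perm,
        p_value=p,
        direction=tuple(range(len(arrays))),
    )


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted
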
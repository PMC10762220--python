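"""Group-level inference: correlations, regressions, sign-flip
permutation tests and JZS Bayes-factor paired t-tests.

Multiple-comparison control across voxels/ROIs uses max-statistic
permutation correction (same family-wise error target as cluster-based
approaches, without image-space machinery).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import statsmodels.api as sm
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "TestResult",
    "pearson_corr",
    "linreg",
    "perm_one_sample",
    "bayes_paired_t",
    "jzs_bf10",
]

DEFAULT_JZS_SCALE = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class TestResult:
    """A single inferential result with its provenance."""

    statistic: float
    dof: float
    p_value: float
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    n_permutations: int | None = None
    seed: int | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def pearson_corr(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson correlation with two-sided p via the t transform
    (df = n - 2) and a Fisher-z 95% confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return TestResult(
        statistic=float(res.statistic),
        dof=n - 2,
        p_value=float(res.pvalue),
        estimate=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        method="pearson",
        extra={"n": n},
    )


def linreg(
    y: np.ndarray,
    x: np.ndarray,
    quadratic: bool = False,
) -> TestResult:
    """Ordinary least squares of y on x (with intercept).

    With ``quadratic=True`` and 1-D x, an x^2 column is appended and
    its t statistic exposed in ``extra['quad_t']`` / ``['quad_p']``.
    The headline statistic is the overall regression F.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if quadratic:
        if x.shape[1] != 1:
            raise ValueError("quadratic term requires a single predictor")
        x = np.column_stack([x, x[:, 0] ** 2])
    design = sm.add_constant(x, has_constant="raise")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient regression design")
    fit = sm.OLS(y, design).fit()
    slope = float(fit.params[1])
    ci = fit.conf_int()
    extra = {
        "params": np.asarray(fit.params),
        "t_values": np.asarray(fit.tvalues),
        "r_squared": float(fit.rsquared),
        "slope_p": float(fit.pvalues[1]),
    }
    if quadratic:
        extra["quad_t"] = float(fit.tvalues[-1])
        extra["quad_p"] = float(fit.pvalues[-1])
    return TestResult(
        statistic=float(fit.fvalue),
        dof=float(fit.df_resid),
        p_value=float(fit.f_pvalue),
        estimate=slope,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        method="ols" + ("+quadratic" if quadratic else ""),
        extra=extra,
    )


def _one_sample_t(values: np.ndarray) -> np.ndarray:
    """Column-wise one-sample t statistics; 0/0 maps to t = 0."""
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def perm_one_sample(
    values: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    tail: str = "greater",
) -> TestResult | list[TestResult]:
    """One-sample sign-flip permutation test on subject values.

    For 1-D input, tests mean = 0 against the given tail. For a 2-D
    (n_subjects, n_variables) input, the null distribution of the
    maximum statistic across variables supplies family-wise-corrected
    p-values (one :class:`TestResult` per variable). p-values use the
    add-one convention p = (1 + #{null >= observed}) / (1 + n_perm) and
    are invariant to rescaling of the values. Deterministic given seed.
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[:, None]
    n, m = values.shape
    if n < 5:
        raise ValueError("need n >= 5 subjects")
    if n_perm < 1000:
        raise ValueError("need n_perm >= 1000")
    if tail not in {"greater", "less", "two-sided"}:
        raise ValueError("tail must be 'greater', 'less' or 'two-sided'")

    t_obs = _one_sample_t(values)
    rng = np.random.default_rng([seed, 0x5F117])
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    sum_sq = np.sum(values**2, axis=0)  # invariant under sign flips
    mean_p = (signs @ values) / n
    var_p = (sum_sq[None, :] - n * mean_p**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = mean_p / np.sqrt(var_p / n)
        t_null = np.where(
            var_p <= 0, np.where(mean_p == 0, 0.0, np.sign(mean_p) * np.inf), t_null
        )

    if tail == "greater":
        score_obs, score_null = t_obs, t_null
    elif tail == "less":
        score_obs, score_null = -t_obs, -t_null
    else:
        score_obs, score_null = np.abs(t_obs), np.abs(t_null)
    # max-statistic correction across variables
    null_max = score_null.max(axis=1)
    p = (1 + np.sum(null_max[:, None] >= score_obs[None, :], axis=0)) / (1 + n_perm)

    results = []
    for j in range(m):
        mean_j = float(values[:, j].mean())
        se_j = float(values[:, j].std(ddof=1) / np.sqrt(n))
        tcrit = sps.t.ppf(0.975, n - 1)
        results.append(
            TestResult(
                statistic=float(t_obs[j]),
                dof=n - 1,
                p_value=float(p[j]),
                estimate=mean_j,
                ci_low=mean_j - tcrit * se_j,
                ci_high=mean_j + tcrit * se_j,
                method=f"sign-flip permutation ({tail}"
                + (", max-stat corrected)" if m > 1 else ")"),
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return results[0] if squeeze else results


def jzs_bf10(t: float, n: int, rscale: float = DEFAULT_JZS_SCALE) -> float:
    """Default JZS Bayes factor BF10 for a one-sample/paired t test.

    Effect size delta ~ Cauchy(0, rscale) under H1, i.e. delta | g ~
    N(0, g) with g ~ InvGamma(1/2, rscale^2/2); the marginal likelihood
    ratio is computed by adaptive quadrature over g.
    """
    nu = n - 1
    if nu < 2:
        raise ValueError("need n >= 3")
    log_den = -(nu + 1) / 2 * np.log1p(t**2 / nu)

    def integrand(g: float) -> float:
        shrink = 1.0 + n * g
        log_num = -0.5 * np.log(shrink) - (nu + 1) / 2 * np.log1p(t**2 / (shrink * nu))
        log_prior = (
            np.log(rscale) - 0.5 * np.log(2 * np.pi) - 1.5 * np.log(g) - rscale**2 / (2 * g)
        )
        return float(np.exp(log_num - log_den + log_prior))

    # split at the prior scale to help the quadrature near g ~ rscale^2
    v1, _ = integrate.quad(integrand, 0.0, rscale**2, limit=200)
    v2, _ = integrate.quad(integrand, rscale**2, np.inf, limit=200)
    return v1 + v2


def bayes_paired_t(
    pre: np.ndarray, post: np.ndarray, rscale: float = DEFAULT_JZS_SCALE
) -> TestResult:
    """Paired-samples t test with a default JZS Bayes factor (BF10).

    The statistic is the paired t on (pre - post); BF10 is exposed in
    ``extra['bf10']`` with the prior scale used.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be matching 1-D arrays")
    n = pre.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    diff = pre - post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences")
    t = float(diff.mean() / (sd / np.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    tcrit = sps.t.ppf(0.975, n - 1)
    se = sd / np.sqrt(n)
    return TestResult(
        statistic=t,
        dof=n - 1,
        p_value=p,
        estimate=float(diff.mean()),
        ci_low=float(diff.mean() - tcrit * se),
        ci_high=float(diff.mean() + tcrit * se),
        method="paired t + JZS Bayes factor",
        extra={"bf10": jzs_bf10(t, n, rscale), "rscale": rscale},
    )
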
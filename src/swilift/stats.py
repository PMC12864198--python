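"""Statistical machinery for the paired real-vs-virtual comparisons.

Frequentist side: z-threshold winsorisation, paired t tests with Cohen's
d_z and 95% CIs, Wilcoxon signed-rank with a Shapiro-Wilk normality gate,
a three-factor within-subjects ANOVA with partial eta squared, and simple
linear regression with R^2.

Bayesian side: default Jeffreys-Zellner-Siow (JZS) Bayes factors.  For a
paired/one-sample design the standardised effect delta gets a Cauchy(0, r)
prior (r = 0.707 by default) and

    BF10 = [ integral over delta of  nct(t; df, delta*sqrt(n)) Cauchy(delta; 0, r) ]
           / t(t; df)

evaluated by adaptive quadrature after mapping the Cauchy tails onto a
bounded interval.  For regression, the Zellner-Siow mixture-of-g prior
(g ~ InverseGamma(1/2, n r^2 / 2), r = sqrt(2)/4 for a continuous
covariate) gives

    BF10 = integral over g of (1+g)^((n-p-1)/2) (1+g(1-R^2))^(-(n-1)/2) pi(g) dg,

again by one-dimensional quadrature.  The ANOVA-term Bayes factors printed
by sampling-based packages are *not* reimplemented; a clearly-labelled BIC
approximation is provided instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

logger = logging.getLogger(__name__)

DEFAULT_WINSOR_Z = 3.29
DEFAULT_TTEST_SCALE = 0.707
DEFAULT_REGRESSION_SCALE = math.sqrt(2.0) / 4.0
_QUAD_RTOL = 1e-8


class DegenerateInputError(ValueError):
    """Input with no usable variation (all-equal differences, constant x, ...)."""


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    ci95: tuple[float, float]
    t: float
    df: int
    p: float
    d_z: float
    bf10: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    ci95: tuple[float, float]
    F: float
    df_num: int
    df_den: int
    p: float
    r_sq: float
    bf10: float
    n: int


# ---------------------------------------------------------------------------
# winsorisation


def winsorize(values, z_limit: float = DEFAULT_WINSOR_Z) -> np.ndarray:
    """Replace values more than ``z_limit`` SDs from the mean by the boundary.

    Mean and sample SD are taken from the *original* vector, in a single
    pass (no re-computation after replacement).  A zero-variance input is
    returned unchanged with a logged note.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("winsorisation needs at least 3 values")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        logger.info("winsorize: zero variance, input returned unchanged")
        return x.copy()
    lo, hi = mu - z_limit * sd, mu + z_limit * sd
    return np.clip(x, lo, hi)


# ---------------------------------------------------------------------------
# JZS Bayes factors


def jzs_bf_ttest(
    t: float, n: int, cauchy_scale: float = DEFAULT_TTEST_SCALE
) -> float:
    """JZS Bayes factor (BF10) for a one-sample / paired-difference t statistic.

    Marginal likelihood under delta ~ Cauchy(0, scale) integrated over the
    noncentral-t likelihood, divided by the central-t null likelihood.  The
    integration variable is mapped via delta = scale * tan(theta) so the
    Cauchy tails land on a bounded interval.
    """
    if not (np.isfinite(t) and n >= 2 and cauchy_scale > 0):
        raise ValueError("need finite t, n >= 2 and a positive prior scale")
    df = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(theta: float) -> float:
        delta = cauchy_scale * math.tan(theta)
        jac = cauchy_scale / math.cos(theta) ** 2
        return (
            stats.nct.pdf(t, df, delta * sqrt_n)
            * stats.cauchy.pdf(delta, 0.0, cauchy_scale)
            * jac
        )

    marginal, _ = integrate.quad(
        integrand, -math.pi / 2, math.pi / 2, epsrel=_QUAD_RTOL, epsabs=0, limit=200
    )
    return marginal / stats.t.pdf(t, df)


def jzs_bf_regression(
    r_sq: float,
    n: int,
    n_predictors: int = 1,
    scale: float = DEFAULT_REGRESSION_SCALE,
) -> float:
    """Zellner-Siow mixture-of-g Bayes factor (BF10) for a linear regression.

    Quadrature over g of the marginal-likelihood ratio against the
    intercept-only null, with g ~ InverseGamma(1/2, n*scale^2/2).  This is
    an approximate reproduction of the default continuous-covariate prior
    used by standard Bayes-factor software; with rounded R^2 inputs agree
    only to a few percent.
    """
    if not (0.0 <= r_sq < 1.0):
        raise ValueError("r_sq must lie in [0, 1)")
    if n <= n_predictors + 1:
        raise ValueError("need n > n_predictors + 1")
    p = n_predictors
    a, b = 0.5, n * scale * scale / 2.0
    log_norm = a * math.log(b) - math.lgamma(a)

    def integrand(u: float) -> float:
        g = u / (1.0 - u)  # map (0,1) -> (0, inf)
        jac = 1.0 / (1.0 - u) ** 2
        log_prior = log_norm - (a + 1.0) * math.log(g) - b / g
        log_lik = ((n - p - 1) / 2.0) * math.log1p(g) - ((n - 1) / 2.0) * math.log1p(
            g * (1.0 - r_sq)
        )
        return math.exp(log_prior + log_lik) * jac

    bf, _ = integrate.quad(integrand, 0.0, 1.0, epsrel=_QUAD_RTOL, epsabs=0, limit=200)
    return bf


def bic_bf10(bic_null: float, bic_alt: float) -> float:
    """Crude BIC-based Bayes factor approximation exp((BIC0 - BIC1)/2).

    Provided only as a rough screening hook for ANOVA terms; it is *not*
    the mixture-of-g Bayes factor that dedicated samplers compute.
    """
    return math.exp((bic_null - bic_alt) / 2.0)


# ---------------------------------------------------------------------------
# paired contrasts


def paired_t(
    x,
    y,
    cauchy_scale: float = DEFAULT_TTEST_SCALE,
    alpha: float = 0.05,
    with_bf: bool = True,
) -> PairedTestResult:
    """Two-tailed paired t test on x - y, with d_z, CI and JZS BF10.

    ``with_bf=False`` skips the Bayes-factor quadrature (bf10 = nan), for
    large simulation loops where only t and p are needed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("inputs must be finite and pairwise complete")
    d = x - y
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance of paired differences")
    mean = d.mean()
    se = sd / math.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    ci = (mean - tcrit * se, mean + tcrit * se)
    return PairedTestResult(
        mean_diff=float(mean),
        ci95=(float(ci[0]), float(ci[1])),
        t=float(t),
        df=df,
        p=float(p),
        d_z=float(mean / sd),
        bf10=float(jzs_bf_ttest(t, n, cauchy_scale)) if with_bf else math.nan,
        n=n,
    )


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns (V, two-tailed p).

    V is the sum of the ranks (average ranks for ties in |d|) of the
    positive differences, zero differences dropped first.  The p-value is
    exact for n <= 25 tie-free samples and a continuity-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise DegenerateInputError("all paired differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return v, float(res.pvalue)


def shapiro_wilk_gate(values, alpha: float = 0.05) -> tuple[bool, float, float]:
    """Shapiro-Wilk normality check used to route a paired contrast.

    Returns (use_nonparametric, W, p): True routes the contrast to the
    Wilcoxon signed-rank test, False to the paired t test.
    """
    x = np.asarray(values, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk supported for 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample has no normality to test")
    w, p = stats.shapiro(x)
    return bool(p < alpha), float(w), float(p)


# ---------------------------------------------------------------------------
# within-subjects ANOVA


def rm_anova_ratings(z_table: pd.DataFrame) -> pd.DataFrame:
    """2x2x2 within-subjects ANOVA on z-scored heaviness ratings.

    Expects trial-level rows with columns ``participant_id``, ``size``
    (small/large), ``weight`` (light/heavy), ``condition`` (real/virtual)
    and ``z_rating``.  Trials are aggregated to participant cell means;
    each effect is tested against its own participant-by-effect interaction
    stratum.  Returns a table with F, dfs, p and partial eta squared for
    the three main effects, the three two-way and the one three-way
    interaction.
    """
    from statsmodels.stats.anova import AnovaRM

    required = {"participant_id", "size", "weight", "condition", "z_rating"}
    missing = required - set(z_table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    cells = (
        z_table.groupby(["participant_id", "size", "weight", "condition"], sort=True)[
            "z_rating"
        ]
        .mean()
        .reset_index()
    )
    n_sub = cells["participant_id"].nunique()
    expected = n_sub * 8
    if len(cells) != expected:
        have = set(
            map(tuple, cells[["participant_id", "size", "weight", "condition"]].values)
        )
        missing_cells = [
            (p, s, w, c)
            for p in sorted(cells["participant_id"].unique())
            for s in ("small", "large")
            for w in ("light", "heavy")
            for c in ("real", "virtual")
            if (p, s, w, c) not in have
        ]
        raise ValueError(f"incomplete factorial design; missing cells: {missing_cells}")

    fit = AnovaRM(
        cells,
        depvar="z_rating",
        subject="participant_id",
        within=["size", "weight", "condition"],
    ).fit()
    tab = fit.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
    )
    tab = tab.reset_index().rename(columns={"index": "term"})
    tab["df_num"] = tab["df_num"].astype(int)
    tab["df_den"] = tab["df_den"].astype(int)
    tab["partial_eta_sq"] = (tab["F"] * tab["df_num"]) / (
        tab["F"] * tab["df_num"] + tab["df_den"]
    )
    return tab[["term", "F", "df_num", "df_den", "p", "partial_eta_sq"]]


# ---------------------------------------------------------------------------
# regression and power


def simple_regression(
    x, y, scale: float = DEFAULT_REGRESSION_SCALE, alpha: float = 0.05
) -> RegressionResult:
    """OLS of y on x with F, R^2, slope CI and the Zellner-Siow BF10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 4")
    if np.ptp(x) == 0:
        raise DegenerateInputError("predictor has zero variance")
    n = len(x)
    res = stats.linregress(x, y)
    r_sq = float(res.rvalue**2)
    df_den = n - 2
    F = (r_sq / 1.0) / ((1.0 - r_sq) / df_den) if r_sq < 1.0 else math.inf
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df_den)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci95=(float(ci[0]), float(ci[1])),
        F=float(F),
        df_num=1,
        df_den=df_den,
        p=float(res.pvalue),
        r_sq=r_sq,
        bf10=(
            jzs_bf_regression(r_sq, n, 1, scale) if r_sq < 1.0 - 1e-9 else math.inf
        ),
        n=n,
    )


def power_paired_t(
    n: int, d_z: float, alpha: float = 0.05, tails: str = "two"
) -> float:
    """Power of a paired t test at sample size n under noncentral t."""
    df = n - 1
    nc = d_z * math.sqrt(n)
    if tails == "two":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
    if tails == "one":
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, nc))
    raise ValueError("tails must be 'one' or 'two'")


def required_n_paired_t(
    d_z: float, alpha: float = 0.05, power: float = 0.90, tails: str = "two"
) -> int:
    """Smallest paired-design n achieving the target power (upward search from 3)."""
    if d_z <= 0:
        raise ValueError("d_z must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    n = 3
    while power_paired_t(n, d_z, alpha, tails) < power:
        n += 1
        if n > 1_000_000:
            raise RuntimeError("required n exceeds 1e6; check inputs")
    return n
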
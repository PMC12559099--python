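"""Statistical engine: through-origin regression, CI-overlap tests, RMSE and
residual-distribution summaries, and ICC(2,1) observer concordance.

All confidence intervals are two-sided 95% unless stated otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ZeroInterceptFit",
    "EstimateWithCI",
    "ResidualSummary",
    "fit_zero_intercept",
    "ci_overlap",
    "rmse_with_ci",
    "fit_residual_normal",
    "icc_2_1",
]


@dataclass(frozen=True)
class ZeroInterceptFit:
    """Result of a least-squares regression through the origin.

    slope = sum(x*y) / sum(x*x); the single estimated parameter leaves
    n - 1 residual degrees of freedom, which drive the t-based CI and
    p-value.
    """

    slope: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.slope <= self.ci_high + 1e-12):
            raise ValueError("slope must lie inside its confidence interval")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must be in [0, 1]")

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n": self.n,
        }


@dataclass(frozen=True)
class EstimateWithCI:
    value: float
    ci_low: float
    ci_high: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def to_dict(self) -> dict:
        return {"value": self.value, "ci_low": self.ci_low, "ci_high": self.ci_high}


@dataclass(frozen=True)
class ResidualSummary:
    """Accuracy summary for one estimation method: RMSE plus the mean (mu)
    and standard deviation (sigma) of a normal fit to the residuals.

    Satisfies rmse^2 = mu^2 + sigma^2 * (n - 1) / n exactly (population
    second moment decomposition).
    """

    method_label: str
    rmse: EstimateWithCI
    mu: EstimateWithCI
    sigma: EstimateWithCI
    n: int
    flags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method_label": self.method_label,
            "rmse": self.rmse.to_dict(),
            "mu": self.mu.to_dict(),
            "sigma": self.sigma.to_dict(),
            "n": self.n,
            "flags": dict(self.flags),
        }


def fit_zero_intercept(x, y) -> ZeroInterceptFit:
    """Least-squares fit of ``y = slope * x`` (no intercept) with inference.

    slope  : sum(xy) / sum(x^2)
    se     : sqrt( SSE / (n - 1) / sum(x^2) )
    95% CI : slope +/- t(0.975, n - 1) * se
    p      : two-sided test of slope == 0 on n - 1 df
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 2:
        raise ValueError("at least 2 observations are required")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    sxx = float(x @ x)
    if sxx <= 0.0:
        raise ValueError("sum(x^2) must be positive (x is all zero)")

    slope = float(x @ y) / sxx
    resid = y - slope * x
    sse = float(resid @ resid)
    dof = n - 1
    se = float(np.sqrt(max(sse, 0.0) / dof / sxx))
    tcrit = float(sps.t.ppf(0.975, dof))
    if se > 0.0:
        tstat = slope / se
        p = float(2.0 * sps.t.sf(abs(tstat), dof))
    else:
        p = 1.0 if slope == 0.0 else 0.0
    return ZeroInterceptFit(
        slope=slope,
        se=se,
        ci_low=slope - tcrit * se,
        ci_high=slope + tcrit * se,
        p_value=p,
        n=n,
    )


def ci_overlap(ci_a, ci_b) -> bool:
    """True iff two closed intervals intersect (touching endpoints count).

    Non-overlap of two 95% CIs is the significance criterion used for
    slope comparisons; the test is symmetric in its arguments.
    """
    a_lo, a_hi = sorted(map(float, ci_a))
    b_lo, b_hi = sorted(map(float, ci_b))
    return a_lo <= b_hi and b_lo <= a_hi


def rmse_with_ci(
    observed,
    estimated,
    n_boot: int = 2000,
    seed: int | None = None,
) -> EstimateWithCI:
    """Root mean square error with a percentile bootstrap 95% CI.

    Patients (paired residuals) are resampled with replacement ``n_boot``
    times; the CI is the (2.5, 97.5) percentile range of the bootstrap
    RMSE distribution. Reproducible under a fixed ``seed``.
    """
    observed = np.asarray(observed, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if observed.shape != estimated.shape or observed.ndim != 1:
        raise ValueError("observed and estimated must be 1-D of equal length")
    n = observed.size
    if n < 1:
        raise ValueError("at least one observation required")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    resid = observed - estimated
    rmse = float(np.sqrt(np.mean(resid**2)))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.sqrt(np.mean(resid[idx] ** 2, axis=1))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return EstimateWithCI(value=rmse, ci_low=float(lo), ci_high=float(hi))


def fit_residual_normal(residuals) -> tuple[EstimateWithCI, EstimateWithCI]:
    """Fit a normal distribution to residuals, with 95% CIs on mu and sigma.

    mu: sample mean, t interval. sigma: sample SD (n-1 denominator),
    chi-square interval — equivalent to MATLAB's ``normfit``.
    """
    r = np.asarray(residuals, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("at least 2 residuals required")
    n = r.size
    mu = float(np.mean(r))
    s = float(np.std(r, ddof=1))
    dof = n - 1
    tcrit = float(sps.t.ppf(0.975, dof))
    sem = s / np.sqrt(n)
    mu_ci = EstimateWithCI(mu, mu - tcrit * sem, mu + tcrit * sem)
    if s == 0.0:
        warnings.warn("zero-variance residuals: sigma CI is degenerate", stacklevel=2)
        sigma_ci = EstimateWithCI(0.0, 0.0, 0.0)
    else:
        chi_hi = float(sps.chi2.ppf(0.975, dof))
        chi_lo = float(sps.chi2.ppf(0.025, dof))
        sigma_ci = EstimateWithCI(
            s,
            float(np.sqrt(dof * s**2 / chi_hi)),
            float(np.sqrt(dof * s**2 / chi_lo)),
        )
    return mu_ci, sigma_ci


def icc_2_1(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Shrout & Fleiss convention:
        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    where MSR, MSC, MSE are the subject, rater and error mean squares of a
    two-way ANOVA on the n x k ratings matrix.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    if not np.isfinite(m).all():
        raise ValueError("ratings must not contain missing values")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_tot = float(np.sum((m - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        raise ValueError("degenerate ratings matrix (no variance)")
    return float((msr - mse) / denom)
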
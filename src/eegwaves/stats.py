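"""Study-level statistics for wave estimates.

One-sample/paired t-tests with classical 95% confidence intervals,
Benjamini–Hochberg FDR correction, Pearson correlations, the per-subject
forward/backward coupling correlation, a default-prior (JZS) one-sample Bayes
factor, and the two-sample t-test power computation used for the group
comparison of post-injection wave amounts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import integrate, stats as sps

from .wave_quant import WaveEstimate


@dataclasses.dataclass(frozen=True)
class TestResult:
    """A t-test outcome with effect estimate and 95% confidence bounds."""

    statistic: float
    df: float
    p_value: float
    estimate: float
    ci_low: float
    ci_high: float
    bf10: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")
        if self.bf10 is not None and not self.bf10 > 0:
            raise ValueError("BF10 must be positive")


@dataclasses.dataclass(frozen=True)
class FdrResult:
    """Benjamini–Hochberg step-up outcome at level ``q``."""

    pvalues: np.ndarray
    adjusted: np.ndarray
    rejected: np.ndarray
    q: float


@dataclasses.dataclass(frozen=True)
class PowerSpec:
    """Inputs of a two-sided two-sample t-test power computation."""

    mu1: float
    mu2: float
    sd: float
    n_per_group: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("sd must be positive")
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def _check_sample(values: np.ndarray, min_n: int = 2) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < min_n:
        raise ValueError(f"need a 1-D sample of >= {min_n} values")
    if not np.isfinite(values).all():
        raise ValueError("sample contains non-finite values")
    if np.ptp(values) == 0:
        raise ValueError("sample has zero variance")
    return values


def one_sample_t(values: Sequence[float], mu0: float = 0.0,
                 with_bf: bool = False) -> TestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``."""
    values = _check_sample(values)
    n = values.size
    res = sps.ttest_1samp(values, mu0)
    se = values.std(ddof=1) / np.sqrt(n)
    tcrit = sps.t.ppf(0.975, n - 1)
    mean = values.mean()
    return TestResult(
        statistic=float(res.statistic), df=float(n - 1),
        p_value=float(res.pvalue), estimate=float(mean),
        ci_low=float(mean - tcrit * se), ci_high=float(mean + tcrit * se),
        bf10=jzs_bf10(values, mu0) if with_bf else None,
    )


def paired_t(a: Sequence[float], b: Sequence[float],
             with_bf: bool = False) -> TestResult:
    """Two-sided paired t-test (a − b against zero)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0, with_bf=with_bf)


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> FdrResult:
    """Benjamini–Hochberg step-up FDR correction.

    Rejects all sorted p(i) with i <= max{k : p(k) <= k q / m}; adjusted
    p-values are the step-up monotone envelope min_{j>=i} m p(j) / j, capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    thresh = ranked <= np.arange(1, m + 1) * q / m
    k = np.flatnonzero(thresh).max() + 1 if thresh.any() else 0
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k]] = True
    return FdrResult(pvalues=p, adjusted=adjusted, rejected=rejected, q=q)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D samples of >= 3 values")
    _check_sample(x, 3), _check_sample(y, 3)
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def fw_bw_coupling(estimates: Sequence[WaveEstimate],
                   t_range_minutes: tuple[float, float] = (2.0, 5.0)
                   ) -> tuple[float, float]:
    """Window-by-window Pearson r between FW and BW dB in a time range.

    ``t_range_minutes`` selects windows with ``t_start`` in
    ``[low*60, high*60)`` seconds relative to injection.
    """
    low, high = (60.0 * m for m in t_range_minutes)
    fw = [e.fw_db for e in estimates if low <= e.t_start < high]
    bw = [e.bw_db for e in estimates if low <= e.t_start < high]
    if len(fw) < 3:
        raise ValueError("fewer than 3 windows in the coupling time range")
    return pearson(fw, bw)


def jzs_bf10(values: Sequence[float], mu0: float = 0.0,
             cauchy_scale: float = 0.707) -> float:
    """One-sample default-prior (JZS) Bayes factor for a nonzero mean.

    Cauchy prior with the given scale on the standardized effect size;
    marginal likelihoods integrated numerically.  BF10 > 1 favours a mean
    different from ``mu0``.
    """
    values = _check_sample(values)
    n = values.size
    t = float(sps.ttest_1samp(values, mu0).statistic)
    nu = n - 1
    r = cauchy_scale

    def integrand(g: float) -> float:
        # likelihood ratio vs the null in log space (stable for large |t|),
        # times the inverse-gamma(1/2, r^2/2) prior density on g
        log_lr = -0.5 * np.log1p(n * g) - (nu + 1) / 2 * (
            np.log1p(t * t / ((1 + n * g) * nu)) - np.log1p(t * t / nu))
        log_prior = np.log(r) - 0.5 * np.log(2 * np.pi) \
            - 1.5 * np.log(g) - r * r / (2 * g)
        return np.exp(log_lr + log_prior)

    lo, err_lo = integrate.quad(integrand, 0, 1, limit=200)
    hi, err_hi = integrate.quad(integrand, 1, np.inf, limit=200)
    bf = lo + hi
    err = err_lo + err_hi
    if not np.isfinite(bf) or bf <= 0 or err > max(1e-6 * bf, 1e-12):
        raise ArithmeticError("JZS marginal likelihood integration failed")
    return float(bf)


def two_sample_power(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test under a noncentral t.

    Noncentrality ``|mu1 - mu2| / sd * sqrt(n/2)`` with ``2n - 2`` degrees of
    freedom.
    """
    n = spec.n_per_group
    df = 2 * n - 2
    ncp = abs(spec.mu1 - spec.mu2) / spec.sd * np.sqrt(n * n / (2 * n))
    tcrit = sps.t.ppf(1 - spec.alpha / 2, df)
    power = (1 - sps.nct.cdf(tcrit, df, ncp)) + sps.nct.cdf(-tcrit, df, ncp)
    return float(power)
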
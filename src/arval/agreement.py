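"""Method-agreement statistics for paired measurements.

This module houses the complete statistics battery used to compare the
training game against the optical reference: mean absolute difference
(MAD, reported as mean +/- SD of the per-sample absolute differences),
RMSE, mean absolute relative difference (MARD), Spearman rank
correlation, the intra-class correlation coefficient ICC(2,1) (two-way
random effects, absolute agreement, single measure) with its F-based 95%
confidence interval, a Kolmogorov-Smirnov normality test with the
Lilliefors correction (parameters estimated from the sample, null
distribution by seeded Monte-Carlo), the non-parametric Bland-Altman
summary (median difference, limits of agreement at the 2.5th/97.5th
percentiles), and the Fisher-z sample-size computation for detecting a
correlation.

Differences are always taken as instrument-under-test minus reference
(TG - reference).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sp_stats

from .errors import DegenerateDataError, ValidationError


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")
    if a.size == 0:
        raise ValidationError("empty input")
    return a, b


def mad(a, b) -> tuple[float, float]:
    """Mean and sample SD of the absolute differences ``|a - b|``."""
    a, b = _paired(a, b)
    d = np.abs(a - b)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd


def rmse(a, b) -> float:
    """Root mean square of the differences ``a - b``."""
    a, b = _paired(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def mard(tg, ref) -> float:
    """Mean absolute relative difference ``mean(|tg - ref| / ref)``.

    Pairs with a zero reference amplitude are excluded with a warning
    reporting how many were dropped.
    """
    tg, ref = _paired(tg, ref)
    nonzero = ref != 0.0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        warnings.warn(f"mard: excluded {n_dropped} pair(s) with zero reference amplitude")
    if not nonzero.any():
        raise DegenerateDataError("all reference amplitudes are zero")
    return float(np.mean(np.abs(tg[nonzero] - ref[nonzero]) / ref[nonzero]))


def spearman(a, b) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and two-sided p."""
    a, b = _paired(a, b)
    if a.size < 3:
        raise ValidationError("spearman needs n >= 3")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise DegenerateDataError("correlation undefined for constant input")
    res = sp_stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    p: float


def icc(tg, ref, alpha: float = 0.05) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    Computed from the mean squares of the two-way ANOVA decomposition of
    the n x 2 (repetition x system) table; the confidence interval uses
    the standard F-based construction (McGraw & Wong case 2A,1) and the
    p-value the F test of the between-repetition variance,
    ``F = MSR/MSE`` on ``(n-1, (n-1)(k-1))`` degrees of freedom.
    """
    tg, ref = _paired(tg, ref)
    n = tg.size
    if n < 5:
        raise ValidationError("icc needs n >= 5 repetitions")
    x = np.stack([tg, ref], axis=1)
    k = 2
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateDataError("icc undefined: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    value = (msr - mse) / denom if denom > 0 else 0.0

    # F-based CI (McGraw & Wong, case A,1)
    r = value
    if mse == 0.0 and msc == 0.0:
        lo, hi = 1.0, 1.0
        p = 0.0
    else:
        a = (k * r) / (n * (1.0 - r)) if r < 1.0 else np.inf
        b = 1.0 + (k * r * (n - 1.0)) / (n * (1.0 - r)) if r < 1.0 else np.inf
        if np.isfinite(a) and np.isfinite(b):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = sp_stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sp_stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
        else:
            lo, hi = 1.0, 1.0
        f_stat = msr / mse if mse > 0 else np.inf
        p = float(sp_stats.f.sf(f_stat, n - 1, (n - 1) * (k - 1))) if np.isfinite(f_stat) else 0.0
    return IccResult(icc=float(value), ci_low=float(lo), ci_high=float(hi), p=float(p))


# -----------------------------------------------------------------------------
# KS normality with Lilliefors correction
# -----------------------------------------------------------------------------

def _lilliefors_stat(x: np.ndarray) -> float:
    """KS distance between the ECDF and a normal law fitted to the sample."""
    n = x.size
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sp_stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


@lru_cache(maxsize=32)
def _lilliefors_null_table(n: int, n_sim: int, seed: int) -> np.ndarray:
    """Sorted null distribution of the Lilliefors statistic at sample size n."""
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((n_sim, n))
    samples.sort(axis=1)
    means = samples.mean(axis=1, keepdims=True)
    sds = samples.std(axis=1, ddof=1, keepdims=True)
    z = (samples - means) / sds
    cdf = sp_stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf, axis=1)
    d_minus = np.max(cdf - (i - 1) / n, axis=1)
    return np.sort(np.maximum(d_plus, d_minus))


def ks_normality(x, n_sim: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with estimated parameters.

    Because mean and SD are estimated from the sample, the classical KS
    null distribution is wrong (too conservative); the p-value is instead
    read from a seeded Monte-Carlo null table of the Lilliefors statistic
    (``n_sim`` standard-normal samples of the same size, cached per size).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 5:
        raise ValidationError("ks_normality needs n >= 5")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("normality test undefined for constant input")
    d = _lilliefors_stat(x)
    null = _lilliefors_null_table(x.size, n_sim, seed)
    n_ge = null.size - np.searchsorted(null, d, side="left")
    p = (1.0 + n_ge) / (null.size + 1.0)
    return d, float(p)


# -----------------------------------------------------------------------------
# Bland-Altman (non-parametric by default)
# -----------------------------------------------------------------------------

@dataclass
class BlandAltman:
    """Plot-ready Bland-Altman summary for TG - reference differences."""

    median: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray
    parametric: bool = False

    def to_dict(self) -> dict:
        return {
            "ba_median": self.median,
            "ba_loa_low": self.loa_low,
            "ba_loa_high": self.loa_high,
            "parametric": self.parametric,
        }


def bland_altman_np(tg, ref, parametric: bool = False) -> BlandAltman:
    """Non-parametric Bland-Altman: median and percentile limits.

    The difference is TG - reference; the limits of agreement are the
    2.5th and 97.5th percentiles of the differences under the
    linear-interpolation percentile definition.  ``parametric=True``
    switches to the classical mean +/- 1.96 SD construction.
    """
    tg, ref = _paired(tg, ref)
    if tg.size < 4:
        raise ValidationError("bland_altman needs n >= 4 (percentiles meaningless below)")
    diffs = tg - ref
    means = (tg + ref) / 2.0
    if parametric:
        center = float(diffs.mean())
        half = 1.96 * float(diffs.std(ddof=1))
        return BlandAltman(center, center - half, center + half, means, diffs, True)
    lo, hi = np.percentile(diffs, [2.5, 97.5], method="linear")
    return BlandAltman(float(np.median(diffs)), float(lo), float(hi), means, diffs, False)


# -----------------------------------------------------------------------------
# Sample size for detecting a correlation (Fisher z)
# -----------------------------------------------------------------------------

def sample_size_correlation(r: float, alpha: float = 0.05, beta: float = 0.2) -> int:
    """Subjects needed to detect correlation ``r`` (two-sided Fisher z).

    ``n = ((z_{1-alpha/2} + z_{1-beta}) / atanh(r))^2 + 3`` rounded to the
    nearest integer, floored at 4 (the smallest n for which the test has
    positive degrees of freedom).  For a strong correlation (r = 0.5) at
    alpha 0.05 and power 0.8 this gives 29 subjects.
    """
    if not 0.0 < r < 1.0:
        raise ValidationError("r must be in (0, 1)")
    if not 0.0 < alpha < 1.0 or not 0.0 < beta < 1.0:
        raise ValidationError("alpha and beta must be in (0, 1)")
    z_a = sp_stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = sp_stats.norm.ppf(1.0 - beta)
    n = ((z_a + z_b) / math.atanh(r)) ** 2 + 3.0
    return max(4, int(round(n)))


# -----------------------------------------------------------------------------
# Aggregate containers used by the pipeline report
# -----------------------------------------------------------------------------

@dataclass
class TrajectoryAgreement:
    """Pooled per-channel trajectory agreement (positions mm, rotations deg)."""

    channel: str
    mad_mean: float
    mad_sd: float
    rmse: float
    n_frames: int
    n_trials: int

    def __post_init__(self) -> None:
        # RMS >= mean of absolute values (power-mean inequality)
        if self.rmse < self.mad_mean - 1e-9:
            raise ValidationError("rmse cannot be smaller than the MAD mean")

    def to_dict(self) -> dict:
        return {
            "channel": self.channel,
            "mad_mean": self.mad_mean,
            "mad_sd": self.mad_sd,
            "rmse": self.rmse,
            "n_frames": self.n_frames,
            "n_trials": self.n_trials,
        }


@dataclass
class AmplitudeAgreement:
    """Per-exercise agreement of the paired repetition amplitudes."""

    exercise: str
    n_reps: int
    mad_mean: float
    mad_sd: float
    rmse: float
    mard: float
    spearman_rho: float
    spearman_p: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_p: float
    ba_median: float
    ba_loa_low: float
    ba_loa_high: float
    ks_diff_stat: float = float("nan")
    ks_diff_p: float = float("nan")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def amplitude_agreement(
    exercise: str, tg, ref, ks_seed: int = 0
) -> AmplitudeAgreement:
    """Run the full amplitude battery for one exercise."""
    tg, ref = _paired(tg, ref)
    m_mean, m_sd = mad(tg, ref)
    rho, rho_p = spearman(tg, ref)
    icc_res = icc(tg, ref)
    ba = bland_altman_np(tg, ref)
    diffs = tg - ref
    if diffs.size >= 5 and np.ptp(diffs) > 0:
        ks_stat, ks_p = ks_normality(diffs, seed=ks_seed)
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    return AmplitudeAgreement(
        exercise=exercise,
        n_reps=int(tg.size),
        mad_mean=m_mean,
        mad_sd=m_sd,
        rmse=rmse(tg, ref),
        mard=mard(tg, ref),
        spearman_rho=rho,
        spearman_p=rho_p,
        icc=icc_res.icc,
        icc_ci_low=icc_res.ci_low,
        icc_ci_high=icc_res.ci_high,
        icc_p=icc_res.p,
        ba_median=ba.median,
        ba_loa_low=ba.loa_low,
        ba_loa_high=ba.loa_high,
        ks_diff_stat=ks_stat,
        ks_diff_p=ks_p,
    )
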
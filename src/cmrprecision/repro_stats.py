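"""Agreement, precision and sample-size statistics for paired measurements.

Implements the duplicate-measurement machinery used to characterize observer
variability: coefficient of variation (SD of paired differences over the
grand mean), the within-subject pooled SD, ICC(A,k) (two-way random effects,
absolute agreement, average measures), Bland-Altman limits of agreement,
Pearson correlation, and the paired-design sample-size formula
n = f(α, P) · σ² · 2 / δ² with f the squared sum of the normal quantiles
z_{1−α/2} + z_P (f ≈ 10.5 at α = 0.05, P = 0.90).

Standard hypothesis tests (Shapiro-Wilk, paired t, one-way ANOVA) are thin
delegations to scipy.stats; only the bespoke statistics above are
implemented here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class AgreementReport:
    n_pairs: int
    mean_all: float
    sd_diff: float
    cov_pct: float
    pooled_sd: float
    pearson_r: float
    icc: float
    bias: float
    loa_lower: float
    loa_upper: float


@dataclass
class SampleSizeSpec:
    alpha: float
    power: float
    f: float
    sigma: float
    delta: float
    n_exact: float  # pre-ceiling value of the formula
    n: int  # subjects per group


def _paired(x1, x2) -> tuple[np.ndarray, np.ndarray]:
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError(f"need two equal-length 1D vectors, got {x1.shape} and {x2.shape}")
    if x1.size < 2:
        raise ValueError(f"need >= 2 pairs, got {x1.size}")
    return x1, x2


def cov_and_pooled_sd(x1, x2, pooled_convention: str = "rms") -> tuple[float, float]:
    """Coefficient of variation (%) and within-subject pooled SD of duplicates.

    CoV = 100 · SD(x1 − x2) / mean(all 2n values), with the sample SD (n−1).
    Pooled SD uses the duplicate-measurement within-subject formula
    sqrt(Σ dᵢ² / (2n)) (``"rms"``); the alternative ``"sd-diff"`` convention
    SD(d)/√2 is exposed because published one-line definitions rarely pin
    the choice down.
    """
    x1, x2 = _paired(x1, x2)
    d = x1 - x2
    grand_mean = float(np.concatenate([x1, x2]).mean())
    if grand_mean == 0:
        raise ValueError("grand mean is zero; CoV undefined")
    cov = 100.0 * float(np.std(d, ddof=1)) / grand_mean
    if pooled_convention == "rms":
        pooled = math.sqrt(float(np.sum(d**2)) / (2.0 * d.size))
    elif pooled_convention == "sd-diff":
        pooled = float(np.std(d, ddof=1)) / math.sqrt(2.0)
    else:
        raise ValueError(f"pooled_convention must be 'rms' or 'sd-diff', got {pooled_convention!r}")
    return cov, pooled


def icc_2k(data: np.ndarray) -> float:
    """ICC(A,k): two-way random effects, absolute agreement, average measures.

    ``data`` is subjects × raters with no missing cells. From the two-way
    ANOVA mean squares (MSR rows/subjects, MSC columns/raters, MSE error):

        ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n)

    Identical raters give 1; a constant between-rater offset is penalized
    (absolute agreement, not consistency).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"data must be subjects × raters, got shape {data.shape}")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 raters, got {n}×{k}")
    if np.isnan(data).any():
        raise ValueError("missing cells are not supported")
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance; ICC undefined")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (msc - mse) / n))


def bland_altman(x1, x2) -> tuple[float, tuple[float, float]]:
    """Bias and 95% limits of agreement: bias ± 1.96·SD(difference)."""
    x1, x2 = _paired(x1, x2)
    d = x1 - x2
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def pearson_r(x1, x2) -> float:
    x1, x2 = _paired(x1, x2)
    return float(sps.pearsonr(x1, x2).statistic)


def agreement_report(x1, x2, pooled_convention: str = "rms") -> AgreementReport:
    """Full paired-observer agreement summary for one metric."""
    x1, x2 = _paired(x1, x2)
    cov, pooled = cov_and_pooled_sd(x1, x2, pooled_convention)
    bias, (lo, hi) = bland_altman(x1, x2)
    d = x1 - x2
    identical = np.allclose(x1, x2)
    return AgreementReport(
        n_pairs=int(x1.size),
        mean_all=float(np.concatenate([x1, x2]).mean()),
        sd_diff=float(np.std(d, ddof=1)),
        cov_pct=cov,
        pooled_sd=pooled,
        pearson_r=1.0 if identical else pearson_r(x1, x2),
        icc=1.0 if identical else icc_2k(np.column_stack([x1, x2])),
        bias=bias,
        loa_lower=lo,
        loa_upper=hi,
    )


# -- sample size ---------------------------------------------------------------


def power_factor(alpha: float = 0.05, power: float = 0.90) -> float:
    """f(α, P) = (z_{1−α/2} + z_P)², the paired-design power factor.

    At α = 0.05 and P = 0.90 this is 10.51, the tabulated 10.5.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError(f"alpha and power must be in (0, 1), got {alpha}, {power}")
    return float((sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)) ** 2)


def sample_size(sigma: float, delta: float, alpha: float = 0.05,
                power: float = 0.90, f: float | None = None) -> SampleSizeSpec:
    """Subjects per group to detect a difference δ given pooled SD σ.

    n = ceil( f(α, P) · σ² · 2 / δ² ). By default f is computed exactly from
    normal quantiles; pass ``f`` explicitly (e.g. the tabulated 10.5) to
    reproduce published round-number examples. Halving σ quarters the
    pre-ceiling n — precision buys sample size quadratically.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if delta <= 0:
        raise ValueError(f"delta must be positive, got {delta}")
    f_used = power_factor(alpha, power) if f is None else float(f)
    n_exact = f_used * sigma**2 * 2.0 / delta**2
    return SampleSizeSpec(
        alpha=alpha, power=power, f=f_used, sigma=sigma, delta=delta,
        n_exact=float(n_exact), n=max(1, math.ceil(n_exact)),
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: min(1, m·p)."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError(f"p-values must lie in [0, 1], got {p}")
    m = p.size if m is None else int(m)
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return np.minimum(1.0, m * p)


# -- delegated standard tests --------------------------------------------------


def shapiro_wilk(x) -> tuple[float, float]:
    """Normality check, delegated to scipy. Returns (statistic, p)."""
    res = sps.shapiro(np.asarray(x, dtype=float))
    return float(res.statistic), float(res.pvalue)


def paired_t(x1, x2) -> tuple[float, float]:
    """Paired t-test, delegated to scipy. Returns (statistic, p)."""
    x1, x2 = _paired(x1, x2)
    res = sps.ttest_rel(x1, x2)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA across groups, delegated to scipy. Returns (F, p)."""
    res = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)
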
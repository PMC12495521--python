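"""Method-agreement statistics for cross-platform and cross-sampling checks.

Two measurement routes for the same quantity (two DIA platforms, or a full
section versus a subsample) are compared with the standard reproducibility
battery: Spearman rank correlation, the two-way mixed-effects single-rater
consistency intraclass correlation ICC(3,1), Lin's concordance correlation
coefficient with a percentile-bootstrap CI, Bland-Altman bias and limits of
agreement, a paired Wilcoxon signed-rank test, and a Lilliefors-corrected
Kolmogorov-Smirnov normality check.

Lin's CCC uses population (1/n) moments, matching the original estimator;
ICC(3,1) is the consistency form, invariant to a fixed shift between the
two raters.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "spearman",
    "icc31",
    "lin_ccc",
    "bland_altman",
    "wilcoxon_signed_rank",
    "ks_normality",
    "AgreementReport",
    "compute_agreement",
]


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    return x, y


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; 2-sided p."""
    x, y = _paired(x, y, 3)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc31(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(3,1): two-way mixed-effects, single rater, consistency form.

    Computed from the two-way ANOVA mean squares with k = 2 raters,
    ``(MS_subjects − MS_error) / (MS_subjects + (k−1)·MS_error)``, with the
    usual F-based confidence interval.
    """
    x, y = _paired(x, y, 5)
    n, k = x.size, 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_subj + (k - 1) * ms_err == 0:
        raise ValueError("zero between-subject variance: ICC undefined")
    icc = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
    if ms_err == 0:
        return float(icc), (float(icc), float(icc))
    f_obs = ms_subj / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return float(icc), (float(lo), float(hi))


def _ccc_point(x: np.ndarray, y: np.ndarray) -> float:
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    sx2 = x.var()  # population (1/n) moments, per Lin's original estimator
    sy2 = y.var()
    denom = sx2 + sy2 + (x.mean() - y.mean()) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both vectors constant")
    return float(2.0 * sxy / denom)


def lin_ccc(
    x,
    y,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Lin's concordance correlation with a percentile-bootstrap 95% CI.

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²), penalizing both decorrelation
    and location/scale shift.  The CI resamples pairs ``n_boot`` times.
    """
    x, y = _paired(x, y, 3)
    ccc = _ccc_point(x, y)
    rng = rng or np.random.default_rng(0)
    n = x.size
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            reps[b] = _ccc_point(x[idx], y[idx])
        except ValueError:
            reps[b] = np.nan
    lo, hi = np.nanpercentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return ccc, (float(lo), float(hi))


def bland_altman(x, y) -> dict[str, float]:
    """Bias, ±1.96·sd limits of agreement, and the trend of differences.

    Differences are x − y; the slope regresses differences on pair means,
    exposing magnitude-dependent bias.
    """
    x, y = _paired(x, y, 3)
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    mean_xy = (x + y) / 2.0
    if np.ptp(mean_xy) > 0:
        slope = float(np.polyfit(mean_xy, d, 1)[0])
    else:
        slope = 0.0
    return {
        "bias": bias,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
        "slope": slope,
    }


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; the exact null distribution is used for
    n ≤ 25 (when free of rank ties), the tie-corrected normal
    approximation otherwise.
    """
    x, y = _paired(x, y, 1)
    d = x - y
    d = d[d != 0]
    if d.size < 5:
        raise ValueError("fewer than 5 non-zero differences")
    ranks = stats.rankdata(np.abs(d))
    has_ties = np.unique(ranks).size < ranks.size
    if d.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return float(res.pvalue)


def ks_normality(x) -> float:
    """Lilliefors-corrected Kolmogorov-Smirnov normality p-value.

    The correction accounts for estimating the normal mean and sd from
    the sample.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("need at least 8 observations")
    if np.ptp(x) == 0:
        raise ValueError("normality test undefined for a constant vector")
    _, p = lilliefors(x, dist="norm")
    return float(p)


@dataclass
class AgreementReport:
    """The full battery for one paired comparison."""

    n: int
    spearman_rho: float
    spearman_p: float
    icc31: float
    icc31_ci: tuple[float, float]
    ccc: float
    ccc_ci: tuple[float, float]
    bias: float
    loa_lower: float
    loa_upper: float
    ba_slope: float
    wilcoxon_p: float

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        d["icc31_lo"], d["icc31_hi"] = d.pop("icc31_ci")
        d["ccc_lo"], d["ccc_hi"] = d.pop("ccc_ci")
        return d


def compute_agreement(
    x, y, n_boot: int = 1000, rng: np.random.Generator | None = None
) -> AgreementReport:
    """Run the whole battery on one paired comparison."""
    x, y = _paired(x, y, 5)
    rho, rho_p = spearman(x, y)
    icc, icc_ci = icc31(x, y)
    ccc, ccc_ci = lin_ccc(x, y, n_boot=n_boot, rng=rng)
    ba = bland_altman(x, y)
    if np.any(x != y):
        try:
            wp = wilcoxon_signed_rank(x, y)
        except ValueError:
            wp = float("nan")  # too few non-zero differences
    else:
        wp = 1.0  # identical measurements: no paired shift to test
    return AgreementReport(
        n=int(x.size),
        spearman_rho=rho,
        spearman_p=rho_p,
        icc31=icc,
        icc31_ci=icc_ci,
        ccc=ccc,
        ccc_ci=ccc_ci,
        bias=ba["bias"],
        loa_lower=ba["loa_lower"],
        loa_upper=ba["loa_upper"],
        ba_slope=ba["slope"],
        wilcoxon_p=wp,
    )
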
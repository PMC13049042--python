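"""Inter-observer reliability and agreement statistics.

All statistics operate on a subjects × observers :class:`MeasurementMatrix`
of one indicator in one phase:

* two-way random-effects absolute-agreement intraclass correlation, both the
  average-measure ICC(A,k) and single-measure ICC(A,1), with F-based 95%
  confidence intervals (McGraw–Wong family) and the subject-effect F test;
* Lin's concordance correlation coefficient (pairwise) and the overall CCC
  for R observers, using population (1/n) moments;
* the standard error of measurement SEM = sigma * sqrt(1 - ICC);
* Bland–Altman mean difference, 1.96-SD limits of agreement, and the
  percentage of paired differences falling within them;
* the paired pre/post t-test on observer-averaged values.

Conventions worth stating once: CCC/OCCC moments use the population (1/n)
form, matching the overall-CCC formula's definition; Bland–Altman SDs use the
sample (n-1) convention, standard in that literature.  Negative ICC or
variance-component estimates are reported unaltered with a quality flag,
never silently truncated to zero.  No multiple-testing correction is applied
across indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class AgreementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class MeasurementMatrix:
    """n_subjects × k_observers values of one indicator in one phase."""

    values: np.ndarray
    indicator: str = ""
    phase: str = ""
    subject_ids: list | None = None
    observer_ids: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise AgreementError("values must be a 2-D subjects x observers array")
        n, k = self.values.shape
        if self.subject_ids is None:
            self.subject_ids = list(range(n))
        if self.observer_ids is None:
            self.observer_ids = list(range(1, k + 1))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_observers(self) -> int:
        return self.values.shape[1]

    def drop_incomplete(self) -> tuple["MeasurementMatrix", int]:
        """Listwise-delete subjects with any missing (NaN) cell.

        Returns the complete matrix and the number of dropped subjects; the
        count is also recorded in ``meta["n_dropped"]``.
        """
        keep = ~np.isnan(self.values).any(axis=1)
        dropped = int((~keep).sum())
        out = MeasurementMatrix(
            self.values[keep],
            indicator=self.indicator, phase=self.phase,
            subject_ids=[s for s, k_ in zip(self.subject_ids, keep) if k_],
            observer_ids=list(self.observer_ids),
            meta={**self.meta, "n_dropped": dropped},
        )
        return out, dropped


def _as_matrix(m) -> np.ndarray:
    vals = m.values if isinstance(m, MeasurementMatrix) else np.asarray(m, dtype=np.float64)
    if vals.ndim != 2:
        raise AgreementError("expected a 2-D subjects x observers array")
    n, k = vals.shape
    if n < 2 or k < 2:
        raise AgreementError(f"need at least 2 subjects and 2 observers, got {n} x {k}")
    if np.isnan(vals).any():
        raise AgreementError("matrix contains missing cells; drop_incomplete() first")
    return vals


# ---------------------------------------------------------------------------
# Two-way ANOVA and ICC
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_s: float
    sigma2_r: float
    sigma2_e: float
    ms_subjects: float
    ms_observers: float
    ms_error: float
    df_subjects: int
    df_observers: int
    df_error: int
    n: int
    k: int
    negative_components: bool = False
    zero_variance: bool = False


def anova_components(m) -> VarianceComponents:
    """Balanced two-way (subjects × observers) ANOVA decomposition with
    method-of-moments variance components:
    sigma2_e = MS_error, sigma2_r = (MS_observers - MS_error)/n,
    sigma2_s = (MS_subjects - MS_error)/k.

    Negative method-of-moments estimates are reported unaltered and flagged.
    """
    vals = _as_matrix(m)
    n, k = vals.shape
    grand = vals.mean()
    row = vals.mean(axis=1)
    col = vals.mean(axis=0)
    ss_s = k * float(((row - grand) ** 2).sum())
    ss_r = n * float(((col - grand) ** 2).sum())
    resid = vals - row[:, None] - col[None, :] + grand
    ss_e = float((resid ** 2).sum())
    df_s, df_r, df_e = n - 1, k - 1, (n - 1) * (k - 1)
    ms_s, ms_r, ms_e = ss_s / df_s, ss_r / df_r, ss_e / df_e
    if ss_s + ss_r + ss_e == 0.0:
        return VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                                  df_s, df_r, df_e, n, k, zero_variance=True)
    s2_e = ms_e
    s2_r = (ms_r - ms_e) / n
    s2_s = (ms_s - ms_e) / k
    return VarianceComponents(s2_s, s2_r, s2_e, ms_s, ms_r, ms_e,
                              df_s, df_r, df_e, n, k,
                              negative_components=(s2_s < 0 or s2_r < 0))


def theoretical_icc_avg(sigma2_s: float, sigma2_r: float, sigma2_e: float, k: int) -> float:
    """ICC(A,k) evaluated at known variance components:
    sigma2_s / (sigma2_s + sigma2_r/k + sigma2_e/k)."""
    return sigma2_s / (sigma2_s + sigma2_r / k + sigma2_e / k)


def theoretical_icc_single(sigma2_s: float, sigma2_r: float, sigma2_e: float) -> float:
    """ICC(A,1) at known components: sigma2_s / (sigma2_s + sigma2_r + sigma2_e)."""
    return sigma2_s / (sigma2_s + sigma2_r + sigma2_e)


@dataclass
class ICCResult:
    icc_avg: float
    icc_single: float
    ci95_avg: tuple[float, float]
    ci95_single: tuple[float, float]
    p_value: float
    n: int
    k: int
    components: VarianceComponents | None = None
    degenerate: bool = False


def icc_absolute(m, ci_level: float = 0.95) -> ICCResult:
    """Two-way random-effects absolute-agreement ICC.

    Point estimates come from the ANOVA mean squares,
    ``ICC(A,k) = (MS_s - MS_e) / (MS_s + (MS_r - MS_e)/n)`` and its
    single-measure analogue; these are algebraically identical to plugging
    the method-of-moments components into the variance-ratio definition.
    Confidence intervals use the F-based absolute-agreement method with a
    Satterthwaite denominator df; the p-value is the subject-effect F test
    (H0: ICC = 0).
    """
    comp = anova_components(m)
    n, k = comp.n, comp.k
    ms_s, ms_r, ms_e = comp.ms_subjects, comp.ms_observers, comp.ms_error
    if comp.zero_variance:
        return ICCResult(math.nan, math.nan, (math.nan, math.nan), (math.nan, math.nan),
                         math.nan, n, k, comp, degenerate=True)

    denom_avg = ms_s + (ms_r - ms_e) / n
    denom_single = ms_s + (k - 1) * ms_e + k * (ms_r - ms_e) / n
    icc_avg = (ms_s - ms_e) / denom_avg if denom_avg != 0 else math.nan
    icc_single = (ms_s - ms_e) / denom_single if denom_single != 0 else math.nan

    if ms_e > 0:
        f_stat = ms_s / ms_e
        p = float(stats.f.sf(f_stat, comp.df_subjects, comp.df_error))
    else:
        p = 0.0

    alpha = 1.0 - ci_level
    degenerate = False
    noise_floor = 1e-12 * max(ms_s, 1.0)
    if ms_e <= noise_floor and ms_r <= noise_floor:
        # columns identical up to rounding: perfect agreement, interval collapses
        ci1 = (icc_single, icc_single)
        cik = (icc_avg, icc_avg)
        degenerate = True
    elif not math.isfinite(icc_single) or icc_single >= 1.0:
        ci1 = (math.nan, math.nan)
        cik = (math.nan, math.nan)
        degenerate = True
    else:
        a = k * icc_single / (n * (1.0 - icc_single))
        b = 1.0 + k * icc_single * (n - 1.0) / (n * (1.0 - icc_single))
        v = (a * ms_r + b * ms_e) ** 2 / (
            (a * ms_r) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (ms_s - f_l * ms_e) / (f_l * (k * ms_r + (k * n - k - n) * ms_e) + n * ms_s)
        hi1 = n * (f_u * ms_s - ms_e) / (k * ms_r + (k * n - k - n) * ms_e + n * f_u * ms_s)
        ci1 = (float(lo1), float(hi1))
        # Spearman-Brown step-up to the average-measure interval
        cik = (float(lo1 * k / (1 + (k - 1) * lo1)), float(hi1 * k / (1 + (k - 1) * hi1)))

    return ICCResult(float(icc_avg), float(icc_single), cik, ci1, p, n, k, comp,
                     degenerate=degenerate)


# ---------------------------------------------------------------------------
# Concordance correlation
# ---------------------------------------------------------------------------

def ccc_pair(x, y) -> float:
    """Lin's concordance correlation coefficient for two observers:
    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
    population (1/n) moments.  Returns NaN when both variances vanish."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise AgreementError("ccc_pair needs two equal-length vectors of length >= 2")
    mx, my = x.mean(), y.mean()
    vx = float(((x - mx) ** 2).mean())
    vy = float(((y - my) ** 2).mean())
    cov = float(((x - mx) * (y - my)).mean())
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        return math.nan
    return 2.0 * cov / denom


@dataclass
class CCCResult:
    overall_ccc: float
    pairwise: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    covariances: np.ndarray
    n: int
    k: int


def occc(m) -> CCCResult:
    """Overall concordance correlation coefficient across R observers:

    ``2 * sum_{r<s} cov_rs / [(R-1) * sum_r var_r + sum_{r<s} (mu_r - mu_s)^2]``

    with population (1/n) moments.  For R = 2 this reduces exactly to Lin's
    pairwise CCC; in general it is the covariance-denominator-weighted average
    of the pairwise CCCs and therefore lies within their span.
    """
    vals = _as_matrix(m)
    n, k = vals.shape
    mu = vals.mean(axis=0)
    centered = vals - mu
    cov = (centered.T @ centered) / n  # population moments
    var = np.diag(cov).copy()

    num = 0.0
    den = (k - 1) * float(var.sum())
    for r in range(k - 1):
        for s in range(r + 1, k):
            num += cov[r, s]
            den += (mu[r] - mu[s]) ** 2
    overall = math.nan if den == 0.0 else 2.0 * num / den

    pairwise = np.full((k, k), np.nan)
    np.fill_diagonal(pairwise, 1.0)
    for r in range(k - 1):
        for s in range(r + 1, k):
            pairwise[r, s] = pairwise[s, r] = ccc_pair(vals[:, r], vals[:, s])
    return CCCResult(overall_ccc=float(overall), pairwise=pairwise, means=mu,
                     variances=var, covariances=cov, n=n, k=k)


# ---------------------------------------------------------------------------
# SEM, Bland–Altman, paired t
# ---------------------------------------------------------------------------

@dataclass
class SEMResult:
    sem: float
    sigma_used: float
    icc_used: float
    formula: str = "sem = sigma * sqrt(1 - ICC(A,k)); sigma = pooled SD of all n*k values"


def sem(m, icc: ICCResult | float) -> SEMResult:
    """Standard error of measurement, ``sigma * sqrt(1 - ICC)``.

    ``sigma`` is the pooled sample SD over all subjects × observers values of
    the indicator; the ICC is the average-measure ICC(A,k) unless a bare
    float is passed.
    """
    vals = _as_matrix(m)
    icc_val = icc.icc_avg if isinstance(icc, ICCResult) else float(icc)
    if icc_val > 1:
        raise AgreementError("ICC above 1 makes SEM undefined")
    sigma = float(vals.std(ddof=1))
    return SEMResult(sem=sigma * math.sqrt(1.0 - icc_val), sigma_used=sigma,
                     icc_used=icc_val)


@dataclass
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within: float
    n_pairs: int
    order: str = "first minus second"


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement between two observers.

    Differences are ``x - y`` (first argument minus second, recorded in the
    result); limits of agreement are mean ± 1.96 × sample SD (n−1), the 1.96
    used literally.  ``pct_within`` counts differences on or inside the
    limits.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise AgreementError("bland_altman needs two equal-length vectors of length >= 2")
    mask = ~(np.isnan(x) | np.isnan(y))  # pairwise deletion
    d = (x - y)[mask]
    if len(d) < 2:
        raise AgreementError("fewer than 2 complete pairs")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi)) * 100.0)
    return BlandAltmanResult(mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi,
                             pct_within=within, n_pairs=int(len(d)))


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_pre: float
    sd_pre: float
    mean_post: float
    sd_post: float
    mean_difference: float
    flagged: bool = False


def paired_t(pre, post) -> PairedTResult:
    """Classical paired t-test (two-sided) of pre vs post values.

    Intended use: per-subject values averaged across observers.  Identical
    inputs give t = 0, p = 1; a constant nonzero difference (zero difference
    variance) is undefined and returned flagged.
    """
    pre = np.asarray(pre, dtype=np.float64)
    post = np.asarray(post, dtype=np.float64)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise AgreementError("paired_t needs two equal-length vectors of length >= 2")
    d = pre - post
    n = len(d)
    sd_d = float(d.std(ddof=1))
    base = dict(df=n - 1, mean_pre=float(pre.mean()), sd_pre=float(pre.std(ddof=1)),
                mean_post=float(post.mean()), sd_post=float(post.std(ddof=1)),
                mean_difference=float(d.mean()))
    if sd_d == 0.0:
        if d.mean() == 0.0:
            return PairedTResult(t=0.0, p=1.0, **base)
        return PairedTResult(t=math.nan, p=math.nan, flagged=True, **base)
    t = float(d.mean() / (sd_d / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return PairedTResult(t=t, p=p, **base)
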
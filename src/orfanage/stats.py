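"""Self-contained statistics for the deletion/fitness/recruitment analyses:
Pearson correlation with t-based significance, salinity-stratified
enrichment correlations, two-sample t-tests with fold difference, and exact
binomial proportion estimation.

The Student-t tail probability is computed in-package via the regularized
incomplete beta function (continued-fraction evaluation), so the module's
behaviour does not depend on any external statistics routine; external
implementations serve only as cross-checks in the test suite.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta_dist


class ZeroVarianceError(ValueError):
    """Raised when a correlation or test statistic is undefined because an
    input vector has no variance."""


# ---------------------------------------------------------------------------
# Regularized incomplete beta and the t distribution

def _betacf(a: float, b: float, x: float, max_iter: int = 300, eps: float = 3e-15) -> float:
    """Continued fraction for the incomplete beta function (modified Lentz)."""
    tiny = 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1.0 / d
    h = d
    for m in range(1, max_iter + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1.0 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < eps:
            return h
    raise RuntimeError("incomplete beta continued fraction did not converge")


def regularized_incomplete_beta(a: float, b: float, x: float) -> float:
    """I_x(a, b) for a, b > 0 and x in [0, 1]."""
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    if not 0.0 <= x <= 1.0:
        raise ValueError("x must lie in [0, 1]")
    if x == 0.0 or x == 1.0:
        return x
    ln_front = (
        math.lgamma(a + b)
        - math.lgamma(a)
        - math.lgamma(b)
        + a * math.log(x)
        + b * math.log1p(-x)
    )
    front = math.exp(ln_front)
    if x < (a + 1.0) / (a + b + 2.0):
        return front * _betacf(a, b, x) / a
    return 1.0 - front * _betacf(b, a, 1.0 - x) / b


def t_two_sided_p(t: float, df: float) -> float:
    """Two-sided tail probability of Student's t with ``df`` degrees of
    freedom: ``I_{df/(df+t^2)}(df/2, 1/2)``."""
    if df <= 0:
        raise ValueError("df must be positive")
    if math.isinf(t):
        return 0.0
    return regularized_incomplete_beta(df / 2.0, 0.5, df / (df + t * t))


# ---------------------------------------------------------------------------
# Pearson correlation

@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    r_squared: float
    df: int
    t_statistic: float
    p_two_sided: float


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with t-based two-sided significance.

    ``t = r * sqrt((n - 2) / (1 - r^2))``; p from Student's t with n - 2 df.
    Raises :class:`ZeroVarianceError` when either vector is constant.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    xm = x - x.mean()
    ym = y - y.mean()
    sxx = float(xm @ xm)
    syy = float(ym @ ym)
    if sxx == 0.0 or syy == 0.0:
        raise ZeroVarianceError("undefined correlation: an input has zero variance")
    r = float(xm @ ym) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        t, p = math.inf if r > 0 else -math.inf, 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = t_two_sided_p(t, df)
    return CorrelationResult(n=n, r=r, r_squared=r * r, df=df, t_statistic=t, p_two_sided=p)


# ---------------------------------------------------------------------------
# Salinity-stratified enrichment

@dataclass
class EnrichmentResult:
    """Per-salinity-class correlation between database size and hit count."""

    salinity_class: str
    n_libraries: int
    result: CorrelationResult | None = None
    notice: str | None = None
    influential: list[dict] = field(default_factory=list)


def salinity_enrichment(
    meta: pd.DataFrame,
    hit_counts,
    leave_one_out: bool = False,
    alpha: float = 0.05,
    on_degenerate: str = "raise",
) -> dict[str, EnrichmentResult]:
    """Correlate database size with per-library hit counts within each
    salinity class.

    ``meta`` needs columns ``library_id``, ``db_size_nt``, ``salinity_class``;
    ``hit_counts`` maps library_id to a hit count (missing libraries count
    0).  Classes with fewer than 3 libraries are skipped with a notice.
    With ``leave_one_out``, libraries whose removal flips significance at
    ``alpha`` are flagged (mirroring single-query-driven correlations).
    ``on_degenerate``: "raise" surfaces :class:`ZeroVarianceError` for a
    constant-count class, "notice" records it instead.
    """
    counts = dict(hit_counts)
    out: dict[str, EnrichmentResult] = {}
    for cls, sub in meta.groupby("salinity_class", sort=True):
        libs = list(sub["library_id"])
        res = EnrichmentResult(salinity_class=str(cls), n_libraries=len(libs))
        if len(libs) < 3:
            res.notice = f"skipped: only {len(libs)} libraries (need >= 3)"
            out[str(cls)] = res
            continue
        x = sub["db_size_nt"].to_numpy(dtype=np.float64)
        y = np.array([float(counts.get(lib, 0)) for lib in libs])
        try:
            res.result = pearson(x, y)
        except ZeroVarianceError:
            if on_degenerate == "raise":
                raise
            res.notice = "undefined correlation: zero variance within class"
            out[str(cls)] = res
            continue
        if leave_one_out and len(libs) >= 4:
            p_full = res.result.p_two_sided
            for i, lib in enumerate(libs):
                xi = np.delete(x, i)
                yi = np.delete(y, i)
                try:
                    p_wo = pearson(xi, yi).p_two_sided
                except ZeroVarianceError:
                    p_wo = float("nan")
                flips = (p_full < alpha) != (p_wo < alpha)
                if flips or math.isnan(p_wo):
                    res.influential.append(
                        {"library_id": lib, "p_with": p_full, "p_without": p_wo}
                    )
        out[str(cls)] = res
    return out


# ---------------------------------------------------------------------------
# Two-sample t-test and fold difference

@dataclass(frozen=True)
class TTestResult:
    n1: int
    n2: int
    mean1: float
    mean2: float
    pooled_sd: float
    t_statistic: float
    df: float
    p_two_sided: float
    fold_difference: float


def two_sample_t(a, b, mode: str = "pooled") -> TTestResult:
    """Two-sample t-test (pooled Student by default, Welch optional) with the
    fold difference of group means reported alongside.

    ``fold_difference`` is larger mean / smaller mean (>= 1).  Degenerate
    input (zero variance in both groups and equal means give t = 0; zero
    variance in both groups with *any* configuration raises, since the
    statistic is undefined).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    m1, m2 = float(a.mean()), float(b.mean())
    v1 = float(a.var(ddof=1))
    v2 = float(b.var(ddof=1))
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            # identical constant samples: no evidence of a difference
            fold = 1.0
            sp = 0.0
            return TTestResult(n1, n2, m1, m2, sp, 0.0, n1 + n2 - 2, 1.0, fold)
        raise ZeroVarianceError("t statistic undefined: zero variance in both groups")
    if mode == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        sp = math.sqrt(sp2)
        se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
        df: float = n1 + n2 - 2
    elif mode == "welch":
        se2 = v1 / n1 + v2 / n2
        se = math.sqrt(se2)
        df = se2 * se2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        sp = math.sqrt((v1 + v2) / 2.0)
    else:
        raise ValueError("mode must be 'pooled' or 'welch'")
    t = (m1 - m2) / se
    p = t_two_sided_p(t, df)
    if m1 == 0.0 or m2 == 0.0:
        fold = math.inf if (m1 != m2) else 1.0
    else:
        fold = max(m1 / m2, m2 / m1)
    return TTestResult(n1, n2, m1, m2, sp, t, df, p, fold)


# ---------------------------------------------------------------------------
# Plaque genotype frequency

@dataclass(frozen=True)
class ProportionResult:
    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95


def genotype_frequency(k: int, n: int, confidence: float = 0.95) -> ProportionResult:
    """Point estimate ``k / n`` with an exact (Clopper-Pearson) binomial
    confidence interval; used for variant-plaque genotyping proportions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(_beta_dist.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(_beta_dist.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return ProportionResult(k=k, n=n, estimate=k / n, ci_low=lo, ci_high=hi, confidence=confidence)
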
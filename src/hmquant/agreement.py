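"""Inter-/intra-rater agreement statistics implemented from their formulas.

Estimates are computed directly from ANOVA mean squares (ICC), observed vs
chance agreement (Fleiss and Cohen kappa), average ranks (Spearman) and the
Pearson chi-square statistic; only distribution quantiles come from
:mod:`scipy.stats`.  Interval estimates: ICC uses the F-distribution method
for the two-way random-effects, absolute-agreement, single-rater form;
Fleiss kappa uses a seeded subject-resampling bootstrap (the asymptotic
variance is valid only under the null hypothesis of no agreement).
"""

from __future__ import annotations

from typing import NamedTuple, Tuple

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DegenerateTableError, ValidationError

__all__ = [
    "ICCResult",
    "FleissResult",
    "CohenResult",
    "SpearmanResult",
    "ChiSquareResult",
    "icc",
    "fleiss_kappa",
    "cohens_kappa",
    "spearman_rho",
    "chi_square_2x2",
    "mcnemar",
    "interpret",
]

_EPS = 1e-12


def _as_matrix(matrix, name: str) -> np.ndarray:
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValidationError(f"{name} must be 2D (subjects x raters), got ndim={m.ndim}")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValidationError(f"{name} needs >= 2 subjects and >= 2 raters, got {m.shape}")
    return m


class ICCResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float


class FleissResult(NamedTuple):
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


class CohenResult(NamedTuple):
    estimate: float
    degenerate: bool = False


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    undefined: bool = False


class ChiSquareResult(NamedTuple):
    statistic: float
    p: float


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _mean_squares(m: np.ndarray) -> Tuple[float, float, float]:
    """Two-way crossed ANOVA mean squares (rows = subjects, cols = raters)."""
    n, k = m.shape
    gm = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - gm) ** 2) / (n - 1)
    msc = n * np.sum((col_means - gm) ** 2) / (k - 1)
    resid = m - row_means[:, None] - col_means[None, :] + gm
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc(matrix, form: str = "icc2", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation with a 95% F-distribution confidence interval.

    Forms: ``icc1`` one-way random; ``icc2`` two-way random, absolute
    agreement, single rater (default); ``icc3`` two-way mixed, consistency,
    single rater.
    """
    m = _as_matrix(matrix, "ratings").astype(float)
    n, k = m.shape
    msr, msc, mse = _mean_squares(m)
    if msr < _EPS and msc < _EPS and mse < _EPS:
        raise DegenerateInputError("zero total variance: ICC undefined")

    if form == "icc2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if abs(denom) < _EPS:
            raise DegenerateInputError("degenerate variance decomposition: ICC undefined")
        est = (msr - mse) / denom
        lo, hi = _icc2_ci(msr, msc, mse, n, k, est, alpha)
    elif form == "icc3":
        if msr + (k - 1) * mse < _EPS:
            raise DegenerateInputError("degenerate variance decomposition: ICC undefined")
        est = (msr - mse) / (msr + (k - 1) * mse)
        lo, hi = _icc3_ci(msr, mse, n, k, alpha)
    elif form == "icc1":
        gm = m.mean()
        msw = np.sum((m - m.mean(axis=1, keepdims=True)) ** 2) / (n * (k - 1))
        if msr + (k - 1) * msw < _EPS:
            raise DegenerateInputError("degenerate variance decomposition: ICC undefined")
        est = (msr - msw) / (msr + (k - 1) * msw)
        lo, hi = _icc1_ci(msr, msw, n, k, alpha)
    else:
        raise ValidationError(f"unknown ICC form {form!r}")
    est = float(np.clip(est, -1.0, 1.0))
    lo = float(np.clip(min(lo, est), -1.0, 1.0))
    hi = float(np.clip(max(hi, est), -1.0, 1.0))
    return ICCResult(est, lo, hi)


def _icc2_ci(msr, msc, mse, n, k, est, alpha):
    if mse < _EPS and msc < _EPS:
        return (est, est)  # perfect agreement: interval degenerates to the point
    a = (k * est) / (n * (1 - est)) if abs(1 - est) > _EPS else np.inf
    b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if abs(1 - est) > _EPS else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return (est, est)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > _EPS else (n - 1) * (k - 1)
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi = n * (f_hi * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_hi * msr
    )
    return lo, hi


def _icc3_ci(msr, mse, n, k, alpha):
    if mse < _EPS:
        return (1.0, 1.0)
    f = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


def _icc1_ci(msr, msw, n, k, alpha):
    if msw < _EPS:
        return (1.0, 1.0)
    f = msr / msw
    df1, df2 = n - 1, n * (k - 1)
    fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


# ---------------------------------------------------------------------------
# Fleiss kappa
# ---------------------------------------------------------------------------

def _category_counts(m: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    cats = np.unique(m)
    counts = np.stack([(m == c).sum(axis=1) for c in cats], axis=1)
    return counts.astype(float), cats


def _fleiss_from_counts(counts: np.ndarray) -> float:
    """Fleiss kappa from an (n_subjects x n_categories) count table.

    Returns ``nan`` when expected agreement is 1 (single category only).
    """
    n, _ = counts.shape
    k = counts.sum(axis=1)
    p_i = (np.sum(counts**2, axis=1) - k) / (k * (k - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / counts.sum()
    p_e = float(np.sum(p_j**2))
    if 1.0 - p_e < _EPS:
        return 1.0 if p_bar >= 1.0 - _EPS else float("nan")
    return float((p_bar - p_e) / (1.0 - p_e))


def fleiss_kappa(
    matrix,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> FleissResult:
    """Fleiss kappa with a subject-resampling bootstrap percentile CI.

    If all ratings fall in a single category the statistic is undefined
    (expected agreement 1) and the result carries ``degenerate=True``.
    """
    m = _as_matrix(matrix, "categorical ratings")
    counts, cats = _category_counts(m)
    if len(cats) < 2:
        return FleissResult(float("nan"), float("nan"), float("nan"), degenerate=True)
    est = _fleiss_from_counts(counts)
    if np.isnan(est):
        return FleissResult(float("nan"), float("nan"), float("nan"), degenerate=True)
    if ci_method == "none":
        return FleissResult(est, float("nan"), float("nan"))
    if ci_method != "bootstrap":
        raise ValidationError(f"unknown ci_method {ci_method!r}")

    n = counts.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    res = counts[idx]  # (B, n, C)
    kk = res.sum(axis=2)
    p_i = (np.sum(res**2, axis=2) - kk) / (kk * (kk - 1))
    p_bar = p_i.mean(axis=1)
    p_j = res.sum(axis=1) / res.sum(axis=(1, 2), keepdims=False)[:, None]
    p_e = np.sum(p_j**2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boots = (p_bar - p_e) / (1.0 - p_e)
    boots = np.where(1.0 - p_e < _EPS, 1.0, boots)  # degenerate resample = total agreement
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return FleissResult(float(est), float(min(lo, est)), float(max(hi, est)))


# ---------------------------------------------------------------------------
# Cohen kappa
# ---------------------------------------------------------------------------

def cohens_kappa(rater_a, rater_b) -> CohenResult:
    """Cohen's kappa for two raters' categorical columns."""
    a = np.asarray(rater_a).ravel()
    b = np.asarray(rater_b).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("rater columns must have equal length >= 2")
    cats = np.unique(np.concatenate([a, b]))
    table = np.zeros((len(cats), len(cats)), dtype=float)
    index = {c: i for i, c in enumerate(cats)}
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    return cohens_kappa_from_table(table)


def cohens_kappa_from_table(table) -> CohenResult:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValidationError(f"cross-table must be square, got {t.shape}")
    n = t.sum()
    if n <= 0:
        raise ValidationError("empty cross-table")
    p_o = np.trace(t) / n
    p_e = float(np.sum(t.sum(axis=1) * t.sum(axis=0)) / n**2)
    if 1.0 - p_e < _EPS:
        return CohenResult(1.0 if p_o >= 1.0 - _EPS else float("nan"), degenerate=True)
    return CohenResult(float((p_o - p_e) / (1.0 - p_e)))


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> SpearmanResult:
    """Spearman rank correlation with the t-approximation p-value.

    Ranks are averaged over ties; a constant input vector makes the
    correlation undefined (flagged, not raised).
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.shape != yv.shape or xv.size < 3:
        raise ValidationError("inputs must have equal length >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return SpearmanResult(float("nan"), float("nan"), undefined=True)
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = xv.size
    if abs(rho) >= 1.0 - _EPS:
        return SpearmanResult(float(np.sign(rho)), 0.0)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return SpearmanResult(rho, float(p))


# ---------------------------------------------------------------------------
# Chi-square (and the paired-design alternative, provided but unused by the
# replication pipeline)
# ---------------------------------------------------------------------------

def chi_square_2x2(table, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table; Yates correction optional."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {t.shape}")
    if (t < 0).any() or not np.allclose(t, np.rint(t)):
        raise ValidationError("table must hold nonnegative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise DegenerateTableError("zero margin: chi-square undefined")
    n = t.sum()
    expected = np.outer(rows, cols) / n
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    return ChiSquareResult(stat, float(stats.chi2.sf(stat, df=1)))


def mcnemar(table, correction: bool = True) -> ChiSquareResult:
    """McNemar test on the discordant cells of a paired 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got {t.shape}")
    b, c = t[0, 1], t[1, 0]
    if b + c == 0:
        raise DegenerateTableError("no discordant pairs: McNemar undefined")
    num = (abs(b - c) - 1.0) ** 2 if correction else (b - c) ** 2
    stat = float(num / (b + c))
    return ChiSquareResult(stat, float(stats.chi2.sf(stat, df=1)))


# ---------------------------------------------------------------------------
# Interpretive bands
# ---------------------------------------------------------------------------

def interpret(statistic_kind: str, value: float) -> str:
    """Deterministic interpretive label for an ICC/Fleiss/Cohen value.

    Bands: ICC <0.5 poor, [0.5,0.75) moderate, [0.75,0.90] good, >0.90
    excellent; Fleiss <=0.20 poor, then fair/moderate/good/very good at
    0.40/0.60/0.80; Cohen <0.01 poor, then slight/fair/moderate/substantial/
    perfect at 0.20/0.40/0.60/0.80.  Upper band edges are inclusive.
    """
    if statistic_kind not in ("icc", "fleiss", "cohen"):
        raise ValidationError(f"unknown statistic kind {statistic_kind!r}")
    if not np.isfinite(value) or not (-1.0 - _EPS <= value <= 1.0 + _EPS):
        raise ValidationError(f"value must lie in [-1, 1], got {value}")
    return _interpret_exact(statistic_kind, float(value))


def _interpret_exact(kind: str, v: float) -> str:
    if kind == "icc":
        if v < 0.5:
            return "poor"
        if v < 0.75:
            return "moderate"
        if v <= 0.90:
            return "good"
        return "excellent"
    if kind == "fleiss":
        if v <= 0.20:
            return "poor"
        if v <= 0.40:
            return "fair"
        if v <= 0.60:
            return "moderate"
        if v <= 0.80:
            return "good"
        return "very good"
    # cohen (Landis-Koch as printed)
    if v < 0.01:
        return "poor"
    if v <= 0.20:
        return "slight"
    if v <= 0.40:
        return "fair"
    if v <= 0.60:
        return "moderate"
    if v <= 0.80:
        return "substantial"
    return "perfect"
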
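"""Cross-station statistical toolkit.

Simple OLS regression with full F/df/p reporting and studentized-residual
diagnostics, Pearson correlation, the Arrhenius model for the growth
performance index, a Chow structural-break test, and one-way ANOVA — the
battery used to compare growth descriptors across stations on a latitudinal
temperature gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionReport",
    "ArrheniusFit",
    "ChowResult",
    "OutlierResult",
    "AnovaResult",
    "simple_regression",
    "pearson_correlation",
    "arrhenius_fit",
    "studentized_outlier_test",
    "chow_test",
    "chow_scan",
    "one_way_anova",
]

KELVIN_OFFSET = 273.15


@dataclass
class RegressionReport:
    """Simple-regression results in the reporting unit used throughout.

    ``F`` is MSR/MSE with model/error degrees of freedom ``dfm = 1`` and
    ``dfe = n − 2``; ``p`` is the upper F tail.  Both internally and
    externally (leave-one-out deleted) studentized residuals are populated.
    """

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    F: float
    dfm: int
    dfe: int
    p: float
    n: int
    residuals: np.ndarray = field(repr=False)
    studentized_internal: np.ndarray = field(repr=False)
    studentized_external: np.ndarray = field(repr=False)
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "r2": self.r2,
            "F": self.F,
            "dfm": self.dfm,
            "dfe": self.dfe,
            "p": self.p,
            "n": self.n,
        }


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionReport:
    """OLS of y on x with the full F/df/p and residual diagnostics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    infl = model.get_influence()
    # an exact line leaves only float noise in the residuals; studentizing
    # noise produces arbitrary O(1) ratios, so report true zeros instead
    sst = float(((y - y.mean()) ** 2).sum())
    if model.ssr <= 1e-20 * max(sst, 1.0):
        zeros = np.zeros(x.size)
        stud_int, stud_ext = zeros, zeros.copy()
    else:
        stud_int = infl.resid_studentized_internal
        stud_ext = infl.resid_studentized_external
    return RegressionReport(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        r2=float(model.rsquared) if sst > 0 else 0.0,  # constant y: nothing to explain
        F=float(model.fvalue) if sst > 0 else 0.0,
        dfm=int(model.df_model),
        dfe=int(model.df_resid),
        p=float(model.f_pvalue) if sst > 0 else 1.0,
        n=int(x.size),
        residuals=np.asarray(model.resid),
        studentized_internal=stud_int,
        studentized_external=stud_ext,
        x=x,
        y=y,
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and its two-sided p; r² equals the regression R²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ArrheniusFit:
    """ln(Φ′) = α·(1/T) + β with T in kelvin; α is the Arrhenius slope."""

    alpha: float
    beta: float
    report: RegressionReport


def arrhenius_fit(
    phi_primes: Sequence[float], temps_C: Sequence[float]
) -> ArrheniusFit:
    """Regress ln Φ′ on inverse absolute temperature."""
    phi = np.asarray(phi_primes, dtype=float)
    t = np.asarray(temps_C, dtype=float)
    if np.any(phi <= 0):
        raise ValueError("Φ′ must be positive for the log transform")
    if phi.size < 3:
        raise ValueError("need n >= 3")
    inv_T = 1.0 / (t + KELVIN_OFFSET)
    report = simple_regression(inv_T, np.log(phi))
    return ArrheniusFit(alpha=report.slope, beta=report.intercept, report=report)


@dataclass
class OutlierResult:
    flagged: list[int]
    statistics: np.ndarray
    critical: float
    df: int
    kind: str


def studentized_outlier_test(
    report: RegressionReport,
    alpha_level: float = 0.05,
    kind: str = "external",
    df: int | None = None,
) -> OutlierResult:
    """Flag points whose |studentized residual| exceeds the t critical value.

    ``kind`` selects the externally (deleted, default) or internally
    studentized residuals.  The comparison degrees of freedom default to
    ``n − 2``; the textbook external-residual df of ``n − 3`` is available by
    passing it explicitly.
    """
    if kind not in ("external", "internal"):
        raise ValueError("kind must be 'external' or 'internal'")
    r = (
        report.studentized_external
        if kind == "external"
        else report.studentized_internal
    )
    use_df = report.n - 2 if df is None else df
    crit = float(stats.t.ppf(1.0 - alpha_level / 2.0, use_df))
    flagged = np.flatnonzero(np.abs(r) > crit).tolist()
    return OutlierResult(
        flagged=flagged, statistics=np.asarray(r), critical=crit, df=use_df, kind=kind
    )


@dataclass
class ChowResult:
    """Structural-break F test via the sum-of-squared-residuals comparison."""

    F: float
    df1: int
    df2: int
    p: float
    ssr_pooled: float
    ssr_left: float
    ssr_right: float
    split_index: int


def _ols_ssr(x: np.ndarray, y: np.ndarray) -> float:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def chow_test(
    x: Sequence[float], y: Sequence[float], split_index: int
) -> ChowResult:
    """Chow test of one pooled line against two segment-wise lines.

    The data are split at ``split_index`` (first segment = points before it).
    With ``kpar = 2`` parameters per line,

        F = [(SSRp − SSR1 − SSR2)/kpar] / [(SSR1 + SSR2)/(n1 + n2 − 2·kpar)]

    and p comes from F(kpar, n1 + n2 − 2·kpar).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not 3 <= split_index <= n - 3:
        raise ValueError("each segment needs >= 3 points")
    kpar = 2
    ssr_p = _ols_ssr(x, y)
    ssr_1 = _ols_ssr(x[:split_index], y[:split_index])
    ssr_2 = _ols_ssr(x[split_index:], y[split_index:])
    df1, df2 = kpar, n - 2 * kpar
    denom = (ssr_1 + ssr_2) / df2
    # the pooled SSR cannot mathematically fall below the split SSRs; clamp
    # the float-noise deficit an exact-line dataset produces
    num = max(0.0, ssr_p - ssr_1 - ssr_2) / df1
    sst = float(((y - y.mean()) ** 2).sum())
    if ssr_p <= 1e-20 * max(sst, 1.0):  # data lie on one exact line
        num, denom = 0.0, max(denom, 1.0)
    if denom > 0:
        F = float(num / denom)
    else:
        F = 0.0 if num == 0 else float("inf")
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return ChowResult(
        F=F,
        df1=df1,
        df2=df2,
        p=p,
        ssr_pooled=ssr_p,
        ssr_left=ssr_1,
        ssr_right=ssr_2,
        split_index=int(split_index),
    )


def chow_scan(
    x: Sequence[float], y: Sequence[float], min_segment: int = 3
) -> ChowResult:
    """Chow test at every admissible split; returns the largest-F result."""
    x = np.asarray(x, dtype=float)
    best: ChowResult | None = None
    for s in range(min_segment, x.size - min_segment + 1):
        res = chow_test(x, y, s)
        if best is None or res.F > best.F:
            best = res
    if best is None:
        raise ValueError("no admissible split")
    return best


@dataclass
class AnovaResult:
    F: float
    dfm: int
    dfe: int
    p: float
    ss_between: float
    ss_within: float


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA between/within decomposition."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size == 0 for a in arrays.values()):
        raise ValueError("every group needs at least one value")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = float(
        sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    )
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays.values()))
    dfm = len(arrays) - 1
    dfe = all_vals.size - len(arrays)
    if dfe <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else float("inf")
    else:
        F = (ss_between / dfm) / (ss_within / dfe)
    p = float(stats.f.sf(F, dfm, dfe)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F), dfm=dfm, dfe=dfe, p=p, ss_between=ss_between, ss_within=ss_within
    )
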
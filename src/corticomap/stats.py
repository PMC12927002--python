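"""Group statistics and weighted calibration-curve quantification.

Zone means and plasma concentrations are compared across diet groups by
one-way ANOVA followed by Dunnett's post hoc test of every treatment group
against the shared control.  Dunnett's single-step adjusted p-values are
computed here from the factor-analytic representation of the equicorrelated
multivariate-t distribution of the treatment-vs-control t statistics:

    T_i = (Xbar_i - Xbar_0) / (S sqrt(1/n_i + 1/n_0)),
    corr(T_i, T_j) = lambda_i lambda_j,   lambda_i = sqrt(n_i / (n_i + n_0)),

so that, conditioning on the common factor Y ~ N(0,1) and the pooled scale
U = S/sigma (with nu U^2 ~ chi^2_nu),

    P(max_i |T_i| <= t) = E_U E_Y prod_i [ Phi((tU + lam_i Y)/s_i)
                                          - Phi((-tU + lam_i Y)/s_i) ],

with s_i = sqrt(1 - lam_i^2).  The expectation over Y uses Gauss-Hermite
quadrature and the one over U adaptive quadrature, giving deterministic
p-values accurate to well below 1e-6.

Plasma quantification follows bioanalytical practice: peak-area-ratio
responses are regressed on nominal concentration with 1/x weights, unknowns
are back-calculated through the curve, and results outside the validated
concentration range are flagged rather than reported as quantitative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "DunnettComparison",
    "DunnettResult",
    "CalibrationCurve",
    "oneway_anova",
    "dunnett",
    "dunnett_critical",
    "active_inactive_ratio",
    "fit_calibration",
    "back_calculate",
    "cv_percent",
    "group_statistics",
    "significance_stars",
]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class DunnettComparison:
    group: str
    estimate: float  # treatment mean - control mean
    t: float
    p_adjusted: float


@dataclass(frozen=True)
class DunnettResult:
    comparisons: tuple[DunnettComparison, ...]
    df: int
    control: str


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA (between/within decomposition)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA requires at least two groups")
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    F, p = sps.f_oneway(*arrays)
    k = len(arrays)
    N = sum(len(g) for g in arrays)
    return AnovaResult(F=float(F), p=float(p), df_between=k - 1, df_within=N - k)


def _u_density(u: np.ndarray, df: int) -> np.ndarray:
    # density of U = S/sigma where df * U^2 ~ chi^2_df
    logc = (df / 2) * np.log(df / 2) - special.gammaln(df / 2) + np.log(2.0)
    return np.exp(logc + (df - 1) * np.log(u) - df * u * u / 2)


_HERMITE_NODES, _HERMITE_WEIGHTS = np.polynomial.hermite.hermgauss(96)


def _prob_max_abs_below(t: float, lambdas: np.ndarray, df: int) -> float:
    """P(max_i |T_i| <= t) for Dunnett-correlated t statistics."""
    if t <= 0:
        return 0.0
    lam = np.asarray(lambdas, dtype=float)
    s = np.sqrt(1.0 - lam * lam)
    y = np.sqrt(2.0) * _HERMITE_NODES  # E over Y ~ N(0,1)
    wy = _HERMITE_WEIGHTS / np.sqrt(np.pi)

    def inner(u: float) -> float:
        upper = (t * u + lam[:, None] * y[None, :]) / s[:, None]
        lower = (-t * u + lam[:, None] * y[None, :]) / s[:, None]
        prod = np.prod(special.ndtr(upper) - special.ndtr(lower), axis=0)
        return float(np.dot(prod, wy))

    val, _err = integrate.quad(
        lambda u: _u_density(np.asarray(u), df) * inner(float(u)),
        0.0,
        np.inf,
        epsabs=1e-11,
        epsrel=1e-10,
        limit=200,
    )
    return min(max(val, 0.0), 1.0)


def dunnett(
    treatments: Sequence[Sequence[float]],
    control: Sequence[float],
    labels: Sequence[str] | None = None,
) -> DunnettResult:
    """Two-sided single-step Dunnett comparisons of each treatment vs control.

    Uses the pooled (equal-variance) error estimate across all groups.  With
    a single treatment group the adjusted p equals the two-sided pooled
    t-test p.
    """
    ctrl = np.asarray(control, dtype=float)
    groups = [np.asarray(g, dtype=float) for g in treatments]
    if len(groups) == 0:
        raise ValueError("at least one treatment group required")
    if len(ctrl) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(groups))]

    n0 = len(ctrl)
    ns = np.array([len(g) for g in groups])
    N = n0 + int(ns.sum())
    k = len(groups)
    df = N - (k + 1)
    ss_within = float(np.sum((ctrl - ctrl.mean()) ** 2)) + sum(
        float(np.sum((g - g.mean()) ** 2)) for g in groups
    )
    s2 = ss_within / df
    lambdas = np.sqrt(ns / (ns + n0))

    comparisons = []
    for label, g, n_i in zip(labels, groups, ns):
        est = float(g.mean() - ctrl.mean())
        t = est / np.sqrt(s2 * (1.0 / n_i + 1.0 / n0))
        p_adj = 1.0 - _prob_max_abs_below(abs(t), lambdas, df)
        comparisons.append(
            DunnettComparison(group=str(label), estimate=est, t=float(t), p_adjusted=p_adj)
        )
    return DunnettResult(tuple(comparisons), df=df, control="control")


def dunnett_critical(
    alpha: float, ns: Sequence[int], n0: int, df: int
) -> float:
    """Two-sided Dunnett critical value: t with P(max |T_i| > t) = alpha."""
    lambdas = np.sqrt(np.asarray(ns, float) / (np.asarray(ns, float) + n0))
    return float(
        optimize.brentq(
            lambda t: _prob_max_abs_below(t, lambdas, df) - (1 - alpha), 0.5, 15.0
        )
    )


def active_inactive_ratio(cort, dhc):
    """Active:inactive glucocorticoid ratio (corticosterone / 11-DHC).

    NaN where the denominator is not strictly positive.  Accepts scalars or
    arrays.
    """
    cort = np.asarray(cort, dtype=float)
    dhc = np.asarray(dhc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dhc > 0, cort / dhc, np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CalibrationCurve:
    analyte: str
    slope: float
    intercept: float
    weighting: str  # "1/x" or "none"
    valid_range: tuple[float, float]  # ng/mL
    r_squared: float

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range low must be below high")


def fit_calibration(
    points: Sequence[tuple[float, float]],
    weighting: Literal["1/x", "none"] = "1/x",
    analyte: str = "",
    valid_range: tuple[float, float] | None = None,
) -> CalibrationCurve:
    """Weighted linear regression of response ratio on nominal concentration.

    ``weighting="1/x"`` uses w_i = 1/x_i (the bioanalytical convention that
    keeps relative error roughly constant across the range); ``"none"`` is
    ordinary least squares.  Both slope and intercept are free.  The valid
    range defaults to the span of the nominal levels.
    """
    import statsmodels.api as sm

    pts = [(float(x), float(y)) for x, y in points]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if len(np.unique(xs)) < 3:
        raise ValueError("calibration requires >=3 points with distinct nominal values")
    if weighting == "1/x":
        if np.any(xs <= 0):
            raise ValueError("1/x weighting requires strictly positive nominal values")
        w = 1.0 / xs
    elif weighting == "none":
        w = np.ones_like(xs)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    model = sm.WLS(ys, sm.add_constant(xs), weights=w)
    res = model.fit()
    intercept, slope = res.params
    if valid_range is None:
        valid_range = (float(xs.min()), float(xs.max()))
    return CalibrationCurve(
        analyte=analyte,
        slope=float(slope),
        intercept=float(intercept),
        weighting=weighting,
        valid_range=valid_range,
        r_squared=float(res.rsquared),
    )


def back_calculate(
    curve: CalibrationCurve, response: float
) -> tuple[float, Literal["ok", "below_range", "above_range"]]:
    """Interpolate a concentration from the curve and flag out-of-range results."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot back-calculate")
    conc = (float(response) - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    if conc < lo:
        flag = "below_range"
    elif conc > hi:
        flag = "above_range"
    else:
        flag = "ok"
    return conc, flag


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation, 100 * sample (n-1) SD / mean; NaN if mean 0."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("CV requires at least 2 values")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * v.std(ddof=1) / m)


def significance_stars(p: float) -> str:
    """Figure-style star coding: ** for P<0.01, * for P<0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_statistics(
    table: pd.DataFrame, control_label: str = "control"
) -> pd.DataFrame:
    """Per-analyte group summary: means +/- SEM, ANOVA F/p, Dunnett p, stars.

    ``table`` needs columns ``group``, ``analyte``, ``value``; NaN values are
    dropped per analyte.  The control group must be present.
    """
    required = {"group", "analyte", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for analyte, sub in table.dropna(subset=["value"]).groupby("analyte", sort=False):
        groups = {g: d["value"].to_numpy(float) for g, d in sub.groupby("group", sort=False)}
        if control_label not in groups:
            raise ValueError(f"control group {control_label!r} missing for {analyte!r}")
        treat_labels = [g for g in groups if g != control_label]
        anova = oneway_anova([groups[control_label]] + [groups[g] for g in treat_labels])
        dn = dunnett(
            [groups[g] for g in treat_labels], groups[control_label], labels=treat_labels
        )
        p_by_group = {c.group: c.p_adjusted for c in dn.comparisons}
        for g, vals in groups.items():
            p_adj = p_by_group.get(g, float("nan"))
            rows.append(
                {
                    "analyte": analyte,
                    "group": g,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals))),
                    "anova_F": anova.F,
                    "anova_p": anova.p,
                    "dunnett_p": p_adj,
                    "stars": significance_stars(p_adj) if g != control_label else "",
                }
            )
    return pd.DataFrame(rows)
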
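"""Allometric scaling of surface area with volume.

Ordinary least squares of log10(SA) on log10(V): the slope is the
scaling exponent beta.  Under geometric similarity (isometry) surface
area scales with volume to the 2/3 power, so each fitted slope is
tested against H0: beta = 2/3 with a t-test on the coefficient, and
slopes are compared across measurement methods with a
log10(V) x method interaction model and its ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ISOMETRIC_EXPONENT",
    "AllometryError",
    "ScalingFit",
    "MethodComparison",
    "fit_scaling",
    "test_isometry",
    "compare_methods",
    "fits_to_frame",
]

ISOMETRIC_EXPONENT = 2.0 / 3.0


class AllometryError(ValueError):
    """Invalid input for a scaling fit."""


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of log10(SA) on log10(V) for one measurement method."""

    method: str
    beta: float
    alpha: float  # intercept, log10(mm^2) units
    beta_se: float
    r_squared: float
    beta_ci_low: float
    beta_ci_high: float
    p_value: float  # H0: beta = 0
    n: int
    df_resid: int

    @property
    def ci_defined(self) -> bool:
        return self.df_resid >= 1 and np.isfinite(self.beta_se) and self.beta_se > 0


@dataclass(frozen=True)
class MethodComparison:
    """Interaction model across methods plus per-method isometry tests."""

    interaction_p_values: dict[str, float]  # contrast label -> p
    interaction_anova_p: float
    isometry_p: dict[str, float]  # method -> p vs beta = 2/3
    fits: tuple[ScalingFit, ...]


def fit_scaling(surface_areas, volumes, method: str = "") -> ScalingFit:
    """OLS of log10(SA) on log10(V) with a Wald 95% CI on the slope.

    With only two points the fit is perfect but the CI is undefined
    (zero residual degrees of freedom); the fit is returned with NaN
    slope SE/CI and ``ci_defined`` false.
    """
    sa = np.asarray(surface_areas, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if sa.shape != v.shape or sa.ndim != 1:
        raise AllometryError("surface_areas and volumes must be 1-D, equal length")
    if len(sa) < 2:
        raise AllometryError("need at least 2 points")
    if (sa <= 0).any() or (v <= 0).any():
        raise AllometryError("all values must be strictly positive for log scaling")
    x = np.log10(v)
    y = np.log10(sa)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(sa)
    df_resid = int(model.df_resid)
    if df_resid >= 1:
        beta_se = float(model.bse[1])
        ci = model.conf_int(alpha=0.05)
        ci_low, ci_high = float(ci[1, 0]), float(ci[1, 1])
        p = float(model.pvalues[1])
    else:
        beta_se = float("nan")
        ci_low = ci_high = float("nan")
        p = float("nan")
    return ScalingFit(
        method=method,
        beta=float(model.params[1]),
        alpha=float(model.params[0]),
        beta_se=beta_se,
        r_squared=float(model.rsquared) if n > 2 else 1.0,
        beta_ci_low=ci_low,
        beta_ci_high=ci_high,
        p_value=p,
        n=n,
        df_resid=df_resid,
    )


def test_isometry(fit: ScalingFit, expected: float = ISOMETRIC_EXPONENT) -> float:
    """Two-sided p-value for H0: beta equals the isometric 2/3.

    Implemented as a t-test on the slope, equivalent to a single-row
    linear-hypothesis (Wald) test.
    """
    if fit.df_resid < 1:
        raise AllometryError("isometry test needs residual df >= 1")
    # numerically exact fit: the slope SE is rounding noise, so compare
    # the slope itself rather than forming a 0/0 statistic
    if not fit.ci_defined or fit.beta_se < 1e-9 * max(1.0, abs(fit.beta)):
        return 1.0 if np.isclose(fit.beta, expected, atol=1e-9) else 0.0
    t = (fit.beta - expected) / fit.beta_se
    return float(2.0 * stats.t.sf(abs(t), fit.df_resid))


# keep pytest from collecting the isometry test operation as a test case
test_isometry.__test__ = False  # type: ignore[attr-defined]


def compare_methods(data: pd.DataFrame) -> MethodComparison:
    """Compare scaling exponents across measurement methods.

    ``data`` is a long table with columns ``method``,
    ``surface_area_mm2``, ``volume_mm3``.  Fits the full interaction
    model log10(SA) ~ log10(V) * method, reports the ANOVA p of the
    interaction plus each non-reference interaction coefficient's p,
    and per-method isometry tests from separate per-method fits.
    """
    required = {"method", "surface_area_mm2", "volume_mm3"}
    if not required.issubset(data.columns):
        raise AllometryError(f"data must have columns {sorted(required)}")
    methods = sorted(data["method"].unique())
    if len(methods) < 2:
        raise AllometryError("need at least 2 methods to compare")
    for m in methods:
        if (data["method"] == m).sum() < 3:
            raise AllometryError(f"method {m!r} has fewer than 3 points")
    df = pd.DataFrame(
        {
            "log_sa": np.log10(data["surface_area_mm2"].to_numpy(dtype=float)),
            "log_v": np.log10(data["volume_mm3"].to_numpy(dtype=float)),
            "method": data["method"].to_numpy(),
        }
    )
    model = smf.ols("log_sa ~ log_v * C(method)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    inter_rows = [i for i in anova.index if "log_v:C(method)" in str(i)]
    anova_p = float(anova.loc[inter_rows[0], "PR(>F)"]) if inter_rows else float("nan")
    interaction_p = {
        name: float(p)
        for name, p in model.pvalues.items()
        if "log_v:" in str(name)
    }
    fits = []
    isometry_p = {}
    for m in methods:
        sub = df[df["method"] == m]
        fit = fit_scaling(10.0 ** sub["log_sa"], 10.0 ** sub["log_v"], method=m)
        fits.append(fit)
        isometry_p[m] = test_isometry(fit)
    return MethodComparison(
        interaction_p_values=interaction_p,
        interaction_anova_p=anova_p,
        isometry_p=isometry_p,
        fits=tuple(fits),
    )


def fits_to_frame(fits) -> pd.DataFrame:
    """Fit table mirroring the standard report: beta, alpha, R², CI, p."""
    return pd.DataFrame(
        [
            {
                "method": f.method,
                "beta": f.beta,
                "alpha": f.alpha,
                "r_squared": f.r_squared,
                "beta_ci_low": f.beta_ci_low,
                "beta_ci_high": f.beta_ci_high,
                "p_value": f.p_value,
                "n": f.n,
            }
            for f in fits
        ]
    )
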
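"""Paired comparison of geometric size estimates against 3D-model measures.

For each body scope (head, mesosoma, metasoma, tagmata sum) and
quantity (surface area, volume) the disagreement between the geometric
estimate and the empirical model measurement is summarized three ways:

* percent error, ``|geometric - model| / model * 100`` — unsigned
  relative bias, reported as mean ± standard error over specimens;
* mean signed error (MSE), the mean of ``geometric - model`` — negative
  when the geometric method systematically underestimates;
* a paired test on the differences: Shapiro–Wilk gates at alpha = 0.05
  between a paired t-test and a Wilcoxon signed-rank fallback (both are
  reported when normality fails, since the choice is a judgement call).

The correction factor inverts the percent error: a geometric value
known to underestimate by fraction ``e`` is rescaled by ``(1 - e)^-1``
to recover the model ("theoretical") value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonError",
    "PairedSample",
    "ComparisonResult",
    "percent_error",
    "mean_signed_error",
    "paired_comparison",
    "corrected_size",
    "comparison_table",
    "format_comparison_table",
]


class ComparisonError(ValueError):
    """Invalid paired data."""


@dataclass(frozen=True)
class PairedSample:
    """Matched geometric and model values for one scope and quantity."""

    specimen_ids: tuple[str, ...]
    geometric_values: np.ndarray
    model_values: np.ndarray
    quantity: str  # "surface_area" | "volume"
    scope: str  # tagma name or "tagmata_sum"

    def __post_init__(self) -> None:
        g = np.asarray(self.geometric_values, dtype=float)
        m = np.asarray(self.model_values, dtype=float)
        object.__setattr__(self, "geometric_values", g)
        object.__setattr__(self, "model_values", m)
        if g.shape != m.shape or g.ndim != 1:
            raise ComparisonError("paired arrays must be 1-D and equal length")
        if len(g) < 2:
            raise ComparisonError("need at least 2 pairs")
        if len(self.specimen_ids) != len(g):
            raise ComparisonError("specimen_ids length mismatch")
        if (g <= 0).any() or (m <= 0).any():
            raise ComparisonError("size values must be strictly positive")

    @property
    def differences(self) -> np.ndarray:
        return self.geometric_values - self.model_values


@dataclass(frozen=True)
class ComparisonResult:
    scope: str
    quantity: str
    n: int
    t_statistic: float
    p_value: float
    test_used: str  # "paired_t" | "wilcoxon_signed_rank" | "degenerate"
    normality_p: float
    wilcoxon_p: float | None
    percent_error_mean: float
    percent_error_se: float
    mean_signed_error: float


def percent_error(geometric, model):
    """Unsigned relative error in percent: |geometric - model| / model * 100.

    Accepts scalars or arrays; the model (reference) value must be
    strictly positive.
    """
    g = np.asarray(geometric, dtype=float)
    m = np.asarray(model, dtype=float)
    if (m <= 0).any():
        raise ComparisonError("model reference values must be > 0")
    out = np.abs(g - m) / m * 100.0
    return float(out) if out.ndim == 0 else out


def mean_signed_error(sample: PairedSample) -> float:
    """Mean of (geometric - model); negative means underestimation."""
    return float(sample.differences.mean())


def paired_comparison(sample: PairedSample, alpha: float = 0.05) -> ComparisonResult:
    """Test whether geometric and model measurements differ, pairwise.

    Shapiro–Wilk on the differences gates (at ``alpha``) between a
    two-sided paired t-test and the Wilcoxon signed-rank fallback.
    Requires n >= 3.  All-zero differences are reported as degenerate
    (t = 0, p = 1) rather than dividing by zero.
    """
    d = sample.differences
    n = len(d)
    if n < 3:
        raise ComparisonError(f"paired test needs n >= 3, got {n}")
    pe = percent_error(sample.geometric_values, sample.model_values)
    pe_mean = float(pe.mean())
    pe_se = float(pe.std(ddof=1) / np.sqrt(n))
    mse = float(d.mean())

    if np.allclose(d, 0.0):
        return ComparisonResult(
            sample.scope, sample.quantity, n, 0.0, 1.0, "degenerate",
            1.0, None, pe_mean, pe_se, mse,
        )
    if np.ptp(d) == 0:
        # identical nonzero differences: Shapiro is undefined; the t-test
        # is still degenerate (zero variance), report the sign via t=inf
        normality_p = 0.0
    else:
        normality_p = float(stats.shapiro(d).pvalue)

    t_stat, t_p = stats.ttest_rel(sample.geometric_values, sample.model_values)
    wilcoxon_p: float | None = None
    if normality_p < alpha:
        wilcoxon_p = float(stats.wilcoxon(d).pvalue)
        test_used = "wilcoxon_signed_rank"
        p_value = wilcoxon_p
    else:
        test_used = "paired_t"
        p_value = float(t_p)
    return ComparisonResult(
        sample.scope, sample.quantity, n, float(t_stat), p_value, test_used,
        normality_p, wilcoxon_p, pe_mean, pe_se, mse,
    )


def corrected_size(geometric_value, percent_error_fraction):
    """Invert a known underestimation: geometric * (1 - fraction)^-1.

    ``percent_error_fraction`` is a fraction in [0, 1), *not* a
    percentage — a 26.4% error is passed as 0.264.
    """
    f = np.asarray(percent_error_fraction, dtype=float)
    if (f < 0).any() or (f >= 1).any():
        raise ComparisonError(
            "percent_error_fraction must lie in [0, 1); "
            "did you pass a percentage instead of a fraction?"
        )
    out = np.asarray(geometric_value, dtype=float) / (1.0 - f)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# table-level interface

_SCOPES = ("head", "mesosoma", "metasoma", "tagmata_sum")
_QUANTITIES = {"volume": "volume_mm3", "surface_area": "surface_area_mm2"}


def paired_samples_from_tables(
    geometric: pd.DataFrame,
    model: pd.DataFrame,
    scopes: Sequence[str] = _SCOPES,
) -> list[PairedSample]:
    """Join two long-format size tables on (specimen_id, scope)."""
    merged = geometric.merge(
        model, on=["specimen_id", "scope"], suffixes=("_geo", "_mod")
    )
    samples = []
    for scope in scopes:
        sub = merged[merged["scope"] == scope].sort_values("specimen_id")
        if len(sub) < 2:
            continue
        for quantity, col in _QUANTITIES.items():
            samples.append(
                PairedSample(
                    specimen_ids=tuple(sub["specimen_id"].astype(str)),
                    geometric_values=sub[f"{col}_geo"].to_numpy(),
                    model_values=sub[f"{col}_mod"].to_numpy(),
                    quantity=quantity,
                    scope=scope,
                )
            )
    return samples


def comparison_table(
    geometric: pd.DataFrame,
    model: pd.DataFrame,
    alpha: float = 0.05,
    report_nonsignificant_errors: bool = False,
) -> pd.DataFrame:
    """Scope x quantity comparison report (one row each).

    Percent errors are reported only where the paired test is
    significant at ``alpha`` (NaN otherwise), mirroring the convention
    of quantifying bias only once a difference is established; set
    ``report_nonsignificant_errors`` to keep them everywhere.
    """
    rows = []
    for sample in paired_samples_from_tables(geometric, model):
        res = paired_comparison(sample, alpha=alpha)
        significant = res.p_value < alpha
        show = significant or report_nonsignificant_errors
        rows.append(
            {
                "scope": res.scope,
                "quantity": res.quantity,
                "n": res.n,
                "t_statistic": res.t_statistic,
                "p_value": res.p_value,
                "test_used": res.test_used,
                "normality_p": res.normality_p,
                "wilcoxon_p": res.wilcoxon_p,
                "percent_error_mean": res.percent_error_mean if show else np.nan,
                "percent_error_se": res.percent_error_se if show else np.nan,
                "mean_signed_error": res.mean_signed_error if show else np.nan,
                "significant": significant,
            }
        )
    return pd.DataFrame(rows)


def format_comparison_table(table: pd.DataFrame) -> str:
    """Human-readable rendering of :func:`comparison_table` output."""
    lines = [
        f"{'scope':<14}{'quantity':<14}{'t':>8}{'P':>9}  "
        f"{'% error (mean ± SE)':>22}  {'MSE':>9}  test"
    ]
    for _, r in table.iterrows():
        if np.isnan(r["percent_error_mean"]):
            err = "NA"
        else:
            err = f"{r['percent_error_mean']:.3f} ± {r['percent_error_se']:.3f}"
        mse = "NA" if np.isnan(r["mean_signed_error"]) else f"{r['mean_signed_error']:.3f}"
        lines.append(
            f"{r['scope']:<14}{r['quantity']:<14}{r['t_statistic']:>8.3f}"
            f"{r['p_value']:>9.4f}  {err:>22}  {mse:>9}  {r['test_used']}"
        )
    return "\n".join(lines)
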
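"""Steady-state heat budget of a flying honey bee worker.

At steady state the four heat-transfer routes sum to zero:

    Q_M + Q_E + Q_R + Q_C = 0            (all mW)

with gains positive and losses negative.  Metabolic heat production
``Q_M`` and evaporative heat loss ``Q_E`` come from linear models of
mass-specific rates (mW g^-1) against air temperature, multiplied by
body mass.  Longwave radiative exchange ``Q_R`` is computed per tagma
from the Stefan–Boltzmann law,

    Q_R,tagma = [a*eps_C*sigma*T_i^4 - eps_S*sigma*T_x^4] * SA_tagma

where ``a`` is body-surface absorptivity, ``eps_C`` the chamber
emissivity, ``eps_S`` the body-surface emissivity, ``T_i`` the chamber
wall (taken equal to air) temperature and ``T_x`` the tagma surface
(taken equal to internal) temperature, both in kelvin; tagma
temperatures are themselves linear in air temperature.  Convection is
never modelled mechanistically: ``Q_C = -(Q_M + Q_E + Q_R)`` is the
budget residual, so closure holds by construction.

Surface-area measurement error propagates through ``Q_R`` only: a
tagma surface area known to be underestimated by fraction ``e`` is
rescaled by ``(1 - e)^-1`` before the budget is rebuilt, and because
``Q_R`` is linear in SA the corrected radiative flux rescales per
tagma by exactly that factor at fixed temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "DEFAULT_GRID_C",
    "KELVIN_OFFSET",
    "BudgetError",
    "RadiativeConstants",
    "LinearResponse",
    "ThermalModelSet",
    "TagmaSurfaceAreas",
    "RouteRegression",
    "metabolic_heat",
    "evaporative_heat",
    "net_radiative_tagma",
    "whole_body_radiative",
    "convective_heat",
    "build_budget",
    "apply_surface_correction",
    "regress_routes",
    "find_crossover",
    "thermal_models_from_dict",
    "thermal_models_to_dict",
]

#: Air-temperature evaluation grid (°C).
DEFAULT_GRID_C = (20.0, 25.0, 30.0, 35.0, 40.0, 45.0, 50.0)
KELVIN_OFFSET = 273.15
ROUTES = ("Q_M", "Q_E", "Q_R", "Q_C")


class BudgetError(ValueError):
    """Invalid heat-budget configuration or input."""


@dataclass(frozen=True)
class RadiativeConstants:
    """Longwave exchange constants (all overridable).

    absorptivity: body-surface absorptivity a = 0.98
    emissivity_chamber: borosilicate chamber emissivity eps_C = 0.90
    emissivity_surface: body-surface emissivity eps_S = 0.98
    stefan_boltzmann: sigma = 5.67e-8 W m^-2 K^-4
    """

    absorptivity: float = 0.98
    emissivity_chamber: float = 0.90
    emissivity_surface: float = 0.98
    stefan_boltzmann: float = 5.67e-8

    def __post_init__(self) -> None:
        for name in ("absorptivity", "emissivity_chamber", "emissivity_surface"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise BudgetError(f"{name} must be in (0, 1], got {v}")
        if self.stefan_boltzmann <= 0:
            raise BudgetError("stefan_boltzmann must be positive")


@dataclass(frozen=True)
class LinearResponse:
    """A linear response to air temperature: value = intercept + slope*T."""

    intercept: float
    slope: float

    def __call__(self, t_air_c):
        return self.intercept + self.slope * np.asarray(t_air_c, dtype=float)


@dataclass(frozen=True)
class ThermalModelSet:
    """Linear thermal-response models vs air temperature (°C).

    ``metabolic`` and ``evaporative`` are mass-specific rates in
    mW g^-1 (evaporative as a magnitude of loss; the budget applies
    the negative sign).  The three tagma-temperature models return °C.
    ``body_mass_g`` converts mass-specific rates to whole-bee mW
    (default 0.0753 g, a typical worker in flight).
    """

    metabolic: LinearResponse
    evaporative: LinearResponse
    head_temperature: LinearResponse
    thorax_temperature: LinearResponse
    abdomen_temperature: LinearResponse
    body_mass_g: float = 0.0753
    label: str = "unnamed"

    def __post_init__(self) -> None:
        if self.body_mass_g <= 0:
            raise BudgetError("body_mass_g must be positive")

    def check_plausible(self, grid_c: Sequence[float] = DEFAULT_GRID_C) -> list[str]:
        """Warnings for tagma temperatures outside 0–60 °C on the grid."""
        warnings = []
        t = np.asarray(grid_c, dtype=float)
        for name in ("head_temperature", "thorax_temperature", "abdomen_temperature"):
            pred = getattr(self, name)(t)
            if (pred < 0).any() or (pred > 60).any():
                warnings.append(
                    f"{name} predicts {pred.min():.1f}–{pred.max():.1f} °C "
                    "over the grid (outside 0–60 °C)"
                )
        return warnings


@dataclass(frozen=True)
class TagmaSurfaceAreas:
    """Head/thorax/abdomen surface areas (mm²) under one method label."""

    head_mm2: float
    thorax_mm2: float
    abdomen_mm2: float
    method: str = "geometric"

    def __post_init__(self) -> None:
        if min(self.head_mm2, self.thorax_mm2, self.abdomen_mm2) <= 0:
            raise BudgetError("tagma surface areas must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "head": self.head_mm2,
            "thorax": self.thorax_mm2,
            "abdomen": self.abdomen_mm2,
        }


# ---------------------------------------------------------------------------
# routes

def metabolic_heat(t_air_c, models: ThermalModelSet):
    """Whole-bee metabolic heat production (mW, positive gain)."""
    return models.metabolic(t_air_c) * models.body_mass_g


def evaporative_heat(t_air_c, models: ThermalModelSet):
    """Whole-bee evaporative heat loss (mW, negative under the sign
    convention); the model supplies the loss magnitude in mW g^-1."""
    return -np.abs(models.evaporative(t_air_c)) * models.body_mass_g


def net_radiative_tagma(
    t_air_c,
    t_tagma_c,
    surface_area_mm2: float,
    constants: RadiativeConstants = RadiativeConstants(),
):
    """Net longwave radiative exchange of one tagma (mW).

    ``[a*eps_C*sigma*T_i^4 - eps_S*sigma*T_x^4] * SA`` with T_i the
    air/chamber temperature and T_x the tagma temperature, converted
    to kelvin; SA converts mm² -> m² and the result W -> mW.
    """
    t_i = np.asarray(t_air_c, dtype=float)
    t_x = np.asarray(t_tagma_c, dtype=float)
    if (t_i < -KELVIN_OFFSET).any() or (t_x < -KELVIN_OFFSET).any():
        raise BudgetError("temperatures below absolute zero")
    if surface_area_mm2 < 0:
        raise BudgetError("surface area must be >= 0")
    ti4 = (t_i + KELVIN_OFFSET) ** 4
    tx4 = (t_x + KELVIN_OFFSET) ** 4
    sigma = constants.stefan_boltzmann
    flux_w_m2 = (
        constants.absorptivity * constants.emissivity_chamber * sigma * ti4
        - constants.emissivity_surface * sigma * tx4
    )
    out = flux_w_m2 * (surface_area_mm2 * 1e-6) * 1000.0
    return float(out) if out.ndim == 0 else out


def whole_body_radiative(
    t_air_c,
    models: ThermalModelSet,
    areas: TagmaSurfaceAreas,
    constants: RadiativeConstants = RadiativeConstants(),
):
    """Summed net radiative exchange over head, thorax and abdomen (mW)."""
    total = 0.0
    for tagma, temp_model in (
        ("head", models.head_temperature),
        ("thorax", models.thorax_temperature),
        ("abdomen", models.abdomen_temperature),
    ):
        total = total + net_radiative_tagma(
            t_air_c, temp_model(t_air_c), areas.as_dict()[tagma], constants
        )
    return total


def convective_heat(q_m, q_e, q_r):
    """Convective transfer back-calculated as the budget residual:
    Q_C = -(Q_M + Q_E + Q_R)."""
    return -(np.asarray(q_m, dtype=float) + np.asarray(q_e) + np.asarray(q_r))


def build_budget(
    models: ThermalModelSet,
    areas: TagmaSurfaceAreas,
    constants: RadiativeConstants = RadiativeConstants(),
    grid_c: Sequence[float] = DEFAULT_GRID_C,
) -> pd.DataFrame:
    """Budget table: one row per air temperature for one SA method.

    Columns: air_temperature_C, Q_M_mW, Q_E_mW, Q_R_mW, Q_C_mW, method.
    Closure (row sum zero) holds by construction of Q_C.
    """
    t = np.asarray(list(grid_c), dtype=float)
    if t.size == 0:
        raise BudgetError("temperature grid is empty")
    q_m = metabolic_heat(t, models)
    q_e = evaporative_heat(t, models)
    q_r = whole_body_radiative(t, models, areas, constants)
    q_c = convective_heat(q_m, q_e, q_r)
    return pd.DataFrame(
        {
            "air_temperature_C": t,
            "Q_M_mW": q_m,
            "Q_E_mW": q_e,
            "Q_R_mW": np.asarray(q_r, dtype=float),
            "Q_C_mW": q_c,
            "method": areas.method,
        }
    )


def apply_surface_correction(
    areas: TagmaSurfaceAreas,
    fractions: Mapping[str, float],
    method: str = "3D-corrected",
) -> TagmaSurfaceAreas:
    """Rescale each tagma SA by (1 - fraction)^-1.

    ``fractions`` maps tagma ("head"/"thorax"/"abdomen") to an
    underestimation *fraction* in [0, 1); missing tagmata are left
    uncorrected (the convention for tagmata whose geometric/model
    difference was not significant).
    """
    scaled = {}
    for tagma, value in areas.as_dict().items():
        f = float(fractions.get(tagma, 0.0))
        if not 0 <= f < 1:
            raise BudgetError(
                f"correction fraction for {tagma} must be in [0, 1), got {f}"
            )
        scaled[tagma] = value / (1.0 - f)
    return TagmaSurfaceAreas(
        head_mm2=scaled["head"],
        thorax_mm2=scaled["thorax"],
        abdomen_mm2=scaled["abdomen"],
        method=method,
    )


# ---------------------------------------------------------------------------
# route regressions and crossover

@dataclass(frozen=True)
class RouteRegression:
    """Per-route temperature regression with a method interaction.

    Model: Q = intercept + T_air + method + T_air:method.  Slopes and
    intercepts are per method; the interaction F/p tests whether the
    temperature slopes differ between methods.  When the interaction is
    not significant, method differences are read as intercept shifts
    (``method_p``).
    """

    route: str
    slopes: dict[str, float]  # method -> mW/°C
    intercepts: dict[str, float]  # method -> mW
    interaction_f: float
    interaction_p: float
    method_f: float
    method_p: float
    anova: pd.DataFrame


def regress_routes(
    budgets: pd.DataFrame | Sequence[pd.DataFrame],
    routes: Sequence[str] = ("Q_R", "Q_C"),
) -> dict[str, RouteRegression]:
    """Regress each route on air temperature with a method interaction.

    ``budgets`` is one concatenated budget table (or a sequence of
    them) covering >= 2 methods on a common temperature grid.
    """
    if not isinstance(budgets, pd.DataFrame):
        budgets = pd.concat(list(budgets), ignore_index=True)
    methods = sorted(budgets["method"].unique())
    if len(methods) < 2:
        raise BudgetError("route regression needs >= 2 methods")
    grids = {
        m: tuple(np.sort(budgets.loc[budgets["method"] == m, "air_temperature_C"]))
        for m in methods
    }
    if len(set(grids.values())) != 1:
        raise BudgetError(f"methods evaluated on different grids: {grids}")

    out: dict[str, RouteRegression] = {}
    for route in routes:
        col = f"{route}_mW"
        if col not in budgets.columns:
            raise BudgetError(f"unknown route {route!r}")
        df = pd.DataFrame(
            {
                "q": budgets[col].to_numpy(dtype=float),
                "t_air": budgets["air_temperature_C"].to_numpy(dtype=float),
                "method": budgets["method"].to_numpy(),
            }
        )
        model = smf.ols("q ~ t_air * C(method)", data=df).fit()
        anova = sm.stats.anova_lm(model, typ=2)

        def _row(prefix: str) -> tuple[float, float]:
            for idx in anova.index:
                if str(idx) == prefix:
                    return float(anova.loc[idx, "F"]), float(anova.loc[idx, "PR(>F)"])
            return float("nan"), float("nan")

        inter_f, inter_p = _row("t_air:C(method)")
        meth_f, meth_p = _row("C(method)")
        slopes = {}
        intercepts = {}
        for m in methods:
            sub = df[df["method"] == m]
            coef = np.polyfit(sub["t_air"], sub["q"], 1)
            slopes[m] = float(coef[0])
            intercepts[m] = float(coef[1])
        out[route] = RouteRegression(
            route=route,
            slopes=slopes,
            intercepts=intercepts,
            interaction_f=inter_f,
            interaction_p=inter_p,
            method_f=meth_f,
            method_p=meth_p,
            anova=anova,
        )
    return out


def find_crossover(
    series_a,
    series_b,
    grid_c: Sequence[float] = DEFAULT_GRID_C,
    method: str = "fitted",
) -> float | None:
    """Temperature where two routes' magnitudes are equal, or None.

    ``method="fitted"`` (default) fits a line to |Q| of each series
    over the grid and intersects the two fitted lines, matching a
    regression-based presentation; ``method="interpolated"`` finds a
    sign change of the |difference| on the raw grid and interpolates
    linearly.  Returns None when no crossing lies within the grid.
    """
    t = np.asarray(list(grid_c), dtype=float)
    a = np.abs(np.asarray(series_a, dtype=float))
    b = np.abs(np.asarray(series_b, dtype=float))
    if not (t.shape == a.shape == b.shape):
        raise BudgetError("series and grid must have matching lengths")
    lo, hi = float(t.min()), float(t.max())
    if method == "fitted":
        sa_, ia = np.polyfit(t, a, 1)
        sb_, ib = np.polyfit(t, b, 1)
        if np.isclose(sa_, sb_):
            return None
        cross = (ib - ia) / (sa_ - sb_)
        return float(cross) if lo <= cross <= hi else None
    if method == "interpolated":
        d = a - b
        for i in range(len(t) - 1):
            if d[i] == 0:
                return float(t[i])
            if d[i] * d[i + 1] < 0:
                frac = d[i] / (d[i] - d[i + 1])
                return float(t[i] + frac * (t[i + 1] - t[i]))
        if d[-1] == 0:
            return float(t[-1])
        return None
    raise BudgetError(f"unknown crossover method {method!r}")


# ---------------------------------------------------------------------------
# config (de)serialization

def thermal_models_from_dict(cfg: Mapping) -> ThermalModelSet:
    """Build a ThermalModelSet from a plain mapping (YAML/TOML-friendly).

    Expected shape::

        body_mass_g: 0.0753
        label: my-models
        metabolic:            {intercept: ..., slope: ...}
        evaporative:          {intercept: ..., slope: ...}
        head_temperature:     {intercept: ..., slope: ...}
        thorax_temperature:   {intercept: ..., slope: ...}
        abdomen_temperature:  {intercept: ..., slope: ...}
    """
    def lin(name: str) -> LinearResponse:
        try:
            entry = cfg[name]
            return LinearResponse(float(entry["intercept"]), float(entry["slope"]))
        except (KeyError, TypeError) as exc:
            raise BudgetError(
                f"thermal model config missing coefficients for {name!r}"
            ) from exc

    return ThermalModelSet(
        metabolic=lin("metabolic"),
        evaporative=lin("evaporative"),
        head_temperature=lin("head_temperature"),
        thorax_temperature=lin("thorax_temperature"),
        abdomen_temperature=lin("abdomen_temperature"),
        body_mass_g=float(cfg.get("body_mass_g", 0.0753)),
        label=str(cfg.get("label", "unnamed")),
    )


def thermal_models_to_dict(models: ThermalModelSet) -> dict:
    def lin(r: LinearResponse) -> dict:
        return {"intercept": r.intercept, "slope": r.slope}

    return {
        "label": models.label,
        "body_mass_g": models.body_mass_g,
        "metabolic": lin(models.metabolic),
        "evaporative": lin(models.evaporative),
        "head_temperature": lin(models.head_temperature),
        "thorax_temperature": lin(models.thorax_temperature),
        "abdomen_temperature": lin(models.abdomen_temperature),
    }
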
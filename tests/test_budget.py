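"""Heat-budget routes, closure, error propagation and crossover."""

import numpy as np
import pandas as pd
import pytest

from beebudget.budget import (
    DEFAULT_GRID_C,
    BudgetError,
    LinearResponse,
    RadiativeConstants,
    TagmaSurfaceAreas,
    ThermalModelSet,
    apply_surface_correction,
    build_budget,
    convective_heat,
    evaporative_heat,
    find_crossover,
    metabolic_heat,
    net_radiative_tagma,
    regress_routes,
    thermal_models_from_dict,
    thermal_models_to_dict,
    whole_body_radiative,
)
from beebudget.synthetic import crossover_preset, default_tagma_areas, default_thermal_models

GRID = np.asarray(DEFAULT_GRID_C)


@pytest.fixture
def models():
    return default_thermal_models()


@pytest.fixture
def areas():
    return default_tagma_areas()


def test_metabolic_heat_is_mass_scaled(models):
    flat = ThermalModelSet(
        metabolic=LinearResponse(500.0, 0.0),
        evaporative=models.evaporative,
        head_temperature=models.head_temperature,
        thorax_temperature=models.thorax_temperature,
        abdomen_temperature=models.abdomen_temperature,
        body_mass_g=0.0753,
    )
    q = metabolic_heat(GRID, flat)
    assert np.allclose(q, 37.65)  # 500 mW/g * 0.0753 g, constant in T
    # hand evaluation of the default line at every grid point
    expected = (900.0 - 8.0 * GRID) * 0.0753
    assert np.allclose(metabolic_heat(GRID, models), expected)


def test_stefan_boltzmann_hand_check():
    """At 300 K on both sides with 1 m² the net longwave flux is
    0.98*0.90*sigma*300^4 - 0.98*sigma*300^4 ≈ -45.01 W."""
    t = 300.0 - 273.15
    net_mw = net_radiative_tagma(t, t, 1e6)  # 1 m² in mm²
    assert net_mw == pytest.approx(-45008.46, abs=1.0)
    gain = 0.98 * 0.90 * 5.67e-8 * 300 ** 4
    loss = 0.98 * 5.67e-8 * 300 ** 4
    assert net_mw / 1000 == pytest.approx(gain - loss, rel=1e-12)


def test_radiative_linearity_and_zero_area():
    assert net_radiative_tagma(25.0, 35.0, 0.0) == 0.0
    one = net_radiative_tagma(25.0, 35.0, 50.0)
    assert net_radiative_tagma(25.0, 35.0, 100.0) == pytest.approx(2 * one, rel=1e-14)


def test_radiative_sign_and_monotonicity():
    """Net radiation is negative whenever the body is at least as warm
    as the chamber (a = eps_S, eps_C < 1), decreases in body
    temperature and increases in air temperature."""
    t_air = np.linspace(0, 50, 26)
    assert (net_radiative_tagma(t_air, t_air, 100.0) < 0).all()
    assert (net_radiative_tagma(t_air, t_air + 5.0, 100.0) < 0).all()
    by_tx = net_radiative_tagma(25.0, np.linspace(20, 45, 20), 100.0)
    assert (np.diff(by_tx) < 0).all()
    by_ti = net_radiative_tagma(np.linspace(5, 45, 20), 30.0, 100.0)
    assert (np.diff(by_ti) > 0).all()


def test_subzero_kelvin_rejected():
    with pytest.raises(BudgetError):
        net_radiative_tagma(-300.0, 20.0, 1.0)


def test_whole_body_radiative_equals_tagma_loop(models, areas):
    total = whole_body_radiative(GRID, models, areas)
    loop = sum(
        net_radiative_tagma(GRID, temp(GRID), sa)
        for temp, sa in (
            (models.head_temperature, areas.head_mm2),
            (models.thorax_temperature, areas.thorax_mm2),
            (models.abdomen_temperature, areas.abdomen_mm2),
        )
    )
    assert np.allclose(total, loop, rtol=1e-14)


def test_convective_residual_closes_budget():
    assert convective_heat(10.0, -3.0, -2.0) == -5.0
    assert convective_heat(0.0, 0.0, 0.0) == 0.0


def test_budget_closure_machine_precision(models, areas):
    table = build_budget(models, areas)
    sums = table[["Q_M_mW", "Q_E_mW", "Q_R_mW", "Q_C_mW"]].sum(axis=1)
    assert (sums == 0.0).all()
    assert (table["Q_M_mW"] > 0).all()
    assert (table["Q_E_mW"] <= 0).all()
    assert len(table) == 7


def test_single_point_grid(models, areas):
    table = build_budget(models, areas, grid_c=[30.0])
    assert len(table) == 1


def test_body_at_air_temperature_radiates_net_loss(areas):
    """With tagma temperatures pinned to air and eps_C < 1, the chamber
    returns less than the body emits, so Q_R < 0 at every grid point."""
    pinned = ThermalModelSet(
        metabolic=LinearResponse(500.0, 0.0),
        evaporative=LinearResponse(10.0, 0.0),
        head_temperature=LinearResponse(0.0, 1.0),
        thorax_temperature=LinearResponse(0.0, 1.0),
        abdomen_temperature=LinearResponse(0.0, 1.0),
    )
    table = build_budget(pinned, areas)
    assert (table["Q_R_mW"] < 0).all()


def test_surface_correction_rescales_radiation_exactly(models, areas):
    fractions = {"head": 0.26424, "thorax": 0.44056}
    corrected = apply_surface_correction(areas, fractions)
    assert corrected.method == "3D-corrected"
    assert corrected.head_mm2 == pytest.approx(
        areas.head_mm2 / (1 - 0.26424), rel=1e-12
    )
    assert corrected.head_mm2 / areas.head_mm2 == pytest.approx(1.35914, abs=1e-4)
    assert corrected.abdomen_mm2 == areas.abdomen_mm2  # uncorrected tagma
    # Q_R is linear in SA: per-tagma fluxes rescale by (1-e)^-1 exactly
    t = 30.0
    q_head = net_radiative_tagma(t, models.head_temperature(t), areas.head_mm2)
    q_head_c = net_radiative_tagma(t, models.head_temperature(t), corrected.head_mm2)
    assert q_head_c == pytest.approx(q_head / (1 - 0.26424), rel=1e-12)


def test_identity_correction(areas):
    same = apply_surface_correction(areas, {})
    assert same.head_mm2 == areas.head_mm2
    with pytest.raises(BudgetError):
        apply_surface_correction(areas, {"head": 1.0})


def test_method_qc_difference_mirrors_qr_difference(models, areas):
    """Q_M and Q_E are method-independent, so between two SA methods
    the difference in Q_C equals minus the difference in Q_R exactly."""
    corrected = apply_surface_correction(areas, {"head": 0.264, "thorax": 0.441})
    a = build_budget(models, areas)
    b = build_budget(models, corrected)
    d_qc = b["Q_C_mW"].to_numpy() - a["Q_C_mW"].to_numpy()
    d_qr = b["Q_R_mW"].to_numpy() - a["Q_R_mW"].to_numpy()
    np.testing.assert_allclose(d_qc, -d_qr, rtol=1e-13)
    assert np.allclose(a["Q_M_mW"], b["Q_M_mW"])


def test_regress_routes_identical_methods_null(models, areas):
    a = build_budget(models, areas)
    b = a.copy()
    b["method"] = "clone"
    regs = regress_routes(pd.concat([a, b], ignore_index=True))
    for reg in regs.values():
        assert reg.interaction_f == pytest.approx(0.0, abs=1e-18)
        assert reg.slopes["geometric"] == pytest.approx(reg.slopes["clone"])


def test_regress_routes_recovers_constructed_slopes():
    t = np.asarray(DEFAULT_GRID_C)
    rows = []
    for method, slope, icpt in (("geometric", 0.3, -20.0), ("model", 0.5, -30.0)):
        rows.append(
            pd.DataFrame(
                {
                    "air_temperature_C": t,
                    "Q_M_mW": 40.0,
                    "Q_E_mW": -5.0,
                    "Q_R_mW": icpt + slope * t,
                    "Q_C_mW": -(40.0 - 5.0 + icpt + slope * t),
                    "method": method,
                }
            )
        )
    regs = regress_routes(pd.concat(rows, ignore_index=True))
    qr = regs["Q_R"]
    assert qr.slopes["geometric"] == pytest.approx(0.3, abs=1e-12)
    assert qr.slopes["model"] == pytest.approx(0.5, abs=1e-12)
    assert qr.intercepts["model"] == pytest.approx(-30.0, abs=1e-10)
    assert qr.interaction_f > 1e6  # exactly linear series, huge F
    assert qr.interaction_p < 1e-10


def test_anova_matches_sum_of_squares_oracle(models, areas):
    """Interaction F agrees with a brute-force nested-model SS
    decomposition: F = (RSS_reduced - RSS_full)/q / (RSS_full/df)."""
    corrected = apply_surface_correction(areas, {"head": 0.3})
    data = pd.concat(
        [build_budget(models, areas), build_budget(models, corrected)],
        ignore_index=True,
    )
    regs = regress_routes(data)
    qr = regs["Q_R"]
    t = data["air_temperature_C"].to_numpy()
    y = data["Q_R_mW"].to_numpy()
    m = (data["method"] == data["method"].unique()[1]).to_numpy().astype(float)
    X_full = np.column_stack([np.ones_like(t), t, m, t * m])
    X_red = X_full[:, :3]

    def rss(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    df_resid = len(y) - X_full.shape[1]
    f_brute = (rss(X_red) - rss(X_full)) / 1 / (rss(X_full) / df_resid)
    assert qr.interaction_f == pytest.approx(f_brute, rel=1e-6)


def test_mismatched_grids_rejected(models, areas):
    a = build_budget(models, areas)
    b = build_budget(models, apply_surface_correction(areas, {"head": 0.2}),
                     grid_c=[20, 30, 40, 50, 60, 70, 80])
    with pytest.raises(BudgetError, match="grids"):
        regress_routes(pd.concat([a, b], ignore_index=True))


def test_crossover_exact_lines():
    # magnitude lines |Q| = 2T - 60 and |Q| = T - 25 meet at T = 35;
    # the grid keeps both positive so the magnitudes are the lines
    t = np.linspace(31, 50, 7)
    a = 2 * t - 60.0
    b = t - 25.0
    assert find_crossover(a, b, t) == pytest.approx(35.0, abs=1e-10)
    assert find_crossover(a, b, t, method="interpolated") == pytest.approx(35.0)
    # parallel lines never cross
    assert find_crossover(t + 1.0, t + 5.0, t) is None


def test_crossover_preset_hits_target(areas):
    for target in (35.0, 28.0):
        preset = crossover_preset(target)
        table = build_budget(preset, areas)
        x = find_crossover(
            table["Q_C_mW"], table["Q_R_mW"], table["air_temperature_C"]
        )
        assert x == pytest.approx(target, abs=0.01)
        # dominance flips at the crossover: convection dominates below,
        # radiation above (on the fitted lines)
        qc = np.abs(np.polyval(np.polyfit(GRID, np.abs(table["Q_C_mW"]), 1),
                               [target - 3, target + 3]))
        qr = np.abs(np.polyval(np.polyfit(GRID, np.abs(table["Q_R_mW"]), 1),
                               [target - 3, target + 3]))
        assert qc[0] > qr[0] and qc[1] < qr[1]


def test_thermal_model_config_round_trip(models):
    cfg = thermal_models_to_dict(models)
    back = thermal_models_from_dict(cfg)
    assert back == models
    with pytest.raises(BudgetError, match="missing"):
        thermal_models_from_dict({"metabolic": {"intercept": 1.0}})


def test_plausibility_warning_for_wild_temperatures():
    wild = ThermalModelSet(
        metabolic=LinearResponse(500.0, 0.0),
        evaporative=LinearResponse(10.0, 0.0),
        head_temperature=LinearResponse(80.0, 1.0),  # way above 60 C
        thorax_temperature=LinearResponse(30.0, 0.2),
        abdomen_temperature=LinearResponse(20.0, 0.5),
    )
    warnings = wild.check_plausible()
    assert any("head" in w for w in warnings)


def test_invalid_constants_rejected():
    with pytest.raises(BudgetError):
        RadiativeConstants(absorptivity=1.5)
    with pytest.raises(BudgetError):
        TagmaSurfaceAreas(0.0, 1.0, 1.0)
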
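"""Core PBPK model: kinetic primitives, closed-form oracles, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanopbpk import (
    AUC_OUTPUTS,
    ExposureScenario,
    InvalidParameterError,
    NanoKineticParams,
    Route,
    TISSUES,
    default_params,
    deposited_dose,
    dose_metrics,
    make_scenario,
    simulate,
    uptake_rate,
)

from conftest import inert_params


class TestUptakeRate:
    @pytest.mark.parametrize(
        "a_tissue, a_pc, k_max, a_cap, expected",
        [
            (5.0, 3.0, 0.7, 3.0, 0.0),  # saturated capacity
            (2.0, 0.0, 0.5, 3.0, 1.0),  # unoccupied capacity
            (2.0, 1.5, 0.5, 3.0, 0.5),  # half-filled capacity
            (0.0, 0.0, 0.5, 3.0, 0.0),  # nothing to take up
            (2.0, 6.0, 0.5, 3.0, 0.0),  # over-capacity clamps at zero
        ],
    )
    def test_saturating_form(self, a_tissue, a_pc, k_max, a_cap, expected):
        assert uptake_rate(a_tissue, a_pc, k_max, a_cap) == pytest.approx(expected)

    def test_invalid_capacity_rejected(self):
        with pytest.raises(InvalidParameterError):
            uptake_rate(1.0, 0.0, 0.5, 0.0)
        with pytest.raises(InvalidParameterError):
            uptake_rate(-1.0, 0.0, 0.5, 1.0)

    @given(
        a_tissue=st.floats(0, 1e3),
        frac=st.floats(0, 2),
        k_max=st.floats(0, 100),
        a_cap=st.floats(1e-6, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_rate_bounded_and_nonnegative(self, a_tissue, frac, k_max, a_cap):
        rate = uptake_rate(a_tissue, frac * a_cap, k_max, a_cap)
        assert 0.0 <= rate <= k_max * a_tissue + 1e-9


class TestDepositedDose:
    def test_direct_product(self):
        assert deposited_dose(1.1, 12, 2, 0.5) == pytest.approx(13.2)

    def test_zero_deposition(self):
        assert deposited_dose(1.1, 12, 2, 0.0) == 0.0

    def test_linear_in_duration(self):
        assert deposited_dose(1.1, 12, 4, 0.5) == pytest.approx(
            2 * deposited_dose(1.1, 12, 2, 0.5)
        )

    def test_fraction_above_one_rejected(self):
        with pytest.raises(InvalidParameterError):
            deposited_dose(1.0, 1.0, 1.0, 1.5)


class TestClosedFormOracles:
    def test_oral_gi_lumen_single_exponential(self, phys):
        """With only fecal elimination, the GI lumen is a single-exponential
        decay: A(t) = D e^{-k t}, cum feces = D (1 - e^{-k t})."""
        k, dose = 0.25, 8.0
        params = inert_params(k_feces=k)
        times = np.linspace(0.5, 30, 12)
        sc = make_scenario("oral", dose, times)
        traj = simulate(phys, params, sc)
        t = traj.times
        np.testing.assert_allclose(
            traj.amount("gi_lumen"), dose * np.exp(-k * t), rtol=1e-6, atol=1e-8
        )
        np.testing.assert_allclose(
            traj.amount("cum_feces"), dose * (1 - np.exp(-k * t)), rtol=1e-6, atol=1e-8
        )

    def test_it_catenary_chain_bateman(self, phys):
        """IT bolus with only mucociliary transfer and fecal elimination is a
        two-compartment catenary chain with the Bateman solution."""
        k1, k2, dose = 0.4, 0.15, 5.0
        params = inert_params(k_mucociliary=k1, k_feces=k2)
        times = np.linspace(0.5, 40, 15)
        sc = make_scenario("it", dose, times)
        traj = simulate(phys, params, sc)
        t = traj.times
        lung_lumen = dose * np.exp(-k1 * t)
        gi_lumen = dose * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
        np.testing.assert_allclose(traj.amount("lung_lumen"), lung_lumen, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(traj.amount("gi_lumen"), gi_lumen, rtol=1e-6, atol=1e-8)
        feces = dose - lung_lumen - gi_lumen
        np.testing.assert_allclose(traj.amount("cum_feces"), feces, rtol=1e-6, atol=1e-8)

    def test_equilibrium_distribution(self, phys):
        """No uptake/excretion, unit distribution coefficients, permeable
        membranes: every concentration converges to dose / total volume."""
        dose = 10.0
        params = inert_params(permeability={t: 0.5 for t in TISSUES})
        sc = make_scenario("iv", dose, [2000.0])
        traj = simulate(phys, params, sc)
        v_total = sum(phys.tissue_volumes.values())
        c_eq = dose / v_total
        c_blood = traj.amount("systemic_blood")[-1] / phys.tissue_volumes["blood"]
        assert c_blood == pytest.approx(c_eq, rel=1e-6)
        for t in TISSUES:
            vcap = phys.capillary_blood_fraction[t] * phys.tissue_volumes[t]
            vtis = (1 - phys.capillary_blood_fraction[t]) * phys.tissue_volumes[t]
            assert traj.amount(f"{t}_capillary")[-1] / vcap == pytest.approx(c_eq, rel=1e-6)
            assert traj.amount(f"{t}_tissue")[-1] / vtis == pytest.approx(c_eq, rel=1e-6)

    def test_gi_tissue_absorption_auc_closed_form(self, phys):
        """Oral dose absorbed into an exit-free GI tissue: the tissue AUC over
        [0, T] equals D/V * (T - (1 - e^{-ka T})/ka) exactly."""
        ka, dose, T = 0.8, 6.0, 24.0
        params = inert_params(k_gi_abs=ka)
        sc = make_scenario("oral", dose, [T])
        traj = simulate(phys, params, sc)
        v_gi = phys.tissue_volumes["gi"]
        expected = dose / v_gi * (T - (1 - np.exp(-ka * T)) / ka)
        assert traj.auc("gi", T) == pytest.approx(expected, rel=1e-6)


class TestConservationAndLinearity:
    @pytest.mark.parametrize("route", ["iv", "oral", "it", "ih"])
    def test_mass_balance_all_routes(self, phys, route):
        size = 23.0 if route == "ih" else 5.0
        params = default_params(size, route)
        times = [2, 4, 24, 168, 672] if route == "ih" else [1, 3, 24]
        sc = make_scenario(route, 20.1 if route == "ih" else 10.0, times)
        traj = simulate(phys, params, sc)
        assert traj.mass_balance_error() < 1e-3

    def test_iv_no_excretion_conserves_dose(self, phys, params_iv):
        params = params_iv.copy()
        for name in ("k_urine", "k_bile", "k_feces"):
            params = params.with_value(name, 0.0)
        sc = make_scenario("iv", 10.0, [1, 6, 24])
        traj = simulate(phys, params, sc)
        total = traj.total_mass()
        np.testing.assert_allclose(total, 10.0, rtol=1e-6)
        assert traj.amount("cum_urine")[-1] == 0.0

    def test_zero_dose_gives_zero_trajectory(self, phys, params_iv):
        sc = ExposureScenario(route=Route.IH, dose_ug=0.0, duration_h=2.0,
                              sim_end_h=24.0, output_times=(1.0, 24.0))
        traj = simulate(phys, params_iv, sc)
        assert np.all(traj.states == 0.0)

    def test_linearity_in_infinite_capacity_regime(self, phys, params_iv):
        params = params_iv.copy()
        for t in TISSUES:
            params.a_cap[t] = 1e12
        sc1 = make_scenario("iv", 5.0, [1, 24])
        sc2 = make_scenario("iv", 10.0, [1, 24])
        tr1 = simulate(phys, params, sc1)
        tr2 = simulate(phys, params, sc2)
        mask = np.abs(tr2.states) > 1e-12
        np.testing.assert_allclose(tr2.states[mask], 2 * tr1.states[mask], rtol=1e-6)

    def test_cumulative_excretion_monotone(self, phys):
        params = default_params(5.0, "it")
        sc = make_scenario("it", 12.0, np.linspace(0.5, 48, 30))
        traj = simulate(phys, params, sc)
        for label in ("cum_urine", "cum_feces", "cum_bile"):
            assert np.all(np.diff(traj.amount(label)) >= -1e-10)

    def test_nonnegative_states(self, phys):
        params = default_params(1.4, "iv")
        sc = make_scenario("iv", 3.2, np.linspace(0.1, 24, 40))
        traj = simulate(phys, params, sc)
        assert traj.states.min() >= -1e-8


class TestAUCAccumulator:
    def test_matches_trapezoid_on_refined_grid(self, phys, params_iv):
        """Integrated AUC states agree with trapezoidal integration of the
        concentration curve on a 10x refined grid within 0.1%."""
        times = np.unique(np.concatenate(
            [np.geomspace(1e-3, 0.5, 120), np.linspace(0.5, 24, 471)]
        ))
        sc = make_scenario("iv", 10.0, times)
        traj = simulate(phys, params_iv, sc)
        t = traj.times
        for tissue in AUC_OUTPUTS:
            if tissue == "blood":
                conc = traj.amount("systemic_blood") / phys.tissue_volumes["blood"]
            else:
                conc = (
                    traj.amount(f"{tissue}_capillary")
                    + traj.amount(f"{tissue}_tissue")
                    + traj.amount(f"{tissue}_pc")
                ) / phys.tissue_volumes[tissue]
            trapz = np.trapezoid(conc, t)
            assert traj.auc(tissue, t[-1]) == pytest.approx(trapz, rel=1e-3)


class TestDoseMetrics:
    def test_pct_id_conservation(self, phys):
        """%ID summed over all observables plus excreta equals 100."""
        params = default_params(5.0, "oral")
        sc = make_scenario("oral", 10.0, [1, 24])
        traj = simulate(phys, params, sc)
        m = dose_metrics(traj, sc, windows=(24.0,))
        for t in (1.0, 24.0):
            total = sum(m.pct_id[(obs, t)] for obs in
                        ("blood",) + TISSUES + ("urine", "feces"))
            assert total == pytest.approx(100.0, rel=1e-6)

    def test_window_beyond_horizon_raises(self, phys, params_iv):
        sc = make_scenario("iv", 10.0, [1, 24])
        traj = simulate(phys, params_iv, sc)
        with pytest.raises(ValueError, match="window"):
            dose_metrics(traj, sc, windows=(672.0,))

    def test_auc_window_nesting(self, phys):
        params = default_params(23.0, "ih")
        sc = make_scenario("ih", 20.1, [24, 672])
        traj = simulate(phys, params, sc, extra_times=(24.0, 672.0))
        m = dose_metrics(traj, sc)
        for tissue in AUC_OUTPUTS:
            assert m.auc[(tissue, 672.0)] >= m.auc[(tissue, 24.0)] >= 0.0

    def test_ih_pct_ipld_normalizer(self, phys):
        params = default_params(23.0, "ih")
        sc = make_scenario(
            "ih", None, [4, 24], aerosol_conc=1.1, minute_ventilation=9.1,
            deposition_fraction=0.5, duration_h=2.0, peripheral_fraction=0.8,
        )
        assert sc.administered_dose == pytest.approx(1.1 * 9.1 * 2 * 0.5)
        traj = simulate(phys, params, sc)
        m = dose_metrics(traj, sc, windows=())
        ratio = m.pct_ipld[("lung", 4.0)] / m.pct_id[("lung", 4.0)]
        assert ratio == pytest.approx(1 / 0.8, rel=1e-9)


class TestScenarioValidation:
    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError, match="route"):
            make_scenario("subcutaneous", 1.0, [1.0])

    def test_missing_bolus_dose_rejected(self):
        with pytest.raises(ValueError, match="dose"):
            ExposureScenario(route=Route.IV, dose_ug=None, output_times=(1.0,))

    def test_ih_requires_dose_or_aerosol(self):
        with pytest.raises(ValueError, match="IH requires"):
            ExposureScenario(route=Route.IH, output_times=(1.0,))
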
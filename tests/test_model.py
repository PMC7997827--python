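"""Reference-model simulation: dilution, conservation, gas summaries."""

import numpy as np
import pandas as pd
import pytest

from mdoe.errors import InvalidParameterError, ModelEvaluationError
from mdoe.feeds import FeedSchedule
from mdoe.model import (
    Environment,
    ProcessState,
    Trajectory,
    respiratory_quotient,
    simulate,
    volume_balance_error,
)
from mdoe.scenario import Scenario
from mdoe.synthetic import s1_scenario


def make_initial(**over):
    base = {
        "c_Glc": 10.0,
        "c_EtOH": 2.0,
        "c_N": 1.0,
        "c_EAA": 0.0,
        "c_E3HB": 0.0,
        "X_pri": 1.0,
        "X_p": 0.0,
        "X_i": 0.1,
        "X_s": 0.4,
        "X_si": 0.1,
        "X_d": 0.1,
        "V_l": 1.5,
        "nO2_mol": 0.0,
        "nCO2_mol": 0.0,
    }
    base.update(over)
    return base


class TestSimulateDegenerate:
    def test_zero_rates_no_feeds_constant_trajectory(self, ref_model, zero_rate_params):
        traj = simulate(
            ref_model, zero_rate_params, make_initial(), feeds=(),
            t_grid=np.linspace(0, 24, 25),
        )
        for col in ("c_Glc", "c_EtOH", "X_pri", "V_l"):
            np.testing.assert_allclose(
                traj.series(col), traj.series(col)[0], rtol=1e-9, atol=1e-10
            )

    def test_pure_dilution_matches_closed_form(self, ref_model, zero_rate_params):
        """Water feed with zeroed kinetics: c(t) = c0 * V0 / V(t)."""
        water = FeedSchedule("water", "constant", composition={}, t_start=0.0, t_end=48.0, F=2.0)
        t_grid = np.linspace(0, 48, 49)
        traj = simulate(
            ref_model, zero_rate_params, make_initial(), feeds=(water,), t_grid=t_grid,
            rtol=1e-9, atol=1e-12,
        )
        v0 = 1.5
        v_t = v0 + 2.0 * 0.06 * t_grid
        np.testing.assert_allclose(traj.series("V_l"), v_t, rtol=1e-9)
        for col, c0 in (("c_Glc", 10.0), ("c_EtOH", 2.0), ("X_pri", 1.0)):
            np.testing.assert_allclose(traj.series(col), c0 * v0 / v_t, rtol=1e-6)

    def test_feed_of_component_reaches_feed_concentration(self, ref_model, zero_rate_params):
        """With no reactions, a fed component converges toward c_feed."""
        feed = FeedSchedule("glc", "constant", composition={"Glc": 100.0}, t_start=0.0, t_end=48.0, F=5.0)
        traj = simulate(
            ref_model, zero_rate_params, make_initial(c_Glc=0.0), feeds=(feed,),
            t_grid=np.linspace(0, 48, 25),
        )
        glc = traj.series("c_Glc")
        assert np.all(np.diff(glc) > 0)
        assert glc[-1] < 100.0
        # closed form: c(t) = c_feed * (1 - V0/V(t))
        v_t = traj.series("V_l")
        np.testing.assert_allclose(glc, 100.0 * (1 - 1.5 / v_t), rtol=1e-6)


class TestSimulateS1:
    def test_volume_balance_closes(self, s1_trajectory):
        sc, traj = s1_trajectory
        assert volume_balance_error(traj) <= 1e-6 * 1.5

    def test_carbon_balance_closes(self, s1_trajectory):
        sc, traj = s1_trajectory
        assert sc.model.carbon_balance_error(traj) <= 1e-5

    def test_dcw_monotone_below_ethanol_inhibition(self, s1_trajectory):
        sc, traj = s1_trajectory
        etoh = traj.series("c_EtOH")
        assert etoh.max() < sc.params["EtOH_inhib_50"]
        dcw = traj.series("c_DCW")
        assert np.all(np.diff(dcw) > -1e-6)

    def test_concentrations_never_negative(self, s1_trajectory):
        _, traj = s1_trajectory
        cols = [c for c in traj.data.columns if c != "time_h"]
        assert (traj.data[cols].to_numpy() >= 0).all()

    def test_pulse_feed_conserves_mass(self, ref_model, zero_rate_params):
        pulse = FeedSchedule(
            "pulse", "pulses", composition={"Glc": 500.0}, t_start=0.0, t_end=48.0,
            pulses=((24.0, 0.05),),
        )
        traj = simulate(
            ref_model, zero_rate_params, make_initial(), feeds=(pulse,),
            t_grid=np.linspace(0, 48, 97),
        )
        v = traj.series("V_l")
        assert v[-1] == pytest.approx(1.55, rel=1e-9)
        glc_mass = traj.series("c_Glc") * v
        assert glc_mass[-1] == pytest.approx(10.0 * 1.5 + 500.0 * 0.05, rel=1e-6)


class TestRespiratoryQuotient:
    @staticmethod
    def gas_traj(o2, co2, times):
        frame = pd.DataFrame({"time_h": times, "nO2_mol": o2, "nCO2_mol": co2})
        return Trajectory(data=frame)

    def test_equal_moles_give_unity(self):
        t = np.array([0.0, 1.0, 2.0])
        traj = self.gas_traj([0.0, 2.0, 4.0], [0.0, 2.0, 4.0], t)
        rq = respiratory_quotient(traj, window=1.0)
        np.testing.assert_allclose(rq["RQ"].iloc[1:], 1.0)

    def test_fermentation_window_is_undefined(self):
        t = np.array([0.0, 1.0, 2.0])
        traj = self.gas_traj([0.0, 0.0, 0.0], [0.0, 1.0, 2.0], t)
        rq = respiratory_quotient(traj, window=1.0)
        assert rq["RQ"].iloc[1:].isna().all()

    def test_oxidative_growth_rq_matches_pathway_stoichiometry(self, s1_trajectory):
        """Simulated cumulative RQ approaches CO2/O2 of the balanced pathways."""
        sc, traj = s1_trajectory
        pw = sc.model.pathways(sc.params.values)["ox"]
        rq_ox = pw.nu["CO2"] / pw.nu["O2"]
        rq = respiratory_quotient(traj, cumulative=True)["RQ"].iloc[-1]
        # growth is overwhelmingly oxidative in the nominal S1 run
        assert rq == pytest.approx(rq_ox, rel=0.05)

    def test_full_oxidation_pathway_rq_is_one(self, ref_model):
        """Complete glucose combustion produces 6 CO2 per 6 O2."""
        from mdoe.stoichiometry import CO2, GLUCOSE, OXYGEN, WATER, PathwayStoichiometry, balance_pathway

        pw = balance_pathway(
            PathwayStoichiometry(
                name="combustion",
                substrate=GLUCOSE,
                species=((OXYGEN, "O2"), (CO2, "CO2"), (WATER, "H2O")),
                nu={"O2": None, "CO2": None, "H2O": None},
            )
        )
        assert pw.nu["CO2"] / pw.nu["O2"] == pytest.approx(1.0, abs=1e-12)


class TestContracts:
    def test_non_monotone_grid_rejected(self, ref_model, zero_rate_params):
        with pytest.raises(InvalidParameterError):
            simulate(ref_model, zero_rate_params, make_initial(), t_grid=[0.0, 2.0, 1.0])

    def test_missing_initial_state_rejected(self, ref_model, zero_rate_params):
        with pytest.raises(InvalidParameterError):
            simulate(ref_model, zero_rate_params, {"c_Glc": 1.0}, t_grid=[0.0, 1.0])

    def test_process_state_invariants(self):
        with pytest.raises(InvalidParameterError):
            ProcessState(concentrations={"Glc": -1.0}, compartments={}, V=1.0)
        with pytest.raises(InvalidParameterError):
            ProcessState(concentrations={}, compartments={}, V=0.0)
        s = ProcessState(
            concentrations={"Glc": 1.0},
            compartments={"X_pri": 1.0, "X_p": 0.5, "X_i": 0.0, "X_s": 0.25, "X_si": 0.0, "X_d": 0.25},
            V=1.0,
        )
        assert s.c_DCW == pytest.approx(2.0)

    def test_environment_invariants(self):
        with pytest.raises(InvalidParameterError):
            Environment(pH=0.0)
        with pytest.raises(InvalidParameterError):
            Environment(DO=120.0)

    def test_non_finite_derivative_reported(self, ref_model):
        class BrokenModel:
            name = "broken"
            state_names = ("a", "V_l")

            def default_parameters(self):
                raise NotImplementedError

            def rhs(self, t, y, params, feeds, env):
                return np.array([np.nan, 0.0])

            def derived_observables(self, frame):
                return frame

        with pytest.raises(ModelEvaluationError, match="a"):
            simulate(BrokenModel(), {}, {"a": 1.0, "V_l": 1.0}, t_grid=[0.0, 1.0])
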
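import numpy as np
import pytest
from dataclasses import replace

from diefill import (
    AirProperties,
    DomainError,
    FillCam,
    MachineConfig,
    PressureModelSpec,
    SyntheticScenario,
    UsageError,
    build_rotary_profile,
    compare_scenarios,
    convergence_error,
    fixed_step_max_delta_p,
    model_constant,
    pressure_rhs,
    solve_pressure,
    stationary_delta_p,
)

P_ATM = 101325.0


def _spec(materials, name="DCP", machine="rotary_press", cam="conventional",
          nt=20.0, **overrides):
    scen = SyntheticScenario(material=name, machine=machine, cam=cam, turret_speed=nt)
    return scen.pressure_spec(**overrides)


class TestAirProperties:
    def test_default_density_is_ideal_gas_consistent(self, air):
        rho = air.ambient_pressure * air.molar_mass / (air.gas_constant * air.temperature)
        assert air.density == pytest.approx(rho)
        assert air.density == pytest.approx(1.20, abs=0.02)

    def test_inconsistent_density_rejected(self):
        with pytest.raises(DomainError):
            AirProperties(density=2.0)


class TestModelConstant:
    def test_collapses_to_permeability_form(self, air):
        """With ideal-gas density, c = K * p_atm / (eta * L)."""
        K, L = 5.20e-12, 0.006
        c = model_constant(K, L, air)
        assert c == pytest.approx(K * P_ATM / (1.8e-5 * L), rel=1e-12)
        assert c == pytest.approx(4.88, abs=0.01)

    def test_scaling_in_K_and_L(self, air):
        c = model_constant(1e-12, 0.01, air)
        assert model_constant(2e-12, 0.01, air) == pytest.approx(2 * c)
        assert model_constant(2e-12, 0.02, air) == pytest.approx(c)

    def test_negative_K_rejected_but_zero_allowed(self, air):
        with pytest.raises(DomainError):
            model_constant(-1e-12, 0.01, air)
        assert model_constant(0.0, 0.01, air) == 0.0


class TestStationaryDeltaP:
    def test_limits(self):
        assert stationary_delta_p(0.0, 1.0) == 0.0
        assert stationary_delta_p(0.1, 1e9) == pytest.approx(0.0, abs=1e-2)

    def test_fixed_point_of_rhs(self, materials):
        spec = _spec(materials, "LAC", nt=20.0)
        v = spec.profile.velocity(0.0)
        p_star = spec.c * P_ATM / (spec.c + v)
        assert pressure_rhs(0.1, p_star, spec) == pytest.approx(0.0, abs=1e-6)

    def test_lac_to_dcp_ratio_on_rotary_press(self, air, materials):
        """Low-permeability LAC sustains ~7.5x the suction pressure of DCP."""
        v, L = 0.15, 0.006
        dps = {
            name: stationary_delta_p(v, model_constant(materials[name].permeability, L, air))
            for name in ("LAC", "DCP")
        }
        assert dps["LAC"] / dps["DCP"] == pytest.approx(7.5, rel=0.10)


class TestPressureRhs:
    def test_equilibrium_at_ambient_with_no_motion(self, materials):
        scen = SyntheticScenario(material="DCP", machine="rotary_press",
                                 cam="stearate", turret_speed=20.0)
        spec = scen.pressure_spec()
        # v = 0 cannot occur on the rotary profile; check the algebra directly
        h = spec.h0 + spec.profile.displacement(0.1)
        assert spec.c * (P_ATM - P_ATM) == 0.0
        rhs = pressure_rhs(0.1, P_ATM, spec)
        v = spec.profile.velocity(0.1)
        assert rhs == pytest.approx(-P_ATM * v / h, rel=1e-12)
        assert rhs < 0.0  # pressure initially falls


class TestSolvePressure:
    def test_output_grid_and_initial_condition(self, materials):
        spec = _spec(materials, "DCP")
        curve = solve_pressure(spec)
        assert len(curve.times) == 300
        assert curve.times[0] == pytest.approx(spec.t_start)
        assert curve.times[-1] == pytest.approx(spec.profile.duration)
        assert curve.delta_p[0] <= spec.rtol * P_ATM
        assert np.all(curve.delta_p >= 0.0) and np.all(curve.delta_p <= P_ATM)

    def test_constant_velocity_monotone_and_bounded_by_fixed_point(self, materials):
        spec = _spec(materials, "LAC", nt=20.0)
        curve = solve_pressure(spec)
        assert np.all(np.diff(curve.delta_p) >= -1e-6 * curve.max_delta_p)
        assert curve.max_delta_p <= curve.stationary_delta_p * (1 + 1e-6)
        assert curve.max_delta_p == pytest.approx(curve.stationary_delta_p, rel=1e-3)

    def test_boyles_law_with_sealed_bed(self, materials):
        """K = 0: no air enters, so p * (h0 + h) is conserved along the curve."""
        scen = SyntheticScenario(material="DCP", machine="rotary_press",
                                 cam="stearate", turret_speed=20.0)
        spec = scen.pressure_spec(permeability=0.0)
        curve = solve_pressure(spec)
        h = spec.h0 + spec.profile.displacement(curve.times)
        conserved = P_ATM * (spec.h0 + spec.profile.displacement(spec.t_start))
        assert np.max(np.abs(curve.pressure * h - conserved)) / conserved < 10 * spec.rtol
        # equals p_atm * h0 up to the t_start geometric offset
        assert np.max(np.abs(curve.pressure * h - P_ATM * spec.h0)) / (
            P_ATM * spec.h0
        ) < 1e-5

    def test_K_L_coscaling_leaves_solution_unchanged(self, materials):
        spec = _spec(materials, "MCC")
        base = solve_pressure(spec)
        mat = replace(spec.material, permeability=spec.material.permeability * 3.0)
        machine = MachineConfig(
            machine="rotary_press",
            turret_speed=spec.machine.turret_speed,
            powder_bed_height=spec.machine.powder_bed_height * 3.0,
        )
        scaled = solve_pressure(replace(spec, material=mat, machine=machine))
        assert scaled.max_delta_p == pytest.approx(base.max_delta_p, rel=1e-6)

    def test_simulator_curve_follows_velocity_profile_shape(self, materials):
        """Delta_p rises during acceleration, plateaus, and decays in deceleration."""
        spec = _spec(materials, "MCC", machine="compaction_simulator", nt=20.0)
        curve = solve_pressure(spec)
        T = spec.profile.duration
        mid = curve.delta_p[(curve.times > 0.35 * T) & (curve.times < 0.65 * T)]
        end = curve.delta_p[-1]
        assert curve.delta_p[10] < mid.mean()
        assert end < 0.2 * mid.mean()  # decays as the punch decelerates

    def test_stearate_full_travel_reproduces_conventional_stationary_dp(self, materials):
        """Giving the stearate cam the full 16 mm travel restores the
        conventional cam's stationary suction pressure."""
        nt = 20.0
        machine = MachineConfig("rotary_press", nt)
        conv = SyntheticScenario(material="MCC", cam="conventional",
                                 turret_speed=nt).pressure_spec()
        cam_full = FillCam("stearate", filling_height=16.0e-3 + 4.7e-3)
        prof = build_rotary_profile(cam_full, machine)
        ste = PressureModelSpec(
            material=conv.material, cam=cam_full, machine=machine, profile=prof
        )
        c_conv = solve_pressure(conv)
        c_ste = solve_pressure(ste)
        assert c_ste.stationary_delta_p == pytest.approx(c_conv.stationary_delta_p)
        assert c_ste.max_delta_p == pytest.approx(c_conv.max_delta_p, rel=1e-3)


class TestConvergence:
    def test_error_small_at_default_tolerances(self, materials):
        spec = _spec(materials, "LAC")
        assert convergence_error(spec) <= 1e-3

    def test_error_nonincreasing_with_tighter_rtol(self, materials):
        errors = []
        for rtol, atol in [(1e-4, 1e-6), (1e-6, 1e-8), (1e-8, 1e-10)]:
            spec = _spec(materials, "MCC", machine="compaction_simulator",
                         rtol=rtol, atol=atol)
            errors.append(convergence_error(spec))
        assert errors[0] >= errors[1] - 1e-12
        assert errors[1] >= errors[2] - 1e-12

    def test_looser_reference_rejected(self, materials):
        spec = _spec(materials, "DCP")
        with pytest.raises(UsageError):
            convergence_error(spec, ref_rtol=1e-3, ref_atol=1e-4)


class TestFixedStepOracle:
    @pytest.mark.parametrize("name, cam", [("DCP", "conventional"), ("LAC", "stearate")])
    def test_agrees_with_radau_on_rotary(self, materials, name, cam):
        spec = _spec(materials, name, cam=cam, nt=60.0)
        oracle = fixed_step_max_delta_p(spec, dt=1e-6)
        assert solve_pressure(spec).max_delta_p == pytest.approx(oracle, rel=5e-3)

    def test_agrees_with_radau_on_simulator(self, materials):
        spec = _spec(materials, "MCC", machine="compaction_simulator", nt=60.0)
        oracle = fixed_step_max_delta_p(spec, dt=1e-6)
        assert solve_pressure(spec).max_delta_p == pytest.approx(oracle, rel=5e-3)


class TestCompareScenarios:
    def test_cam_and_material_orderings(self, materials):
        specs = [
            _spec(materials, "MCC", cam="conventional", nt=20.0),
            _spec(materials, "MCC", cam="stearate", nt=20.0),
            _spec(materials, "LAC", cam="stearate", nt=20.0),
        ]
        df = compare_scenarios(specs, labels=["mcc_conv", "mcc_ste", "lac_ste"])
        assert df.loc["mcc_ste", "max_delta_p_pa"] < df.loc["mcc_conv", "max_delta_p_pa"]
        assert df.loc["mcc_ste", "rise_time_s"] > df.loc["mcc_conv", "rise_time_s"]
        # the air-pocket buffer empties more slowly for the low-permeability material
        assert df.loc["lac_ste", "rise_time_s"] > df.loc["mcc_ste", "rise_time_s"]
        assert df.loc["mcc_conv", "ratio_vs_mcc_conv"] == pytest.approx(1.0)

    def test_requires_two_scenarios(self, materials):
        with pytest.raises(UsageError):
            compare_scenarios([_spec(materials, "DCP")])


def test_mass_balance_along_solution(materials, air):
    """d(pV)/dt equals R*T times the Darcy molar inflow along the curve."""
    spec = _spec(materials, "LAC", cam="stearate", nt=20.0)
    curve = solve_pressure(spec)
    t = curve.times
    A = spec.machine.die.area
    V = A * (spec.h0 + spec.profile.displacement(t))
    pv = curve.pressure * V
    dpv_dt = np.gradient(pv, t)
    rho, M = air.density, air.molar_mass
    n_dot = spec.K * A * rho / (air.dynamic_viscosity * spec.machine.powder_bed_height * M) * (
        P_ATM - curve.pressure
    )
    rhs = air.gas_constant * air.temperature * n_dot
    interior = slice(5, -5)  # endpoints suffer one-sided differences
    scale = np.max(np.abs(rhs[interior]))
    assert np.allclose(dpv_dt[interior], rhs[interior], atol=0.02 * scale)
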
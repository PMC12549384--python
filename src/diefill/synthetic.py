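"""Synthetic punch reports and tablet-weight datasets with known ground truth.

No raw instrumentation or weight data is published for the reference
study, so every pipeline input is generated here with controllable ground
truth: punch reports are the scenario's velocity profile sampled at the
instrumentation rate with white Gaussian velocity noise, and tablet
weights follow a saturating yield model in which the mean filling yield
responds to the peak suction pressure and to the paddle-driven powder
supply. All draws are deterministic given the scenario seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, UsageError
from .filling import FillingExperiment, theoretical_tablet_mass
from .kinematics import (
    PADDLE_SPOKES,
    CamKind,
    DieGeometry,
    FillCam,
    MachineConfig,
    MachineKind,
    PunchReport,
    VelocityProfile,
    build_rotary_profile,
    build_simulator_profile,
    linear_pull_down_velocity,
    pull_down_time,
)
from .materials import PowderMaterial
from .suction import AirProperties, PressureModelSpec, solve_pressure

#: Instrumentation acquisition frequency, Hz.
SAMPLING_RATE_HZ = 2000.0
#: Turret speeds of the full experimental design, min^-1.
TURRET_SPEEDS = (20.0, 30.0, 40.0, 50.0, 60.0)
#: Paddle speeds per machine, min^-1 (the simulator sets them in 3 min^-1 steps).
PADDLE_SPEEDS = {
    "rotary_press": (5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
    "compaction_simulator": (6.0, 9.0, 21.0, 30.0, 39.0, 51.0, 60.0),
}
#: Tablets weighed per experiment cell.
TABLETS_PER_CELL = {"rotary_press": 20, "compaction_simulator": 10}
#: Reports analyzed per simulated turret speed.
REPORTS_PER_SPEED = 10


def fixture_materials() -> tuple[PowderMaterial, ...]:
    """The three characterized excipient blends (DCP, MCC, LAC).

    Loaded from the packaged characterization table (mean values of the
    triplicate measurements).
    """
    path = importlib.resources.files("diefill.data").joinpath("table_materials.csv")
    with importlib.resources.as_file(path) as p:
        df = pd.read_csv(p)
    return tuple(
        PowderMaterial(
            name=row["name"],
            x10=row["x10_um"],
            x50=row["x50_um"],
            x90=row["x90_um"],
            rho_bulk=row["rho_bulk_g_cm3"],
            rho_tapped=row["rho_tapped_g_cm3"],
            rho_particle=row["rho_particle_g_cm3"],
            permeability=row["permeability_m2"],
        )
        for _, row in df.iterrows()
    )


def fixture_material(name: str) -> PowderMaterial:
    """Look up one fixture material by name."""
    for m in fixture_materials():
        if m.name == name:
            return m
    raise UsageError(f"unknown fixture material {name!r}")


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters for one synthetic (machine, cam, speed) cell.

    ``stationary_velocity`` (m/s) applies to simulator profiles; when None
    it defaults to 1.4x the mean pull-down velocity. ``velocity_noise`` is
    the Gaussian noise sd as a fraction of the plateau velocity. The
    weight model is mean_phi = base_yield * s(dp_max) * g(paddle passes)
    with exponential-saturation links s and g (a synthetic construct, not
    a fitted model); ``weight_rsd`` is the fractional sd of the weights.
    """

    material: str = "DCP"
    machine: MachineKind = "rotary_press"
    cam: CamKind = "conventional"
    turret_speed: float = 20.0
    paddle_speed: float = 30.0
    theta_ppd_deg: float = 72.0
    stationary_velocity: float | None = None
    accel_fraction: float = 0.3
    decel_fraction: float = 0.3
    velocity_noise: float = 0.01
    base_yield: float = 1.0
    suction_sensitivity: float = 0.2
    supply_sensitivity: float = 0.2
    weight_rsd: float = 0.015
    delta_p_ref: float = 2000.0  # Pa; saturation scale of the suction link
    supply_ref: float = 1.0  # paddle passes; saturation scale of the supply link
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("velocity_noise", "suction_sensitivity", "supply_sensitivity", "weight_rsd"):
            if getattr(self, name) < 0.0:
                raise DomainError(f"{name} cannot be negative")
        if not (0.0 <= self.suction_sensitivity < 1.0 and 0.0 <= self.supply_sensitivity < 1.0):
            raise DomainError("sensitivities must lie in [0, 1)")
        if self.base_yield <= 0.0:
            raise DomainError("base yield must be positive")

    @property
    def fill_cam(self) -> FillCam:
        return FillCam(kind=self.cam, theta_ppd_deg=self.theta_ppd_deg)

    @property
    def machine_config(self) -> MachineConfig:
        return MachineConfig(
            machine=self.machine,
            turret_speed=self.turret_speed,
            paddle_speed=self.paddle_speed,
        )

    def build_profile(self) -> VelocityProfile:
        """Velocity profile implied by the scenario's machine and cam."""
        cam = self.fill_cam
        if self.machine == "rotary_press":
            return build_rotary_profile(cam, self.machine_config)
        t_ppd = pull_down_time(self.theta_ppd_deg, self.turret_speed)
        v_mean = linear_pull_down_velocity(cam.pull_down_height, t_ppd)
        vs = 1.4 * v_mean if self.stationary_velocity is None else self.stationary_velocity
        return build_simulator_profile(
            cam.pull_down_height, t_ppd, vs, self.accel_fraction, self.decel_fraction
        )

    def pressure_spec(self, air: AirProperties | None = None, **overrides) -> PressureModelSpec:
        """Pressure-model spec for this scenario (fixture material constants)."""
        return PressureModelSpec(
            material=fixture_material(self.material),
            cam=self.fill_cam,
            machine=self.machine_config,
            profile=self.build_profile(),
            air=air if air is not None else AirProperties(),
            **overrides,
        )


_SCENARIO_FIELDS = {f for f in SyntheticScenario.__dataclass_fields__}


def scenario_from_mapping(d: Mapping) -> SyntheticScenario:
    """Build a scenario from a parsed config mapping, rejecting unknown keys."""
    unknown = set(d) - _SCENARIO_FIELDS
    if unknown:
        raise UsageError(f"unknown scenario keys: {sorted(unknown)}")
    return SyntheticScenario(**dict(d))


def _cell_entropy(scenario: SyntheticScenario, stream: int, index: int) -> list[int]:
    """Stable integer entropy for one rng stream of one scenario cell."""
    return [
        int(scenario.seed) % (2**31),
        stream,
        index,
        int(round(scenario.turret_speed * 1000)),
        int(round(scenario.paddle_speed * 1000)),
        0 if scenario.machine == "rotary_press" else 1,
        0 if scenario.cam == "conventional" else 1,
    ]


def generate_punch_report(scenario: SyntheticScenario, report_index: int = 0) -> PunchReport:
    """One synthetic instrumentation report sampled at 2000 Hz.

    Velocity carries independent Gaussian noise with sd equal to
    ``velocity_noise`` times the plateau velocity; displacement is the
    noiseless integral of the true profile (instrument-style smooth
    trace). Deterministic given (seed, report_index).
    """
    profile = scenario.build_profile()
    n = int(np.floor(profile.duration * SAMPLING_RATE_HZ)) + 1
    t = np.arange(n) / SAMPLING_RATE_HZ
    v = profile.velocity(t)
    plateau = profile.max_velocity()
    rng = np.random.default_rng(_cell_entropy(scenario, 101, report_index))
    noisy_v = v + rng.normal(0.0, scenario.velocity_noise * plateau, size=n)
    return PunchReport(
        times=t,
        displacement=profile.displacement(t),
        velocity=noisy_v,
        sampling_rate=SAMPLING_RATE_HZ,
    )


def mean_filling_yield(scenario: SyntheticScenario, die: DieGeometry | None = None) -> float:
    """Ground-truth mean filling yield of the scenario's weight model.

    mean_phi = base_yield * (1 - s_dp * exp(-dp_max / dp_ref))
                          * (1 - s_sup * exp(-n_pass / n_ref)),

    where dp_max is the peak suction pressure of the scenario's pressure
    model and n_pass the number of paddle passes during the filling time.
    With both sensitivities zero the yield is ``base_yield`` regardless of
    speeds (null model).
    """
    profile = scenario.build_profile()
    if scenario.suction_sensitivity > 0.0:
        dp_max = solve_pressure(scenario.pressure_spec()).max_delta_p
        suction_link = 1.0 - scenario.suction_sensitivity * np.exp(
            -dp_max / scenario.delta_p_ref
        )
    else:
        suction_link = 1.0
    if scenario.supply_sensitivity > 0.0:
        n_pass = (
            scenario.paddle_speed / 60.0 * profile.duration * PADDLE_SPOKES[scenario.machine]
        )
        supply_link = 1.0 - scenario.supply_sensitivity * np.exp(-n_pass / scenario.supply_ref)
    else:
        supply_link = 1.0
    return float(scenario.base_yield * suction_link * supply_link)


def generate_tablet_weights(
    scenario: SyntheticScenario, n: int | None = None, die: DieGeometry | None = None
) -> FillingExperiment:
    """Synthetic tablet weights for one experiment cell.

    Weights are Gaussian around mean_phi * theoretical mass with fractional
    sd ``weight_rsd``; n defaults to the per-machine protocol (20 rotary,
    10 simulator). Deterministic given the scenario seed.
    """
    if n is None:
        n = TABLETS_PER_CELL[scenario.machine]
    if n < 2:
        raise UsageError("need at least 2 tablets per cell")
    if die is None:
        die = DieGeometry()
    material = fixture_material(scenario.material)
    mu_phi = mean_filling_yield(scenario, die)
    mu_mg = mu_phi * theoretical_tablet_mass(die, material.rho_bulk)
    rng = np.random.default_rng(_cell_entropy(scenario, 211, 0))
    weights = rng.normal(mu_mg, scenario.weight_rsd * mu_mg, size=n)
    if np.any(weights <= 0.0):
        raise DomainError("weight model produced non-positive weights; lower the RSD")
    return FillingExperiment(
        machine=scenario.machine,
        cam=scenario.cam,
        material=scenario.material,
        turret_speed=scenario.turret_speed,
        paddle_speed=scenario.paddle_speed,
        weights=tuple(float(w) for w in weights),
    )


@dataclass(frozen=True)
class StudyDesign:
    """One (machine, cam, material) block of the full experimental design."""

    machine: MachineKind = "rotary_press"
    cam: CamKind = "conventional"
    material: str = "DCP"
    turret_speeds: tuple[float, ...] = TURRET_SPEEDS
    paddle_speeds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.paddle_speeds is None:
            object.__setattr__(self, "paddle_speeds", PADDLE_SPEEDS[self.machine])


@dataclass(frozen=True)
class StudyDataset:
    """Synthetic dataset for one design block: weights per cell, reports per speed."""

    design: StudyDesign
    experiments: tuple[FillingExperiment, ...]
    reports: dict  # turret speed -> list[PunchReport]; simulator designs only
    seed: int


def generate_study(
    design: StudyDesign, template: SyntheticScenario | None = None, seed: int = 0
) -> StudyDataset:
    """Generate the full dataset for one design block.

    One weight experiment per (turret, paddle) cell; for simulator designs
    additionally 10 instrumentation reports per turret speed. Reproducible
    from ``seed``.
    """
    if template is None:
        template = SyntheticScenario()
    experiments = []
    for nt in design.turret_speeds:
        for npad in design.paddle_speeds:
            scenario = replace(
                template,
                material=design.material,
                machine=design.machine,
                cam=design.cam,
                turret_speed=nt,
                paddle_speed=npad,
                seed=seed,
            )
            experiments.append(generate_tablet_weights(scenario))
    reports: dict = {}
    if design.machine == "compaction_simulator":
        for nt in design.turret_speeds:
            scenario = replace(
                template,
                material=design.material,
                machine=design.machine,
                cam=design.cam,
                turret_speed=nt,
                paddle_speed=design.paddle_speeds[0],
                seed=seed,
            )
            reports[nt] = [
                generate_punch_report(scenario, i) for i in range(REPORTS_PER_SPEED)
            ]
    return StudyDataset(
        design=design, experiments=tuple(experiments), reports=reports, seed=seed
    )
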
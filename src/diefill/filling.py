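"""Filling yield phi from tablet weights and (turret x paddle) experiment grids.

The filling yield phi = m_t / (pi * r_die^2 * h_d * rho_b) is a
dimensionless, material-independent measure of the degree of die filling:
tablet mass over the theoretical mass of the dosing volume at bulk
density. phi > 1 indicates overfilling (in-die densification above bulk
density). Bulk density is used as the reference because the actual in-die
density during filling is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, UsageError
from .kinematics import CamKind, DieGeometry, MachineKind
from .materials import PowderMaterial


def theoretical_tablet_mass(die: DieGeometry, rho_bulk: float) -> float:
    """Theoretical tablet mass pi * r_die^2 * h_d * rho_b, mg.

    ``die`` holds SI lengths (m); ``rho_bulk`` is in g/cm^3 as printed in
    characterization tables. The dosing volume in cm^3 times g/cm^3 gives
    grams; returned in mg.
    """
    if rho_bulk <= 0.0:
        raise DomainError("bulk density must be positive")
    volume_cm3 = die.area * die.dosing_height * 1e6
    return volume_cm3 * rho_bulk * 1e3


def filling_yield(mt_mg: float, die: DieGeometry, rho_bulk: float) -> float:
    """Filling yield phi = m_t / (pi * r_die^2 * h_d * rho_b), dimensionless."""
    if mt_mg <= 0.0:
        raise DomainError("tablet weight must be positive")
    return mt_mg / theoretical_tablet_mass(die, rho_bulk)


@dataclass(frozen=True)
class FillingExperiment:
    """Tablet weights for one (machine, cam, material, turret, paddle) cell.

    Weights in mg; n = 20 on the rotary press and n = 10 on the compaction
    simulator in the reference protocol.
    """

    machine: MachineKind
    cam: CamKind
    material: str
    turret_speed: float
    paddle_speed: float
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            raise UsageError("experiment must contain at least one weight")
        if any(w <= 0.0 for w in self.weights):
            raise DomainError("all tablet weights must be positive")

    @property
    def n(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class YieldSummary:
    """Summary statistics of one filling experiment."""

    mean_phi: float
    phi_rsd: float  # percent relative standard deviation of the weights
    n: int
    overfill: bool  # mean_phi > 1: in-die densification above bulk density


def summarize_experiment(
    e: FillingExperiment, die: DieGeometry, material: PowderMaterial
) -> YieldSummary:
    """Mean filling yield and percent weight RSD for one experiment.

    Because phi is linear in the weight, the RSD of phi equals the RSD of
    the raw weights (the pharmacopoeial weight-variation convention).
    """
    if e.n < 2:
        raise UsageError("dispersion statistics need at least 2 tablets")
    w = np.asarray(e.weights, dtype=float)
    mean_phi = filling_yield(float(w.mean()), die, material.rho_bulk)
    rsd = float(w.std(ddof=1) / w.mean() * 100.0)
    return YieldSummary(mean_phi=mean_phi, phi_rsd=rsd, n=e.n, overfill=mean_phi > 1.0)


def yield_grid(
    experiments: Sequence[FillingExperiment],
    die: DieGeometry,
    material: PowderMaterial,
) -> pd.DataFrame:
    """Summarize a (turret x paddle) grid of experiments as a long-format table.

    All experiments must share machine, cam and material; duplicate
    (turret, paddle) cells are rejected. Returns a DataFrame with columns
    machine, cam, material, turret_speed_min, paddle_speed_min, mean_phi,
    phi_rsd, n, overfill, sorted by (turret, paddle).
    """
    if len(experiments) == 0:
        raise UsageError("at least one experiment is required")
    first = experiments[0]
    for e in experiments:
        if (e.machine, e.cam, e.material) != (first.machine, first.cam, first.material):
            raise UsageError("experiments in a grid must share machine, cam and material")
        if e.material != material.name:
            raise UsageError(
                f"experiment material {e.material!r} does not match {material.name!r}"
            )
    seen: set[tuple[float, float]] = set()
    rows = []
    for e in experiments:
        cell = (e.turret_speed, e.paddle_speed)
        if cell in seen:
            raise UsageError(f"duplicate grid cell {cell}")
        seen.add(cell)
        s = summarize_experiment(e, die, material)
        rows.append(
            {
                "machine": e.machine,
                "cam": e.cam,
                "material": e.material,
                "turret_speed_min": e.turret_speed,
                "paddle_speed_min": e.paddle_speed,
                "mean_phi": s.mean_phi,
                "phi_rsd": s.phi_rsd,
                "n": s.n,
                "overfill": s.overfill,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["turret_speed_min", "paddle_speed_min"])
        .reset_index(drop=True)
    )
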
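"""Powder characterization: flow function, compressibility index, Darcy permeability.

Material constants are stored in the units in which powder technologists
report them (densities in g/cm^3, particle sizes in µm, permeability in m^2);
SI conversions happen at computation boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, UsageError

G_CM3_TO_KG_M3 = 1000.0


@dataclass(frozen=True)
class PowderMaterial:
    """One excipient blend with its characterization constants.

    Parameters
    ----------
    name : short material label (e.g. ``"DCP"``).
    x10, x50, x90 : particle size percentiles, µm.
    rho_bulk, rho_tapped, rho_particle : densities, g/cm^3.
    permeability : air permeability ``K`` of the powder bed at 1 kPa
        normal stress, m^2 (Darcy coefficient).
    ffc : optional flow function coefficient (dimensionless).
    """

    name: str
    x10: float
    x50: float
    x90: float
    rho_bulk: float
    rho_tapped: float
    rho_particle: float
    permeability: float
    ffc: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.rho_bulk <= self.rho_tapped <= self.rho_particle):
            raise DomainError(
                f"{self.name}: densities must satisfy 0 < bulk <= tapped <= particle, "
                f"got {self.rho_bulk}, {self.rho_tapped}, {self.rho_particle}"
            )
        if self.permeability <= 0.0:
            raise DomainError(f"{self.name}: permeability must be positive")
        if not (self.x10 <= self.x50 <= self.x90):
            raise DomainError(f"{self.name}: particle size percentiles must be ordered")

    @property
    def rho_bulk_si(self) -> float:
        """Bulk density in kg/m^3."""
        return self.rho_bulk * G_CM3_TO_KG_M3

    @property
    def compressibility_index(self) -> float:
        """Carr compressibility index, percent."""
        return compressibility_index(self.rho_bulk, self.rho_tapped)


@dataclass(frozen=True)
class FlowMeasurement:
    """One shear-cell measurement point.

    sigma1 is the consolidation stress, sigma0 the unconfined yield
    strength (both kPa); ``preshear_stress`` records the pre-shear level
    the point belongs to.
    """

    sigma1: float
    sigma0: float
    preshear_stress: float | None = None

    def __post_init__(self) -> None:
        if self.sigma1 <= 0.0:
            raise DomainError("consolidation stress must be positive")
        if self.sigma0 < 0.0:
            raise DomainError("unconfined yield strength cannot be negative")


def flow_function_coefficient(m: FlowMeasurement) -> float:
    """Flow function coefficient ffc = sigma1 / sigma0 for one measurement."""
    if m.sigma0 <= 0.0:
        raise DomainError("ffc undefined for non-positive unconfined yield strength")
    return m.sigma1 / m.sigma0


#: Jenike flowability classes as (upper ffc bound, label); the last bound is open.
JENIKE_CLASSES = (
    (2.0, "very cohesive"),
    (4.0, "cohesive"),
    (10.0, "easy flowing"),
    (np.inf, "free flowing"),
)


def classify_flowability(ffc: float) -> str:
    """Map an ffc value onto the Jenike flowability class label.

    Classes: very cohesive (<2), cohesive (2-4), easy flowing (4-10),
    free flowing (>10). Boundaries belong to the upper class.
    """
    if ffc <= 0.0:
        raise DomainError("ffc must be positive")
    for bound, label in JENIKE_CLASSES:
        if ffc < bound:
            return label
    return JENIKE_CLASSES[-1][1]


def compressibility_index(rho_bulk: float, rho_tapped: float) -> float:
    """Carr compressibility index CI = (rho_t - rho_b) / rho_t * 100, percent.

    Any consistent density unit may be used; the ratio is dimensionless.
    """
    if rho_bulk <= 0.0:
        raise DomainError("bulk density must be positive")
    if rho_bulk > rho_tapped:
        raise DomainError("bulk density cannot exceed tapped density")
    return (rho_tapped - rho_bulk) / rho_tapped * 100.0


def darcy_volume_flow(K: float, A: float, eta: float, L: float, delta_p: float) -> float:
    """Air volume flow Q = K*A/(eta*L) * delta_p through a powder bed, m^3/s.

    K : permeability, m^2;  A : cross-sectional area, m^2;
    eta : dynamic viscosity of air, Pa*s;  L : bed height, m;
    delta_p : pressure difference across the bed, Pa (>= 0).
    """
    if K <= 0.0 or A <= 0.0 or eta <= 0.0 or L <= 0.0:
        raise DomainError("K, A, eta and L must all be positive")
    if delta_p < 0.0:
        raise DomainError("delta_p must be non-negative")
    return K * A / (eta * L) * delta_p


def permeability_from_darcy(Q: float, A: float, eta: float, L: float, delta_p: float) -> float:
    """Invert Darcy's law: K = Q*eta*L / (A*delta_p), m^2.

    Exact inverse of :func:`darcy_volume_flow` for positive arguments.
    """
    if Q <= 0.0 or A <= 0.0 or eta <= 0.0 or L <= 0.0:
        raise DomainError("Q, A, eta and L must all be positive")
    if delta_p <= 0.0:
        raise DomainError("delta_p must be positive to infer permeability")
    return Q * eta * L / (A * delta_p)


def permeability_from_flow_sweep(
    flows: Sequence[float],
    delta_ps: Sequence[float],
    A: float,
    eta: float,
    L: float,
) -> float:
    """Permeability from several (volume flow, delta_p) pairs on the same bed.

    The rheometer protocol applies two volume flows (0.4 and 0.6 L/min) and
    records the resulting pressure drop for each; the bed permeability is
    taken as the mean of the per-flow Darcy estimates.
    """
    if len(flows) != len(delta_ps):
        raise UsageError("flows and delta_ps must have equal length")
    if len(flows) == 0:
        raise UsageError("at least one (flow, delta_p) pair is required")
    estimates = [permeability_from_darcy(q, A, eta, L, dp) for q, dp in zip(flows, delta_ps)]
    return float(np.mean(estimates))
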
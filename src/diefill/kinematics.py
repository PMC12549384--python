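"""Lower-punch kinematics: fill-cam geometry, pull-down profiles, report analysis.

The lower punch is pulled down under the powder bed by a fill cam while the
die passes beneath the feed frame. On a rotary press the turret guides the
punch at constant velocity down a linear cam slope; on a compaction
simulator the punch is accelerated to a stationary velocity and decelerated
to stop precisely at the filling height. Displacement is measured
downward-positive from the die table surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import AnalysisError, ConstraintError, DomainError, UsageError

CamKind = Literal["conventional", "stearate"]
MachineKind = Literal["rotary_press", "compaction_simulator"]

#: Pre-pull height of the stearate (external-lubrication) fill cam, m.
STEARATE_PRE_PULL_M = 4.7e-3
#: Default pull-down sector of the fill cam, degrees (assumed; not a
#: catalogue value — every kinematic quantity is linear in it).
DEFAULT_THETA_PPD_DEG = 72.0
#: Feed-frame spoke height = effective powder bed height, m.
SPOKE_HEIGHT_M = {"rotary_press": 6.0e-3, "compaction_simulator": 11.0e-3}
#: Number of paddle-wheel spokes per machine.
PADDLE_SPOKES = {"rotary_press": 12, "compaction_simulator": 6}


@dataclass(frozen=True)
class DieGeometry:
    """Die bore geometry. All lengths in metres.

    radius : die radius (4.5 mm for the 9 mm round EU-D tooling);
    dosing_height : lower-punch height at dosing (15.5 mm);
    filling_height : lower-punch height at the bottom of the fill cam (16 mm).
    """

    radius: float = 4.5e-3
    dosing_height: float = 15.5e-3
    filling_height: float = 16.0e-3

    def __post_init__(self) -> None:
        if self.radius <= 0.0:
            raise DomainError("die radius must be positive")
        if not (0.0 < self.dosing_height <= self.filling_height):
            raise DomainError("need 0 < dosing height <= filling height")

    @property
    def area(self) -> float:
        """Cross-sectional area of the die bore, m^2."""
        return float(np.pi * self.radius**2)


@dataclass(frozen=True)
class FillCam:
    """Fill-cam geometry guiding the lower punch under the powder bed.

    ``conventional`` cams start with the punch face flush with the die
    table (no initial air pocket); ``stearate`` cams pre-pull the punch by
    ``pre_pull_height`` before it enters the feed frame, leaving an initial
    cavity that buffers the suction pressure.
    """

    kind: CamKind
    filling_height: float = 16.0e-3
    pre_pull_height: float | None = None
    theta_ppd_deg: float = DEFAULT_THETA_PPD_DEG

    def __post_init__(self) -> None:
        if self.pre_pull_height is None:
            hs = STEARATE_PRE_PULL_M if self.kind == "stearate" else 0.0
            object.__setattr__(self, "pre_pull_height", hs)
        if not (0.0 <= self.pre_pull_height < self.filling_height):
            raise DomainError("need 0 <= pre-pull height < filling height")
        if not (0.0 < self.theta_ppd_deg <= 360.0):
            raise DomainError("pull-down angle must be in (0, 360] degrees")

    @property
    def pull_down_height(self) -> float:
        """Effective pull-down height under the powder bed h_ppd = h_f - h_s, m."""
        return self.filling_height - self.pre_pull_height

    @property
    def initial_cavity_height(self) -> float:
        """Initial cavity height h_0 below the die table at feed-frame entry, m."""
        return self.pre_pull_height


@dataclass(frozen=True)
class MachineConfig:
    """Machine context for one tableting run.

    turret_speed and paddle_speed in min^-1; powder_bed_height is the
    effective bed thickness over the die, bound by default to the
    feed-frame spoke height of the machine (6 mm rotary press, 11 mm
    compaction simulator).
    """

    machine: MachineKind
    turret_speed: float
    paddle_speed: float = 30.0
    powder_bed_height: float | None = None
    die: DieGeometry = field(default_factory=DieGeometry)

    def __post_init__(self) -> None:
        if self.powder_bed_height is None:
            object.__setattr__(self, "powder_bed_height", SPOKE_HEIGHT_M[self.machine])
        if self.turret_speed <= 0.0:
            raise DomainError("turret speed must be positive")
        if self.powder_bed_height <= 0.0:
            raise DomainError("powder bed height must be positive")


def pull_down_time(theta_ppd_deg: float, turret_speed: float) -> float:
    """Pull-down time t_ppd = theta_ppd / (360 * n_t), seconds.

    The pull-down sector occupies theta_ppd/360 of one turret revolution;
    turret_speed n_t is in min^-1.
    """
    if not (0.0 < theta_ppd_deg <= 360.0):
        raise DomainError("pull-down angle must be in (0, 360] degrees")
    if turret_speed <= 0.0:
        raise DomainError("turret speed must be positive")
    return theta_ppd_deg / (360.0 * turret_speed / 60.0)


def linear_pull_down_velocity(h_ppd: float, t_ppd: float) -> float:
    """Linear pull-down velocity v_ppd = h_ppd / t_ppd, m/s."""
    if h_ppd <= 0.0 or t_ppd <= 0.0:
        raise DomainError("pull-down height and time must be positive")
    return h_ppd / t_ppd


@dataclass(frozen=True)
class VelocityProfile:
    """Piecewise-polynomial punch velocity v(t) with induced displacement h(t).

    ``breaks`` are the n+1 phase boundaries (s, starting at 0); ``coeffs``
    holds, per phase, polynomial coefficients in ascending powers of the
    local time t - t_phase_start. Velocity must be continuous and
    non-negative; displacement is the running integral of v.
    """

    breaks: tuple[float, ...]
    coeffs: tuple[tuple[float, ...], ...]
    _h_offsets: tuple[float, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.breaks) != len(self.coeffs) + 1:
            raise UsageError("need one more break than phases")
        if any(b1 <= b0 for b0, b1 in zip(self.breaks, self.breaks[1:])):
            raise UsageError("phase boundaries must be strictly increasing")
        # displacement offset at the start of each phase (exact polynomial integral)
        offsets = [0.0]
        for (t0, t1), c in zip(zip(self.breaks, self.breaks[1:]), self.coeffs):
            integ = np.polynomial.polynomial.polyint(c)
            offsets.append(offsets[-1] + float(np.polynomial.polynomial.polyval(t1 - t0, integ)))
        object.__setattr__(self, "_h_offsets", tuple(offsets))
        # continuity at interior boundaries
        for i in range(len(self.coeffs) - 1):
            dt = self.breaks[i + 1] - self.breaks[i]
            v_end = float(np.polynomial.polynomial.polyval(dt, self.coeffs[i]))
            v_next = float(self.coeffs[i + 1][0])
            if abs(v_end - v_next) > 1e-9 * max(1.0, abs(v_end)):
                raise ConstraintError("velocity must be continuous at phase boundaries")

    @property
    def duration(self) -> float:
        """Total pull-down duration, s."""
        return self.breaks[-1]

    @property
    def total_displacement(self) -> float:
        """h(duration) — the effective pull-down height the profile traverses, m."""
        return self._h_offsets[-1]

    def _phase_index(self, t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.breaks[1:-1]), t, side="right")
        return idx

    def velocity(self, t):
        """Punch velocity v(t), m/s; accepts scalars or arrays, clamped to [0, duration]."""
        t_arr = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), 0.0, self.duration)
        idx = self._phase_index(t_arr)
        out = np.empty_like(t_arr)
        for i, c in enumerate(self.coeffs):
            sel = idx == i
            if np.any(sel):
                out[sel] = np.polynomial.polynomial.polyval(t_arr[sel] - self.breaks[i], c)
        return float(out[0]) if np.ndim(t) == 0 else out

    def displacement(self, t):
        """Displacement h(t) = integral of v from 0 to t, m (downward-positive)."""
        t_arr = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), 0.0, self.duration)
        idx = self._phase_index(t_arr)
        out = np.empty_like(t_arr)
        for i, c in enumerate(self.coeffs):
            sel = idx == i
            if np.any(sel):
                integ = np.polynomial.polynomial.polyint(c)
                out[sel] = self._h_offsets[i] + np.polynomial.polynomial.polyval(
                    t_arr[sel] - self.breaks[i], integ
                )
        return float(out[0]) if np.ndim(t) == 0 else out

    def max_velocity(self) -> float:
        """Exact maximum of v(t) over the profile (phases are <= quadratic)."""
        vmax = 0.0
        for (t0, t1), c in zip(zip(self.breaks, self.breaks[1:]), self.coeffs):
            dt = t1 - t0
            candidates = [0.0, dt]
            deriv = np.polynomial.polynomial.polyder(c)
            if len(deriv) == 2 and deriv[1] != 0.0:  # quadratic phase
                t_ext = -deriv[0] / deriv[1]
                if 0.0 < t_ext < dt:
                    candidates.append(t_ext)
            vmax = max(vmax, max(float(np.polynomial.polynomial.polyval(x, c)) for x in candidates))
        return vmax


def build_rotary_profile(cam: FillCam, machine: MachineConfig) -> VelocityProfile:
    """Constant-velocity pull-down profile for the turret-guided rotary press.

    The punch rides a linear cam slope, so v is constant at
    h_ppd / t_ppd for the whole pull-down sector.
    """
    if machine.machine != "rotary_press":
        raise UsageError("rotary profile requires a rotary_press machine config")
    t_ppd = pull_down_time(cam.theta_ppd_deg, machine.turret_speed)
    v = linear_pull_down_velocity(cam.pull_down_height, t_ppd)
    return VelocityProfile(breaks=(0.0, t_ppd), coeffs=((v,),))


def build_simulator_profile(
    h_ppd: float,
    target_duration: float,
    stationary_velocity: float,
    accel_fraction: float = 0.3,
    decel_fraction: float = 0.3,
) -> VelocityProfile:
    """Three-phase (accelerate / stationary / decelerate) simulator profile.

    The acceleration and deceleration phases are second-degree polynomials
    in time with v(0) = v(end) = 0 and v equal to ``stationary_velocity``
    at the plateau boundaries; a shared shape parameter is solved so the
    profile integrates exactly to ``h_ppd``, making the time-averaged
    velocity equal h_ppd / target_duration.

    Raises :class:`ConstraintError` when no non-negative quadratic ramp
    can satisfy the displacement constraint (stationary velocity too low
    or too high for the requested phase split).
    """
    if h_ppd <= 0.0 or target_duration <= 0.0:
        raise DomainError("pull-down height and duration must be positive")
    if not (0.0 < accel_fraction < 1.0 and 0.0 < decel_fraction < 1.0):
        raise DomainError("phase fractions must lie in (0, 1)")
    if accel_fraction + decel_fraction >= 1.0:
        raise DomainError("acceleration and deceleration fractions must sum to < 1")
    v_mean = h_ppd / target_duration
    if stationary_velocity <= v_mean:
        raise ConstraintError(
            f"stationary velocity {stationary_velocity:.4g} m/s must exceed the "
            f"mean pull-down velocity {v_mean:.4g} m/s"
        )
    T = target_duration
    ta = accel_fraction * T
    td = decel_fraction * T
    vs = stationary_velocity
    # ramp shape v(tau)=vs*u*(1+a*(1-u)), u=tau/ta: integral = vs*ta*(1/2 + a/6)
    a = 6.0 * ((h_ppd / vs - (T - ta - td)) / (ta + td) - 0.5)
    if a < -1.0:
        raise ConstraintError(
            "stationary velocity too high for the phase split: ramps would need "
            "negative velocity to hit the pull-down height"
        )
    accel = (0.0, vs * (1.0 + a) / ta, -vs * a / ta**2)
    decel = (vs, vs * (a - 1.0) / td, -vs * a / td**2)
    return VelocityProfile(
        breaks=(0.0, ta, T - td, T),
        coeffs=(accel, (vs,), decel),
    )


@dataclass(frozen=True)
class PunchReport:
    """One instrumentation report: uniformly sampled punch displacement and velocity."""

    times: np.ndarray
    displacement: np.ndarray
    velocity: np.ndarray
    sampling_rate: float = 2000.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise UsageError("report needs at least two samples")
        if len(self.displacement) != len(t) or len(self.velocity) != len(t):
            raise UsageError("time, displacement and velocity must have equal length")
        dt = np.diff(t)
        if np.any(dt <= 0.0):
            raise UsageError("sample times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise UsageError("sample times must be uniformly spaced")


@dataclass(frozen=True)
class ReportAnalysis:
    """Per-report kinematic statistics from :func:`analyze_report`."""

    stationary_mean: float
    stationary_sd: float
    acceleration: float
    deceleration: float
    window: tuple[int, int]  # [start, stop) sample indices of the stationary window
    degenerate: bool = False  # True when accel/decel segments were too short to fit


def _longest_run(mask: np.ndarray) -> tuple[int, int]:
    """Return [start, stop) of the longest contiguous True run, or (0, 0)."""
    best = (0, 0)
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and len(mask) - start > best[1] - best[0]:
        best = (start, len(mask))
    return best


def analyze_report(r: PunchReport, stationary_threshold: float = 0.95) -> ReportAnalysis:
    """Extract stationary velocity and accel/decel slopes from one report.

    The stationary window is the maximal contiguous run of samples with
    v >= threshold * max(v); the acceleration (deceleration) is the OLS
    slope of v(t) over the samples before (after) that window. Segments
    with fewer than 3 samples yield NaN slopes and set ``degenerate``.
    """
    if not (0.0 < stationary_threshold <= 1.0):
        raise DomainError("stationary threshold must be a fraction in (0, 1]")
    v = np.asarray(r.velocity, dtype=float)
    t = np.asarray(r.times, dtype=float)
    vmax = float(v.max())
    if vmax <= 0.0:
        raise AnalysisError("report contains no positive velocity samples")
    start, stop = _longest_run(v >= stationary_threshold * vmax)
    if stop - start < 3:
        raise AnalysisError("stationary window has fewer than 3 samples")
    window = v[start:stop]
    mean = float(window.mean())
    sd = float(window.std(ddof=1))

    def _slope(seg_t: np.ndarray, seg_v: np.ndarray) -> float:
        if len(seg_t) < 3:
            return float("nan")
        return float(np.polyfit(seg_t, seg_v, 1)[0])

    accel = _slope(t[:start], v[:start])
    decel = _slope(t[stop:], v[stop:])
    degenerate = bool(np.isnan(accel) or np.isnan(decel))
    return ReportAnalysis(mean, sd, accel, decel, (start, stop), degenerate)


def weighted_stats(means: Sequence[float], sds: Sequence[float]) -> tuple[float, float]:
    """Inverse-variance weighted mean and weighted standard deviation.

    mu_w = sum(mu_i / sd_i^2) / sum(1 / sd_i^2);
    sd_w = sqrt(1 / sum(1 / sd_i^2)).
    """
    mu = np.asarray(means, dtype=float)
    sd = np.asarray(sds, dtype=float)
    if mu.size == 0:
        raise UsageError("weighted_stats requires at least one (mean, sd) pair")
    if mu.shape != sd.shape:
        raise UsageError("means and sds must have equal length")
    if np.any(sd <= 0.0):
        raise DomainError("all standard deviations must be positive")
    w = 1.0 / sd**2
    mu_w = float(np.sum(w * mu) / np.sum(w))
    sd_w = float(np.sqrt(1.0 / np.sum(w)))
    return mu_w, sd_w


@dataclass(frozen=True)
class KinematicsSummary:
    """Ensemble summary across instrumentation reports."""

    pull_down_time: float
    stationary_velocity_mean: float
    stationary_velocity_sd: float
    acceleration: float
    deceleration: float
    n_reports: int


def summarize_reports(
    reports: Sequence[PunchReport], stationary_threshold: float = 0.95
) -> KinematicsSummary:
    """Combine per-report analyses with inverse-variance weighting.

    The pull-down time is the mean over reports of the span between the
    first and last sample at which the displacement changes.
    """
    if len(reports) == 0:
        raise UsageError("at least one report is required")
    analyses = [analyze_report(r, stationary_threshold) for r in reports]
    mu_w, sd_w = weighted_stats(
        [a.stationary_mean for a in analyses], [a.stationary_sd for a in analyses]
    )
    times = []
    for r in reports:
        d = np.asarray(r.displacement, dtype=float)
        moving = np.flatnonzero(np.abs(np.diff(d)) > 1e-12)
        if moving.size == 0:
            raise AnalysisError("report shows no displacement change")
        t = np.asarray(r.times, dtype=float)
        times.append(t[moving[-1] + 1] - t[moving[0]])
    accels = [a.acceleration for a in analyses if not np.isnan(a.acceleration)]
    decels = [a.deceleration for a in analyses if not np.isnan(a.deceleration)]
    return KinematicsSummary(
        pull_down_time=float(np.mean(times)),
        stationary_velocity_mean=mu_w,
        stationary_velocity_sd=sd_w,
        acceleration=float(np.mean(accels)) if accels else float("nan"),
        deceleration=float(np.mean(decels)) if decels else float("nan"),
        n_reports=len(reports),
    )
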
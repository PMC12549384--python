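"""Text I/O: report / curve / weight CSVs with provenance headers, YAML configs.

All files are plain CSV with an optional header block of ``# key = value``
lines carrying provenance (scenario, seed, tolerances); pandas skips the
block via ``comment='#'`` on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import UsageError
from .filling import FillingExperiment
from .kinematics import PunchReport
from .suction import PressureCurve


def _write_with_header(path: Path, df: pd.DataFrame, metadata: Mapping | None) -> None:
    with open(path, "w") as fh:
        if metadata:
            for key, value in metadata.items():
                fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False)


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
    return meta


def write_punch_report(path, report: PunchReport, metadata: Mapping | None = None) -> None:
    """Write one report as CSV (time_s, displacement_m, velocity_m_s)."""
    df = pd.DataFrame(
        {
            "time_s": report.times,
            "displacement_m": report.displacement,
            "velocity_m_s": report.velocity,
        }
    )
    meta = {"sampling_rate_hz": report.sampling_rate, **(metadata or {})}
    _write_with_header(Path(path), df, meta)


def read_punch_report(path) -> tuple[PunchReport, dict]:
    """Read one report CSV; returns (report, header metadata)."""
    path = Path(path)
    meta = _read_header(path)
    df = pd.read_csv(path, comment="#")
    required = {"time_s", "displacement_m", "velocity_m_s"}
    if not required.issubset(df.columns):
        raise UsageError(f"{path}: report CSV needs columns {sorted(required)}")
    rate = float(meta.get("sampling_rate_hz", 2000.0))
    report = PunchReport(
        times=df["time_s"].to_numpy(),
        displacement=df["displacement_m"].to_numpy(),
        velocity=df["velocity_m_s"].to_numpy(),
        sampling_rate=rate,
    )
    return report, meta


def write_pressure_curve(path, curve: PressureCurve) -> None:
    """Write a solved pressure curve as CSV (time_s, pressure_pa, delta_p_pa)."""
    df = pd.DataFrame(
        {
            "time_s": curve.times,
            "pressure_pa": curve.pressure,
            "delta_p_pa": curve.delta_p,
        }
    )
    meta = dict(curve.metadata)
    meta["max_delta_p_pa"] = curve.max_delta_p
    if curve.stationary_delta_p is not None:
        meta["stationary_delta_p_pa"] = curve.stationary_delta_p
    _write_with_header(Path(path), df, meta)


WEIGHT_COLUMNS = [
    "machine",
    "cam",
    "material",
    "turret_speed_min",
    "paddle_speed_min",
    "tablet_index",
    "weight_mg",
]


def write_weights_csv(
    path, experiments: Sequence[FillingExperiment], metadata: Mapping | None = None
) -> None:
    """Write tablet weights in long format, one row per tablet."""
    rows = []
    for e in experiments:
        for i, w in enumerate(e.weights):
            rows.append(
                {
                    "machine": e.machine,
                    "cam": e.cam,
                    "material": e.material,
                    "turret_speed_min": e.turret_speed,
                    "paddle_speed_min": e.paddle_speed,
                    "tablet_index": i,
                    "weight_mg": w,
                }
            )
    _write_with_header(Path(path), pd.DataFrame(rows, columns=WEIGHT_COLUMNS), metadata)


def read_weights_csv(path) -> list[FillingExperiment]:
    """Read a long-format weight CSV back into per-cell experiments."""
    df = pd.read_csv(Path(path), comment="#")
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise UsageError(f"{path}: weight CSV missing columns {sorted(missing)}")
    experiments = []
    keys = ["machine", "cam", "material", "turret_speed_min", "paddle_speed_min"]
    for (machine, cam, material, nt, npad), group in df.groupby(keys, sort=True):
        group = group.sort_values("tablet_index")
        experiments.append(
            FillingExperiment(
                machine=machine,
                cam=cam,
                material=material,
                turret_speed=float(nt),
                paddle_speed=float(npad),
                weights=tuple(float(w) for w in group["weight_mg"]),
            )
        )
    return experiments


def load_scenario_config(path) -> dict:
    """Load a YAML scenario config as a plain mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise UsageError(f"{path}: scenario config must be a mapping")
    return data


def write_manifest(path, payload: Mapping) -> None:
    """Write a JSON manifest recording scenario parameters and seed."""
    with open(path, "w") as fh:
        json.dump(dict(payload), fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
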
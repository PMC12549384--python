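#!/usr/bin/env python
"""Suction-pressure curves for every material / machine / cam scenario.

Integrates the in-die pressure ODE for the 3 materials x 2 machines x
2 cams x turret speeds {20, 60} grid, exports the scenario table and two
representative full curves, and prints the mechanistic headlines: the
LAC:DCP stationary-pressure ratio, the stearate cam's buffering of the
suction pressure, and the worst-case solver convergence error.
"""

from pathlib import Path

import pandas as pd

from diefill import (
    FillCam,
    MachineConfig,
    PressureModelSpec,
    SyntheticScenario,
    VelocityProfile,
    convergence_error,
    fixture_material,
    solve_pressure,
)
from diefill.io import write_pressure_curve

RESULTS = Path(__file__).resolve().parents[1] / "results"


def scenario_table() -> pd.DataFrame:
    rows = []
    for name in ("DCP", "MCC", "LAC"):
        for machine in ("rotary_press", "compaction_simulator"):
            for cam in ("conventional", "stearate"):
                for nt in (20.0, 60.0):
                    scen = SyntheticScenario(
                        material=name, machine=machine, cam=cam, turret_speed=nt
                    )
                    spec = scen.pressure_spec()
                    curve = solve_pressure(spec)
                    rows.append(
                        {
                            "material": name,
                            "machine": machine,
                            "cam": cam,
                            "turret_speed_min": nt,
                            "model_constant_m_s": spec.c,
                            "max_delta_p_pa": curve.max_delta_p,
                            "stationary_delta_p_pa": curve.stationary_delta_p,
                            "rise_time_90_s": curve.rise_time(0.9),
                            "convergence_error": convergence_error(spec),
                        }
                    )
    return pd.DataFrame(rows)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    df = scenario_table()
    out = RESULTS / "pressure_scenarios.csv"
    df.to_csv(out, index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4g}"))

    # reference constant-velocity comparison (6 mm bed, 0.15 m/s)
    dps = {}
    for name in ("LAC", "DCP", "MCC"):
        spec = PressureModelSpec(
            material=fixture_material(name),
            cam=FillCam("conventional"),
            machine=MachineConfig("rotary_press", 20.0),
            profile=VelocityProfile(breaks=(0.0, 16.0e-3 / 0.15), coeffs=((0.15,),)),
        )
        dps[name] = solve_pressure(spec).delta_p[-1]
    print(
        f"\nstationary delta_p at 0.15 m/s on the 6 mm bed: "
        f"LAC {dps['LAC']:.0f} Pa, MCC {dps['MCC']:.0f} Pa, DCP {dps['DCP']:.0f} Pa"
    )
    print(f"LAC:DCP ratio = {dps['LAC'] / dps['DCP']:.2f} (low permeability amplifies suction)")

    ste = df[(df.cam == "stearate")].set_index(["material", "machine", "turret_speed_min"])
    conv = df[(df.cam == "conventional")].set_index(["material", "machine", "turret_speed_min"])
    buffering = (ste.max_delta_p_pa / conv.max_delta_p_pa).mean()
    print(
        f"stearate cam reaches on average {buffering:.2f}x the conventional peak delta_p "
        "(initial air pocket + slower punch)"
    )
    print(f"worst convergence error vs tight-tolerance reference: "
          f"{df.convergence_error.max() * 100:.2g}%")

    for name, nt in (("LAC", 20.0), ("MCC", 20.0)):
        scen = SyntheticScenario(material=name, machine="compaction_simulator",
                                 cam="conventional", turret_speed=nt)
        curve = solve_pressure(scen.pressure_spec())
        path = RESULTS / f"pressure_curve_{name.lower()}_simulator_nt{nt:g}.csv"
        write_pressure_curve(path, curve)
        print(f"wrote {path}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
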
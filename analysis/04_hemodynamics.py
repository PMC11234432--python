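#!/usr/bin/env python
"""Pulsatile hemodynamics of the bifurcation with and without magnet force.

Solves the 0.48 s perfusion cycle (mean 2 mL/min, reversal peak at
t = 0.24 s) in the rasterized planform, exports WSS and field snapshots at
the two reported phases (t = 0.07 and 0.24 s), and quantifies the
steady-flow perturbation from the concentration-weighted magnetophoretic
body force.

Writes results/wss_t{0.07,0.24}.csv, results/flow_snapshot_*.csv and
results/magnet_perturbation.csv.
"""

import numpy as np
import pandas as pd

from pvtarget.config import RunConfig
from pvtarget.geometry import rasterize
from pvtarget.hemodynamics import (FlowConfig, magnet_perturbation,
                                   make_waveform, solve_pulsatile, wss_with)
from pvtarget.scenarios import bifurcation_setup, particle_body_force
from pvtarget.writers import write_grid_csv

OUT = "results"


def main():
    cfg = RunConfig()
    spec = cfg.geometry.spec()
    mask = rasterize(spec, cfg.geometry.spacing_mm * 1e-3)
    fc = FlowConfig(n_cycles=3)
    wf = make_waveform()
    snaps, info = solve_pulsatile(mask, wf, fc, snapshot_times=(0.07, 0.24))
    print(f"pulsatile solve: cycle-to-cycle periodicity "
          f"{info['periodicity']:.2e}")
    for s in snaps:
        tag = f"t{s.time:.2f}"
        w = wss_with(s, mask, fc.viscosity)
        w.to_csv(f"{OUT}/wss_{tag}.csv", index=False)
        uc, vc = s.center_velocity()
        write_grid_csv(f"{OUT}/flow_snapshot_{tag}_u.csv", uc, mask.spacing,
                       mask.origin, "u_m_s")
        write_grid_csv(f"{OUT}/flow_snapshot_{tag}_vz.csv",
                       s.magnetward_velocity(), mask.spacing, mask.origin,
                       "v_magnetward_m_s")
        q = s.dynamic_pressure(fc.density)
        write_grid_csv(f"{OUT}/flow_snapshot_{tag}_q.csv", q, mask.spacing,
                       mask.origin, "dynamic_pressure_Pa")
        print(f"  t = {s.time:.2f} s: Q_in = {s.flux_in():.2e} m^2/s, "
              f"peak |WSS| = {np.abs(w.tau).max():.3f} Pa, "
              f"peak dynamic pressure = {np.nanmax(q):.3g} Pa")

    mask_c, flow_c = bifurcation_setup(cfg)
    bf = particle_body_force(cfg, mask_c, flow_c, seed=0)
    rep = magnet_perturbation(mask_c, FlowConfig(), bf, Q_ml_min=2.0)
    pd.DataFrame([dict(dwss_target_Pa=rep.dwss_target,
                       dwss_elsewhere_Pa=rep.dwss_elsewhere,
                       dp_target_Pa=rep.dp_target,
                       dvz_min_um_s=rep.dvz_target[0] * 1e6,
                       dvz_max_um_s=rep.dvz_target[1] * 1e6)]).to_csv(
        f"{OUT}/magnet_perturbation.csv", index=False)
    print(f"\nmagnet body-force perturbation (steady 2 mL/min): "
          f"mean |dWSS| in apex ROI {rep.dwss_target:.2e} Pa vs "
          f"{rep.dwss_elsewhere:.2e} Pa elsewhere; "
          f"d(magnet-ward velocity) in ROI "
          f"[{rep.dvz_target[0] * 1e6:+.0f}, {rep.dvz_target[1] * 1e6:+.0f}] um/s")


if __name__ == "__main__":
    main()
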
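#!/usr/bin/env python
"""Micro-indentation modulus recovery at the three printed-surface levels.

Generates noise-free and 2%-noise Hertzian force-displacement curves at
the measured construct moduli (top 56.4, bottom 72.2, lumen 87.6 kPa),
runs the unloading-stiffness contact-mechanics chain on each, and tables
the recovered moduli.

Writes results/indentation_recovery.csv.
"""

import numpy as np
import pandas as pd

from pvtarget.indentation import analyze
from pvtarget.synth import gen_indentation_curve

OUT = "results"
SURFACES = {"top": 56.4e3, "bottom": 72.2e3, "lumen": 87.6e3}


def main():
    rows = []
    for name, e_true in SURFACES.items():
        curve, rec = gen_indentation_curve(E_true=e_true)
        res = analyze(curve)
        rows.append(dict(surface=name, E_true_kPa=e_true / 1e3,
                         noise="none", seed=0,
                         E_recovered_kPa=res.E / 1e3,
                         rel_err_pct=100 * (res.E / e_true - 1),
                         S_N_per_m=res.S, hc_um=res.hc * 1e6,
                         Er_kPa=res.Er / 1e3))
        errs = []
        for seed in range(20):
            noisy, _ = gen_indentation_curve(E_true=e_true, noise_frac=0.02,
                                             seed=seed)
            errs.append(analyze(noisy).E / e_true - 1)
        rows.append(dict(surface=name, E_true_kPa=e_true / 1e3,
                         noise="2% force", seed="median of 20",
                         E_recovered_kPa=e_true / 1e3 * (1 + np.median(errs)),
                         rel_err_pct=100 * np.median(errs),
                         S_N_per_m=np.nan, hc_um=np.nan, Er_kPa=np.nan))
    df = pd.DataFrame(rows)
    df.to_csv(f"{OUT}/indentation_recovery.csv", index=False)
    print(df.to_string(index=False))
    clean = df[df.noise == "none"]
    print(f"\nnoise-free recovery bias: "
          f"{clean.rel_err_pct.min():+.1f}% to {clean.rel_err_pct.max():+.1f}% "
          f"(method bias at hmax/R = 0.4); ordering of the three surfaces "
          f"preserved: {clean.E_recovered_kPa.is_monotonic_increasing}")


if __name__ == "__main__":
    main()
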
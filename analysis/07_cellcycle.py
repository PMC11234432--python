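#!/usr/bin/env python
"""Cell-cycle deconvolution: recovery and the rapamycin-arrest scenario.

Fits the Dean-Jett-Fox model to synthetic PI histograms for a cycling
population (60/25/15), the rapamycin-arrest scenario (G1-enriched
80/10/10), and a TNF-alpha-like proliferative shift (lower G1), and
tables fitted vs generated phase fractions.

Writes results/cellcycle_fits.csv.
"""

import pandas as pd

from pvtarget.cellcycle import fit_djf
from pvtarget.synth import gen_dna_histogram

OUT = "results"

SCENARIOS = {
    "cycling control": (60.0, 25.0, 15.0),
    "rapamycin arrest (G1-enriched)": (80.0, 10.0, 10.0),
    "proliferative shift": (45.0, 35.0, 20.0),
}


def main():
    rows = []
    for name, (g1, s, g2m) in SCENARIOS.items():
        hist, rec = gen_dna_histogram(f_g1=g1, f_s=s, f_g2m=g2m, seed=5)
        m = fit_djf(hist)
        gt = rec.ground_truth
        rows.append(dict(scenario=name,
                         g1_true=gt["f_g1"], g1_fit=round(m.f_g1, 2),
                         s_true=gt["f_s"], s_fit=round(m.f_s, 2),
                         g2m_true=gt["f_g2m"], g2m_fit=round(m.f_g2m, 2),
                         ratio_g2=round(m.ratio_g2, 3)))
    df = pd.DataFrame(rows)
    df.to_csv(f"{OUT}/cellcycle_fits.csv", index=False)
    print(df.to_string(index=False))
    arrest = df.iloc[1]
    print(f"\nrapamycin-arrest scenario: G1 fraction {arrest.g1_fit:.1f}% "
          f"dominates S ({arrest.s_fit:.1f}%) and G2/M "
          f"({arrest.g2m_fit:.1f}%), the arrest signature")


if __name__ == "__main__":
    main()
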
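#!/usr/bin/env python
"""Population LFP power and frequency-resolved spatial reach vs input
correlation.

Simulates disc populations of deep-pyramidal cells with basal input at
several shared-input fractions c_in, accumulates the LFP of subpopulations
of growing radius, and reports the 95%-amplitude spatial reach per Welch
bin.  Correlated input boosts low-frequency power by orders of magnitude
and extends the reach toward the population radius; uncorrelated input
stays local (a few hundred micrometres) at every frequency.
"""

from pathlib import Path

import pandas as pd

from lfpreach.orchestration import ExperimentConfig, run_population

OUT = Path("results/population")


def main():
    cfg = ExperimentConfig(
        preset="L5-like", region="basal", n_cells=400, radius=1000.0,
        n_lateral=17, duration_ms=1200.0, seed=0,
    )
    res = run_population(cfg, OUT, c_values=[0.0, 0.2, 1.0])
    reach = pd.read_csv(OUT / "reach.csv")
    for c, grp in reach.groupby("c_in"):
        g = grp.sort_values("freq_hz")
        print(f"c_in={c}: reach {g.reach_um.iloc[1]:.0f} um near DC, "
              f"{g.reach_um.iloc[-1]:.0f} um at 500 Hz")
    coh = pd.read_csv(OUT / "coherence.csv")
    c1 = coh[coh.c_in == 1.0].sort_values("freq_hz")
    print(f"population-averaged coherence at c_in=1: "
          f"{c1.cbar.iloc[1]:.3f} near DC vs {abs(c1.cbar.iloc[-1]):.3f} "
          f"at 500 Hz (low-pass correlation transfer)")
    print("Tables in", OUT)


if __name__ == "__main__":
    main()
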
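#!/usr/bin/env python
"""Lateral decay of the population LFP and its detectability (SNR) outside
the active population.

For a basally driven deep-pyramidal population, the LFP measured outside
the disc is compared against the 'noise' signal of an equally sized
uncorrelated population with homogeneous input.  The distances at which the
rms signal-to-noise ratio falls below 0.5 and 0.1 are tabulated per Welch
bin.  Correlated populations remain detectable far outside their edge at
low frequencies; high-frequency components and uncorrelated populations
fade within a few hundred micrometres.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lfpreach.forward import ElectrodeGrid
from lfpreach.orchestration import ExperimentConfig
from lfpreach.population import (lateral_electrode_line, layout_disc,
                                 simulate_population, snr_profile)
from lfpreach.spectra import coherence_vs_offset

OUT = Path("results/lateral")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ExperimentConfig(preset="L5-like", region="basal", n_cells=400,
                           radius=1000.0, seed=0)
    model = cfg.model()
    grid = lateral_electrode_line(17, 2 * cfg.radius, 0.0, cfg.sigma)
    lay = layout_disc(cfg.n_cells, cfg.radius, seed=cfg.seed)
    noise = simulate_population(
        lay, model, cfg.input_spec(c_in=0.0, region="homogeneous",
                                   seed=cfg.seed + 1), grid)
    rows, coh_rows = [], []
    offsets = np.linalg.norm(grid.positions[:, :2], axis=1)
    for c in (0.0, 0.2, 1.0):
        rec = simulate_population(lay, model, cfg.input_spec(c_in=c), grid)
        prof = snr_profile(rec, noise, noise_reference="center")
        for thr, cross in prof.crossings.items():
            for b, f in enumerate(prof.freqs):
                rows.append({"c_in": c, "threshold": thr, "freq_hz": f,
                             "crossing_um": cross[b]})
        curves = coherence_vs_offset(rec.traces, offsets)
        for curve in curves:
            for b, f in enumerate(curve.freqs):
                coh_rows.append({"c_in": c, "offset_um": curve.offset,
                                 "freq_hz": f, "cbar": curve.values[b]})
        lowf = prof.crossings[0.5][1]
        highf = prof.crossings[0.5][-1]
        print(f"c_in={c}: SNR=0.5 crossing {lowf:.0f} um near DC, "
              f"{highf:.0f} um at 500 Hz")
    pd.DataFrame(rows).to_csv(OUT / "snr_crossings.csv", index=False)
    pd.DataFrame(coh_rows).to_csv(OUT / "coherence_vs_offset.csv", index=False)
    print("Low-frequency components of correlated populations extend "
          "farthest outside the disc. Tables in", OUT)


if __name__ == "__main__":
    main()
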
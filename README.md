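# lfpreach

Frequency-resolved modelling of the power and spatial reach of population
local field potentials (LFPs).

The LFP — the low-frequency part of extracellular recordings — sums the
transmembrane currents of many neurons, and two obvious questions about any
recording are *how large is the signal-generating region around the
electrode* and *how far does the signal spread outside an active
population*, both as functions of temporal frequency. `lfpreach` answers
them with a biophysical forward model at desk scale: passive
multicompartment neurons driven by correlated Poisson synaptic input,
mapped to extracellular potentials through volume-conductor theory, plus a
simplified mean-field model that makes the mechanisms explicit. It is
aimed at computational neuroscientists and electrophysiologists who want
quantitative intuition for LFP locality without a cluster-scale
simulation.

## Model

For a disc population of planar density ρ, the PSD of the LFP at the
population centre is

    S_pop(f) = S_in(f) · [ (1 − c̄(f)) · A0(R) + c̄(f) · A1(R) ]

    A0(R) = 2πρ ∫₀ᴿ F(r,f)² r dr        (incoherent: variances add)
    A1(R) = ( 2πρ ∫₀ᴿ F(r,f) r dr )²    (coherent: amplitudes add)

where `S_in` is the synaptic input-current PSD, `F(r,f)` the single-cell
*shape function* (rms LFP amplitude vs lateral distance, normalized by
√S_in), and `c̄(f)` the population-averaged coherence of single-cell
contributions. `F` is fitted by a piecewise power law `A/r0 → A/r →
A·ε/r²` whose cutoff distance `ε(f)` falls with frequency (intrinsic
dendritic filtering), and `c̄(f)` is estimated by exactly inverting the
combiner identity on Welch spectra. The *spatial reach* at a frequency is
the smallest radius delivering 95% of the full-population rms amplitude.
The full simulation engine (line-source forward model, frequency-domain
cable solver, shared-pool correlated Poisson drive) computes all of these
quantities from scratch; see `docs/methods.md`.

## Worked example

```python
import numpy as np
from lfpreach import (ElectrodeGrid, InputSpec, PassiveParams, discretize,
                      layout_disc, simulate_population, population_coherence,
                      cumulative_by_radius, compute_reach)
from lfpreach.presets import l5_like

model = discretize(l5_like(), PassiveParams(), max_compartment_length=20.0)
centre = ElectrodeGrid([[0.0, 0.0, 0.0]], sigma=0.3)
layout = layout_disc(n_cells=200, radius=1000.0, seed=0)

for c_in in (0.0, 1.0):
    spec = InputSpec(region="basal", c_in=c_in, duration_ms=1200.0, seed=1)
    rec = simulate_population(layout, model, spec, centre)
    cum = cumulative_by_radius(rec, np.arange(100.0, 1001.0, 100.0))
    reach = compute_reach(np.sqrt(cum.psd), cum.radii)
    cbar = population_coherence(rec.per_cell_traces(0))
    print(f"c_in={c_in}: reach {reach[1]:.0f} um at 31 Hz, "
          f"{reach[-1]:.0f} um at 500 Hz; "
          f"coherence {cbar.values[1]:.3f} at 31 Hz")
```

Output:

```
c_in=0.0: reach 300 um at 31 Hz, 300 um at 500 Hz; coherence 0.003 at 31 Hz
c_in=1.0: reach 900 um at 31 Hz, 500 um at 500 Hz; coherence 0.206 at 31 Hz
```

With uncorrelated input the LFP is local (~300 µm) at every frequency and
the single-cell contributions are incoherent. Fully shared input onto the
basal dendrites makes the low-frequency contributions coherent
(c̄ ≈ 0.21 at 31 Hz), which boosts low-frequency power and stretches the
31 Hz reach to essentially the population radius, while at 500 Hz — where
the dendritic cable no longer transfers the input correlation — the reach
stays much smaller.

The `analysis/` scripts run the full study at desk scale (single-cell
shape functions and ε(f) for all cell/input patterns, population reach vs
correlation, lateral decay and detectability, depth profiles, and the
mean-field vs simulation comparison), writing tables under `results/`.
A `lfpreach` command-line front end wraps the same recipes
(`lfpreach single-cell|population|meanfield --seed 0 -o results`).

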
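# Methods

## Scope and model

`lfpreach` models the extracellular local field potential (LFP) generated
by synaptically driven populations of passive cortical neurons, resolved by
temporal frequency. The pipeline has three tiers:

1. **Single cell.** A morphology (tree of cylindrical segments labelled
   soma/basal/apical) is discretized into compartments with membrane
   capacitance `C_k = C_m a_k`, leak `G_k = a_k / R_m` and axial couplings
   from the half-compartment cylinder resistances. With purely passive
   membranes and current-based synapses the system is linear, so it is
   solved per temporal frequency: `(i w C + G_L + L_ax) V = I_in`, and the
   extracellular source is the total transmembrane current
   `I_m = (i w C + G_L) V - I_in` (positive outward; it sums to zero over
   the cell at every frequency). Potentials follow from volume-conductor
   theory in an infinite homogeneous ohmic medium, `phi = I/(4 pi sigma R)`
   for a point source and its analytic integral along each cylindrical
   compartment (line-source method); the electrode is an ideal point and
   can never be closer to a source than the neurite radius (radial
   distances are clamped there).

2. **Population.** `n` copies of one morphology are placed uniformly in a
   disc of radius `R` at a common soma depth, each rotated randomly about
   the vertical axis. Every cell receives `n_syn` excitatory
   alpha-function current synapses placed with probability proportional to
   compartment membrane area within the target region (apical, basal, or
   homogeneous). Each synapse is driven by a homogeneous Poisson train at
   rate 5 spikes/s; pairwise input correlation `c_in` between cells is
   created by drawing each cell's trains without replacement from a common
   pool of `round(n_syn/c_in)` trains (expected pairwise overlap
   `n_syn c_in`; shared trains land on independently drawn synaptic
   locations in every cell). The population LFP is the exact sum of the
   per-cell contributions.

3. **Simplified (mean-field) model.** The single-cell LFP PSD is
   factorized as `S_1(r, f) = S_in(f) F(r, f)^2`, where the *shape
   function* F depends only on frequency and lateral distance. F is
   approximated by a piecewise power law — plateau `A/r0` inside `r0`,
   near-field `A/r` up to the *cutoff distance* `eps(f)`, dipolar
   `A eps/r^2` beyond — fitted in log-log space with slopes fixed at -1
   and -2, the amplitude solved in closed form per candidate breakpoint
   and `eps` located by a grid search refined by golden-section (ties
   toward smaller `eps`). The population PSD at the disc centre is

       S_pop(f) = S_in(f) [ (1 - cbar(f)) A0(R) + cbar(f) A1(R) ],
       A0 = 2 pi rho Int_0^R F^2 r dr,   A1 = (2 pi rho Int_0^R F r dr)^2,

   with `rho` the planar cell density and `cbar(f)` the
   population-averaged coherence of single-cell contributions, estimated
   by inverting the same identity:
   `cbar = (S_pop - sum S_i) / ((sum sqrt(S_i))^2 - sum S_i)` on Welch
   spectra. The estimator is exact for identical traces (`cbar = 1`) and
   for cancelling equal-power traces (`-1/(N-1)`); spurious negative bins
   are flagged and their magnitude used downstream. Both integrals have
   closed forms under the law (verified against adaptive quadrature to
   1e-8 relative); `A0` saturates with `R` while `A1` grows like
   `log^2 R`. The *spatial reach* at a frequency is the smallest grid
   radius whose rms amplitude reaches 95% of the largest-population
   amplitude (grid point, not interpolated). For electrodes offset
   laterally by `X`, `F` is evaluated at the distance from the electrode
   and integrated over the disc through the coverage-angle reduction to a
   one-dimensional adaptive quadrature; per-depth shape functions and
   coherences give vertical profiles.

## Numerical engine

Because every map is linear, population traces are synthesized in the
frequency domain on the 1 kHz recording grid rather than by
sub-millisecond time stepping:

* Spike trains enter through their continuous-time Fourier sums
  `sum_s exp(-2 pi i f t_s)` (computed by a stable geometric recurrence on
  the uniform grid), and the alpha kernel through its analytic transform
  `A e tau / (1 + i w tau)^2`. For very large train pools an equivalent
  binned path quantizes spike times to the 1 ms recording grid and uses
  one real FFT per (cell, compartment) channel; the binned counting
  process has the same flat spectral statistics, and shared trains remain
  identical across cells, so correlation transfer is preserved. The two
  paths agree within sampling error and the choice is a deterministic
  function of the problem size.
* The cable system `K + i w C` (with `K` real symmetric) is diagonalized
  once per morphology (`S = C^{-1/2} K C^{-1/2} = Q L Q^T`), after which
  every frequency is a diagonal solve and all cells are handled by two
  wide real GEMMs. Charge conservation holds to ~1e-13 relative.
* Traces are periodic in the effective duration; there is no start-up
  transient to discard, so an `InputSpec` duration of 1200 ms with a
  200 ms transient yields a 1000 ms synthesized record (matching the
  convention of discarding an initial transient from a stepped
  simulation). An independent backward-Euler integrator at 1/64 ms exists
  purely as a test oracle and agrees with the frequency-domain path within
  1% RMS.

Expected single-cell PSDs are also available in closed form: for
independent Poisson synapses the one-sided PSD is
`2 rate |alpha_ft|^2 sum_j w_j n_syn |L(e, j, f)|^2`, averaged over the
cell's azimuthal rotation. The azimuth average uses 64 samples with an
irrational phase offset; fewer, symmetric samples alias the sharp
near-field peaks around individual dendrites and can overestimate the
near-field shape function severalfold.

## Parameters and defaults

| parameter | default | notes |
|---|---|---|
| axial resistivity | 150 Ohm cm | conventional cortical value; configurable |
| membrane resistance | 30 kOhm cm^2 | membrane time constant 30 ms |
| membrane capacitance | 1.0 uF/cm^2 | |
| max compartment length | 20 um | halving it changes soma-level PSDs by <1% |
| sigma (extracellular) | 0.3 S/m | potentials scale exactly as 1/sigma |
| synapses per cell | 1000 | |
| train rate | 5 s^-1 | homogeneous Poisson |
| alpha tau | 0.02 ms | keeps the synaptic spectrum flat to <1% at 500 Hz; a configuration warning fires if flatness drops below 0.99 |
| alpha amplitude | 0.1 nA peak | pure scale factor (cancels in shape functions and coherence) |
| durations | 10200 ms (centre-PSD and shape-function runs), 1200 ms (fast runs); first 200 ms discarded | |
| sampling | 1 kHz; Welch Hanning window 32 or 128 samples, 50% overlap, per-window mean removal | 17 or 65 bins spanning 0-500 Hz |
| population | n = 1000 cells in R = 1000 um by default | analyses that compare against the continuum mean-field model use n = 200 in R = 250 um so the planar density (~1000 cells/mm^2) stays in the biologically plausible range of a few thousand LFP sources per mm^2 |
| r0 policy | soma level: max(closest sampled distance, 10 um); other depths: vertical offset from the soma plane (floor 10 um) | A0 depends only logarithmically on r0 |
| reach grid | 100 um steps to R | |

One master seed drives named `SeedSequence` substreams (pool, assignments,
placements, rotations, layout, trials), so any single stage can be re-run
reproducibly and changing, e.g., the cell count does not shift the spike
realisations of other streams.

## Synthetic morphologies

The stylized templates stand in for reconstructed cells: a pyramidal
template (single-cylinder soma; vertical apical trunk with a horizontal
tuft fan; basal star tilted 20 degrees below horizontal) in deep (L5-like,
800 um trunk) and superficial (L3-like, 400 um trunk) variants, and a
stellate template with deterministically isotropic dendrites (antipodal
pairs from a golden-angle spiral, so the direction sum vanishes). They
reproduce the geometric features that control LFP generation — spatial
asymmetry of input vs return current, vertical dendritic extent, presence
or absence of polarity — but not the detailed branching, diameter taper or
surface statistics of real reconstructions. Passing tests therefore
demonstrate the mechanisms (intrinsic dendritic filtering, correlation
transfer, reach growth with correlation, dumbbell depth profiles), not
quantitative parameter values for any particular cell type; all headline
numbers (cutoff distances, reach values) are specific to these templates
and the defaults above. SWC import is provided for users who wish to run
the pipeline on real reconstructions.

## Design choices and edge cases

* The population combiner is fixed to
  `S_pop = S_in [(1-cbar) A0 + cbar A1]` — the unique form linear in
  `cbar` that reduces to variance addition at `cbar = 0` and amplitude
  addition at `cbar = 1`. The coherence estimator is its exact inversion
  (the denominator uses `(sum sqrt(S_i))^2 - sum S_i` exactly, not the
  equal-power approximation).
* Coherence values outside `[-1/(N-1), 1]` are clipped with a warning;
  undefined bins (zero traces) are NaN-flagged.
* rms from a PSD uses the trapezoidal rule over the equally spaced bins
  (edge bins at half weight), so a flat PSD of height `h` over bandwidth
  `B` gives exactly `sqrt(h B)`.
* Welch detrending (per-window mean removal) biases the DC bin low by
  design; analytic-vs-measured comparisons therefore either use matched
  conventions on both sides or skip the DC bin where one side is an
  un-detrended closed form.
* Detectability (SNR) analyses use the noise population's
  centre-electrode PSD as a constant ambient level per frequency
  (`noise_reference="center"`), modelling an electrode embedded in its own
  inactive background population; the per-electrode ratio remains available
  as `"local"`.
* Zero-length segments fall back to point sources; empty subpopulations in
  cumulative-radius scans are flagged rather than erroring; degenerate
  single-regime shape tables pin `eps` to the sampled boundary with a
  warning.
* Test and acceptance problem sizes (100-400 cells, 1.2 s traces for
  stochastic aggregates over 10-20 seeds; one 10.2 s run for the
  mean-field comparison) were chosen as the smallest sizes at which the
  qualitative contrasts are stable across seeds.

## Known limitations

* Passive membranes and current synapses only: no spikes, no
  conductance-based or quasi-active effects; contributions above ~100 Hz
  in real recordings may include spike currents not modelled here.
* The medium is infinite, homogeneous, isotropic and ohmic; no electrode
  filtering or boundary effects.
* All cells in a population share one morphology and soma depth; only
  position and azimuthal rotation vary.
* The simplified model inherits the factorization assumption (F depends
  only on lateral distance); it systematically overestimates far-outside
  power for correlated populations unless the offset-resolved coherence
  `cbar(X, f)` is supplied, and it is least accurate for small correlated
  subpopulations unless the coherence is re-estimated per radius.
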
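"""Disc populations of identical cells and their summed extracellular signal.

Cells share one canonical morphology; each instance differs only by a
uniform-in-area lateral position inside a disc of radius R, a uniform random
rotation about the vertical axis, its synapse placement and its spike trains.
Because the cable model and the volume conductor are both linear, the
per-cell LFP is synthesized in the frequency domain: each cell's synaptic
drive is reduced to per-compartment current spectra on the 1 kHz recording
grid (spike trains entering through their exact continuous-time Fourier sums
and the alpha kernel through its analytic transform), one sparse cable solve
per frequency (shared across cells) converts them to transmembrane-current
spectra, and the cell-specific line-source weights project them onto the
electrodes.  This is mathematically identical to summing per-compartment
contributions per time step, and is unit-tested against that brute-force
path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .cable import (CompartmentalModel, SpectralSolver, TransferKernelSet,
                    frequency_grid)
from .forward import ElectrodeGrid, geometry_weights
from .inputs import (InputSpec, RegionMissingError, SpikeTrainPool,
                     alpha_kernel_ft, build_pool, place_synapses,
                     pool_train_spectra)
from .rng import substream
from .spectra import PSDMatrix, rms_from_psd, welch_psd

DEFAULT_FS = 1000.0


class PopulationError(ValueError):
    pass


@dataclass
class PopulationLayout:
    """Lateral positions (um), azimuthal rotations (rad) and soma depth of a
    disc population."""

    n_cells: int
    radius: float
    soma_depth: float
    xy: np.ndarray          # (n_cells, 2)
    rotations: np.ndarray   # (n_cells,)

    @property
    def density_per_um2(self) -> float:
        return self.n_cells / (np.pi * self.radius**2)

    @property
    def density_per_mm2(self) -> float:
        return self.density_per_um2 * 1e6

    def lateral_distances(self, point_xy=(0.0, 0.0)) -> np.ndarray:
        p = np.asarray(point_xy, dtype=float)
        return np.linalg.norm(self.xy - p[None, :], axis=1)


def layout_disc(n_cells: int, radius: float, soma_depth: float = 0.0,
                seed: int = 0) -> PopulationLayout:
    """Uniform-in-area placement: r = R*sqrt(u), angle uniform; rotations
    uniform on [0, 2 pi)."""
    if n_cells < 1:
        raise PopulationError("n_cells must be >= 1")
    if not (radius > 0):
        raise PopulationError("radius must be positive")
    rng_layout = substream(seed, "layout")
    rng_rot = substream(seed, "rotations")
    r = radius * np.sqrt(rng_layout.uniform(size=n_cells))
    theta = rng_layout.uniform(0.0, 2 * np.pi, size=n_cells)
    xy = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    rotations = rng_rot.uniform(0.0, 2 * np.pi, size=n_cells)
    return PopulationLayout(n_cells, radius, soma_depth, xy, rotations)


@dataclass
class LFPRecord:
    """Per-electrode, per-cell potential traces (uV) at ``fs``.

    ``traces`` has shape (n_electrodes, n_cells, n_samples); the population
    signal is their exact sum over cells.  ``input_traces`` carries each
    cell's total synaptic input current (nA) for input-spectrum
    normalization.
    """

    electrodes: ElectrodeGrid
    layout: PopulationLayout
    spec: InputSpec
    fs: float
    traces: np.ndarray
    input_traces: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.traces.shape[-1]

    def population_trace(self, electrode: int | None = None) -> np.ndarray:
        pop = self.traces.sum(axis=1)
        return pop if electrode is None else pop[electrode]

    def per_cell_traces(self, electrode: int) -> np.ndarray:
        return self.traces[electrode]


def _electrodes_in_cell_frame(positions, x, y, rotation, soma_depth):
    p = positions - np.array([x, y, soma_depth])
    c, s = np.cos(-rotation), np.sin(-rotation)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return p @ rot.T


def cell_input_spectra(
    model: CompartmentalModel,
    spec: InputSpec,
    pool: SpikeTrainPool,
    placements: np.ndarray,
    freqs: np.ndarray,
    pool_spectra: np.ndarray | None = None,
) -> np.ndarray:
    """(n_cells, N, F) injected-current spectra from trains and placements."""
    n_cells, n_syn = pool.assignments.shape
    N = model.n_compartments
    if pool_spectra is None:
        pool_spectra = pool_train_spectra(pool.trains, freqs)
    alpha = alpha_kernel_ft(freqs, spec.tau_ms, spec.amplitude_na)
    rows = (np.arange(n_cells)[:, None] * N + placements).ravel()
    cols = pool.assignments.ravel()
    P = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_cells * N, pool.n_trains)
    )
    B = (P @ pool_spectra).reshape(n_cells, N, len(freqs))
    return B * alpha[None, None, :]


def _binned_cell_spectra(model, spec, pool, placements, cells, freqs,
                         n_samples, fs) -> np.ndarray:
    """(len(cells), N, F) input spectra via 1-sample binning of spike times.

    Spike times are quantized to the recording grid and transformed with one
    real FFT per (cell, compartment) channel.  The binned counting process
    has the same (flat) spectral statistics as the exact delta train — only
    sub-sample phase is quantized — and shared trains stay identical across
    cells, so correlation transfer is preserved.  Used automatically when the
    exact per-train Fourier sums would be too costly.
    """
    N = model.n_compartments
    dt = 1000.0 / fs
    counts = np.zeros((len(cells), N, n_samples))
    for li, ci in enumerate(cells):
        idx = pool.assignments[ci]
        parts = [pool.trains[j] for j in idx]
        lens = np.array([len(p) for p in parts])
        if lens.sum() == 0:
            continue
        times = np.concatenate(parts)
        bins = np.minimum((times / dt).astype(int), n_samples - 1)
        comp = np.repeat(placements[ci], lens)
        np.add.at(counts[li], (comp, bins), 1.0)
    B = np.fft.rfft(counts, axis=-1)
    alpha = alpha_kernel_ft(freqs, spec.tau_ms, spec.amplitude_na)
    return B * alpha[None, None, :]


def simulate_population(
    layout: PopulationLayout,
    model: CompartmentalModel,
    input_spec: InputSpec,
    electrodes: ElectrodeGrid,
    fs: float = DEFAULT_FS,
    kernels: TransferKernelSet | None = None,
    soma_point_source: bool = False,
    method: str = "auto",
) -> LFPRecord:
    """Simulate the population LFP; see the module docstring for the method.

    ``method`` selects how synaptic-drive spectra are built: "exact"
    (continuous-time Fourier sums per pool train), "binned" (spike counts on
    the recording grid, FFT per cell/compartment channel) or "auto" (exact
    unless the spike-count times frequency-bin product makes it slower than
    binning).  If a precomputed ``kernels`` set matching the frequency grid
    is supplied, transmembrane currents are obtained by applying it instead
    of solving the cable system per frequency — the two paths are
    mathematically identical.
    """
    spec = input_spec
    n_cells = layout.n_cells
    N = model.n_compartments
    n_samples = int(round(spec.effective_duration_ms * fs / 1000.0))
    freqs = frequency_grid(n_samples, fs)
    F = len(freqs)

    pool = build_pool(spec, n_cells)
    rng_place = substream(spec.seed, "placements")
    placements = np.stack(
        [place_synapses(model, spec, rng_place) for _ in range(n_cells)]
    )

    if method == "auto":
        pool_spikes = sum(len(t) for t in pool.trains)
        method = "exact" if pool_spikes * F <= 2e9 else "binned"
    if method not in ("exact", "binned"):
        raise PopulationError(f"unknown synthesis method {method!r}")

    # cell blocks bound the (block, N, F) workspaces
    block = max(1, int(2.5e7 // max(1, N * F)))
    if method == "exact" and spec.c_in == 0.0:
        # each cell owns a disjoint train range; keep block-local pools small
        block = min(block, max(1, int(1.0e7 // max(1, spec.n_synapses * F))))
    pool_spectra = None
    if method == "exact" and spec.c_in > 0.0:
        pool_spectra = pool_train_spectra(pool.trains, freqs)

    solver = SpectralSolver(model) if kernels is None else None
    E = electrodes.n_electrodes
    traces = np.empty((E, n_cells, n_samples))
    input_traces = np.empty((n_cells, n_samples))
    clamp_hits = 0

    for lo in range(0, n_cells, block):
        cells = np.arange(lo, min(lo + block, n_cells))
        # -- synaptic drive spectra (cells, N, F), units nA*s -------------
        if method == "binned":
            Bblk = _binned_cell_spectra(model, spec, pool, placements,
                                        cells, freqs, n_samples, fs)
        else:
            if spec.c_in == 0.0:
                t0, t1 = cells[0] * spec.n_synapses, (cells[-1] + 1) * spec.n_synapses
                local_spectra = pool_train_spectra(pool.trains[t0:t1], freqs)
                local_assign = pool.assignments[cells] - t0
            else:
                local_spectra = pool_spectra
                local_assign = pool.assignments[cells]
            rows = (np.arange(len(cells))[:, None] * N + placements[cells]).ravel()
            P = sp.csr_matrix(
                (np.ones(rows.size), (rows, local_assign.ravel())),
                shape=(len(cells) * N, local_spectra.shape[0]),
            )
            Bblk = (P @ local_spectra).reshape(len(cells), N, F)
            alpha = alpha_kernel_ft(freqs, spec.tau_ms, spec.amplitude_na)
            Bblk = Bblk * alpha[None, None, :]
        # -- geometry weights for the block -------------------------------
        G = np.empty((len(cells), E, N))
        for li, ci in enumerate(cells):
            pos = _electrodes_in_cell_frame(
                electrodes.positions, layout.xy[ci, 0], layout.xy[ci, 1],
                layout.rotations[ci], layout.soma_depth,
            )
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                G[li] = geometry_weights(
                    model, pos, electrodes.sigma,
                    soma_point_source=soma_point_source,
                )
            clamp_hits += sum("clamping" in str(w.message) for w in wlist)
        # -- cable solve and projection -----------------------------------
        if kernels is not None:
            Bc = np.ascontiguousarray(Bblk.transpose(2, 1, 0))  # (F, N, cells)
            Imem = np.einsum("fkj,fjc->fkc", kernels.H, Bc)
            phi = np.einsum("ces,fsc->ecf", G, Imem)
        else:
            Bn = np.ascontiguousarray(Bblk.transpose(1, 2, 0))  # (N, F, cells)
            Imem = solver.membrane_currents_nfr(freqs, Bn)
            phi = np.einsum("ces,sfc->ecf", G, Imem)
        # both paths produce continuous-time Fourier sums (units * seconds);
        # the Fourier-series coefficient is phi/T and irfft carries a 1/n
        # factor, so the sampled periodic signal is irfft(phi) * fs.
        traces[:, cells, :] = np.fft.irfft(phi, n=n_samples, axis=-1) * fs
        input_traces[cells] = np.fft.irfft(
            Bblk.sum(axis=1), n=n_samples, axis=-1
        ) * fs

    if clamp_hits:
        warnings.warn(
            f"electrode inside the membrane clamp radius for {clamp_hits} "
            "cells; distances clamped"
        )
    return LFPRecord(
        electrodes=electrodes, layout=layout, spec=spec, fs=fs,
        traces=traces, input_traces=input_traces, seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# analyses over records
# ---------------------------------------------------------------------------

@dataclass
class CumulativeByRadius:
    radii: np.ndarray
    freqs: np.ndarray
    psd: np.ndarray          # (n_radii, n_bins)
    amplitude: np.ndarray    # (n_radii,)
    empty: np.ndarray        # (n_radii,) True where no cell included
    electrode: int


def cumulative_by_radius(
    record: LFPRecord,
    radii,
    electrode: int = 0,
    window_len: int = 32,
) -> CumulativeByRadius:
    """PSD and rms amplitude of subpopulations of increasing radius.

    Subpopulation r includes exactly the cells whose lateral distance from
    the electrode axis is <= r (inclusive tie rule).  The largest radius
    reproduces the full population signal when it covers every cell.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) < 0):
        raise PopulationError("radii must be sorted ascending")
    exy = record.electrodes.positions[electrode, :2]
    dist = record.layout.lateral_distances(exy)
    n_bins = window_len // 2 + 1
    psd = np.zeros((len(radii), n_bins))
    amp = np.zeros(len(radii))
    empty = np.zeros(len(radii), dtype=bool)
    freqs = None
    for k, r in enumerate(radii):
        sel = dist <= r
        if not np.any(sel):
            empty[k] = True
            freqs = welch_psd(np.zeros(record.n_samples), fs=record.fs,
                              window_len=window_len).freqs
            continue
        trace = record.traces[electrode, sel].sum(axis=0)
        p = welch_psd(trace, fs=record.fs, window_len=window_len)
        freqs = p.freqs
        psd[k] = p.values
        amp[k] = rms_from_psd(p)
    return CumulativeByRadius(radii=radii, freqs=freqs, psd=psd,
                              amplitude=amp, empty=empty, electrode=electrode)


@dataclass
class SNRProfile:
    distances: np.ndarray    # lateral distance of each electrode (um)
    freqs: np.ndarray
    snr: np.ndarray          # (n_electrodes, n_bins), rms ratio per bin
    crossings: dict          # threshold -> (n_bins,) distance of crossing


def snr_profile(
    signal_record: LFPRecord,
    noise_record: LFPRecord,
    window_len: int = 32,
    thresholds=(0.5, 0.1),
    noise_reference: str = "local",
) -> SNRProfile:
    """Per-bin rms signal-to-noise ratio along the electrode grid.

    The noise reference is the signal of a population of uncorrelated cells
    with homogeneous input.  With ``noise_reference="local"`` the ratio is
    taken electrode by electrode; with ``"center"`` the noise level is the
    noise population's centre-electrode PSD applied everywhere — the ambient
    background an electrode embedded in its own inactive population would
    see, which is the convention for detectability-vs-distance analyses.
    Crossing distances report, per frequency bin, where the SNR first falls
    below each threshold when scanning outward; NaN if it never does.  Zero
    noise power in a bin yields an infinite SNR there.
    """
    if signal_record.electrodes.n_electrodes != noise_record.electrodes.n_electrodes:
        raise PopulationError("records must share the electrode grid")
    sig = welch_psd(signal_record.population_trace(), fs=signal_record.fs,
                    window_len=window_len)
    noi = welch_psd(noise_record.population_trace(), fs=noise_record.fs,
                    window_len=window_len)
    if noise_reference == "center":
        centre = int(np.argmin(
            np.linalg.norm(noise_record.electrodes.positions[:, :2], axis=1)))
        noi.values = np.broadcast_to(
            noi.values[centre], sig.values.shape).copy()
    elif noise_reference != "local":
        raise PopulationError("noise_reference must be 'local' or 'center'")
    with np.errstate(divide="ignore"):
        snr = np.sqrt(np.where(noi.values > 0, sig.values / np.where(
            noi.values > 0, noi.values, 1.0), np.inf))
    dist = np.linalg.norm(signal_record.electrodes.positions[:, :2], axis=1)
    order = np.argsort(dist)
    crossings = {}
    for thr in thresholds:
        cross = np.full(snr.shape[1], np.nan)
        for b in range(snr.shape[1]):
            prof = snr[order, b]
            below = prof < thr
            if below[0]:
                cross[b] = dist[order][0]
            elif below.any():
                cross[b] = dist[order][np.argmax(below)]
        crossings[thr] = cross
    return SNRProfile(distances=dist, freqs=sig.freqs, snr=snr,
                      crossings=crossings)


# ---------------------------------------------------------------------------
# single-cell shape-function measurements
# ---------------------------------------------------------------------------

def single_cell_psd_analytic(
    model: CompartmentalModel,
    spec: InputSpec,
    electrode_positions: np.ndarray,
    freqs: np.ndarray,
    sigma: float,
    n_azimuth: int = 64,
    fs: float | None = DEFAULT_FS,
) -> np.ndarray:
    """Expected one-sided single-cell LFP PSD (uV^2/Hz) at given positions.

    Expectation is over Poisson spike times, synapse placement (area weights
    within the input region) and the cell's azimuthal rotation (averaged over
    ``n_azimuth`` angles).  For independent-synapse shot noise the PSD is
    ``2 rate |alpha_ft|^2 sum_j w_j n |L(e, j, f)|^2`` — one cable solve per
    frequency, no Monte Carlo.
    """
    from .cable import membrane_current_spectra

    positions = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    mask = model.region_mask(spec.region)
    areas = np.where(mask, model.areas, 0.0)
    if areas.sum() <= 0:
        raise RegionMissingError(f"region {spec.region!r} missing from model")
    w = areas / areas.sum()
    N = model.n_compartments
    eye = np.broadcast_to(np.eye(N, dtype=complex), (len(freqs), N, N))
    H = membrane_current_spectra(model, freqs, np.ascontiguousarray(eye))
    alpha2 = np.abs(alpha_kernel_ft(freqs, spec.tau_ms, spec.amplitude_na)) ** 2
    factor = np.full(len(freqs), 2.0)
    if fs is not None:
        factor[np.isclose(freqs, 0.0)] = 1.0
        factor[np.isclose(freqs, fs / 2.0)] = 1.0
    out = np.zeros((positions.shape[0], len(freqs)))
    for k in range(n_azimuth):
        # irrational offset so the samples never align with a discrete
        # rotational symmetry of the morphology (which would alias the
        # sharp near-field peaks around individual dendrites)
        ang = 2 * np.pi * (k + 0.3819660) / n_azimuth
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        G = geometry_weights(model, positions @ rot.T, sigma,
                             warn_on_clamp=False)
        L = np.einsum("ek,fkj->fej", G, H)  # (F, E, N)
        out += (np.abs(L) ** 2 @ w).T / n_azimuth
    return out * (factor * alpha2 * spec.rate * spec.n_synapses)[None, :]


def single_cell_psd_simulated(
    model: CompartmentalModel,
    spec: InputSpec,
    electrode_positions: np.ndarray,
    sigma: float,
    n_trials: int = 100,
    window_len: int = 32,
    fs: float = DEFAULT_FS,
) -> PSDMatrix:
    """Trial-averaged Welch PSD of a simulated single cell (random rotation,
    placement and spikes per trial) at the given electrode positions."""
    positions = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    grid = ElectrodeGrid(positions, sigma=sigma)
    acc = None
    for trial in range(n_trials):
        trial_seed = int(
            substream(spec.seed, "trials", trial).integers(0, 2**31 - 1)
        )
        layout = PopulationLayout(
            n_cells=1, radius=1.0, soma_depth=model.soma_depth,
            xy=np.zeros((1, 2)),
            rotations=substream(trial_seed, "rotations").uniform(0, 2 * np.pi, 1),
        )
        from .inputs import with_seed
        rec = simulate_population(layout, model,
                                  with_seed(spec, trial_seed), grid, fs=fs)
        p = welch_psd(rec.population_trace(), fs=fs, window_len=window_len)
        acc = p.values if acc is None else acc + p.values
    return PSDMatrix(freqs=p.freqs, values=acc / n_trials, fs=fs,
                     window_len=window_len)


def lateral_electrode_line(
    n_positions: int, max_distance: float, depth: float,
    sigma: float = 0.3,
) -> ElectrodeGrid:
    """Electrodes on a lateral line from the centre outward at fixed depth."""
    x = np.linspace(0.0, max_distance, n_positions)
    pos = np.stack([x, np.zeros_like(x), np.full_like(x, depth)], axis=1)
    return ElectrodeGrid(pos, sigma=sigma)


def depth_electrode_column(
    depths: np.ndarray, sigma: float = 0.3, x: float = 0.0
) -> ElectrodeGrid:
    depths = np.asarray(depths, dtype=float)
    pos = np.stack(
        [np.full_like(depths, x), np.zeros_like(depths), depths], axis=1
    )
    return ElectrodeGrid(pos, sigma=sigma)
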
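"""Experiment configuration and canned analysis recipes.

Three recipes reproduce the study's analyses at desk scale:

* ``run_single_cell`` — frequency-resolved single-cell shape functions on a
  lateral distance grid and the fitted cutoff distances eps(f);
* ``run_population`` — disc-population simulation: population PSD,
  population-averaged coherence (centre, offsets, depths), cumulative
  amplitude vs subpopulation radius and the derived spatial reach, and the
  detectability (SNR) profile against an uncorrelated homogeneous-input
  reference population;
* ``run_meanfield`` — simplified-model predictions assembled from the shape
  functions and the measured coherence, overlaid on the simulated population
  PSD with a per-bin residual report.

Every run writes a manifest (config hash, seed, library versions) next to
its CSV outputs, sufficient to re-run any table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import presets
from .cable import PassiveParams, discretize
from .forward import ElectrodeGrid
from .inputs import InputSpec, analytic_input_psd
from .meanfield import (a0_from_table, a1_from_table, compute_reach,
                        estimate_shape, fit_piecewise)
from .morphology import read_swc
from .population import (cumulative_by_radius, depth_electrode_column,
                         lateral_electrode_line, layout_disc,
                         simulate_population, single_cell_psd_analytic,
                         snr_profile)
from .spectra import population_coherence, welch_psd

log = logging.getLogger("lfpreach")


@dataclass
class ExperimentConfig:
    """Schema for one experiment; defaults give the desk-scale setup."""

    preset: str = "L5-like"            # morphology preset name
    swc_path: str | None = None        # overrides preset if given
    soma_depth: float = 0.0
    # passive membrane
    axial_resistivity: float = 150.0
    membrane_resistance: float = 30000.0
    membrane_capacitance: float = 1.0
    max_compartment_length: float = 20.0
    # synaptic input
    n_synapses: int = 1000
    rate: float = 5.0
    c_in: float = 0.0
    region: str = "basal"
    duration_ms: float = 1200.0        # fast preset; 10200 for long runs
    discard_ms: float = 200.0
    tau_ms: float = 0.02
    amplitude_na: float = 0.1
    # population
    n_cells: int = 1000
    radius: float = 1000.0
    sigma: float = 0.3
    # electrodes
    n_lateral: int = 33
    depth_points: int = 0              # 0: soma level only
    # analysis
    window_len: int = 32
    radii_step: float = 100.0
    reach_fraction: float = 0.95
    shape_distances: tuple = tuple(float(x) for x in
                                   np.geomspace(10.0, 3000.0, 25).round(2))
    seed: int = 0

    def __post_init__(self):
        self.shape_distances = tuple(float(x) for x in self.shape_distances)

    # -- plumbing -----------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "shape_distances" in data:
            data["shape_distances"] = tuple(data["shape_distances"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- derived objects ----------------------------------------------------
    def morphology(self):
        if self.swc_path:
            return read_swc(self.swc_path).with_soma_depth(self.soma_depth)
        return presets.get_preset(self.preset, soma_depth=self.soma_depth)

    def passive(self) -> PassiveParams:
        return PassiveParams(self.axial_resistivity, self.membrane_resistance,
                             self.membrane_capacitance)

    def model(self):
        return discretize(self.morphology(), self.passive(),
                          self.max_compartment_length)

    def input_spec(self, **overrides) -> InputSpec:
        kw = dict(
            n_synapses=self.n_synapses, rate=self.rate, c_in=self.c_in,
            region=self.region, duration_ms=self.duration_ms,
            discard_ms=self.discard_ms, tau_ms=self.tau_ms,
            amplitude_na=self.amplitude_na, seed=self.seed,
        )
        kw.update(overrides)
        return InputSpec(**kw)

    def electrode_grid(self, model) -> ElectrodeGrid:
        """Lateral line from the centre to 2R at soma level, plus an optional
        depth column at the centre spanning the dendritic extent."""
        lat = lateral_electrode_line(
            self.n_lateral, 2 * self.radius, self.soma_depth, self.sigma
        ).positions
        if self.depth_points > 0:
            zlo, zhi = (model.starts[:, 2].min(), model.ends[:, 2].max())
            depths = np.linspace(zlo, zhi, self.depth_points) + self.soma_depth
            col = depth_electrode_column(depths, self.sigma).positions
            lat = np.vstack([lat, col])
        return ElectrodeGrid(lat, sigma=self.sigma)


def write_manifest(outdir: Path, cfg: ExperimentConfig, stage: str,
                   extra: dict | None = None) -> None:
    import scipy

    manifest = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "seed": cfg.seed,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    manifest["config"]["shape_distances"] = list(
        manifest["config"]["shape_distances"]
    )
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def _welch_bin_freqs(cfg: ExperimentConfig, fs: float = 1000.0) -> np.ndarray:
    return np.fft.rfftfreq(cfg.window_len, 1.0 / fs)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------

def run_single_cell(cfg: ExperimentConfig, outdir) -> dict:
    """Shape-function tables F(r, f) and fitted cutoff distances eps(f).

    Uses the analytic (expectation over spikes, placement and rotation)
    single-cell PSD, so the outputs are deterministic for a given config.
    """
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = cfg.model()
    spec = cfg.input_spec()
    freqs = _welch_bin_freqs(cfg)
    dist = np.asarray(cfg.shape_distances, dtype=float)
    positions = np.stack(
        [dist, np.zeros_like(dist), np.full_like(dist, cfg.soma_depth)], axis=1
    )
    S_single = single_cell_psd_analytic(
        model, spec, positions, freqs, cfg.sigma
    )
    S_in = analytic_input_psd(spec, freqs, fs=1000.0)
    table = estimate_shape(S_single, S_in, dist, freqs, depth=cfg.soma_depth)
    laws = fit_piecewise(table)

    shape_rows = [
        {"distance_um": r, "freq_hz": f, "F": table.F[i, j]}
        for i, r in enumerate(dist) for j, f in enumerate(freqs)
    ]
    pd.DataFrame(shape_rows).to_csv(outdir / "shape_function.csv", index=False)
    pd.DataFrame(
        {"freq_hz": freqs,
         "eps_um": [l.eps for l in laws],
         "amplitude": [l.amplitude for l in laws],
         "r0_um": [l.r0 for l in laws]}
    ).to_csv(outdir / "cutoff_distance.csv", index=False)
    write_manifest(outdir, cfg, "single_cell",
                   {"runtime_s": round(time.monotonic() - t0, 2)})
    log.info("single-cell stage done in %.1fs", time.monotonic() - t0)
    return {"table": table, "laws": laws, "freqs": freqs, "S_in": S_in}


def run_population(cfg: ExperimentConfig, outdir,
                   c_values=None, with_snr: bool = True) -> dict:
    """Population PSDs, coherence, reach and SNR tables for each c_in."""
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = cfg.model()
    electrodes = cfg.electrode_grid(model)
    layout = layout_disc(cfg.n_cells, cfg.radius, cfg.soma_depth, seed=cfg.seed)
    c_values = [cfg.c_in] if c_values is None else list(c_values)

    noise_rec = None
    if with_snr:
        noise_rec = simulate_population(
            layout, model,
            cfg.input_spec(c_in=0.0, region="homogeneous", seed=cfg.seed + 1),
            electrodes,
        )

    radii = np.arange(cfg.radii_step, cfg.radius + cfg.radii_step / 2,
                      cfg.radii_step)
    results, psd_rows, coh_rows, reach_rows, snr_rows = {}, [], [], [], []
    for c in c_values:
        rec = simulate_population(
            layout, model, cfg.input_spec(c_in=c), electrodes
        )
        pop_psd = welch_psd(rec.population_trace(), fs=rec.fs,
                            window_len=cfg.window_len)
        lat_dist = np.linalg.norm(electrodes.positions[:, :2], axis=1)
        for e in range(electrodes.n_electrodes):
            for b, f in enumerate(pop_psd.freqs):
                psd_rows.append(
                    {"c_in": c, "electrode": e,
                     "lateral_um": lat_dist[e],
                     "depth_um": electrodes.positions[e, 2],
                     "freq_hz": f, "psd": pop_psd.values[e, b]}
                )
        coh = population_coherence(rec.per_cell_traces(0),
                                   window_len=cfg.window_len, fs=rec.fs)
        for b, f in enumerate(coh.freqs):
            coh_rows.append(
                {"c_in": c, "freq_hz": f, "cbar": coh.values[b],
                 "negative": bool(coh.negative[b])}
            )
        cum = cumulative_by_radius(rec, radii, electrode=0,
                                   window_len=cfg.window_len)
        reach = compute_reach(np.sqrt(cum.psd), radii,
                              fraction=cfg.reach_fraction)
        for b, f in enumerate(cum.freqs):
            reach_rows.append({"c_in": c, "freq_hz": f, "reach_um": reach[b]})
        if noise_rec is not None:
            snr = snr_profile(rec, noise_rec, window_len=cfg.window_len,
                              noise_reference="center")
            for thr, cross in snr.crossings.items():
                for b, f in enumerate(snr.freqs):
                    snr_rows.append(
                        {"c_in": c, "threshold": thr, "freq_hz": f,
                         "crossing_um": cross[b]}
                    )
        results[c] = {"record": rec, "psd": pop_psd, "coherence": coh,
                      "cumulative": cum, "reach": reach}

    pd.DataFrame(psd_rows).to_csv(outdir / "population_psd.csv", index=False)
    pd.DataFrame(coh_rows).to_csv(outdir / "coherence.csv", index=False)
    pd.DataFrame(reach_rows).to_csv(outdir / "reach.csv", index=False)
    if snr_rows:
        pd.DataFrame(snr_rows).to_csv(outdir / "snr_crossings.csv", index=False)
    write_manifest(outdir, cfg, "population",
                   {"c_values": c_values,
                    "runtime_s": round(time.monotonic() - t0, 2)})
    log.info("population stage done in %.1fs", time.monotonic() - t0)
    results["noise_record"] = noise_rec
    return results


def run_meanfield(cfg: ExperimentConfig, outdir, c_values=None,
                  radius_resolved_coherence: bool = False) -> dict:
    """Simplified-model predictions vs simulation, with residual report.

    The prediction uses the measured (non-parametric) shape table together
    with the coherence estimated from the simulated population; optionally
    the coherence is re-estimated for each subpopulation radius separately,
    which improves small-R residuals.
    """
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    single = run_single_cell(cfg, outdir)
    pop = run_population(cfg, outdir, c_values=c_values, with_snr=False)
    table, freqs = single["table"], single["freqs"]
    rho = cfg.n_cells / (np.pi * cfg.radius**2)
    rows = []
    out = {}
    for c, res in pop.items():
        if c == "noise_record":
            continue
        rec, coh = res["record"], res["coherence"]
        sim = res["psd"].values[0]
        # measured input PSD of one cell, same Welch settings
        S_in = welch_psd(rec.input_traces, fs=rec.fs,
                         window_len=cfg.window_len).values.mean(axis=0)
        cb = np.abs(np.nan_to_num(coh.values))
        A0 = np.array([a0_from_table(table, cfg.radius, rho, b)
                       for b in range(len(freqs))])
        A1 = np.array([a1_from_table(table, cfg.radius, rho, b)
                       for b in range(len(freqs))])
        pred = S_in * ((1 - cb) * A0 + cb * A1)
        rel = (pred - sim) / np.where(sim > 0, sim, 1.0)
        for b, f in enumerate(freqs):
            rows.append({"c_in": c, "freq_hz": f, "sim_psd": sim[b],
                         "pred_psd": pred[b], "rel_error": rel[b]})
        out[c] = {"pred": pred, "sim": sim, "rel_error": rel,
                  "rms_rel_error": float(np.sqrt(np.mean(rel**2)))}
        if radius_resolved_coherence:
            radii = np.arange(cfg.radii_step, cfg.radius + cfg.radii_step / 2,
                              cfg.radii_step)
            cum = res["cumulative"]
            dist = rec.layout.lateral_distances()
            pred_r, sim_r = [], []
            for R in radii:
                sel = dist <= R
                if sel.sum() < 2:
                    continue
                coh_R = population_coherence(rec.per_cell_traces(0)[sel],
                                             window_len=cfg.window_len)
                cbR = np.abs(np.nan_to_num(coh_R.values))
                A0R = np.array([a0_from_table(table, R, rho, b)
                                for b in range(len(freqs))])
                A1R = np.array([a1_from_table(table, R, rho, b)
                                for b in range(len(freqs))])
                pred_r.append(S_in * ((1 - cbR) * A0R + cbR * A1R))
                sim_r.append(cum.psd[np.searchsorted(radii, R)])
            out[c]["radius_resolved"] = {
                "pred": np.array(pred_r), "sim": np.array(sim_r)
            }
    pd.DataFrame(rows).to_csv(outdir / "meanfield_residuals.csv", index=False)
    write_manifest(outdir, cfg, "meanfield",
                   {"runtime_s": round(time.monotonic() - t0, 2)})
    log.info("meanfield stage done in %.1fs", time.monotonic() - t0)
    return out
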
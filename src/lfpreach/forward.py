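"""Extracellular potentials in an infinite homogeneous ohmic medium.

A transmembrane point current I at distance R sets up the potential
``phi = I / (4 pi sigma R)``; for cylindrical neurite compartments the same
kernel is integrated analytically along the segment axis assuming uniformly
distributed membrane current (the line-source method).  Electrodes are ideal
points; units are nA, um, S/m and uV throughout.

The electrode can never be closer to a source than the neurite radius (it
cannot sit inside the membrane), so radial distances are clamped there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cable import CompartmentalModel, TransferKernelSet
from .units import POTENTIAL_PREFACTOR

DEFAULT_SIGMA = 0.3  # S/m, standard value for cortical tissue


class ForwardError(ValueError):
    pass


@dataclass
class ElectrodeGrid:
    """Ideal point electrodes at ``positions`` (E, 3) um in a medium of
    conductivity ``sigma`` (S/m)."""

    positions: np.ndarray
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 3:
            raise ForwardError("electrode positions must be (E, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ForwardError("electrode positions must be finite")
        if not (self.sigma > 0):
            raise ForwardError("conductivity must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]


def point_source_potential(current, source_position, electrode, sigma,
                           min_distance: float = 1.0):
    """phi = I/(4 pi sigma R) in uV; R clamped to ``min_distance`` um."""
    source_position = np.asarray(source_position, dtype=float)
    electrode = np.asarray(electrode, dtype=float)
    R = float(np.linalg.norm(electrode - source_position))
    if R < min_distance:
        warnings.warn("electrode closer than minimum distance; clamping")
        R = min_distance
    return POTENTIAL_PREFACTOR * current / (4.0 * np.pi * sigma * R)


def _stable_sqrt_minus(x, r2):
    """sqrt(x^2 + r2) - x, computed without cancellation for x > 0."""
    s = np.sqrt(x * x + r2)
    return np.where(x > 0, r2 / (s + x), s - x)


def line_source_weights(
    starts: np.ndarray,
    ends: np.ndarray,
    radii: np.ndarray,
    electrodes: np.ndarray,
    sigma: float,
    warn_on_clamp: bool = True,
) -> np.ndarray:
    """Potential per unit current (uV/nA) of uniform line sources.

    Returns a (n_electrodes, n_segments) weight matrix.  Radial distances
    below the neurite radius are clamped to the radius.
    """
    starts = np.atleast_2d(starts)
    ends = np.atleast_2d(ends)
    electrodes = np.atleast_2d(electrodes)
    delta = ends - starts
    L = np.linalg.norm(delta, axis=1)
    if np.any(L <= 0):
        raise ForwardError("zero-length segment; use a point source instead")
    u = delta / L[:, None]
    d = electrodes[:, None, :] - starts[None, :, :]     # (E, N, 3)
    a = np.einsum("enk,nk->en", d, u)                   # axial projection
    r2 = np.maximum(np.einsum("enk,enk->en", d, d) - a * a, 0.0)
    rmin = np.broadcast_to(radii, r2.shape[1:])
    clamped = r2 < rmin**2
    if np.any(clamped):
        if warn_on_clamp:
            warnings.warn(
                f"{int(clamped.sum())} electrode-segment pairs inside the "
                "membrane radius; clamping radial distance"
            )
        r2 = np.maximum(r2, rmin**2)
    h = a - L[None, :]
    l = a
    num = _stable_sqrt_minus(h, r2)
    den = _stable_sqrt_minus(l, r2)
    return (
        POTENTIAL_PREFACTOR
        / (4.0 * np.pi * sigma * L[None, :])
        * np.log(num / den)
    )


def line_source_potential(segment, current, electrode, sigma):
    """Potential (uV) of a single uniform line source carrying ``current`` nA.

    ``segment`` needs start/end/diameter attributes; degenerate (zero-length)
    segments fall back to a point source at the midpoint.
    """
    start = np.asarray(segment.start, dtype=float)
    end = np.asarray(segment.end, dtype=float)
    if np.linalg.norm(end - start) <= 0:
        return point_source_potential(
            current, 0.5 * (start + end), electrode, sigma,
            min_distance=segment.diameter / 2,
        )
    w = line_source_weights(
        start[None], end[None], np.array([segment.diameter / 2]),
        np.asarray(electrode, dtype=float)[None], sigma,
    )
    return float(w[0, 0]) * current


def geometry_weights(
    model: CompartmentalModel,
    electrode_positions: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    soma_point_source: bool = False,
    warn_on_clamp: bool = True,
) -> np.ndarray:
    """(E, N) map from per-compartment current (nA) to potential (uV).

    Electrode positions are in the cell-local frame of ``model``.  All
    compartments use the line-source kernel; optionally the soma compartments
    use a point source at their midpoint instead.
    """
    W = line_source_weights(
        model.starts, model.ends, model.diameters / 2.0,
        electrode_positions, sigma, warn_on_clamp=warn_on_clamp,
    )
    if soma_point_source:
        soma = model.region_mask("soma")
        mid = model.midpoints[soma]
        d = np.linalg.norm(
            np.atleast_2d(electrode_positions)[:, None, :] - mid[None, :, :], axis=2
        )
        d = np.maximum(d, (model.diameters[soma] / 2.0)[None, :])
        W[:, soma] = POTENTIAL_PREFACTOR / (4.0 * np.pi * sigma * d)
    return W


def lfp_kernel(
    model: CompartmentalModel,
    kernels: TransferKernelSet,
    electrode_grid: ElectrodeGrid,
    soma_point_source: bool = False,
) -> np.ndarray:
    """Complex LFP transfer L[f, e, j]: potential at electrode e per unit
    synaptic current injected at compartment j, at each kernel frequency."""
    if kernels.H.shape[1] != model.n_compartments:
        raise ForwardError("kernel set and model have different compartment counts")
    G = geometry_weights(
        model, electrode_grid.positions, electrode_grid.sigma,
        soma_point_source=soma_point_source,
    )
    return np.einsum("ek,fkj->fej", G, kernels.H)
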
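"""Passive compartmental cable model solved in the frequency domain.

With purely passive membranes and current-based synapses the whole
cell-to-potential map is linear, so every temporal frequency can be handled
independently: for each angular frequency ``w = 2*pi*f`` the compartment
voltages solve ``(i*w*C + G_L + L_ax) V = I_in`` where ``C`` and ``G_L`` are
diagonal membrane capacitance/leak matrices and ``L_ax`` the axial-conductance
Laplacian.  The transmembrane current that acts as the extracellular source is
the capacitive-plus-leak current minus the injected synaptic current,

    I_m = (i*w*C + G_L) V - I_in,

which sums to zero over the cell at every frequency (charge conservation).
Positive transmembrane current flows outward into the extracellular medium;
injected synaptic current is inward.

A time-domain path exists only as an independent test oracle
(:func:`implicit_euler_membrane_currents`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .morphology import Morphology


class CableError(ValueError):
    pass


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane constants.

    axial_resistivity in Ohm*cm, membrane_resistance in Ohm*cm^2,
    membrane_capacitance in uF/cm^2.  Defaults are conventional cortical
    values; they are configurable everywhere.
    """

    axial_resistivity: float = 150.0
    membrane_resistance: float = 30000.0
    membrane_capacitance: float = 1.0

    def __post_init__(self):
        for name in ("axial_resistivity", "membrane_resistance", "membrane_capacitance"):
            if not (getattr(self, name) > 0):
                raise CableError(f"{name} must be strictly positive")


@dataclass
class CompartmentalModel:
    """Discretized cell: per-compartment RC elements plus axial couplings.

    Geometry arrays (starts/ends/midpoints in um, cell-local frame) are
    carried along for the forward model.  ``capacitance`` is in farad,
    ``leak`` in siemens; ``axial`` holds (i, j, g[S]) for each adjacent pair.
    """

    starts: np.ndarray
    ends: np.ndarray
    diameters: np.ndarray
    areas: np.ndarray
    regions: np.ndarray          # array of str
    capacitance: np.ndarray
    leak: np.ndarray
    axial: list = field(default_factory=list)
    soma_depth: float = 0.0

    @property
    def n_compartments(self) -> int:
        return len(self.areas)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    def laplacian(self) -> sp.csc_matrix:
        n = self.n_compartments
        if not self.axial:
            return sp.csc_matrix((n, n))
        i, j, g = (np.array(x) for x in zip(*self.axial))
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([-g, -g, g, g])
        return sp.csc_matrix((vals, (rows, cols)), shape=(n, n))

    def system_matrix(self, f: float) -> sp.csc_matrix:
        """(i*w*C + G_L + L_ax) at frequency f (Hz)."""
        w = 2.0 * np.pi * f
        diag = sp.diags(1j * w * self.capacitance + self.leak)
        return (diag + self.laplacian()).tocsc()

    def region_mask(self, region: str) -> np.ndarray:
        if region == "homogeneous":
            return np.ones(self.n_compartments, dtype=bool)
        return self.regions == region

    def connected(self) -> bool:
        n = self.n_compartments
        if n == 1:
            return True
        adj = sp.csr_matrix(
            (np.ones(len(self.axial)), tuple(np.array(x) for x in zip(*self.axial))[:2]),
            shape=(n, n),
        )
        ncomp, _ = sp.csgraph.connected_components(adj, directed=False)
        return ncomp == 1


def discretize(
    morphology: Morphology,
    params: PassiveParams,
    max_compartment_length: float = 20.0,
) -> CompartmentalModel:
    """Split each segment into compartments no longer than the given length.

    Membrane elements: C_k = Cm * area_k, G_L,k = area_k / Rm.  Axial
    conductances combine the two half-compartment cylinder resistances in
    series; for a uniform chain this reduces to g = pi d^2 / (4 Ra dx).
    """
    if not (max_compartment_length > 0):
        raise CableError("max_compartment_length must be positive")
    ra = params.axial_resistivity

    starts, ends, diams, areas, regions = [], [], [], [], []
    # half-compartment axial resistance of each compartment, Ohm
    half_res = []
    axial = []
    seg_first = {}
    seg_last = {}
    for seg in morphology.segments:
        n_sub = max(1, int(np.ceil(seg.length / max_compartment_length)))
        pts = np.linspace(0.0, 1.0, n_sub + 1)[:, None]
        coords = seg.start[None, :] * (1 - pts) + seg.end[None, :] * pts
        dx = seg.length / n_sub
        cross = np.pi * seg.diameter**2 / 4.0
        area = np.pi * seg.diameter * dx
        if area <= 0:
            raise CableError(f"zero-area compartment in segment {seg.id}")
        rhalf = (ra * (dx / 2.0) / cross) / units.AXIAL_S_FACTOR  # Ohm
        base = len(areas)
        for k in range(n_sub):
            starts.append(coords[k])
            ends.append(coords[k + 1])
            diams.append(seg.diameter)
            areas.append(area)
            regions.append(seg.region)
            half_res.append(rhalf)
            if k > 0:
                axial.append((base + k - 1, base + k, 1.0 / (2 * rhalf)))
        seg_first[seg.id] = base
        seg_last[seg.id] = base + n_sub - 1
        if seg.parent_id != -1:
            i = seg_last[seg.parent_id]
            j = seg_first[seg.id]
            g = 1.0 / (half_res[i] + half_res[j])
            axial.append((i, j, g))

    areas = np.array(areas)
    model = CompartmentalModel(
        starts=np.array(starts),
        ends=np.array(ends),
        diameters=np.array(diams),
        areas=areas,
        regions=np.array(regions, dtype=object),
        capacitance=params.membrane_capacitance * units.CAPACITANCE_F_PER_UF_UM2 * areas,
        leak=areas * units.CONDUCTANCE_S_PER_INVOHMCM2_UM2 / params.membrane_resistance,
        axial=axial,
        soma_depth=morphology.soma_depth,
    )
    if not model.connected():
        raise CableError("discretized model is not connected")
    return model


# ---------------------------------------------------------------------------
# transfer kernels
# ---------------------------------------------------------------------------

@dataclass
class TransferKernelSet:
    """Complex transfer tensor H[f, k, j]: transmembrane current at
    compartment k per unit current injected at compartment j (dimensionless).
    """

    freqs: np.ndarray
    H: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.H.shape[0] != len(self.freqs):
            raise CableError("frequency axis mismatch in TransferKernelSet")


class SpectralSolver:
    """Frequency-sweep solver built on one symmetric eigendecomposition.

    The system matrix is ``A(w) = K + i w C`` with ``K = G_L + L_ax`` real
    symmetric and ``C`` diagonal positive, so with ``S = C^{-1/2} K C^{-1/2}
    = Q diag(lam) Q^T`` every frequency reduces to a diagonal solve:
    ``A^{-1} = C^{-1/2} Q diag(1/(lam + i w)) Q^T C^{-1/2}``.  One O(N^3)
    factorization then serves the whole frequency grid and batches over
    right-hand sides (cells) with BLAS matmuls.
    """

    def __init__(self, model: CompartmentalModel):
        import scipy.linalg

        self.model = model
        K = (model.laplacian() + sp.diags(model.leak)).toarray()
        self._s = 1.0 / np.sqrt(model.capacitance)
        S = self._s[:, None] * K * self._s[None, :]
        self.lam, self.Q = scipy.linalg.eigh(0.5 * (S + S.T))
        if not np.all(np.isfinite(self.lam)):
            raise CableError("singular cable system (disconnected tree?)")
        self._Qs = self._s[:, None] * self.Q  # A^{-1} = Qs diag(1/(lam+iw)) Qs^T

    @staticmethod
    def _real_gemm(M: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Real matrix times complex matrix through one dgemm.

        A C-contiguous complex array viewed as float interleaves re/im along
        the last axis, so ``M @ X`` reduces to a single real GEMM.
        """
        Xf = np.ascontiguousarray(X).view(np.float64).reshape(X.shape[0], -1)
        return (M @ Xf).view(np.complex128)

    def solve_nfr(self, freqs: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Voltages for injected-current spectra B of shape (N, F, R)."""
        n = self.model.n_compartments
        if B.ndim != 3 or B.shape[0] != n:
            raise CableError(f"expected ({n}, n_freqs, n_rhs) spectra, got {B.shape}")
        w = 2j * np.pi * np.asarray(freqs, dtype=float)
        _, nf, nr = B.shape
        Y = self._real_gemm(self._Qs.T, B).reshape(n, nf, nr)
        Y /= self.lam[:, None, None] + w[None, :, None]
        return self._real_gemm(self._Qs, Y).reshape(n, nf, nr)

    def membrane_currents_nfr(self, freqs: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Transmembrane-current spectra (N, F, R) for injected spectra B."""
        memb = (1j * 2 * np.pi * np.asarray(freqs, dtype=float)[None, :]
                * self.model.capacitance[:, None] + self.model.leak[:, None])
        return memb[:, :, None] * self.solve_nfr(freqs, B) - B

    def solve(self, freqs: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Voltages for injected-current spectra B of shape (F, N, R)."""
        if B.ndim != 3 or B.shape[1] != self.model.n_compartments:
            raise CableError(
                f"expected (n_freqs, {self.model.n_compartments}, n_rhs) "
                f"spectra, got {B.shape}"
            )
        out = self.solve_nfr(freqs, np.ascontiguousarray(B.transpose(1, 0, 2)))
        return out.transpose(1, 0, 2)

    def membrane_currents(self, freqs: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Transmembrane-current spectra (F, N, R) for injected spectra B."""
        memb = (1j * 2 * np.pi * np.asarray(freqs, dtype=float)[:, None]
                * self.model.capacitance[None, :] + self.model.leak[None, :])
        return memb[:, :, None] * self.solve(freqs, B) - B


def membrane_current_spectra(
    model: CompartmentalModel, freqs: np.ndarray, input_spectra: np.ndarray
) -> np.ndarray:
    """Transmembrane-current spectra for given injected-current spectra.

    ``input_spectra`` has shape (n_freqs, n_compartments, ...): the injected
    synaptic current per compartment at each frequency (any units; output in
    the same units).  Returns the same shape.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs < 0) or not np.all(np.isfinite(freqs)):
        raise CableError("frequencies must be finite and non-negative")
    n = model.n_compartments
    B = np.asarray(input_spectra, dtype=complex).reshape(len(freqs), n, -1)
    out = SpectralSolver(model).membrane_currents(freqs, B)
    return out.reshape(np.shape(input_spectra))


def transfer_kernels(model: CompartmentalModel, freqs: np.ndarray) -> TransferKernelSet:
    """Full transfer tensor (unit injection at every compartment)."""
    n = model.n_compartments
    eye = np.broadcast_to(np.eye(n, dtype=complex), (len(freqs), n, n))
    H = membrane_current_spectra(model, freqs, np.ascontiguousarray(eye))
    return TransferKernelSet(freqs=np.asarray(freqs, dtype=float), H=H)


def frequency_grid(n_samples: int, fs: float = 1000.0) -> np.ndarray:
    """One-sided FFT frequency grid (Hz) for a trace of n_samples at fs."""
    return np.fft.rfftfreq(n_samples, d=1.0 / fs)


def membrane_currents(
    model: CompartmentalModel,
    kernels: TransferKernelSet,
    synaptic_current_timeseries: np.ndarray,
    synapse_compartments,
) -> np.ndarray:
    """Per-compartment transmembrane-current time series by superposition.

    ``synaptic_current_timeseries`` has shape (n_synapses, n_samples) on a
    uniform grid whose one-sided FFT frequencies equal ``kernels.freqs``;
    ``synapse_compartments`` maps each synapse to its compartment.  Returns an
    (n_compartments, n_samples) array whose columns sum to ~0.
    """
    I_syn = np.atleast_2d(np.asarray(synaptic_current_timeseries, dtype=float))
    n_samples = I_syn.shape[1]
    expect = frequency_grid(n_samples, fs=2.0 * kernels.freqs[-1])
    if len(expect) != len(kernels.freqs) or not np.allclose(expect, kernels.freqs):
        raise CableError(
            "time grid inconsistent with kernel frequency grid "
            f"({n_samples} samples vs {len(kernels.freqs)} frequencies)"
        )
    comp = np.asarray(synapse_compartments, dtype=int)
    if comp.shape[0] != I_syn.shape[0]:
        raise CableError("one compartment index per synapse required")
    if comp.min(initial=0) < 0 or comp.max(initial=0) >= model.n_compartments:
        raise IndexError("synapse compartment index outside model")
    # per-compartment injected current spectra
    inj = np.zeros((model.n_compartments, n_samples))
    np.add.at(inj, comp, I_syn)
    inj_hat = np.fft.rfft(inj, axis=1).T[:, :, None]  # (F, N, 1)
    out_hat = np.einsum("fkj,fjl->fkl", kernels.H, inj_hat)[:, :, 0]
    return np.fft.irfft(out_hat.T, n=n_samples, axis=1)


# ---------------------------------------------------------------------------
# kernel export
# ---------------------------------------------------------------------------

def save_kernels(kernels: TransferKernelSet, path_npz, path_json=None) -> None:
    """Binary array container (.npz) plus a JSON sidecar of the grid."""
    np.savez_compressed(path_npz, H=kernels.H, freqs=kernels.freqs)
    if path_json is None:
        path_json = str(path_npz) + ".json"
    with open(path_json, "w") as fh:
        json.dump(
            {"freqs_hz": kernels.freqs.tolist(),
             "shape": list(kernels.H.shape),
             "layout": "H[frequency, target_compartment, source_compartment]"},
            fh, indent=1,
        )


def load_kernels(path_npz) -> TransferKernelSet:
    data = np.load(path_npz)
    return TransferKernelSet(freqs=data["freqs"], H=data["H"])


# ---------------------------------------------------------------------------
# independent time-domain oracle (kept for testing only)
# ---------------------------------------------------------------------------

def implicit_euler_membrane_currents(
    model: CompartmentalModel,
    injected: np.ndarray,
    dt_ms: float,
    v0: np.ndarray | None = None,
) -> np.ndarray:
    """Backward-Euler time stepping of the same RC tree.

    ``injected``: (n_compartments, n_steps) injected current (same units as
    desired output) sampled at dt_ms.  Returns transmembrane currents
    (capacitive + leak - injected) at each step.  Slow and simple on purpose:
    this is the independent oracle for the frequency-domain path.
    """
    n, n_steps = injected.shape
    dt = dt_ms * units.S_PER_MS
    C = model.capacitance
    A = sp.diags(C / dt + model.leak) + model.laplacian()
    lu = spla.splu(A.tocsc())
    v = np.zeros(n) if v0 is None else v0.copy()
    out = np.empty_like(injected, dtype=float)
    for t in range(n_steps):
        vnew = lu.solve(C / dt * v + injected[:, t])
        out[:, t] = model.leak * vnew - injected[:, t] + C * (vnew - v) / dt
        v = vnew
    return out
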
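"""Welch spectra, rms amplitudes and the population-averaged coherence.

The coherence of single-cell LFP contributions is summarized per frequency
bin by a single number ``cbar(f)`` obtained by inverting the identity that
relates the population PSD to single-cell PSDs under the equal-coherence
approximation,

    S_pop = (1 - cbar) * sum_i S_i + cbar * (sum_i sqrt(S_i))^2,

which gives the estimator

    cbar = (S_pop - sum_i S_i) / ((sum_i sqrt(S_i))^2 - sum_i S_i).

It equals 1 for identical traces and -1/(N-1) when equal-power traces cancel
exactly.  Finite data can push the estimate slightly negative; such bins are
flagged and their magnitude used for display, as the value is then merely too
small to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

DEFAULT_FS = 1000.0


class SpectraError(ValueError):
    pass


@dataclass
class PSDMatrix:
    """One-sided Welch PSD(s): ``values[..., bin]`` in signal-units^2/Hz."""

    freqs: np.ndarray
    values: np.ndarray
    fs: float
    window_len: int

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def welch_psd(trace, fs: float = DEFAULT_FS, window_len: int = 32) -> PSDMatrix:
    """Welch average periodogram: Hanning taper, 50% overlap, mean removal
    per window, density normalization (integral over frequency ~ variance).

    A window of 32 (128) samples at 1 kHz yields 17 (65) equally spaced bins
    spanning 0-500 Hz.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] < window_len:
        raise SpectraError(
            f"trace of {trace.shape[-1]} samples is shorter than the "
            f"window ({window_len})"
        )
    freqs, psd = scipy.signal.welch(
        trace, fs=fs, window="hann", nperseg=window_len,
        noverlap=window_len // 2, detrend="constant", scaling="density",
        axis=-1,
    )
    return PSDMatrix(freqs=freqs, values=psd, fs=fs, window_len=window_len)


def rms_from_psd(psd: PSDMatrix) -> np.ndarray:
    """Root-mean-square amplitude: sqrt of the PSD integrated over 0..fs/2.

    The integral uses the trapezoidal rule over the equally spaced bins, so
    the two edge bins (DC, Nyquist) enter with half weight.
    """
    return np.sqrt(np.trapezoid(psd.values, psd.freqs, axis=-1))


@dataclass
class CoherenceCurve:
    """Population-averaged coherence per frequency bin.

    ``values`` keeps the signed estimate; ``negative`` flags bins where it
    came out (spuriously) below zero.  ``magnitude`` is what is plotted and
    fed to the mean-field combiner.  ``offset``/``depth`` label where the
    population signal was recorded.
    """

    freqs: np.ndarray
    values: np.ndarray
    n_cells: int
    negative: np.ndarray = field(default=None)
    undefined: np.ndarray = field(default=None)
    offset: float | None = None
    depth: float | None = None

    def __post_init__(self):
        if self.negative is None:
            self.negative = self.values < 0
        if self.undefined is None:
            self.undefined = np.zeros_like(self.values, dtype=bool)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


def population_coherence(
    per_cell_traces: np.ndarray,
    window_len: int = 32,
    fs: float = DEFAULT_FS,
    offset: float | None = None,
    depth: float | None = None,
) -> CoherenceCurve:
    """Estimate cbar(f) from per-cell traces (n_cells, n_samples)."""
    traces = np.asarray(per_cell_traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise SpectraError("need a (n_cells >= 2, n_samples) trace array")
    n = traces.shape[0]
    S_i = welch_psd(traces, fs=fs, window_len=window_len)
    S_pop = welch_psd(traces.sum(axis=0), fs=fs, window_len=window_len)
    sum_S = S_i.values.sum(axis=0)
    sum_sqrt = np.sqrt(S_i.values).sum(axis=0)
    denom = sum_sqrt**2 - sum_S
    undefined = denom <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        cbar = (S_pop.values - sum_S) / denom
    cbar = np.where(undefined, np.nan, cbar)
    return CoherenceCurve(
        freqs=S_i.freqs, values=cbar, n_cells=n,
        negative=np.nan_to_num(cbar) < 0, undefined=undefined,
        offset=offset, depth=depth,
    )


def reconstruct_population_psd(curve: CoherenceCurve, per_cell_psd: np.ndarray) -> np.ndarray:
    """Invert the estimator: S_pop implied by {S_i} and cbar (identity check)."""
    sum_S = per_cell_psd.sum(axis=0)
    sum_sqrt = np.sqrt(per_cell_psd).sum(axis=0)
    return (1 - curve.values) * sum_S + curve.values * sum_sqrt**2


def coherence_vs_offset(
    per_cell_traces_by_electrode: np.ndarray,
    offsets: np.ndarray,
    window_len: int = 32,
    fs: float = DEFAULT_FS,
) -> list[CoherenceCurve]:
    """cbar(f) at each lateral electrode offset X.

    ``per_cell_traces_by_electrode`` has shape (n_offsets, n_cells,
    n_samples); ``offsets`` gives the lateral position (um) of each
    electrode.
    """
    traces = np.asarray(per_cell_traces_by_electrode, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if traces.shape[0] != len(offsets):
        raise SpectraError("one electrode trace block per offset required")
    return [
        population_coherence(traces[k], window_len=window_len, fs=fs,
                             offset=float(offsets[k]))
        for k in range(len(offsets))
    ]


def coherence_decay_exponent(
    curves: list[CoherenceCurve], f_index: int, min_offset: float
) -> float:
    """Log-log slope of cbar(X) at one frequency bin for offsets beyond
    ``min_offset`` (e.g. the population radius)."""
    X = np.array([c.offset for c in curves], dtype=float)
    y = np.array([c.magnitude[f_index] for c in curves], dtype=float)
    sel = (X > min_offset) & (y > 0)
    if sel.sum() < 2:
        raise SpectraError("need at least two offsets beyond min_offset")
    slope, _ = np.polyfit(np.log(X[sel]), np.log(y[sel]), 1)
    return float(slope)
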
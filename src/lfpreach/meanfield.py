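"""Simplified (mean-field) model of the population LFP.

The single-cell LFP PSD at lateral distance r is factorized as
``S_single(r, f) = S_in(f) * F(r, f)^2`` where F is the frequency-dependent
*shape function*.  F is approximated by a piecewise power law with a plateau
inside r0, a 1/r near-field and a 1/r^2 (dipolar) far field beyond the
*cutoff distance* eps:

    F(r) = A/r0        for r <= r0
           A/r         for r0 < r <= eps
           A*eps/r^2   for r > eps

For a disc population of planar density rho (cells/um^2) the population PSD
at the centre combines an incoherent (variance-adding) term and a coherent
(amplitude-adding) term weighted by the population-averaged coherence cbar:

    S_pop = S_in * [ (1 - cbar) * A0(R) + cbar * A1(R) ],
    A0(R) = 2 pi rho * Int_0^R F(r)^2 r dr,
    A1(R) = ( 2 pi rho * Int_0^R F(r) r dr )^2.

Both integrals have closed forms under the piecewise law (A0 saturates with
R; A1 grows like log^2 R).  The *spatial reach* at a frequency is the
smallest radius whose rms amplitude reaches 95% of the full-population
amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.optimize

from .spectra import CoherenceCurve


class MeanFieldError(ValueError):
    pass


# ---------------------------------------------------------------------------
# shape functions
# ---------------------------------------------------------------------------

@dataclass
class ShapeFunctionTable:
    """F(r, f): rms single-cell LFP amplitude normalized by sqrt(S_in)."""

    distances: np.ndarray         # (n_r,), um, strictly increasing
    freqs: np.ndarray             # (n_f,), Hz
    F: np.ndarray                 # (n_r, n_f), >= 0 (NaN where excluded)
    depth: float | None = None
    excluded_bins: np.ndarray = field(default=None)

    def __post_init__(self):
        if np.any(np.diff(self.distances) <= 0):
            raise MeanFieldError("distances must be strictly increasing")
        if self.excluded_bins is None:
            self.excluded_bins = np.zeros(len(self.freqs), dtype=bool)

    def interp(self, r, f_index: int) -> np.ndarray:
        """F at arbitrary distances by log-log interpolation (power-law
        extrapolation beyond the sampled range)."""
        r = np.asarray(r, dtype=float)
        logF = np.interp(
            np.log(np.maximum(r, self.distances[0] * 1e-3)),
            np.log(self.distances), np.log(self.F[:, f_index]),
        )
        # linear extrapolation in log-log space beyond the grid
        lr = np.log(self.distances)
        lF = np.log(self.F[:, f_index])
        out = np.exp(logF)
        hi = r > self.distances[-1]
        if np.any(hi):
            slope = (lF[-1] - lF[-2]) / (lr[-1] - lr[-2])
            out = np.where(
                hi, np.exp(lF[-1] + slope * (np.log(r) - lr[-1])), out
            )
        return out


def estimate_shape(
    single_cell_psd_by_distance: np.ndarray,
    input_psd: np.ndarray,
    distances: np.ndarray,
    freqs: np.ndarray,
    depth: float | None = None,
) -> ShapeFunctionTable:
    """F = sqrt(S_single / S_in) per distance and frequency bin.

    Bins with zero (or negative) input PSD are excluded (flagged, F = NaN).
    PSDs are trial-averaged by the caller; any common normalization of the
    input spectrum cancels between numerator and denominator.
    """
    S = np.asarray(single_cell_psd_by_distance, dtype=float)
    S_in = np.asarray(input_psd, dtype=float)
    bad = ~(S_in > 0)
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} input-PSD bins are zero; excluded")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.sqrt(S / np.where(bad, np.nan, S_in)[None, :])
    return ShapeFunctionTable(
        distances=np.asarray(distances, dtype=float),
        freqs=np.asarray(freqs, dtype=float),
        F=F, depth=depth, excluded_bins=bad,
    )


# ---------------------------------------------------------------------------
# piecewise power law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiecewisePowerLaw:
    """Continuous plateau / 1/r / 1/r^2 shape law (see module docstring)."""

    amplitude: float
    r0: float
    eps: float

    def __post_init__(self):
        if not (0 < self.r0 <= self.eps):
            raise MeanFieldError("require 0 < r0 <= eps")

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        A, r0, eps = self.amplitude, self.r0, self.eps
        return np.where(
            r <= r0, A / r0,
            np.where(r <= eps, A / np.maximum(r, r0), A * eps / r**2),
        )


def _fit_amplitude(log_r_eff: np.ndarray, log_F: np.ndarray) -> float:
    """Closed-form log A for fixed breakpoints (ordinary least squares)."""
    return float(np.mean(log_F - log_r_eff))


def _sse_for_eps(log_eps, log_r, log_F, log_r0):
    # effective regressor: -log r in the 1/r regime, log eps - 2 log r beyond,
    # -log r0 on the plateau
    b = np.where(
        log_r <= log_r0, -log_r0,
        np.where(log_r <= log_eps, -log_r, log_eps - 2 * log_r),
    )
    logA = _fit_amplitude(b, log_F)
    resid = log_F - (logA + b)
    return float(resid @ resid)


def fit_piecewise(
    table: ShapeFunctionTable,
    r0: float | None = None,
    min_r0: float = 10.0,
    n_grid: int = 200,
) -> list[PiecewisePowerLaw]:
    """Fit the law per frequency bin by least squares in log-log space.

    Slopes are fixed at -1 and -2; the amplitude is solved in closed form
    for each candidate cutoff; eps is found on a log grid of breakpoints
    refined by golden-section search, ties broken toward smaller eps.

    r0 policy: at the soma level r0 = max(closest sampled distance, min_r0);
    for records at other depths pass r0 = max(vertical offset from the soma
    plane, min_r0).
    """
    r = table.distances
    if len(r) < 6:
        raise MeanFieldError("need at least 6 distances spanning both regimes")
    if r0 is None:
        r0 = max(r[0], min_r0)
    log_r = np.log(r)
    log_r0 = np.log(r0)
    lo, hi = np.log(r[0]), np.log(r[-1])
    grid = np.linspace(max(lo, log_r0), hi, n_grid)
    laws = []
    for fi in range(len(table.freqs)):
        F = table.F[:, fi]
        ok = np.isfinite(F) & (F > 0)
        if ok.sum() < 6:
            raise MeanFieldError(f"too few valid shape points in bin {fi}")
        lr, lF = log_r[ok], np.log(F[ok])
        sse = np.array([_sse_for_eps(g, lr, lF, log_r0) for g in grid])
        k = int(np.argmin(sse))  # argmin returns the first (smallest eps) tie
        if k == 0 or k == len(grid) - 1:
            warnings.warn(
                "all shape points lie in one power-law regime; cutoff pinned "
                "to the sampled boundary"
            )
            log_eps = grid[k]
        else:
            res = scipy.optimize.minimize_scalar(
                _sse_for_eps, bracket=(grid[k - 1], grid[k], grid[k + 1]),
                args=(lr, lF, log_r0), method="golden",
                options={"xtol": 1e-10},
            )
            log_eps = float(res.x)
        b = np.where(
            lr <= log_r0, -log_r0,
            np.where(lr <= log_eps, -lr, log_eps - 2 * lr),
        )
        logA = _fit_amplitude(b, lF)
        laws.append(
            PiecewisePowerLaw(
                amplitude=float(np.exp(logA)),
                r0=float(r0), eps=float(np.exp(max(log_eps, log_r0))),
            )
        )
    return laws


# ---------------------------------------------------------------------------
# closed-form A0 / A1
# ---------------------------------------------------------------------------

def _int_F2_r(R: float, law: PiecewisePowerLaw) -> float:
    """Int_0^R F(r)^2 r dr in closed form."""
    A, r0, eps = law.amplitude, law.r0, law.eps
    if R <= r0:
        return A**2 * R**2 / (2 * r0**2)
    val = A**2 / 2.0
    if R <= eps:
        return val + A**2 * np.log(R / r0)
    val += A**2 * np.log(eps / r0)
    return val + A**2 / 2.0 * (1.0 - eps**2 / R**2)


def _int_F_r(R: float, law: PiecewisePowerLaw) -> float:
    """Int_0^R F(r) r dr in closed form."""
    A, r0, eps = law.amplitude, law.r0, law.eps
    if R <= r0:
        return A * R**2 / (2 * r0)
    val = A * r0 / 2.0
    if R <= eps:
        return val + A * (R - r0)
    val += A * (eps - r0)
    return val + A * eps * np.log(R / eps)


def a0(R: float, law: PiecewisePowerLaw, rho: float) -> float:
    """Incoherent population factor: 2 pi rho Int_0^R F^2 r dr.

    rho in cells/um^2; saturates as R -> infinity.
    """
    if not (R > 0):
        raise MeanFieldError("R must be positive")
    return 2 * np.pi * rho * _int_F2_r(R, law)


def a1(R: float, law: PiecewisePowerLaw, rho: float) -> float:
    """Coherent population factor: (2 pi rho Int_0^R F r dr)^2; grows ~log^2 R."""
    if not (R > 0):
        raise MeanFieldError("R must be positive")
    return (2 * np.pi * rho * _int_F_r(R, law)) ** 2


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

@dataclass
class MeanFieldPrediction:
    freqs: np.ndarray
    S_pop: np.ndarray
    A0: np.ndarray
    A1: np.ndarray
    cbar: np.ndarray
    R: float
    rho: float

    @property
    def amplitude(self) -> np.ndarray:
        """Per-bin rms amplitude contribution sqrt(S_pop * df) up to df."""
        return np.sqrt(self.S_pop)


def _as_cbar_array(cbar, n_bins: int, n_cells: int | None) -> np.ndarray:
    if isinstance(cbar, CoherenceCurve):
        vals = cbar.magnitude.copy()
        n_cells = n_cells or cbar.n_cells
    else:
        vals = np.broadcast_to(np.asarray(cbar, dtype=float), (n_bins,)).copy()
    lo = -1.0 / (n_cells - 1) if n_cells else 0.0
    if np.any(vals > 1.0) or np.any(vals < lo):
        warnings.warn("coherence outside the admissible range; clipping")
        vals = np.clip(vals, lo, 1.0)
    return vals


def predict_population_psd(
    R: float,
    laws: list[PiecewisePowerLaw],
    cbar,
    rho: float,
    S_in: np.ndarray,
    freqs: np.ndarray | None = None,
    n_cells: int | None = None,
) -> MeanFieldPrediction:
    """S_pop(f) = S_in(f) * [(1 - cbar) A0 + cbar A1] per frequency bin.

    Reduces to pure variance addition at cbar = 0 and pure amplitude
    addition at cbar = 1.  Negative (flagged) coherence bins enter through
    their magnitude.
    """
    S_in = np.asarray(S_in, dtype=float)
    n_bins = len(S_in)
    if len(laws) != n_bins:
        raise MeanFieldError("one fitted law per frequency bin required")
    cb = _as_cbar_array(cbar, n_bins, n_cells)
    A0 = np.array([a0(R, law, rho) for law in laws])
    A1 = np.array([a1(R, law, rho) for law in laws])
    S_pop = S_in * ((1 - cb) * A0 + cb * A1)
    if freqs is None:
        freqs = np.arange(n_bins, dtype=float)
    return MeanFieldPrediction(freqs=np.asarray(freqs, dtype=float),
                               S_pop=S_pop, A0=A0, A1=A1, cbar=cb, R=R, rho=rho)


def predict_population_psd_discrete(F_by_cell: np.ndarray, cbar,
                                    S_in: np.ndarray) -> np.ndarray:
    """Combiner evaluated on a finite set of cells.

    ``F_by_cell`` has shape (n_cells, n_bins): the shape function at each
    realized cell distance.  ``(1 - cbar) sum F_i^2 + cbar (sum F_i)^2``
    equals the full pairwise double sum with equal pairwise coherence, and
    replaces the continuum integrals when layout sampling noise matters
    (small populations).
    """
    F = np.asarray(F_by_cell, dtype=float)
    S_in = np.asarray(S_in, dtype=float)
    cb = _as_cbar_array(cbar, F.shape[1], F.shape[0])
    return S_in * ((1 - cb) * (F**2).sum(axis=0) + cb * F.sum(axis=0) ** 2)


def a0_from_table(table: ShapeFunctionTable, R: float, rho: float,
                  f_index: int, n_quad: int = 2048) -> float:
    """Non-parametric A0: trapezoidal 2 pi rho Int F(r)^2 r dr using the
    measured shape table (log-log interpolated)."""
    r = np.linspace(0.0, R, n_quad)
    F = np.where(r > 0, table.interp(np.maximum(r, 1e-9), f_index), 0.0)
    F = np.where(r <= table.distances[0], table.F[0, f_index], F)
    return float(2 * np.pi * rho * np.trapezoid(F**2 * r, r))


def a1_from_table(table: ShapeFunctionTable, R: float, rho: float,
                  f_index: int, n_quad: int = 2048) -> float:
    r = np.linspace(0.0, R, n_quad)
    F = np.where(r > 0, table.interp(np.maximum(r, 1e-9), f_index), 0.0)
    F = np.where(r <= table.distances[0], table.F[0, f_index], F)
    return float((2 * np.pi * rho * np.trapezoid(F * r, r)) ** 2)


# ---------------------------------------------------------------------------
# spatial reach
# ---------------------------------------------------------------------------

def compute_reach(
    amplitude_vs_R: np.ndarray,
    radii: np.ndarray,
    fraction: float = 0.95,
) -> np.ndarray:
    """Smallest grid radius whose amplitude reaches ``fraction`` of the
    largest-population amplitude; per frequency bin if 2-D input
    (n_radii, n_bins).  With non-monotone (noisy) amplitudes this is the
    first upward crossing."""
    amp = np.asarray(amplitude_vs_R, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) < 0):
        raise MeanFieldError("radii must be ascending")
    one_d = amp.ndim == 1
    amp = amp[:, None] if one_d else amp
    target = fraction * amp[-1][None, :]
    mask = amp >= target
    reach = radii[np.argmax(mask, axis=0)]
    return reach[0] if one_d else reach


def reach_from_laws(
    laws: list[PiecewisePowerLaw],
    cbar,
    rho: float,
    R_max: float,
    fraction: float = 0.95,
    dr: float = 100.0,
    n_cells: int | None = None,
) -> np.ndarray:
    """Frequency-resolved reach predicted by the simplified model.

    Per bin, amplitude(R) ~ sqrt((1 - cbar) A0(R) + cbar A1(R)); the radius
    grid runs from dr to R_max in steps of dr.
    """
    radii = np.arange(dr, R_max + dr / 2, dr)
    cb = _as_cbar_array(cbar, len(laws), n_cells)
    amp = np.empty((len(radii), len(laws)))
    for fi, law in enumerate(laws):
        A0v = np.array([a0(R, law, rho) for R in radii])
        A1v = np.array([a1(R, law, rho) for R in radii])
        amp[:, fi] = np.sqrt((1 - cb[fi]) * A0v + cb[fi] * A1v)
    return compute_reach(amp, radii, fraction=fraction)


# ---------------------------------------------------------------------------
# offset (out-of-population) and depth predictions
# ---------------------------------------------------------------------------

def _coverage_angle(s: np.ndarray, X: float, R: float) -> np.ndarray:
    """Half-angle of the circle of radius s around the electrode that lies
    inside the population disc (0..pi)."""
    s = np.asarray(s, dtype=float)
    if X == 0.0:
        return np.where(s <= R, np.pi, 0.0)
    arg = (X**2 + s**2 - R**2) / (2 * X * np.maximum(s, 1e-300))
    return np.where(
        s <= R - X, np.pi,
        np.where(s >= R + X, 0.0, np.arccos(np.clip(arg, -1.0, 1.0))),
    )


def _disc_integral(func, X: float, R: float, law: PiecewisePowerLaw) -> float:
    """Int over the disc of func(F(distance to electrode)) via the coverage
    angle; 1-D adaptive quadrature with breakpoints at the law's regimes."""
    upper = X + R
    pts = sorted({p for p in (law.r0, law.eps, abs(R - X), R + X)
                  if 0 < p < upper})

    def integrand(s):
        return func(law(s)) * s * 2.0 * _coverage_angle(s, X, R)

    val, err = scipy.integrate.quad(
        integrand, 0.0, upper, points=pts, limit=200,
        epsabs=0.0, epsrel=1e-9,
    )
    if not np.isfinite(val) or (abs(val) > 0 and err > 1e-4 * abs(val)):
        raise MeanFieldError(
            f"offset-disc quadrature did not converge (X={X}, R={R}, "
            f"value={val}, err={err})"
        )
    return val


def a0_offset(X: float, R: float, law: PiecewisePowerLaw, rho: float) -> float:
    """Incoherent factor at lateral electrode offset X from the disc centre."""
    return rho * _disc_integral(lambda F: F**2, X, R, law)


def a1_offset(X: float, R: float, law: PiecewisePowerLaw, rho: float) -> float:
    return (rho * _disc_integral(lambda F: F, X, R, law)) ** 2


def predict_offset_psd(
    X: float,
    R: float,
    laws: list[PiecewisePowerLaw],
    cbar,
    rho: float,
    S_in: np.ndarray,
    freqs: np.ndarray | None = None,
    n_cells: int | None = None,
) -> MeanFieldPrediction:
    """Population PSD at a laterally offset electrode.

    The shape function is evaluated at the distance from the electrode and
    integrated numerically over the disc.  ``cbar`` may be offset-resolved
    (cbar(X, f)); if only the centre value is available it is reused.
    """
    S_in = np.asarray(S_in, dtype=float)
    cb = _as_cbar_array(cbar, len(S_in), n_cells)
    A0 = np.array([a0_offset(X, R, law, rho) for law in laws])
    A1 = np.array([a1_offset(X, R, law, rho) for law in laws])
    S_pop = S_in * ((1 - cb) * A0 + cb * A1)
    if freqs is None:
        freqs = np.arange(len(S_in), dtype=float)
    return MeanFieldPrediction(freqs=np.asarray(freqs, dtype=float),
                               S_pop=S_pop, A0=A0, A1=A1, cbar=cb, R=R, rho=rho)


def depth_profile_prediction(
    laws_by_depth: dict,
    cbar_by_depth: dict,
    R: float,
    rho: float,
    S_in: np.ndarray,
    normalize_per_depth: bool = False,
) -> dict:
    """Apply the combiner independently per recording depth.

    ``laws_by_depth`` maps depth -> list of per-bin laws, ``cbar_by_depth``
    maps depth -> coherence (scalar, array or CoherenceCurve).  Returns
    depth -> S_pop array; optionally each profile normalized to its maximum.
    """
    missing = set(laws_by_depth) - set(cbar_by_depth)
    if missing:
        raise MeanFieldError(f"missing coherence for depths {sorted(missing)}")
    out = {}
    for depth, laws in laws_by_depth.items():
        pred = predict_population_psd(R, laws, cbar_by_depth[depth], rho, S_in)
        vals = pred.S_pop
        if normalize_per_depth and vals.max() > 0:
            vals = vals / vals.max()
        out[depth] = vals
    return out
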
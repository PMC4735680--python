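"""Umbrella-sampling free-energy reconstruction (WHAM) and PMF matching.

``wham_solve`` implements the standard self-consistent weighted-histogram
iteration for 1-D umbrella windows with harmonic biases,

    P(z) propto sum_i n_i(z) / sum_j N_j exp[(F_j - w_j(z)) / kT],
    F_j = -kT ln sum_z P(z) exp(-w_j(z) / kT),

gauge-fixed with F_1 = 0, iterated until the window free energies stop
changing.  ``optimize_cross_parameters`` wraps a derivative-free Nelder-Mead
search over cross-interaction epsilon scaling factors, minimizing the RMS
discrepancy between a computed and a reference profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constants import KB
from .errors import ConvergenceError

log = logging.getLogger(__name__)

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "MatchResult",
    "wham_solve",
    "anchor_pmf",
    "pmf_discrepancy",
    "optimize_cross_parameters",
    "bootstrap_pmf_error",
]


@dataclass
class UmbrellaWindow:
    """Samples of the reaction coordinate under one harmonic restraint."""

    center: float  # nm
    spring_k: float  # kJ/mol/nm^2
    samples: np.ndarray  # nm
    temperature: float = 303.0  # K

    def __post_init__(self):
        self.samples = np.atleast_1d(np.asarray(self.samples, float))
        if self.spring_k < 0:
            raise ValueError("spring_k must be >= 0")
        if self.samples.size < 1:
            raise ValueError("window needs at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    def bias(self, z) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(z, float) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free energy vs insertion depth, with optional per-bin uncertainty."""

    z_grid: np.ndarray  # nm, bin centers, strictly increasing
    free_energy: np.ndarray  # kJ/mol
    error: np.ndarray | None = None  # kJ/mol
    reference_zero: float | None = None  # nm

    def __post_init__(self):
        self.z_grid = np.asarray(self.z_grid, float)
        self.free_energy = np.asarray(self.free_energy, float)
        if np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly increasing")
        if self.z_grid.shape != self.free_energy.shape:
            raise ValueError("z_grid and free_energy must have equal length")
        if self.error is not None:
            self.error = np.asarray(self.error, float)

    def copy(self) -> "PMFProfile":
        return PMFProfile(
            self.z_grid.copy(),
            self.free_energy.copy(),
            None if self.error is None else self.error.copy(),
            self.reference_zero,
        )


@dataclass
class MatchResult:
    """Outcome of the cross-parameter refinement."""

    scalings: np.ndarray  # refined per-pair epsilon scaling factors
    objective: float  # kJ/mol RMS discrepancy at the returned scalings
    trace: list = field(default_factory=list)  # best objective after each accepted step
    converged: bool = True
    n_evaluations: int = 0


def statistical_inefficiency(samples: np.ndarray) -> float:
    """Integrated-autocorrelation factor g >= 1; n/g is the effective sample count."""
    x = np.asarray(samples, float)
    n = len(x)
    if n < 4:
        return 1.0
    xm = x - x.mean()
    var = float(np.mean(xm * xm))
    if var == 0:
        return 1.0
    g = 1.0
    for t in range(1, n // 2):
        c = float(np.mean(xm[:-t] * xm[t:]) / var)
        if c < 0.05:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(g, 1.0)


def effective_sample_counts(windows: list[UmbrellaWindow], z_grid: np.ndarray) -> np.ndarray:
    """Per-bin effective sample count: window histograms weighted by 1/g."""
    edges = _bin_edges(np.asarray(z_grid, float))
    out = np.zeros(len(z_grid))
    for w in windows:
        out += np.histogram(w.samples, bins=edges)[0] / statistical_inefficiency(w.samples)
    return out


def _bin_edges(z_grid: np.ndarray) -> np.ndarray:
    mid = 0.5 * (z_grid[1:] + z_grid[:-1])
    first = z_grid[0] - (mid[0] - z_grid[0])
    last = z_grid[-1] + (z_grid[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


def wham_solve(
    windows: list[UmbrellaWindow],
    z_grid: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100000,
    reference_zero: float | None = None,
) -> PMFProfile:
    """Self-consistent WHAM solution on the given bin-center grid.

    Bins never visited by any window get infinite free energy and infinite
    error.  Windows are canonically ordered internally so the result is
    invariant (bitwise) under permutation of the input list.  Raises
    :class:`ConvergenceError` (carrying the last iterate) if ``max_iter`` is
    exhausted.
    """
    if not windows:
        raise ValueError("need at least one window")
    z_grid = np.asarray(z_grid, float)
    windows = sorted(windows, key=lambda w: (w.center, w.spring_k, len(w.samples)))
    t0 = windows[0].temperature
    if any(abs(w.temperature - t0) > 1e-9 for w in windows):
        raise ValueError("all windows must share one temperature")
    kt = KB * t0

    edges = _bin_edges(z_grid)
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    n_tot = counts.sum(axis=0).astype(float)  # per bin
    n_win = counts.sum(axis=1).astype(float)  # per window
    _warn_poor_overlap(windows, counts)

    bias = np.stack([w.bias(z_grid) for w in windows])  # (W, B)
    expw = np.exp(-bias / kt)
    f = np.zeros(len(windows))
    for it in range(max_iter):
        denom = (n_win[:, None] * np.exp(f[:, None] / kt) * expw).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n_tot > 0, n_tot / denom, 0.0)
        z_norm = (p[None, :] * expw).sum(axis=1)
        f_new = -kt * np.log(z_norm)
        f_new -= f_new[0]  # gauge: F_1 = 0
        delta = np.max(np.abs(f_new - f) / (1.0 + np.abs(f_new)))
        f = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (delta={delta:.3g})",
            last_iterate=f,
        )
    log.debug("wham converged in %d iterations", it + 1)

    with np.errstate(divide="ignore"):
        g = np.where(p > 0, -kt * np.log(np.where(p > 0, p, 1.0)), np.inf)
    err = np.where(n_tot > 0, 0.0, np.inf)
    profile = PMFProfile(z_grid, g, error=err, reference_zero=reference_zero)
    if reference_zero is not None:
        profile = anchor_pmf(profile, reference_zero, width=0.0)
    else:
        finite = np.isfinite(g)
        if finite.any():
            profile.free_energy = g - np.min(g[finite])
    return profile


def _warn_poor_overlap(windows, counts):
    for i in range(len(windows) - 1):
        a, b = counts[i] > 0, counts[i + 1] > 0
        shared = a & b
        overlap = counts[i][shared].sum() / max(counts[i].sum(), 1)
        if overlap < 0.05:
            log.warning(
                "windows %d and %d overlap on <5%% of samples (%.1f%%); "
                "expect unreliable bins",
                i,
                i + 1,
                100 * overlap,
            )


def anchor_pmf(profile: PMFProfile, z_bulk: float, width: float = 0.5) -> PMFProfile:
    """Shift the profile so the plateau around ``z_bulk`` averages to zero.

    The plateau window is ``width`` nm wide, truncated (and logged) where it
    straddles the grid edge; ``width = 0`` anchors to the single nearest bin.
    """
    z = profile.z_grid
    if not (z[0] <= z_bulk <= z[-1]):
        raise ValueError(f"z_bulk={z_bulk} outside grid [{z[0]}, {z[-1]}]")
    lo, hi = z_bulk - width / 2, z_bulk + width / 2
    if lo < z[0] or hi > z[-1]:
        log.warning("anchor window [%.3g, %.3g] truncated to grid extent", lo, hi)
    sel = (z >= lo) & (z <= hi) & np.isfinite(profile.free_energy)
    if not sel.any():
        sel = np.zeros_like(z, bool)
        finite = np.isfinite(profile.free_energy)
        if not finite.any():
            raise ValueError("no finite bins to anchor on")
        candidates = np.where(finite)[0]
        sel[candidates[np.argmin(np.abs(z[candidates] - z_bulk))]] = True
    out = profile.copy()
    out.free_energy = profile.free_energy - np.mean(profile.free_energy[sel])
    out.reference_zero = z_bulk
    return out


def pmf_discrepancy(cg: PMFProfile, ref: PMFProfile, z_range: tuple[float, float] | None = None) -> float:
    """RMS difference (kJ/mol) between two anchored profiles over ``z_range``.

    ``ref`` is linearly interpolated onto the ``cg`` grid; comparison is
    restricted to the overlap of both grids and the requested range.
    """
    lo = max(cg.z_grid[0], ref.z_grid[0])
    hi = min(cg.z_grid[-1], ref.z_grid[-1])
    if z_range is not None:
        lo, hi = max(lo, z_range[0]), min(hi, z_range[1])
    sel = (cg.z_grid >= lo) & (cg.z_grid <= hi) & np.isfinite(cg.free_energy)
    if not sel.any():
        raise ValueError("profiles share no usable z range")
    ref_finite = np.isfinite(ref.free_energy)
    ref_interp = np.interp(cg.z_grid[sel], ref.z_grid[ref_finite], ref.free_energy[ref_finite])
    diff = cg.free_energy[sel] - ref_interp
    return float(np.sqrt(np.mean(diff**2)))


def optimize_cross_parameters(
    evaluator,
    ref: PMFProfile,
    initial_scalings,
    budget: int = 200,
    z_range: tuple[float, float] | None = None,
    bounds: tuple[float, float] = (0.2, 5.0),
) -> MatchResult:
    """Refine epsilon scaling factors so the evaluated PMF matches ``ref``.

    ``evaluator`` maps a scaling vector to a :class:`PMFProfile` (for real
    use: re-run the CG umbrella pipeline with scaled cross epsilons; the same
    refined per-bead-type scalings then transfer unchanged to longer-tail
    cations built from the same bead types).  Nelder-Mead with the scalings
    clipped to ``bounds``; the returned parameters are never worse than the
    starting point.
    """
    x0 = np.atleast_1d(np.asarray(initial_scalings, float))
    lo, hi = bounds
    trace: list[float] = []
    best = {"x": x0.copy(), "f": np.inf}
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        xc = np.clip(x, lo, hi)
        f = pmf_discrepancy(evaluator(xc), ref, z_range)
        if f < best["f"]:
            best["x"], best["f"] = xc.copy(), f
            trace.append(f)
        return f

    f0 = objective(x0)
    if f0 == 0.0:
        return MatchResult(scalings=x0, objective=0.0, trace=trace, converged=True, n_evaluations=n_eval)
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxfev": max(budget - 1, 1), "xatol": 1e-6, "fatol": 1e-10},
    )
    converged = bool(res.success)
    if not converged:
        log.warning("cross-parameter search budget exhausted; returning best-so-far")
    return MatchResult(
        scalings=best["x"],
        objective=float(best["f"]),
        trace=trace,
        converged=converged,
        n_evaluations=n_eval,
    )


def bootstrap_pmf_error(
    windows: list[UmbrellaWindow],
    z_grid: np.ndarray,
    n_boot: int = 50,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100000,
    reference_zero: float | None = None,
) -> np.ndarray:
    """Per-bin standard deviation of the WHAM profile under sample resampling."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.Generator(np.random.PCG64(seed))
    z_grid = np.asarray(z_grid, float)
    reps = np.empty((n_boot, len(z_grid)))
    for b in range(n_boot):
        resampled = [
            UmbrellaWindow(
                w.center,
                w.spring_k,
                rng.choice(w.samples, size=len(w.samples), replace=True),
                w.temperature,
            )
            for w in windows
        ]
        prof = wham_solve(resampled, z_grid, tol=tol, max_iter=max_iter, reference_zero=reference_zero)
        reps[b] = prof.free_energy
    with np.errstate(invalid="ignore"):
        return np.nanstd(np.where(np.isfinite(reps), reps, np.nan), axis=0, ddof=1)
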
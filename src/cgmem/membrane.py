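"""Bilayer observables: leaflet assignment, cation insertion statistics,
leaflet height surfaces, undulation spectra and Helfrich bending moduli.

Height-field conventions used throughout this module:

* Fourier coefficients are ``h_hat(q) = (1/N^2) sum_r h(r) exp(-i q.r)``
  (numpy ``fft2`` divided by ``N^2``).
* The spectral intensity is ``S(q) = A <|h_hat(q)|^2>`` with ``A = L^2`` the
  projected membrane area, frame-averaged, radially binned over ``|q|`` with
  the ``q = 0`` mode excluded.
* Helfrich theory then predicts ``S(q) = k_B T / (kappa q^4)`` for a
  tensionless membrane, which is the model fitted by
  :func:`fit_bending_modulus` (log-log fit with the slope fixed at -4).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import KB_J
from .errors import DegenerateBilayerError, FitError, ResolutionError
from .forcefield import ParameterSet, SystemConfiguration

log = logging.getLogger(__name__)

__all__ = [
    "MembraneTopology",
    "LeafletAssignment",
    "InsertionSeries",
    "SaturationResult",
    "UndulationSurface",
    "FluctuationSpectrum",
    "BendingFit",
    "assign_leaflets",
    "count_inserted_cations",
    "detect_saturation",
    "reconstruct_surface",
    "undulation_spectrum",
    "fit_bending_modulus",
    "bending_modulus_blocks",
    "block_average",
]


@dataclass
class MembraneTopology:
    """Bead bookkeeping the analysis needs: phosphates per lipid, cation rings."""

    phosphate_idx: np.ndarray  # (n_lipids,) bead index of each lipid's phosphate
    lipid_ids: np.ndarray  # (n_lipids,) molecule id per lipid
    cation_ring_idx: np.ndarray  # (n_cations,) bead index of each cation's ring bead

    @classmethod
    def from_config(cls, config: SystemConfiguration, params: ParameterSet) -> "MembraneTopology":
        roles = np.array([params.bead_types[n].role for n in config.bead_types])
        phos = np.where(roles == "lipid-phosphate")[0]
        rings = np.where(roles == "cation-ring")[0]
        return cls(
            phosphate_idx=phos,
            lipid_ids=config.molecule_ids[phos],
            cation_ring_idx=rings,
        )

    @property
    def n_lipids(self) -> int:
        return len(self.phosphate_idx)


@dataclass
class LeafletAssignment:
    """Per-lipid leaflet labels plus the local surfaces used to derive them."""

    labels: np.ndarray  # (n_lipids,) "upper" | "lower"
    midplane: np.ndarray  # (g, g) local midplane height, relative to z_ref
    upper_surface: np.ndarray  # (g, g)
    lower_surface: np.ndarray  # (g, g)
    z_ref: float  # absolute z the relative heights refer to
    grid: int
    box: np.ndarray


@dataclass
class InsertionSeries:
    """Per-frame inserted-cation counts, normalized per lipid in each leaflet."""

    time: np.ndarray
    inserted_upper: np.ndarray
    inserted_lower: np.ndarray
    lipids_upper: np.ndarray
    lipids_lower: np.ndarray

    @property
    def ratio_upper(self) -> np.ndarray:
        return self.inserted_upper / self.lipids_upper

    @property
    def ratio_lower(self) -> np.ndarray:
        return self.inserted_lower / self.lipids_lower


@dataclass
class SaturationResult:
    defined: bool
    ratio: float | None = None
    onset_index: int | None = None
    onset_time: float | None = None


@dataclass
class UndulationSurface:
    """Gridded leaflet height field for one frame, mean-subtracted, nm."""

    heights: np.ndarray  # (N, N)
    box_edge: float  # L, nm
    time: float = 0.0

    def __post_init__(self):
        self.heights = np.asarray(self.heights, float)
        n = self.heights.shape[0]
        if self.heights.shape != (n, n) or n & (n - 1):
            raise ValueError("heights must be N x N with N a power of two")


@dataclass
class FluctuationSpectrum:
    q_values: np.ndarray  # nm^-1, radial bin centers (q = 0 excluded)
    intensity: np.ndarray  # S(q), nm^4
    stderr: np.ndarray  # per-bin standard error over frames
    n_frames: int
    box_edge: float
    grid: int
    intensity_2d: np.ndarray | None = None  # (N, N) frame-averaged A<|h_hat|^2>


@dataclass
class BendingFit:
    kappa: float  # J
    kappa_error: float  # J
    q_fit_range: tuple[float, float]
    goodness: float  # R^2 of the fixed-slope log-log fit
    n_bins: int

    @property
    def kappa_e20(self) -> float:
        """kappa in units of 1e-20 J, as conventionally reported."""
        return self.kappa * 1e20

    @property
    def kappa_error_e20(self) -> float:
        return self.kappa_error * 1e20


# ---------------------------------------------------------------------------
# leaflets & insertion


def _relative_z(z: np.ndarray, z_ref: float, lz: float) -> np.ndarray:
    """Signed height above z_ref, minimum-imaged along z."""
    return (z - z_ref + lz / 2) % lz - lz / 2


def _cell_of(xy: np.ndarray, box: np.ndarray, g: int) -> tuple[np.ndarray, np.ndarray]:
    ix = np.floor(np.mod(xy[:, 0], box[0]) / box[0] * g).astype(int) % g
    iy = np.floor(np.mod(xy[:, 1], box[1]) / box[1] * g).astype(int) % g
    return ix, iy


def _binned_mean(ix, iy, values, g):
    """Mean of values per (g, g) cell; returns (grid, filled_mask)."""
    s = np.zeros((g, g))
    c = np.zeros((g, g))
    np.add.at(s, (ix, iy), values)
    np.add.at(c, (ix, iy), 1)
    mask = c > 0
    out = np.zeros((g, g))
    out[mask] = s[mask] / c[mask]
    return out, mask


def _fill_periodic(grid: np.ndarray, mask: np.ndarray, max_sweeps: int = 1000) -> np.ndarray:
    """Fill unset cells by iterative averaging of filled periodic neighbors."""
    grid = grid.copy()
    mask = mask.copy()
    for _ in range(max_sweeps):
        if mask.all():
            return grid
        acc = np.zeros_like(grid)
        cnt = np.zeros_like(grid)
        for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb_val = np.roll(grid, shift, axis=(0, 1))
            nb_ok = np.roll(mask, shift, axis=(0, 1))
            acc += np.where(nb_ok, nb_val, 0.0)
            cnt += nb_ok
        fillable = (~mask) & (cnt > 0)
        grid[fillable] = acc[fillable] / cnt[fillable]
        mask |= fillable
    raise ResolutionError("hole filling did not complete (grid fully empty?)")


def assign_leaflets(
    frame: SystemConfiguration,
    topology: MembraneTopology,
    grid: int = 4,
    local: bool = True,
) -> LeafletAssignment:
    """Assign each lipid to the upper or lower leaflet.

    Start from a global-mean split of phosphate heights, build smoothed upper
    and lower candidate surfaces on a coarse periodic grid, and re-assign each
    lipid by the sign of its phosphate height minus the grid-local midplane
    (one iteration).  With ``local=False`` the global-mean midplane is used.
    Ties (height exactly on the midplane) go to the upper leaflet.
    """
    if topology.n_lipids < 2:
        raise DegenerateBilayerError("need at least 2 lipids")
    pos = frame.positions[topology.phosphate_idx]
    lz = frame.box[2]
    z_ref = _mean_periodic(pos[:, 2], lz)
    dz = _relative_z(pos[:, 2], z_ref, lz)
    upper = dz >= 0
    if upper.all() or (~upper).all():
        raise DegenerateBilayerError("all lipids on one side of the midplane")
    g = grid
    ix, iy = _cell_of(pos[:, :2], frame.box, g)
    if local:
        up_s, up_m = _binned_mean(ix[upper], iy[upper], dz[upper], g)
        lo_s, lo_m = _binned_mean(ix[~upper], iy[~upper], dz[~upper], g)
        up_s = _fill_periodic(up_s, up_m)
        lo_s = _fill_periodic(lo_s, lo_m)
        mid = 0.5 * (up_s + lo_s)
        upper = dz >= mid[ix, iy]
        if upper.all() or (~upper).all():
            raise DegenerateBilayerError("all lipids on one side of the local midplane")
        up_s, up_m = _binned_mean(ix[upper], iy[upper], dz[upper], g)
        lo_s, lo_m = _binned_mean(ix[~upper], iy[~upper], dz[~upper], g)
        up_s = _fill_periodic(up_s, up_m)
        lo_s = _fill_periodic(lo_s, lo_m)
        mid = 0.5 * (up_s + lo_s)
    else:
        up_s = np.full((g, g), float(np.mean(dz[upper])))
        lo_s = np.full((g, g), float(np.mean(dz[~upper])))
        mid = np.zeros((g, g))
    labels = np.where(upper, "upper", "lower").astype(object)
    return LeafletAssignment(
        labels=labels,
        midplane=mid,
        upper_surface=up_s,
        lower_surface=lo_s,
        z_ref=z_ref,
        grid=g,
        box=frame.box.copy(),
    )


def _mean_periodic(z: np.ndarray, lz: float) -> float:
    """Circular mean of z over a periodic box edge of length lz."""
    ang = z / lz * 2 * np.pi
    return float(np.angle(np.exp(1j * ang).mean()) / (2 * np.pi) * lz) % lz


def count_inserted_cations(
    frame: SystemConfiguration,
    topology: MembraneTopology,
    assignment: LeafletAssignment,
):
    """One insertion-series row for a frame.

    A cation counts as inserted in the upper leaflet iff its ring bead's
    height lies between the local midplane (inclusive; documented tie-break)
    and the local upper phosphate surface (inclusive); symmetric, exclusive at
    the midplane, for the lower leaflet.
    """
    n_up = int(np.sum(assignment.labels == "upper"))
    n_lo = int(np.sum(assignment.labels == "lower"))
    ins_up = ins_lo = 0
    if len(topology.cation_ring_idx):
        rp = frame.positions[topology.cation_ring_idx]
        dz = _relative_z(rp[:, 2], assignment.z_ref, frame.box[2])
        ix, iy = _cell_of(rp[:, :2], assignment.box, assignment.grid)
        mid = assignment.midplane[ix, iy]
        up = assignment.upper_surface[ix, iy]
        lo = assignment.lower_surface[ix, iy]
        eps = 1e-9  # tolerance so the documented tie-break survives float noise
        ins_up = int(np.sum((dz >= mid - eps) & (dz <= up + eps)))
        ins_lo = int(np.sum((dz < mid - eps) & (dz >= lo - eps)))
    return {
        "time": frame.time,
        "inserted_upper": ins_up,
        "inserted_lower": ins_lo,
        "lipids_upper": n_up,
        "lipids_lower": n_lo,
        "ratio_upper": ins_up / n_up,
        "ratio_lower": ins_lo / n_lo,
    }


def insertion_series(frames, topology, grid: int = 4, local: bool = True) -> InsertionSeries:
    """Run leaflet assignment + insertion counting over a trajectory."""
    rows = []
    prev_labels = None
    for i, frame in enumerate(frames):
        a = assign_leaflets(frame, topology, grid=grid, local=local)
        if prev_labels is not None:
            flips = int(np.sum(a.labels != prev_labels))
            if flips:
                log.info("frame %d: %d lipid leaflet flip(s) detected", i, flips)
        prev_labels = a.labels
        rows.append(count_inserted_cations(frame, topology, a))
    return InsertionSeries(
        time=np.array([r["time"] for r in rows]),
        inserted_upper=np.array([r["inserted_upper"] for r in rows]),
        inserted_lower=np.array([r["inserted_lower"] for r in rows]),
        lipids_upper=np.array([r["lipids_upper"] for r in rows]),
        lipids_lower=np.array([r["lipids_lower"] for r in rows]),
    )


def detect_saturation(ratio: np.ndarray, window: int) -> SaturationResult:
    """Plateau value and onset of an insertion ratio series.

    The plateau is the mean over the final ``window`` frames, accepted only if
    the linear-fit slope over that window is statistically indistinguishable
    from zero (|slope| < its standard error).  The onset is the first frame
    whose value comes within 5% of the plateau.
    """
    ratio = np.asarray(ratio, float)
    if len(ratio) < 2 * window:
        raise ValueError("series must be at least twice the window length")
    tail = ratio[-window:]
    x = np.arange(window, dtype=float)
    res = stats.linregress(x, tail)
    if np.isnan(res.stderr):  # constant series: slope exactly 0, stderr 0/0
        slope_ok = np.allclose(tail, tail[0])
    else:
        slope_ok = abs(res.slope) < res.stderr
    if not slope_ok:
        return SaturationResult(defined=False)
    plateau = float(np.mean(tail))
    tolerance = 0.05 * abs(plateau) if plateau != 0 else 0.0
    within = np.abs(ratio - plateau) <= tolerance
    onset = int(np.argmax(within)) if within.any() else len(ratio) - window
    return SaturationResult(defined=True, ratio=plateau, onset_index=onset)


# ---------------------------------------------------------------------------
# surfaces & spectra


def reconstruct_surface(
    frame: SystemConfiguration,
    topology: MembraneTopology,
    assignment: LeafletAssignment,
    n_grid: int = 32,
    leaflet: str = "upper",
) -> UndulationSurface:
    """Grid one leaflet's phosphate heights into an N x N mean-subtracted field.

    Cells holding several phosphates are averaged; empty cells are filled by
    iterative nearest-neighbor averaging under periodic boundaries.  More than
    50% empty cells raises :class:`ResolutionError` (use a coarser grid).
    """
    if n_grid & (n_grid - 1):
        raise ValueError("n_grid must be a power of two")
    sel = assignment.labels == leaflet
    if not sel.any():
        raise DegenerateBilayerError(f"no lipids in {leaflet} leaflet")
    pos = frame.positions[topology.phosphate_idx[sel]]
    dz = _relative_z(pos[:, 2], assignment.z_ref, frame.box[2])
    ix, iy = _cell_of(pos[:, :2], frame.box, n_grid)
    grid, mask = _binned_mean(ix, iy, dz, n_grid)
    empty_frac = 1.0 - mask.mean()
    if empty_frac > 0.5:
        raise ResolutionError(
            f"{empty_frac:.0%} of {n_grid}x{n_grid} cells empty; use a smaller grid"
        )
    grid = _fill_periodic(grid, mask)
    grid = grid - grid.mean()
    return UndulationSurface(heights=grid, box_edge=float(frame.box[0]), time=frame.time)


def undulation_spectrum(surfaces: list[UndulationSurface]) -> FluctuationSpectrum:
    """Frame-averaged, radially binned fluctuation spectrum S(q) = A <|h_hat|^2>."""
    if not surfaces:
        raise ValueError("need at least one surface")
    n = surfaces[0].heights.shape[0]
    length = surfaces[0].box_edge
    for s in surfaces:
        if s.heights.shape[0] != n or not np.isclose(s.box_edge, length):
            raise ValueError("all surfaces must share grid size and box edge")
    area = length * length
    # |h_hat|^2 per frame, h_hat = fft2(h)/N^2
    power = np.empty((len(surfaces), n, n))
    for i, s in enumerate(surfaces):
        h_hat = np.fft.fft2(s.heights - s.heights.mean()) / (n * n)
        power[i] = np.abs(h_hat) ** 2
    mean2d = area * power.mean(axis=0)

    k = np.fft.fftfreq(n, d=1.0 / n)  # integer mode numbers
    kx, ky = np.meshgrid(k, k, indexing="ij")
    k2 = (kx**2 + ky**2).astype(int)
    dq = 2 * np.pi / length
    # bin by exact |q| (integer k^2) so modes of different wavelength never mix;
    # averaging 1/q^4-like intensities across unequal q would bias kappa low
    max_k2 = (n // 2) ** 2
    qs, means, errs = [], [], []
    for r2 in np.unique(k2):
        if r2 == 0 or r2 > max_k2:
            continue
        sel = k2 == r2
        qs.append(math.sqrt(r2) * dq)
        per_frame = area * power[:, sel].mean(axis=1)
        means.append(float(per_frame.mean()))
        errs.append(
            float(per_frame.std(ddof=1) / np.sqrt(len(surfaces))) if len(surfaces) > 1 else np.nan
        )
    return FluctuationSpectrum(
        q_values=np.array(qs),
        intensity=np.array(means),
        stderr=np.array(errs),
        n_frames=len(surfaces),
        box_edge=length,
        grid=n,
        intensity_2d=mean2d,
    )


def fit_bending_modulus(
    spectrum: FluctuationSpectrum,
    temperature: float,
    q_max: float = 1.0,
) -> BendingFit:
    """Bending modulus from the low-q Helfrich regime S(q) = k_B T / (kappa q^4).

    Fits log S against log q with the slope fixed at -4; the intercept gives
    kappa.  Bins are weighted by their standard errors when available.
    """
    q = spectrum.q_values
    s = spectrum.intensity
    sel = (q < q_max) & (s > 0) & np.isfinite(s)
    if sel.sum() < 3:
        raise FitError(f"need >= 3 bins below q_max={q_max}, have {int(sel.sum())}")
    q, s = q[sel], s[sel]
    se = spectrum.stderr[sel] if spectrum.stderr is not None else None
    c = np.log(s) + 4.0 * np.log(q)  # per-bin intercept estimate
    weighted = se is not None and np.all(np.isfinite(se)) and np.all(se > 0)
    if weighted:
        w = (s / se) ** 2  # delta method: var(log S) = (se/S)^2 = 1/w
        c_hat = float(np.average(c, weights=w))
        var_c = float(1.0 / np.sum(w))
    else:
        c_hat = float(np.mean(c))
        var_c = float(np.var(c, ddof=1) / len(c)) if len(c) > 1 else 0.0
    kbt = KB_J * temperature
    kappa = kbt / np.exp(c_hat)  # S in nm^4, q in nm^-1 -> kappa in J
    kappa_err = kappa * np.sqrt(var_c)
    pred = c_hat - 4.0 * np.log(q)
    obs = np.log(s)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return BendingFit(
        kappa=float(kappa),
        kappa_error=float(kappa_err),
        q_fit_range=(float(q.min()), float(q.max())),
        goodness=r2,
        n_bins=int(len(q)),
    )


def bending_modulus_blocks(
    surfaces: list[UndulationSurface],
    temperature: float,
    q_max: float = 1.0,
    n_blocks: int = 5,
):
    """kappa with a block-averaged error bar: fit each frame block separately."""
    if len(surfaces) < n_blocks:
        raise ValueError("need at least one surface per block")
    size = len(surfaces) // n_blocks
    kappas = []
    for b in range(n_blocks):
        block = surfaces[b * size : (b + 1) * size]
        fit = fit_bending_modulus(undulation_spectrum(block), temperature, q_max)
        kappas.append(fit.kappa)
    mean, err = block_average(np.array(kappas), n_blocks=len(kappas))
    return mean, err


def block_average(series: np.ndarray, n_blocks: int) -> tuple[float, float]:
    """Mean of contiguous block means and their standard error."""
    series = np.asarray(series, float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if len(series) < n_blocks:
        raise ValueError("series shorter than n_blocks")
    size = len(series) // n_blocks
    trimmed = series[: size * n_blocks].reshape(n_blocks, size)
    bm = trimmed.mean(axis=1)
    return float(bm.mean()), float(bm.std(ddof=1) / np.sqrt(n_blocks))
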
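"""Ground-truth synthetic inputs: Helfrich surfaces, umbrella samples, toy bilayers.

Every generator is deterministic under a fixed seed; specs and seeds are
returned alongside the data so callers can serialize them into run manifests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np

from .constants import KB, KB_J
from .errors import PackingError, SamplingError
from .forcefield import ParameterSet, SystemConfiguration
from .membrane import UndulationSurface
from .pmf import UmbrellaWindow

log = logging.getLogger(__name__)

__all__ = [
    "HelfrichSpec",
    "ToyBilayerSpec",
    "sample_helfrich_surfaces",
    "sample_umbrella_windows",
    "build_toy_bilayer",
    "double_well",
]


def double_well(z):
    """Analytic benchmark potential U(z) = 4 (z^2 - 1)^2, kJ/mol."""
    z = np.asarray(z, float)
    return 4.0 * (z * z - 1.0) ** 2


# ---------------------------------------------------------------------------
# Helfrich surfaces


@dataclass(frozen=True)
class HelfrichSpec:
    """Thermally fluctuating quasi-planar membrane with known bending modulus."""

    kappa: float  # J
    temperature: float = 303.0  # K
    box_edge: float = 25.0  # L, nm
    grid: int = 32  # N, power of two
    n_frames: int = 500
    seed: int = 0

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if self.grid & (self.grid - 1):
            raise ValueError("grid must be a power of two")


def sample_helfrich_surfaces(spec: HelfrichSpec) -> list[UndulationSurface]:
    """Draw i.i.d. membrane height fields with exact Helfrich statistics.

    Each Fourier mode is an independent complex Gaussian with
    ``<|h_hat(q)|^2> = k_B T / (A kappa q^4)`` under the convention
    ``h_hat = fft2(h) / N^2``; Hermitian symmetry is enforced so h(x, y) is
    real.  This is an exact sampler: the target spectrum holds with zero
    model/discretization error, which is what estimator round-trip tests need.
    """
    n, length = spec.grid, spec.box_edge
    area = length * length
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    k = np.fft.fftfreq(n, d=1.0 / n)
    kx, ky = np.meshgrid(k, k, indexing="ij")
    q2 = (2 * np.pi / length) ** 2 * (kx**2 + ky**2)
    with np.errstate(divide="ignore"):
        var = KB_J * spec.temperature / (area * spec.kappa * q2**2)
    var[0, 0] = 0.0
    sd = np.sqrt(var)
    flip = (-np.arange(n)) % n
    out = []
    for i in range(spec.n_frames):
        g = (rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))) * (sd / math.sqrt(2))
        h_hat = (g + np.conj(g[np.ix_(flip, flip)])) / math.sqrt(2)
        h = np.real(np.fft.ifft2(h_hat)) * n * n
        out.append(UndulationSurface(heights=h - h.mean(), box_edge=length, time=float(i)))
    return out


# ---------------------------------------------------------------------------
# umbrella sampling oracle


def sample_umbrella_windows(
    potential,
    centers,
    spring_k: float,
    n_per_window: int,
    temperature: float = 303.0,
    seed: int = 0,
    burn_in: int = 500,
    stride: int = 10,
    n_chains: int = 8,
    step: float | None = None,
) -> list[UmbrellaWindow]:
    """Metropolis samples from exp(-[U(z) + k/2 (z - c)^2] / k_B T) per window.

    Runs ``n_chains`` independent chains per window (vectorized), discards
    ``burn_in`` sweeps, keeps every ``stride``-th sweep until ``n_per_window``
    samples accumulate.  The proposal step is auto-tuned during burn-in toward
    ~40% acceptance; a window still accepting < 5% afterwards raises
    :class:`SamplingError`.
    """
    kt = KB * temperature
    rng = np.random.Generator(np.random.PCG64(seed))
    windows = []
    for c in np.atleast_1d(np.asarray(centers, float)):
        def energy(z):
            return potential(z) + 0.5 * spring_k * (z - c) ** 2

        st = step if step is not None else max(0.5 * math.sqrt(kt / max(spring_k, 1e-9)), 0.02)
        x = np.full(n_chains, c)
        e = energy(x)
        acc_cnt = prop_cnt = 0
        # burn-in with step tuning
        for sweep in range(burn_in):
            x, e, acc = _metropolis_sweep(x, e, energy, st, kt, rng)
            acc_cnt += acc
            prop_cnt += n_chains
            if (sweep + 1) % 50 == 0:
                rate = acc_cnt / prop_cnt
                if rate < 0.3:
                    st *= 0.8
                elif rate > 0.55:
                    st *= 1.25
                acc_cnt = prop_cnt = 0
        # production
        keep = []
        acc_cnt = prop_cnt = 0
        sweeps = 0
        needed = n_per_window
        while len(keep) * n_chains < needed * 1:  # keep whole sweeps
            for _ in range(stride):
                x, e, acc = _metropolis_sweep(x, e, energy, st, kt, rng)
                acc_cnt += acc
                prop_cnt += n_chains
                sweeps += 1
            keep.append(x.copy())
        rate = acc_cnt / prop_cnt
        if rate < 0.05:
            raise SamplingError(f"window at {c}: acceptance {rate:.1%} after tuning")
        log.debug("window %.3f: acceptance %.1f%%, step %.3g", c, 100 * rate, st)
        samples = np.concatenate(keep)[:n_per_window]
        windows.append(UmbrellaWindow(center=float(c), spring_k=spring_k, samples=samples, temperature=temperature))
    return windows


def _metropolis_sweep(x, e, energy, step, kt, rng):
    prop = x + rng.normal(scale=step, size=x.shape)
    ep = energy(prop)
    accept = rng.random(x.shape) < np.exp(np.minimum((e - ep) / kt, 0.0))
    x = np.where(accept, prop, x)
    e = np.where(accept, ep, e)
    return x, e, int(accept.sum())


# ---------------------------------------------------------------------------
# toy bilayer builder


@dataclass(frozen=True)
class ToyBilayerSpec:
    """Prescribed-geometry bilayer + cations with known ground-truth labels."""

    lipids_per_leaflet: int = 64
    area_per_lipid: float = 0.65  # nm^2
    cation_count: int = 0
    inserted_per_lipid_upper: float = 0.0  # inserted cations / lipid, in [0, 1]
    inserted_per_lipid_lower: float = 0.0
    tail_beads: int = 2  # beads per cation tail (~ alkyl carbons / 3)
    nacl_pairs: int = 0
    seed: int = 0
    phosphate_z: float = 1.8  # nm, +/- phosphate plane height
    water_depth: float = 2.5  # nm of solvent space above each leaflet
    lipid_tail_beads: int = 4
    xy_jitter: float = 0.0  # nm, optional lattice jitter

    def __post_init__(self):
        for f in (self.inserted_per_lipid_upper, self.inserted_per_lipid_lower):
            if not 0.0 <= f <= 1.0:
                raise ValueError("inserted fraction must be in [0, 1]")
        if self.lipids_per_leaflet < 1 or self.cation_count < 0 or self.nacl_pairs < 0:
            raise ValueError("counts must be non-negative")


_MIN_DIST = 0.35  # nm, solvent placement rejection radius
_BOND_K = 1250.0  # kJ/mol/nm^2
_BOND_R0 = 0.3  # nm
_ANGLE_K = 25.0  # kJ/mol/rad^2


def chain_bonded_templates(n_beads: int):
    """Harmonic bond/angle templates for a linear chain of ``n_beads`` beads."""
    from .forcefield import BondedTerm

    terms = [
        BondedTerm("bond", (i, i + 1), _BOND_R0, _BOND_K) for i in range(n_beads - 1)
    ]
    terms += [
        BondedTerm("angle", (i, i + 1, i + 2), math.pi, _ANGLE_K)
        for i in range(n_beads - 2)
    ]
    return terms


def _clear_of(candidate: np.ndarray, existing: np.ndarray, box: np.ndarray, min_dist: float) -> bool:
    """True if every candidate bead is at least min_dist from every existing bead."""
    if len(existing) == 0:
        return True
    d = existing[None, :, :] - candidate[:, None, :]
    d -= box * np.round(d / box)
    return bool(np.min(np.einsum("ijk,ijk->ij", d, d)) > min_dist * min_dist)


def _role_bead(params: ParameterSet, role: str) -> str:
    for name, bt in sorted(params.bead_types.items()):
        if bt.role == role:
            return name
    raise ValueError(f"parameter set has no bead with role {role!r}")


def build_toy_bilayer(spec: ToyBilayerSpec, params: ParameterSet):
    """Construct a toy bilayer + cation configuration with known labels.

    Lipids sit on two opposing square lattices (tails inward) at the given
    area per lipid.  The prescribed number of inserted cations per leaflet is
    placed with ring beads strictly between that leaflet's midplane and
    phosphate plane; remaining cations go into the upper solvent region
    (mirroring an asymmetric exposure), chloride counter-ions and NaCl pairs
    are placed randomly in the solvent with minimum-distance rejection.

    Returns ``(config, truth)`` where ``truth`` records the leaflet of every
    lipid and the inserted flag/leaflet of every cation, plus the spec itself.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    side = math.ceil(math.sqrt(spec.lipids_per_leaflet))
    a = math.sqrt(spec.area_per_lipid)
    lx = side * a
    lz = 2 * (spec.phosphate_z + 0.3 + spec.water_depth)
    box = np.array([lx, lx, lz])
    zc = lz / 2  # bilayer midplane in box coordinates

    head = _role_bead(params, "lipid-head")
    phos = _role_bead(params, "lipid-phosphate")
    glyc = _role_bead(params, "lipid-glycerol")
    ltail = _role_bead(params, "lipid-tail")
    ring = _role_bead(params, "cation-ring")
    ctail = _role_bead(params, "cation-tail")
    anion = _role_bead(params, "anion")
    sodium = _role_bead(params, "sodium")

    positions, types, molnames, molids = [], [], [], []
    bonds, angles = [], []
    mol = 0

    def add_molecule(chain_xyz, chain_types, name):
        nonlocal mol
        start = len(positions)
        positions.extend(chain_xyz)
        types.extend(chain_types)
        molnames.extend([name] * len(chain_xyz))
        molids.extend([mol] * len(chain_xyz))
        for i in range(len(chain_xyz) - 1):
            bonds.append((start + i, start + i + 1))
        for i in range(len(chain_xyz) - 2):
            angles.append((start + i, start + i + 1, start + i + 2))
        mol += 1
        return start

    lipid_types = [head, phos, glyc] + [ltail] * spec.lipid_tail_beads
    leaflet_truth = []
    for leaflet, sign in (("upper", +1), ("lower", -1)):
        count = 0
        for i in range(side):
            for j in range(side):
                if count >= spec.lipids_per_leaflet:
                    break
                x = (i + 0.5) * a
                y = (j + 0.5) * a
                if spec.xy_jitter > 0:
                    x += rng.normal(scale=spec.xy_jitter)
                    y += rng.normal(scale=spec.xy_jitter)
                zs = [
                    zc + sign * (spec.phosphate_z + 0.3),  # head
                    zc + sign * spec.phosphate_z,  # phosphate
                    zc + sign * (spec.phosphate_z - 0.3),  # glycerol
                ]
                for t in range(spec.lipid_tail_beads):
                    zs.append(zc + sign * (spec.phosphate_z - 0.6 - 0.3 * t))
                add_molecule([(x, y, z) for z in zs], lipid_types, "LIP")
                leaflet_truth.append(leaflet)
                count += 1

    n_ins_up = round(spec.inserted_per_lipid_upper * spec.lipids_per_leaflet)
    n_ins_lo = round(spec.inserted_per_lipid_lower * spec.lipids_per_leaflet)
    if n_ins_up + n_ins_lo > spec.cation_count:
        raise ValueError("inserted cations exceed cation_count")

    cation_types = [ring] + [ctail] * spec.tail_beads
    occupied = np.array(positions) if positions else np.empty((0, 3))
    cation_truth = []

    def place_cation(region):
        for _ in range(10000):
            x, y = rng.uniform(0, lx, size=2)
            if region == "upper":
                z0 = zc + rng.uniform(0.4, spec.phosphate_z - 0.2)
                dz = -0.3  # tail toward midplane
            elif region == "lower":
                z0 = zc - rng.uniform(0.4, spec.phosphate_z - 0.2)
                dz = 0.3
            else:  # solvent above upper leaflet
                z0 = rng.uniform(zc + spec.phosphate_z + 0.8, lz - 0.5)
                dz = 0.25
            xyz = np.array([(x, y, z0 + dz * t) for t in range(1 + spec.tail_beads)])
            if _clear_of(xyz, np.array(positions), box, 0.30):
                add_molecule([tuple(p) for p in xyz], cation_types, "CAT")
                return
        raise PackingError(f"could not place cation in {region} after 10000 attempts")

    for _ in range(n_ins_up):
        place_cation("upper")
        cation_truth.append({"inserted": True, "leaflet": "upper"})
    for _ in range(n_ins_lo):
        place_cation("lower")
        cation_truth.append({"inserted": True, "leaflet": "lower"})
    for _ in range(spec.cation_count - n_ins_up - n_ins_lo):
        place_cation("solvent")
        cation_truth.append({"inserted": False, "leaflet": None})

    # solvent ions with minimum-distance rejection
    def place_ion(bead, name):
        for _ in range(10000):
            x, y = rng.uniform(0, lx, size=2)
            if rng.random() < 0.5:
                z = rng.uniform(zc + spec.phosphate_z + 0.6, lz - 0.3)
            else:
                z = rng.uniform(0.3, zc - spec.phosphate_z - 0.6)
            if _clear_of(np.array([[x, y, z]]), np.array(positions), box, _MIN_DIST):
                add_molecule([(x, y, z)], [bead], name)
                return
        raise PackingError(f"could not place {name} after 10000 attempts")

    for _ in range(spec.cation_count):  # counter-ions for +1 cations
        place_ion(anion, "CL")
    for _ in range(spec.nacl_pairs):
        place_ion(sodium, "NA")
        place_ion(anion, "CL")

    bond_index = np.array(bonds, int).reshape(-1, 2)
    angle_index = np.array(angles, int).reshape(-1, 3)
    config = SystemConfiguration(
        positions=np.array(positions),
        box=box,
        bead_types=np.array(types, dtype=object),
        molecule_ids=np.array(molids),
        molecule_names=np.array(molnames, dtype=object),
        bond_index=bond_index,
        bond_r0=np.full(len(bond_index), _BOND_R0),
        bond_k=np.full(len(bond_index), _BOND_K),
        angle_index=angle_index,
        angle_theta0=np.full(len(angle_index), math.pi),
        angle_k=np.full(len(angle_index), _ANGLE_K),
    )
    truth = {
        "spec": asdict(spec),
        "seed": spec.seed,
        "lipid_leaflets": leaflet_truth,
        "cations": cation_truth,
        "n_inserted_upper": n_ins_up,
        "n_inserted_lower": n_ins_lo,
        "total_charge": _total_charge(config, params),
    }
    return config, truth


def _total_charge(config: SystemConfiguration, params: ParameterSet) -> float:
    return float(params.charges(config.bead_types).sum())
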
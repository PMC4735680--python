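"""Minimal CG dynamics: velocity Verlet, BAOAB Langevin, Berendsen semi-isotropic barostat.

The engine is intentionally desk-scale: vectorized numpy forces with a
Verlet neighbor list refreshed when any bead has moved more than half the
skin.  All randomness flows through one counter-based generator
(``numpy.random.Generator(PCG64)``) seeded from ``IntegratorSettings.seed``
so trajectories are bitwise reproducible and checkpoint-restartable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .constants import KB, BAR_PER_KJMOLNM3, WATER_COMPRESSIBILITY
from .errors import IntegrationError
from .forcefield import (
    ParameterSet,
    SystemConfiguration,
    _PairTables,
    build_neighbor_list,
    energy_forces_virial,
)

log = logging.getLogger(__name__)

__all__ = [
    "IntegratorSettings",
    "ToyMD",
    "velocity_verlet_step",
    "langevin_step",
    "semi_isotropic_barostat_step",
    "run_simulation",
    "init_velocities",
    "kinetic_energy",
    "kinetic_temperature",
]


@dataclass
class IntegratorSettings:
    timestep: float = 0.01  # ps
    temperature: float = 303.0  # K
    friction: float = 1.0  # 1/ps; 0 => NVE velocity Verlet
    pressure: float | None = None  # bar; None => no barostat
    barostat_coupling_time: float = 1.0  # ps
    compressibility: float = WATER_COMPRESSIBILITY  # bar^-1
    seed: int = 0
    skin: float = 0.2  # nm, neighbor-list skin

    def __post_init__(self):
        if not self.timestep > 0:
            raise ValueError("timestep must be > 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


def init_velocities(
    config: SystemConfiguration, params: ParameterSet, temperature: float, seed: int = 0
) -> None:
    """Draw Maxwell-Boltzmann velocities in place and remove net momentum."""
    rng = np.random.Generator(np.random.PCG64(seed))
    m = params.masses(config.bead_types)
    v = rng.normal(size=(config.n_beads, 3)) * np.sqrt(KB * temperature / m)[:, None]
    p = (m[:, None] * v).sum(axis=0)
    v -= p / m.sum()
    config.velocities = v


def kinetic_energy(config: SystemConfiguration, params: ParameterSet) -> float:
    m = params.masses(config.bead_types)
    return float(0.5 * np.sum(m[:, None] * config.velocities**2))


def kinetic_temperature(config: SystemConfiguration, params: ParameterSet) -> float:
    """Instantaneous temperature from equipartition, 3N degrees of freedom."""
    return 2.0 * kinetic_energy(config, params) / (3.0 * config.n_beads * KB)


class ToyMD:
    """Stateful integrator bound to one configuration/parameter set."""

    def __init__(self, config: SystemConfiguration, params: ParameterSet, settings: IntegratorSettings):
        if config.velocities is None:
            raise IntegrationError("velocities required; call init_velocities first")
        self.config = config.copy()
        self.params = params
        self.settings = settings
        self.rng = np.random.Generator(np.random.PCG64(settings.seed))
        self._tables = _PairTables(self.config, params)
        self.mass = self._tables.mass
        self.step_count = 0
        self._nlist_ref = None
        self._neighbor = None
        self._refresh_neighbors()
        self.energy, self.forces, self.virial = self._evaluate()

    # -- neighbor bookkeeping ------------------------------------------------

    def _refresh_neighbors(self):
        from .forcefield import _drop_exclusions

        self._neighbor = _drop_exclusions(
            build_neighbor_list(self.config, self.params.cutoff, self.settings.skin),
            self.config,
        )
        self._nlist_ref = self.config.positions.copy()

    def _maybe_refresh(self):
        disp = self.config.positions - self._nlist_ref
        if self.config.periodic:
            from .forcefield import minimum_image

            disp = minimum_image(disp, self.config.box)
        if np.max(np.einsum("ij,ij->i", disp, disp)) > (self.settings.skin / 2) ** 2:
            self._refresh_neighbors()

    def _evaluate(self):
        e, f, w = energy_forces_virial(
            self.config,
            self.params,
            neighbor=self._neighbor,
            tables=self._tables,
            exclusions_removed=True,
        )
        if not np.isfinite(e) or not np.all(np.isfinite(f)):
            raise IntegrationError(f"non-finite energy/forces at step {self.step_count}")
        return e, f, w

    # -- integrators ---------------------------------------------------------

    def step(self):
        """One BAOAB step (reduces to plain velocity Verlet when friction = 0)."""
        dt = self.settings.timestep
        c = self.config
        m = self.mass[:, None]
        v = c.velocities
        v += 0.5 * dt * self.forces / m  # B
        c.positions += 0.5 * dt * v  # A
        gamma = self.settings.friction
        if gamma > 0:
            c1 = np.exp(-gamma * dt)
            c2 = np.sqrt((1.0 - c1 * c1) * KB * self.settings.temperature / self.mass)
            v *= c1
            v += c2[:, None] * self.rng.normal(size=v.shape)  # O
        c.positions += 0.5 * dt * v  # A
        self._wrap()
        self._maybe_refresh()
        self.energy, self.forces, self.virial = self._evaluate()
        v += 0.5 * dt * self.forces / m  # B
        c.time += dt
        self.step_count += 1
        if self.settings.pressure is not None:
            self.barostat_step()

    def _wrap(self):
        if self.config.periodic:
            np.mod(self.config.positions, self.config.box, out=self.config.positions)

    # -- barostat ------------------------------------------------------------

    def pressure_tensor(self) -> np.ndarray:
        """Instantaneous pressure tensor in bar (kinetic + virial parts)."""
        c = self.config
        vol = float(np.prod(c.box))
        kin = (self.mass[:, None, None] * c.velocities[:, :, None] * c.velocities[:, None, :]).sum(axis=0)
        return (kin + self.virial) / vol * BAR_PER_KJMOLNM3

    def barostat_step(self):
        """Berendsen weak coupling; Lx=Ly share one scale factor, Lz another."""
        s = self.settings
        p = self.pressure_tensor()
        p_lat = 0.5 * (p[0, 0] + p[1, 1])
        p_z = p[2, 2]
        pref = s.compressibility * s.timestep / s.barostat_coupling_time
        mu_lat = (1.0 - pref * (s.pressure - p_lat)) ** (1.0 / 3.0)
        mu_z = (1.0 - pref * (s.pressure - p_z)) ** (1.0 / 3.0)
        clamped = False
        for name, mu in (("lateral", mu_lat), ("normal", mu_z)):
            if not 0.9 <= mu <= 1.1:
                log.warning("barostat %s rescale factor %.4f clamped to [0.9, 1.1]", name, mu)
                clamped = True
        mu_lat = float(np.clip(mu_lat, 0.9, 1.1))
        mu_z = float(np.clip(mu_z, 0.9, 1.1))
        c = self.config
        c.box[0] *= mu_lat
        c.box[1] *= mu_lat
        c.box[2] *= mu_z
        c.positions[:, 0] *= mu_lat
        c.positions[:, 1] *= mu_lat
        c.positions[:, 2] *= mu_z
        # box deformation invalidates the list reference frame
        self._refresh_neighbors()
        self.energy, self.forces, self.virial = self._evaluate()
        self._zero_momentum()
        return clamped

    def _zero_momentum(self):
        v = self.config.velocities
        p = (self.mass[:, None] * v).sum(axis=0)
        v -= p / self.mass.sum()

    # -- checkpointing -------------------------------------------------------

    def checkpoint_state(self) -> dict:
        c = self.config
        return {
            "step": self.step_count,
            "time": c.time,
            "positions": c.positions.tolist(),
            "velocities": c.velocities.tolist(),
            "box": c.box.tolist(),
            "rng_state": _jsonify_rng(self.rng.bit_generator.state),
            "seed": self.settings.seed,
        }

    def restore(self, state: dict):
        c = self.config
        c.positions = np.array(state["positions"])
        c.velocities = np.array(state["velocities"])
        c.box = np.array(state["box"])
        c.time = state["time"]
        self.step_count = state["step"]
        self.rng.bit_generator.state = _unjsonify_rng(state["rng_state"])
        self._refresh_neighbors()
        self.energy, self.forces, self.virial = self._evaluate()


def _jsonify_rng(state: dict) -> dict:
    out = json.loads(json.dumps(state, default=str))
    s = state["state"]
    out["state"] = {"state": str(s["state"]), "inc": str(s["inc"])}
    return out


def _unjsonify_rng(state: dict) -> dict:
    s = dict(state)
    s["state"] = {"state": int(state["state"]["state"]), "inc": int(state["state"]["inc"])}
    if "has_uint32" in s:
        s["has_uint32"] = int(s["has_uint32"])
    if "uinteger" in s:
        s["uinteger"] = int(s["uinteger"])
    return s


def minimize_energy(
    config: SystemConfiguration,
    params: ParameterSet,
    max_steps: int = 200,
    max_disp: float = 0.02,
    f_tol: float = 100.0,
) -> SystemConfiguration:
    """Clamped steepest descent to relax bad contacts before dynamics.

    Each step moves beads along the force, with the largest displacement
    clamped to ``max_disp`` nm; stops when the max force drops below
    ``f_tol`` kJ/mol/nm.
    """
    from .forcefield import _PairTables

    c = config.copy()
    tables = _PairTables(c, params)
    nlist = build_neighbor_list(c, params.cutoff, 0.2)
    e, f, _ = energy_forces_virial(c, params, neighbor=nlist, tables=tables)
    for i in range(max_steps):
        fmax = np.max(np.linalg.norm(f, axis=1))
        if fmax < f_tol:
            break
        step = min(max_disp / fmax, 1e-4)
        trial = c.copy()
        trial.positions = c.positions + step * f
        if trial.periodic:
            np.mod(trial.positions, trial.box, out=trial.positions)
        nlist_t = build_neighbor_list(trial, params.cutoff, 0.2)
        e_t, f_t, _ = energy_forces_virial(trial, params, neighbor=nlist_t, tables=tables)
        if e_t < e:
            c, e, f = trial, e_t, f_t
            max_disp = min(max_disp * 1.2, 0.05)
        else:
            max_disp *= 0.5
            if max_disp < 1e-6:
                break
    return c


# ---------------------------------------------------------------------------
# functional single-step API


def velocity_verlet_step(
    config: SystemConfiguration, params: ParameterSet, settings: IntegratorSettings
) -> SystemConfiguration:
    """One deterministic NVE velocity-Verlet step (friction forced to 0)."""
    s = IntegratorSettings(**{**asdict(settings), "friction": 0.0, "pressure": None})
    md = ToyMD(config, params, s)
    md.step()
    return md.config


def langevin_step(
    config: SystemConfiguration, params: ParameterSet, settings: IntegratorSettings
) -> SystemConfiguration:
    """One BAOAB Langevin step; identical seed => identical trajectory."""
    s = IntegratorSettings(**{**asdict(settings), "pressure": None})
    md = ToyMD(config, params, s)
    md.step()
    return md.config


def semi_isotropic_barostat_step(
    config: SystemConfiguration,
    params: ParameterSet,
    settings: IntegratorSettings,
) -> SystemConfiguration:
    """Apply one Berendsen semi-isotropic rescaling (no time integration)."""
    md = ToyMD(config, params, settings)
    md.barostat_step()
    return md.config


# ---------------------------------------------------------------------------
# trajectory driver


@dataclass
class SimulationResult:
    times: np.ndarray
    potential: np.ndarray
    kinetic: np.ndarray
    temperature: np.ndarray
    box: np.ndarray  # (n, 3)
    final: SystemConfiguration
    frames_written: int = 0
    checkpoint_path: str | None = None


def run_simulation(
    config: SystemConfiguration,
    params: ParameterSet,
    settings: IntegratorSettings,
    n_steps: int,
    out_dir: str | Path | None = None,
    frame_stride: int = 100,
    sample_stride: int = 10,
    checkpoint: str | Path | None = None,
    traj_name: str = "traj.gro",
) -> SimulationResult:
    """Integrate ``n_steps`` steps, writing frames/series/checkpoint under ``out_dir``.

    ``checkpoint`` restores a previous run's state (positions, velocities, box
    and the random stream), so a restarted run continues bitwise identically.
    With ``n_steps = 0`` only the initial frame is emitted.
    """
    from .gro import write_gro  # local import to avoid cycle

    md = ToyMD(config, params, settings)
    if checkpoint is not None:
        with open(checkpoint) as fh:
            md.restore(json.load(fh))

    out_dir = Path(out_dir) if out_dir is not None else None
    traj_path = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        traj_path = out_dir / traj_name

    times, epot, ekin, temp, boxes = [], [], [], [], []
    frames = 0

    def sample():
        times.append(md.config.time)
        epot.append(md.energy)
        ekin.append(kinetic_energy(md.config, params))
        temp.append(kinetic_temperature(md.config, params))
        boxes.append(md.config.box.copy())

    def write_frame(mode):
        nonlocal frames
        if traj_path is not None:
            write_gro(traj_path, md.config, append=(mode == "a"))
            frames += 1

    sample()
    write_frame("w")
    for i in range(n_steps):
        try:
            md.step()
        except IntegrationError:
            if out_dir is not None:
                write_gro(out_dir / "crash.gro", md.config)
            raise
        if (i + 1) % sample_stride == 0 or i + 1 == n_steps:
            sample()
        if (i + 1) % frame_stride == 0:
            write_frame("a")

    ck_path = None
    if out_dir is not None:
        ck_path = out_dir / "checkpoint.json"
        with open(ck_path, "w") as fh:
            json.dump(md.checkpoint_state(), fh)
        series = np.column_stack([times, epot, ekin, temp, np.array(boxes)])
        header = "time_ps\tpotential_kJ_per_mol\tkinetic_kJ_per_mol\ttemperature_K\tLx_nm\tLy_nm\tLz_nm"
        np.savetxt(out_dir / "series.tsv", series, delimiter="\t", header=header, comments="", fmt="%.10g")

    return SimulationResult(
        times=np.array(times),
        potential=np.array(epot),
        kinetic=np.array(ekin),
        temperature=np.array(temp),
        box=np.array(boxes),
        final=md.config,
        frames_written=frames,
        checkpoint_path=None if ck_path is None else str(ck_path),
    )
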
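"""Fixed-column GRO coordinate reader/writer (nm, optional velocities).

Record layout per atom line (GROMACS fixed columns):
``%5d%-5s%5s%5d%8.3f%8.3f%8.3f`` + optional ``%8.4f%8.4f%8.4f`` velocities.
Multi-frame files are plain concatenations of single frames.  A plain-XYZ
fallback is provided for ad-hoc fixtures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import GroParseError
from .forcefield import SystemConfiguration

__all__ = ["read_gro", "write_gro", "read_xyz", "write_xyz", "read_topology_tsv", "write_topology_tsv"]


def read_gro(path) -> list[SystemConfiguration]:
    """Parse a (multi-frame) GRO file into configurations.

    Atom names are stored as bead types and residue names as molecule names;
    a sidecar topology table can remap them.  A zero-length file yields an
    empty list.  Malformed records raise :class:`GroParseError` with the
    offending line number.
    """
    lines = Path(path).read_text().splitlines()
    frames = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip() and ln == len(lines) - 1:
            break
        title = lines[ln]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.rsplit("t=", 1)[1].split()[0])
            except (ValueError, IndexError):
                pass
        ln += 1
        if ln >= len(lines):
            raise GroParseError("truncated file: missing atom count", line=ln + 1)
        try:
            natoms = int(lines[ln].strip())
        except ValueError:
            raise GroParseError(f"bad atom count {lines[ln]!r}", line=ln + 1) from None
        ln += 1
        if ln + natoms > len(lines):
            raise GroParseError("truncated frame: missing box line", line=len(lines))
        pos = np.empty((natoms, 3))
        vel = np.empty((natoms, 3))
        has_vel = True
        resids = np.empty(natoms, int)
        resnames = np.empty(natoms, dtype=object)
        atomnames = np.empty(natoms, dtype=object)
        for i in range(natoms):
            line = lines[ln + i]
            if len(line) < 44:
                raise GroParseError(f"atom record too short ({len(line)} chars)", line=ln + i + 1)
            try:
                resids[i] = int(line[0:5])
                resnames[i] = line[5:10].strip()
                atomnames[i] = line[10:15].strip()
                pos[i] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except ValueError as e:
                raise GroParseError(f"malformed atom record: {e}", line=ln + i + 1) from None
            if has_vel and len(line) >= 68:
                try:
                    vel[i] = [float(line[44:52]), float(line[52:60]), float(line[60:68])]
                except ValueError:
                    has_vel = False
            else:
                has_vel = False
        ln += natoms
        if ln >= len(lines):
            raise GroParseError("missing box line", line=len(lines))
        box_fields = lines[ln].split()
        if len(box_fields) < 3:
            raise GroParseError(f"malformed box line {lines[ln]!r}", line=ln + 1)
        try:
            box = np.array([float(x) for x in box_fields[:3]])
        except ValueError:
            raise GroParseError(f"malformed box line {lines[ln]!r}", line=ln + 1) from None
        ln += 1
        frames.append(
            SystemConfiguration(
                positions=pos,
                box=box,
                bead_types=atomnames,
                molecule_ids=resids,
                molecule_names=resnames,
                velocities=vel if has_vel else None,
                semi_isotropic=bool(np.isclose(box[0], box[1])),
                time=time,
            )
        )
    return frames


def write_gro(path, config: SystemConfiguration, append: bool = False, title: str | None = None):
    """Write one frame in fixed-column GRO format (3-decimal nm positions)."""
    mode = "a" if append else "w"
    n = config.n_beads
    molnames = config.molecule_names
    if molnames is None:
        molnames = np.full(n, "MOL", dtype=object)
    with open(path, mode) as fh:
        fh.write(f"{title or 'cgmem'} t= {config.time:.4f}\n")
        fh.write(f"{n:5d}\n")
        vel = config.velocities
        for i in range(n):
            resid = int(config.molecule_ids[i]) % 100000
            line = (
                f"{resid:5d}{str(molnames[i])[:5]:<5s}{str(config.bead_types[i])[:5]:>5s}"
                f"{(i + 1) % 100000:5d}"
                f"{config.positions[i, 0]:8.3f}{config.positions[i, 1]:8.3f}{config.positions[i, 2]:8.3f}"
            )
            if vel is not None:
                line += f"{vel[i, 0]:8.4f}{vel[i, 1]:8.4f}{vel[i, 2]:8.4f}"
            fh.write(line + "\n")
        fh.write(f"{config.box[0]:10.5f}{config.box[1]:10.5f}{config.box[2]:10.5f}\n")


def read_xyz(path) -> list[SystemConfiguration]:
    """Plain-XYZ fallback (no box in the format; a cubic 100 nm box is assumed)."""
    lines = Path(path).read_text().splitlines()
    frames = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        natoms = int(lines[ln].strip())
        names, xyz = [], []
        for i in range(natoms):
            parts = lines[ln + 2 + i].split()
            names.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        ln += 2 + natoms
        frames.append(
            SystemConfiguration(
                positions=np.array(xyz),
                box=np.array([100.0, 100.0, 100.0]),
                bead_types=np.array(names, dtype=object),
                periodic=False,
            )
        )
    return frames


def write_xyz(path, config: SystemConfiguration, append: bool = False):
    with open(path, "a" if append else "w") as fh:
        fh.write(f"{config.n_beads}\ncgmem t= {config.time:.4f}\n")
        for i in range(config.n_beads):
            x, y, z = config.positions[i]
            fh.write(f"{config.bead_types[i]} {x:.6f} {y:.6f} {z:.6f}\n")


def read_topology_tsv(path) -> list[tuple[str, int, str]]:
    """Sidecar bead-typing table: rows of (molecule, bead_index, bead_type)."""
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        want = ["molecule", "bead_index", "bead_type"]
        if sorted(header) != sorted(want):
            raise GroParseError(f"topology header {header} != {want}")
        col = {name: header.index(name) for name in want}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rows.append((parts[col["molecule"]], int(parts[col["bead_index"]]), parts[col["bead_type"]]))
    return rows


def write_topology_tsv(path, rows):
    with open(path, "w") as fh:
        fh.write("molecule\tbead_index\tbead_type\n")
        for mol, idx, bt in rows:
            fh.write(f"{mol}\t{idx}\t{bt}\n")
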
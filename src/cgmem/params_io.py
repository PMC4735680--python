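"""YAML serialization of :class:`~cgmem.forcefield.ParameterSet`.

Layout::

    globals: {dielectric: 16.0, cutoff: 1.5, temperature: 303.0}
    bead_types:
      - {name: W, mass: 54.0, charge: 0.0, role: water}
    pairs:
      - {a: W, b: W, epsilon: 0.8, sigma: 0.43, form: "12-4"}
    bonds:
      LIP:
        - {i: 0, j: 1, r0: 0.3, k: 1250.0}
    angles:
      LIP:
        - {i: 0, j: 1, k_idx: 2, theta0: 180.0, k: 25.0}
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .forcefield import BeadType, BondedTerm, MiePairParam, ParameterSet

__all__ = ["read_parameter_set", "write_parameter_set"]


def read_parameter_set(path) -> tuple[ParameterSet, dict]:
    """Load a parameter file; returns (params, globals dict)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: not a mapping")
    g = doc.get("globals", {})
    beads = [
        BeadType(b["name"], float(b["mass"]), float(b["charge"]), b["role"])
        for b in doc.get("bead_types", [])
    ]
    pairs = [
        MiePairParam(p["a"], p["b"], float(p["epsilon"]), float(p["sigma"]), str(p["form"]))
        for p in doc.get("pairs", [])
    ]
    bonded: dict[str, list[BondedTerm]] = {}
    for species, terms in (doc.get("bonds") or {}).items():
        bonded.setdefault(species, []).extend(
            BondedTerm("bond", (int(t["i"]), int(t["j"])), float(t["r0"]), float(t["k"]))
            for t in terms
        )
    for species, terms in (doc.get("angles") or {}).items():
        bonded.setdefault(species, []).extend(
            BondedTerm(
                "angle",
                (int(t["i"]), int(t["j"]), int(t["k_idx"])),
                math.radians(float(t["theta0"])),
                float(t["k"]),
            )
            for t in terms
        )
    params = ParameterSet(
        beads,
        pairs,
        bonded=bonded,
        dielectric=float(g.get("dielectric", 16.0)),
        cutoff=float(g.get("cutoff", 1.5)),
    )
    return params, g


def write_parameter_set(path, params: ParameterSet, extra_globals: dict | None = None):
    doc = {
        "globals": {"dielectric": params.dielectric, "cutoff": params.cutoff, **(extra_globals or {})},
        "bead_types": [
            {"name": b.name, "mass": b.mass, "charge": b.charge, "role": b.role}
            for b in sorted(params.bead_types.values(), key=lambda b: b.name)
        ],
        "pairs": [
            {"a": p.type_a, "b": p.type_b, "epsilon": p.epsilon, "sigma": p.sigma, "form": p.form}
            for _, p in sorted(params.pairs.items())
        ],
    }
    bonds, angles = {}, {}
    for species, terms in params.bonded.items():
        for t in terms:
            if t.kind == "bond":
                bonds.setdefault(species, []).append(
                    {"i": t.indices[0], "j": t.indices[1], "r0": t.value, "k": t.force_constant}
                )
            else:
                angles.setdefault(species, []).append(
                    {
                        "i": t.indices[0],
                        "j": t.indices[1],
                        "k_idx": t.indices[2],
                        "theta0": math.degrees(t.value),
                        "k": t.force_constant,
                    }
                )
    if bonds:
        doc["bonds"] = bonds
    if angles:
        doc["angles"] = angles
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
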
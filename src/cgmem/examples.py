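"""A documented example CG parameter set.

This is a schema-complete, physically plausible SDK-style parameter set for a
lipid bilayer in salt solution with an imidazolium-type cation, intended for
toy simulations and tests.  It is an *example*, not a claim of identity to
any published force-field file: absolute base values live in the cited model
families' own publications and the refined cross terms are exposed as
scaling knobs (see :func:`scaled_cross_parameters`).
"""

from __future__ import annotations

import math

from .forcefield import BeadType, MiePairParam, ParameterSet

__all__ = ["example_parameter_set", "scaled_cross_parameters", "DEFAULT_CROSS_PAIRS"]

# name, mass (amu), charge (e), role, self-sigma (nm), self-epsilon (kJ/mol)
_BEADS = [
    ("NC", 87.0, 1.0, "lipid-head", 0.60, 1.00),
    ("PH", 95.0, -1.0, "lipid-phosphate", 0.55, 1.20),
    ("GL", 41.0, 0.0, "lipid-glycerol", 0.50, 1.00),
    ("CT", 42.0, 0.0, "lipid-tail", 0.48, 1.40),
    ("W", 54.0, 0.0, "water", 0.43, 0.80),
    ("RI", 81.0, 1.0, "cation-ring", 0.50, 1.10),
    ("CA", 42.0, 0.0, "cation-tail", 0.48, 1.40),
    ("CL", 35.5, -1.0, "anion", 0.44, 0.60),
    ("NA", 23.0, 1.0, "sodium", 0.30, 0.50),
]

#: cross pairs whose epsilon the PMF-matching refinement scales by default
DEFAULT_CROSS_PAIRS = [("RI", "NC"), ("RI", "PH"), ("CA", "CT")]


def example_parameter_set(
    dielectric: float = 16.0,
    cutoff: float = 1.5,
    cross_scalings: dict[tuple[str, str], float] | None = None,
) -> ParameterSet:
    """Build the example parameter set with Lorentz-Berthelot combined pairs.

    ``cross_scalings`` maps unordered bead-name pairs to multiplicative
    epsilon factors (the refinement knob); unlisted pairs keep their combined
    value.
    """
    scale = {tuple(sorted(k)): v for k, v in (cross_scalings or {}).items()}
    beads = [BeadType(n, m, q, role) for n, m, q, role, _, _ in _BEADS]
    self_sig = {n: s for n, _, _, _, s, _ in _BEADS}
    self_eps = {n: e for n, _, _, _, _, e in _BEADS}
    roles = {n: r for n, _, _, r, _, _ in _BEADS}
    pairs = []
    names = [b[0] for b in _BEADS]
    for i, a in enumerate(names):
        for b in names[i:]:
            sig = 0.5 * (self_sig[a] + self_sig[b])
            eps = math.sqrt(self_eps[a] * self_eps[b])
            eps *= scale.get(tuple(sorted((a, b))), 1.0)
            form = "12-4" if "water" in (roles[a], roles[b]) else "9-6"
            pairs.append(MiePairParam(a, b, eps, sig, form))
    return ParameterSet(beads, pairs, dielectric=dielectric, cutoff=cutoff)


def scaled_cross_parameters(scalings, pairs=None) -> dict[tuple[str, str], float]:
    """Map a refinement vector onto the default refinable cross pairs."""
    pairs = pairs if pairs is not None else DEFAULT_CROSS_PAIRS
    if len(scalings) != len(pairs):
        raise ValueError(f"expected {len(pairs)} scalings, got {len(scalings)}")
    return {tuple(sorted(p)): float(s) for p, s in zip(pairs, scalings)}
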
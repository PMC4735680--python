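import numpy as np
import pytest

from cgmem.examples import example_parameter_set
from cgmem.forcefield import BeadType, MiePairParam, ParameterSet, SystemConfiguration


@pytest.fixture(scope="session")
def params():
    return example_parameter_set()


@pytest.fixture(scope="session")
def ideal_params():
    """Non-interacting single-species parameter set (ideal gas of 'tracer' beads)."""
    bt = BeadType("X", 42.0, 0.0, "lipid-tail")
    pair = MiePairParam("X", "X", 0.0, 0.4, "9-6")
    return ParameterSet([bt], [pair], dielectric=16.0, cutoff=1.5)


def make_config(positions, types, box=(10.0, 10.0, 10.0), **kw):
    positions = np.asarray(positions, float)
    return SystemConfiguration(
        positions=positions,
        box=np.asarray(box, float),
        bead_types=np.asarray(types, dtype=object),
        **kw,
    )


@pytest.fixture
def dimer_factory(params):
    """Two CT beads at a given separation along x, centred in a big box."""

    def build(r, type_a="CT", type_b="CT", box=12.0):
        half = box / 2
        return make_config(
            [[half - r / 2, half, half], [half + r / 2, half, half]],
            [type_a, type_b],
            box=(box, box, box),
        )

    return build


@pytest.fixture(scope="session")
def double_well_windows():
    """24 umbrella windows sampled from U(z) = 4 (z^2 - 1)^2, shared across tests."""
    from cgmem.synth import double_well, sample_umbrella_windows

    centers = np.linspace(-2, 2, 24)
    return sample_umbrella_windows(
        double_well, centers, spring_k=100.0, n_per_window=4000, temperature=303.0, seed=1
    )


@pytest.fixture(scope="session")
def helfrich_500():
    """500 exact Helfrich surfaces at the reference stiffness."""
    from cgmem.synth import HelfrichSpec, sample_helfrich_surfaces

    spec = HelfrichSpec(
        kappa=22.6e-20, temperature=303.0, box_edge=25.0, grid=32, n_frames=500, seed=13
    )
    return spec, sample_helfrich_surfaces(spec)
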
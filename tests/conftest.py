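"""Shared fixtures: toy parameter sets, small systems, gradient oracle."""

import numpy as np
import pytest

from lbmd.forcefield import (AngleTerm, BeadType, BondTerm, ParameterSet,
                             Topology)
from lbmd.forcefield.field import ForceField
from lbmd.state import ParticleState


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_params():
    ps = ParameterSet()
    ps.add_bead_type(BeadType("T", 72.0, 0.0, sigma=4.7, epsilon=0.5))
    ps.add_bead_type(BeadType("P", 72.0, -1.0, sigma=4.7, epsilon=0.5))
    ps.add_bead_type(BeadType("C", 72.0, +1.0, sigma=4.7, epsilon=0.5))
    return ps


@pytest.fixture
def dimer_topology():
    """Two bonded beads, one charged pair."""
    topo = Topology(["C", "P"], bonds=[BondTerm(0, 1, 4.7, 3.0)])
    topo.build_exclusions()
    return topo


@pytest.fixture
def triple_topology():
    topo = Topology(["T", "T", "T"],
                    bonds=[BondTerm(0, 1, 4.7, 3.0), BondTerm(1, 2, 4.7, 3.0)],
                    angles=[AngleTerm(0, 1, 2, 120.0, 6.0)])
    topo.build_exclusions()
    return topo


def numerical_gradient(energy_fn, positions, h=1e-5):
    """Central-difference −∇U oracle, independent of the force routines."""
    forces = np.zeros_like(positions)
    for i in range(len(positions)):
        for d in range(3):
            xp = positions.copy()
            xm = positions.copy()
            xp[i, d] += h
            xm[i, d] -= h
            forces[i, d] = -(energy_fn(xp) - energy_fn(xm)) / (2 * h)
    return forces


def assert_forces_match_gradient(topology, params, positions, box, rtol=1e-6):
    state = ParticleState(positions.copy(), np.asarray(box, dtype=float))
    ff = ForceField(topology, params)
    _, forces = ff.compute(state)

    def energy(x):
        st = ParticleState(x.copy(), np.asarray(box, dtype=float))
        return ForceField(topology, params).compute(st)[0]

    num = numerical_gradient(energy, positions)
    scale = max(np.max(np.abs(forces)), 1.0)
    np.testing.assert_allclose(forces, num, atol=rtol * scale)
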
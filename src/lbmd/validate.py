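"""Physics validation computations: sampling, thermostat, coupling, assembly.

Each function runs a small, fully seeded simulation with the package's
own machinery and returns the measured quantity so it can be compared
against the analytic expectation (Boltzmann densities, the Einstein
relation, equipartition, exact momentum closure).  The CLI and the
acceptance script call these; the test suite asserts on them at the
documented tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .coupling import CouplingParams, LBMDIntegrator
from .forcefield.bonded import (AngleTerm, BondTerm, angle_energy_forces,
                                bond_energy_forces)
from .forcefield.topology import Topology
from .lb import LatticeState, ShearSpec, apply_couette, equilibrium
from .rng import stream
from .state import ParticleState
from .units import KB, KCAL_MOL


class BondedOnlyForceField:
    """Bond + angle terms only — for sampling checks of the bonded wells."""

    def __init__(self, topology: Topology):
        self.topology = topology

        class _NullList:
            def invalidate(self):
                pass

        self.nlist = _NullList()

    def compute(self, state: ParticleState):
        eb, fb = bond_energy_forces(state, self.topology.bonds)
        ea, fa = angle_energy_forces(state, self.topology.angles)
        return eb + ea, fb + fa


def _l1_distance(centers, hist, oracle):
    dr = centers[1] - centers[0]
    return float(np.sum(np.abs(hist - oracle)) * dr)


def bond_sampling_l1(seed: int = 0, n_replicas: int = 192, steps: int = 40000,
                     kb: float = 3.0, r0: float = 4.7, temperature: float = 310.0,
                     gamma: float = 0.05, dt: float = 10.0,
                     burn_in: int = 4000, sample_every: int = 10
                     ) -> Tuple[float, Dict]:
    """L1 distance between the sampled bond-length density of a Langevin
    dimer ensemble and the Boltzmann density ∝ r² exp(−βU).

    The replicas are independent two-bead molecules with a single
    harmonic bond; their histogram is compared against a numerically
    integrated radial Boltzmann density.
    """
    rng = stream(seed, "bond_sampling")
    box = np.full(3, 1000.0)
    pos = np.zeros((2 * n_replicas, 3))
    centres = rng.uniform(100, 900, (n_replicas, 3))
    dirs = rng.standard_normal((n_replicas, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pos[0::2] = centres - 0.5 * r0 * dirs
    pos[1::2] = centres + 0.5 * r0 * dirs
    topo = Topology(["T"] * 2 * n_replicas,
                    bonds=[BondTerm(2 * k, 2 * k + 1, r0, kb)
                           for k in range(n_replicas)])
    topo.build_exclusions()
    state = ParticleState(pos, box)
    params = CouplingParams(gamma_default=gamma, temperature=temperature,
                            hydrodynamics=False)
    integ = LBMDIntegrator(state, BondedOnlyForceField(topo), params, dt=dt,
                           rng=rng)
    samples = []
    for k in range(steps):
        integ.step()
        if k >= burn_in and (k - burn_in) % sample_every == 0:
            d = state.minimum_image(state.positions[0::2] - state.positions[1::2])
            samples.append(np.linalg.norm(d, axis=1))
    r = np.concatenate(samples)
    beta = 1.0 / (KB * temperature)
    edges = np.arange(max(r0 - 3.0, 0.05), r0 + 3.0, 0.08)
    hist, _ = np.histogram(r, bins=edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    dens = centers**2 * np.exp(-beta * 0.5 * kb * (centers - r0) ** 2)
    dens /= np.trapezoid(dens, centers)
    return _l1_distance(centers, hist, dens), {"n_samples": len(r)}


def angle_sampling_l1(seed: int = 0, n_replicas: int = 192, steps: int = 40000,
                      ktheta: float = 6.0, theta0: float = 120.0,
                      kb: float = 3.0, r0: float = 4.7,
                      temperature: float = 310.0, gamma: float = 0.05,
                      dt: float = 10.0, burn_in: int = 4000,
                      sample_every: int = 10) -> Tuple[float, Dict]:
    """Same check for a three-bead angle: sampled θ density vs
    sin θ · exp(−βU_θ) (the exact marginal for decoupled internal
    coordinates)."""
    rng = stream(seed, "angle_sampling")
    box = np.full(3, 2000.0)
    pos = np.zeros((3 * n_replicas, 3))
    th = np.radians(theta0)
    template = np.array([[r0, 0, 0], [0, 0, 0],
                         [r0 * np.cos(th), r0 * np.sin(th), 0]])
    centres = rng.uniform(200, 1800, (n_replicas, 3))
    for k in range(n_replicas):
        pos[3 * k:3 * k + 3] = template + centres[k]
    bonds, angles = [], []
    for k in range(n_replicas):
        b = 3 * k
        bonds += [BondTerm(b, b + 1, r0, kb), BondTerm(b + 1, b + 2, r0, kb)]
        angles.append(AngleTerm(b, b + 1, b + 2, theta0, ktheta))
    topo = Topology(["T"] * 3 * n_replicas, bonds, angles)
    topo.build_exclusions()
    state = ParticleState(pos, box)
    params = CouplingParams(gamma_default=gamma, temperature=temperature,
                            hydrodynamics=False)
    integ = LBMDIntegrator(state, BondedOnlyForceField(topo), params, dt=dt,
                           rng=rng)
    samples = []
    for k in range(steps):
        integ.step()
        if k >= burn_in and (k - burn_in) % sample_every == 0:
            a = state.minimum_image(state.positions[0::3] - state.positions[1::3])
            b = state.minimum_image(state.positions[2::3] - state.positions[1::3])
            cos = np.sum(a * b, axis=1) / (np.linalg.norm(a, axis=1)
                                           * np.linalg.norm(b, axis=1))
            samples.append(np.degrees(np.arccos(np.clip(cos, -1, 1))))
    theta = np.concatenate(samples)
    beta = 1.0 / (KB * temperature)
    edges = np.arange(0.0, 180.0, 2.0)
    hist, _ = np.histogram(theta, bins=edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    crad = np.radians(centers)
    u = 0.5 * ktheta * (np.cos(crad) - np.cos(th)) ** 2
    dens = np.sin(crad) * np.exp(-beta * u)
    dens /= np.trapezoid(dens, centers)
    return _l1_distance(centers, hist, dens), {"n_samples": len(theta)}


def nve_energy_drift(steps: int = 100000, dt: float = 1.0) -> float:
    """Relative total-energy drift of an isolated bonded dimer under NVE."""
    topo = Topology(["T", "T"], bonds=[BondTerm(0, 1, 4.7, 3.0)])
    topo.build_exclusions()
    state = ParticleState(np.array([[50.0, 50, 50], [55.2, 50, 50]]),
                          np.full(3, 100.0))
    ff = BondedOnlyForceField(topo)
    params = CouplingParams(hydrodynamics=False, thermostat=False,
                            temperature=310.0)
    integ = LBMDIntegrator(state, ff, params, dt=dt)

    def total_energy():
        e, _ = ff.compute(state)
        ke = 0.5 * np.sum(state.masses * np.sum(state.velocities**2, axis=1))
        return e * KCAL_MOL + ke  # amu Å²/fs²

    e0 = total_energy()
    drift = 0.0
    for k in range(steps):
        integ.step()
        if k % 1000 == 999:
            drift = max(drift, abs(total_energy() - e0))
    return drift / abs(e0)


def equipartition_temperature(seed: int = 0, n: int = 1000,
                              steps: int = 4000, burn_in: int = 2000,
                              gamma: float = 0.002,
                              temperature: float = 310.0) -> float:
    """Time-averaged kinetic temperature of a free Langevin ensemble."""
    state = ParticleState(np.full((n, 3), 50.0), np.full(3, 100.0))
    params = CouplingParams(gamma_default=gamma, temperature=temperature,
                            hydrodynamics=False)
    integ = LBMDIntegrator(state, None, params, rng=stream(seed, "equipartition"))
    ts = []
    for k in range(steps):
        integ.step()
        if k >= burn_in:
            ts.append(integ.kinetic_temperature())
    return float(np.mean(ts))


def einstein_diffusion_ratio(seed: int = 0, n: int = 2000, steps: int = 8000,
                             burn_in: int = 2000, gamma: float = 0.002,
                             temperature: float = 310.0) -> float:
    """Measured ensemble diffusion over the Einstein value k_BT/(mγ)."""
    state = ParticleState(np.full((n, 3), 50.0), np.full(3, 100.0))
    params = CouplingParams(gamma_default=gamma, temperature=temperature,
                            hydrodynamics=False)
    integ = LBMDIntegrator(state, None, params, rng=stream(seed, "einstein"))
    for _ in range(burn_in):
        integ.step()
    x0 = state.unwrapped_positions.copy()
    for _ in range(steps):
        integ.step()
    msd = np.mean(np.sum((state.unwrapped_positions - x0) ** 2, axis=1))
    d_meas = msd / (6.0 * steps * integ.dt)
    d_e = KB * temperature * KCAL_MOL / (72.0 * gamma)
    return float(d_meas / d_e)


def velocity_decay_ratio(gamma: float = 1e-3, steps: int = 100) -> float:
    """v(t)/v(0) of a single particle at T = 0 over exp(−γt)."""
    state = ParticleState(np.array([[50.0, 50, 50]]), np.full(3, 100.0),
                          velocities=np.array([[0.01, 0.0, 0.0]]))
    params = CouplingParams(gamma_default=gamma, temperature=0.0,
                            hydrodynamics=False)
    integ = LBMDIntegrator(state, None, params)
    for _ in range(steps):
        integ.step()
    return float(state.velocities[0, 0] / 0.01
                 / np.exp(-gamma * steps * integ.dt))


def momentum_closure_residual(seed: int = 0, steps: int = 200,
                              n: int = 20) -> float:
    """Relative particle+fluid momentum drift with back-reaction on."""
    rng = stream(seed, "closure")
    lattice = LatticeState((10, 10, 10), tau=0.85)
    state = ParticleState(rng.uniform(0, 30, (n, 3)), np.full(3, 30.0),
                          velocities=1e-3 * rng.standard_normal((n, 3)))
    params = CouplingParams(gamma_default=0.01, temperature=310.0,
                            hydrodynamics=True, back_reaction=True)
    integ = LBMDIntegrator(state, None, params, lattice=lattice, rng=rng)
    p0 = integ.total_momentum()
    for _ in range(steps):
        integ.step()
    scale = float(np.sum(np.abs(state.masses[:, None] * state.velocities)))
    return float(np.abs(integ.total_momentum() - p0).max() / scale)


# ----------------------------------------------------------------------
# scaled-down self-assembly
# ----------------------------------------------------------------------
@dataclass
class AggregationResult:
    largest_cluster_fraction: float
    n_clusters: int
    segregation: float
    kinetic_temperature: float
    initial_largest_cluster_fraction: float = float("nan")
    initial_segregation: float = float("nan")


def cluster_lipids(state: ParticleState, contact: float = 6.0) -> np.ndarray:
    """Label lipids into clusters: molecules sharing any bead pair
    within ``contact`` Å are connected."""
    pos = np.mod(state.positions, state.box)
    tree = cKDTree(pos, boxsize=state.box)
    pairs = tree.query_pairs(contact, output_type="ndarray")
    mols = state.mol_index
    n_mol = int(mols.max()) + 1
    if len(pairs):
        mi, mj = mols[pairs[:, 0]], mols[pairs[:, 1]]
        adj = coo_matrix((np.ones(len(mi)), (mi, mj)), shape=(n_mol, n_mol))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n_mol)
    return labels


def amphiphilic_segregation(state: ParticleState, contact: float = 6.0) -> float:
    """Head/tail segregation order parameter of inter-lipid contacts.

    1 − (observed head–tail contact fraction) / (the 2·f_h·f_t fraction
    a randomly mixed system of the same composition would show).
    Zero for a random gas, positive once tails bury together under the
    hydrophobic driving force (bilayer-like ordering).
    """
    pos = np.mod(state.positions, state.box)
    tree = cKDTree(pos, boxsize=state.box)
    pairs = tree.query_pairs(contact, output_type="ndarray")
    inter = state.mol_index[pairs[:, 0]] != state.mol_index[pairs[:, 1]]
    pairs = pairs[inter]
    if len(pairs) == 0:
        return 0.0
    is_tail = state.species == "tail"
    t0, t1 = is_tail[pairs[:, 0]], is_tail[pairs[:, 1]]
    observed_ht = np.mean(t0 != t1)
    f_t = float(np.mean(is_tail))
    expected_ht = 2.0 * f_t * (1.0 - f_t)
    return float(1.0 - observed_ht / expected_ht)


def aggregation_run(seed: int = 0, n_lipids: int = 32, box: float = 62.0,
                    steps: int = 60000, hydrodynamics: bool = False,
                    gamma: float = 2.5e-5, n_md_per_lb: int = 10,
                    temperature: float = 310.0) -> AggregationResult:
    """Scaled-down lipid self-assembly smoke run.

    Lipids start as a seeded random gas and are evolved with the toy
    amphiphilic parameter set; the run reports how much of the system
    ends up in the largest cluster and the tail-contact enrichment.
    The friction is reduced below the production lipid value so the
    Brownian coalescence completes within a short trajectory.
    """
    from .builders import build_random_gas, default_lipid_parameters
    from .forcefield.field import ForceField
    from .minimize import steepest_descent

    state, topo = build_random_gas(n_lipids, box, seed=seed)
    init_labels = cluster_lipids(state)
    init_frac = float(np.bincount(init_labels).max() / n_lipids)
    init_seg = amphiphilic_segregation(state)
    ff = ForceField(topo, default_lipid_parameters())
    steepest_descent(state, ff, steps=200)
    lattice = None
    if hydrodynamics:
        lattice = LatticeState.for_box(state.box)
    params = CouplingParams(gamma_default=gamma, temperature=temperature,
                            hydrodynamics=hydrodynamics)
    integ = LBMDIntegrator(state, ff, params, lattice=lattice,
                           n_md_per_lb=n_md_per_lb,
                           rng=stream(seed, "aggregation"))
    for _ in range(steps):
        integ.step()
    labels = cluster_lipids(state)
    counts = np.bincount(labels)
    return AggregationResult(
        largest_cluster_fraction=float(counts.max() / counts.sum()),
        n_clusters=int(len(counts)),
        segregation=amphiphilic_segregation(state),
        kinetic_temperature=integ.kinetic_temperature(),
        initial_largest_cluster_fraction=init_frac,
        initial_segregation=init_seg,
    )


def validate_lb(seed: int = 0) -> Dict[str, float]:
    """Analytic fluid test suite: viscosity, Couette, conservation.

    Returns relative errors/drifts; all should be tiny (the CLI
    ``validate-lb`` command prints them).
    """
    out: Dict[str, float] = {}
    # shear-wave decay viscosity
    st = LatticeState((4, 4, 32), tau=0.9)
    nz = 32
    z = np.arange(nz)
    u = np.zeros((4, 4, nz, 3))
    u[..., 0] = 0.01 * np.sin(2 * np.pi * z / nz)
    st.f = equilibrium(np.ones((4, 4, nz)), u)
    amps = []
    for _ in range(400):
        st.collide_stream()
        _, uu = st.macroscopic()
        amps.append(2 * np.mean(uu[..., 0] * np.sin(2 * np.pi * z / nz)))
    k = 2 * np.pi / nz
    rate = np.polyfit(np.arange(1, 401), np.log(amps), 1)[0]
    out["viscosity_rel_err"] = abs(-rate / k**2 / st.nu_lattice - 1.0)
    # Couette profile
    st = LatticeState((4, 4, 24), tau=0.9)
    target = 0.004 / 24 / st.dt  # wall speed 0.048 lattice... per-fs rate
    spec = ShearSpec(shear_rate=target)
    apply_couette(st, spec)
    _, uu = st.macroscopic()
    prof = uu[..., 0].mean(axis=(0, 1))
    slope = np.polyfit(np.arange(24), prof, 1)[0]
    out["couette_slope_rel_err"] = abs(slope / (target * st.dt) - 1.0)
    # conservation
    st = LatticeState((8, 8, 8), tau=0.8)
    rng = stream(seed, "validate_lb")
    st.f += 5e-4 * rng.standard_normal(st.f.shape)
    m0, p0 = st.mass(), st.momentum()
    st.run(10000)
    out["mass_drift_rel"] = abs(st.mass() - m0) / m0
    out["momentum_drift_per_mass"] = float(np.abs(st.momentum() - p0).max() / m0)
    return out
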
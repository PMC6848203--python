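"""Force-field evaluation engine: neighbour search and total forces.

Pair enumeration uses a periodic k-d tree with a Verlet skin: the pair
list is built out to cutoff + skin and reused until any bead has moved
more than half the skin, which reproduces the classic cell-list
contract at the same O(N) cost.  Every result is checked (in tests)
against a brute-force all-pairs evaluation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..state import ParticleState
from ..units import COULOMB
from .bonded import _angle_arrays, _bond_arrays, angle_energy_forces, bond_energy_forces
from .nonbonded import _shift_coeffs
from .params import ParameterSet
from .topology import Topology


class NeighborList:
    """Verlet pair list from a periodic k-d tree.

    Rebuilds lazily when the accumulated displacement of any bead
    exceeds half the skin.  For z-walled boxes the tree still treats z
    as periodic; spuriously wrapped pairs are filtered by their true
    wall-aware distance.
    """

    def __init__(self, cutoff: float, skin: float = 1.0):
        self.cutoff = cutoff
        self.skin = skin
        self._pairs = None
        self._ref_positions = None

    def _build(self, state: ParticleState) -> None:
        reach = self.cutoff + self.skin
        if np.any(state.box < 2.0 * reach):
            raise ValueError(
                f"box {state.box} too small for cutoff+skin {reach:.1f} Å "
                "(each periodic edge must be at least twice that)"
            )
        pos = state.positions - state.box * np.floor(state.positions / state.box)
        pos = np.minimum(pos, np.nextafter(state.box, 0.0))
        tree = cKDTree(pos, boxsize=state.box)
        pairs = tree.query_pairs(reach, output_type="ndarray")
        if state.z_walled and len(pairs):
            dr = state.minimum_image(state.positions[pairs[:, 0]] - state.positions[pairs[:, 1]])
            keep = np.einsum("ij,ij->i", dr, dr) <= reach**2
            pairs = pairs[keep]
        self._pairs = pairs
        self._ref_positions = state.positions.copy()

    def pairs(self, state: ParticleState) -> np.ndarray:
        if self._pairs is None:
            self._build(state)
        else:
            disp = state.minimum_image(state.positions - self._ref_positions)
            if np.max(np.einsum("ij,ij->i", disp, disp)) > (0.5 * self.skin) ** 2:
                self._build(state)
        return self._pairs

    def invalidate(self) -> None:
        self._pairs = None


def _pair_tables(params: ParameterSet, type_names):
    """Per-type-pair coefficient matrices (C12, C6, Coulomb scale)."""
    types = sorted(set(type_names))
    index = {t: k for k, t in enumerate(types)}
    T = len(types)
    c12 = np.zeros((T, T))
    c6 = np.zeros((T, T))
    qs = np.zeros((T, T))
    for a in types:
        for b in types:
            sigma, eps = params.pair_lj(a, b)
            c12[index[a], index[b]] = 4.0 * eps * sigma**12
            if ParameterSet._key(a, b) not in params.repulsive_pairs:
                c6[index[a], index[b]] = 4.0 * eps * sigma**6
            qs[index[a], index[b]] = (
                COULOMB * params.pair_charge_product(a, b) / params.dielectric
            )
    tindex = np.array([index[t] for t in type_names], dtype=int)
    return tindex, c12, c6, qs


class ForceField:
    """Total potential energy and forces for a topology + parameter set."""

    def __init__(self, topology: Topology, params: ParameterSet, skin: float = 1.0):
        topology.validate()
        self.topology = topology
        self.params = params
        self.cutoff = params.cutoff
        self.nlist = NeighborList(params.cutoff, skin)
        self._bond_arrays = _bond_arrays(topology.bonds) if topology.bonds else None
        self._angle_arrays = _angle_arrays(topology.angles) if topology.angles else None
        self._tindex, self._c12, self._c6, self._qs = _pair_tables(
            params, topology.type_names
        )
        n = topology.n
        self._excl_keys = np.sort(
            np.array([i * n + j for (i, j) in topology.exclusions], dtype=np.int64)
        )
        # shift-polynomial coefficients, precomputed per power
        self._coeffs = {a: _shift_coeffs(a, self.cutoff) for a in (12.0, 6.0, 1.0)}
        self._raw_pairs = None
        self._filtered_pairs = None

    def _filter_exclusions(self, pairs: np.ndarray) -> np.ndarray:
        if len(self._excl_keys) == 0 or len(pairs) == 0:
            return pairs
        lo = np.minimum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        hi = np.maximum(pairs[:, 0], pairs[:, 1]).astype(np.int64)
        keys = lo * self.topology.n + hi
        pos = np.searchsorted(self._excl_keys, keys)
        pos = np.minimum(pos, len(self._excl_keys) - 1)
        return pairs[self._excl_keys[pos] != keys]

    def _phi(self, r, alpha):
        A, B, C = self._coeffs[alpha]
        U = r ** (-alpha) - (A / 3.0) * r**3 - (B / 4.0) * r**4 + C
        F = alpha * r ** (-(alpha + 1)) + A * r**2 + B * r**3
        return U, F

    def nonbonded(self, state: ParticleState, pairs: np.ndarray = None):
        """Nonbonded energy and forces over a pair list (default: neighbour list)."""
        if pairs is None:
            raw = self.nlist.pairs(state)
            if raw is not self._raw_pairs:  # re-filter only after a rebuild
                self._raw_pairs = raw
                self._filtered_pairs = self._filter_exclusions(raw)
            pairs = self._filtered_pairs
        forces = np.zeros_like(state.positions)
        if len(pairs) == 0:
            return 0.0, forces
        dr = state.minimum_image(state.positions[pairs[:, 0]] - state.positions[pairs[:, 1]])
        r2 = np.einsum("ij,ij->i", dr, dr)
        mask = r2 < self.cutoff**2
        if not np.any(mask):
            return 0.0, forces
        pairs = pairs[mask]
        dr = dr[mask]
        r = np.sqrt(r2[mask])
        if np.any(r == 0.0):
            bad = int(np.argmin(r))
            raise ValueError(f"overlapping beads ({pairs[bad, 0]}, {pairs[bad, 1]})")
        ti = self._tindex[pairs[:, 0]]
        tj = self._tindex[pairs[:, 1]]
        c12 = self._c12[ti, tj]
        c6 = self._c6[ti, tj]
        qs = self._qs[ti, tj]
        U12, F12 = self._phi(r, 12.0)
        U6, F6 = self._phi(r, 6.0)
        U = c12 * U12 - c6 * U6
        F = c12 * F12 - c6 * F6
        charged = qs != 0.0
        if np.any(charged):
            U1, F1 = self._phi(r[charged], 1.0)
            U[charged] += qs[charged] * U1
            F[charged] += qs[charged] * F1
        fvec = (F / r)[:, None] * dr
        n = state.n
        for d in range(3):
            forces[:, d] += np.bincount(pairs[:, 0], weights=fvec[:, d],
                                        minlength=n)
            forces[:, d] -= np.bincount(pairs[:, 1], weights=fvec[:, d],
                                        minlength=n)
        return float(np.sum(U)), forces

    def all_pairs(self, state: ParticleState):
        """Brute-force O(N²) nonbonded evaluation (reference oracle)."""
        n = state.n
        ii, jj = np.triu_indices(n, k=1)
        pairs = self._filter_exclusions(np.column_stack([ii, jj]))
        return self.nonbonded(state, pairs)

    def compute(self, state: ParticleState, breakdown: bool = False):
        """Total energy (kcal/mol) and forces (kcal mol⁻¹ Å⁻¹)."""
        eb, fb = bond_energy_forces(state, self.topology.bonds, self._bond_arrays)
        ea, fa = angle_energy_forces(state, self.topology.angles, self._angle_arrays)
        en, fn = self.nonbonded(state)
        if breakdown:
            return (
                eb + ea + en,
                fb + fa + fn,
                {"bond": eb, "angle": ea, "nonbonded": en},
            )
        return eb + ea + en, fb + fa + fn


def nonbonded_energy_forces(state: ParticleState, topology: Topology,
                            params: ParameterSet, pairs: np.ndarray = None):
    """One-shot nonbonded evaluation (thin wrapper over :class:`ForceField`)."""
    ff = ForceField(topology, params)
    return ff.nonbonded(state, pairs)
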
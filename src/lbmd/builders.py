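"""Deterministic, seeded constructors for every system class.

Planar bilayers at a prescribed area per lipid (69.4 Å² by default),
random lipid gases for self-assembly runs, two-leaflet spherical
vesicles on Fibonacci lattices, rigid bead nanotubes, and vesicles
packed with peptide/protein cargo.  All builders are pure functions of
their arguments plus a seed, and every built system is clash-free by
construction (checked by the force field's finite-energy contract).

The shipped lipid is a 12-bead POPC-like template: one choline (+1)
and one phosphate (−1) head bead, two glycerol linkers, and two
4-bead apolar tails, ~4 heavy atoms per bead.  The template geometry
puts the phosphate plane 19 Å from the bilayer mid-plane, giving the
38 Å phosphate–phosphate thickness of a relaxed membrane.  Real
topology files read through the ITP parser override it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .forcefield.bonded import AngleTerm, BondTerm
from .forcefield.params import BeadType, ParameterSet
from .forcefield.topology import Topology
from .protein import CGBead, ENModel, build_elastic_network
from .rng import stream
from .state import ParticleState

DEFAULT_APL = 69.4  # Å² per lipid
BILAYER_THICKNESS = 38.0  # Å, phosphate plane to phosphate plane
MIN_SEPARATION = 3.0  # Å, clash-free contract for random placement


@dataclass
class LipidTemplate:
    """Internal coordinates of one lipid, head-to-tail along +z."""

    coords: np.ndarray
    names: List[str]
    types: List[str]
    classes: List[str]  # choline | phosphate | glycerol | tail
    bonds: List[Tuple[int, int]]
    angle_triples: List[Tuple[int, int, int]]
    kb: float = 3.0  # kcal/(mol Å²)
    ktheta: float = 6.0  # kcal/mol
    #: beads pushed outward along the template axis on curved surfaces
    #: (second tail chain; avoids tail-end crowding in vesicles)
    stagger_beads: Tuple[int, ...] = ()
    stagger_dz: float = 1.5

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        # head above glycerol above tails along the template axis
        z = self.coords[:, 2]
        cls = np.array(self.classes)
        assert z[cls == "choline"].min() > z[cls == "glycerol"].max()
        assert z[cls == "glycerol"].min() > z[cls == "tail"].max()

    @property
    def n(self) -> int:
        return len(self.coords)


def lipid_template() -> LipidTemplate:
    """The default 12-bead POPC-like template."""
    names = ["NC3", "PO4", "GL1", "GL2",
             "C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"]
    types = ["Q0", "Qa", "Na", "Na", "C1", "C1", "C1", "C1", "C1", "C1", "C1", "C1"]
    classes = ["choline", "phosphate", "glycerol", "glycerol"] + ["tail"] * 8
    za = [11.875, 8.55, 5.225, 1.9]
    ya = [0.88, -0.88, 0.88, -0.88]
    coords = [
        [0.0, 0.0, 23.8], [0.0, 0.0, 19.0],
        [-1.9, -0.88, 15.2], [1.9, -0.88, 15.2],
    ]
    coords += [[-1.9, ya[k], za[k]] for k in range(4)]
    coords += [[1.9, ya[k], za[k]] for k in range(4)]
    bonds = [(0, 1), (1, 2), (2, 3), (2, 4), (5, 4), (5, 6), (7, 6),
             (3, 8), (9, 8), (9, 10), (11, 10)]
    angles = [(0, 1, 2), (1, 2, 4), (2, 4, 5), (4, 5, 6), (5, 6, 7),
              (1, 3, 8), (3, 8, 9), (8, 9, 10), (9, 10, 11)]
    return LipidTemplate(coords, names, types, classes, bonds, angles,
                         stagger_beads=(8, 9, 10, 11))


def default_lipid_parameters() -> ParameterSet:
    """Toy amphiphilic parameter set for the template's four bead types.

    Apolar tails attract strongly, head groups moderately, and
    head–tail cross interactions weakly — the hydrophobic effect of
    the implicit solvent folded into the well depths.  Head charges ±1
    interact through the screened Coulomb term (ε_r = 15, r_c = 12 Å).
    """
    ps = ParameterSet()
    ps.add_bead_type(BeadType("Q0", 72.0, +1.0, radius=2.35, sigma=4.7, epsilon=0.5))
    ps.add_bead_type(BeadType("Qa", 72.0, -1.0, radius=2.35, sigma=4.7, epsilon=0.5))
    ps.add_bead_type(BeadType("Na", 72.0, 0.0, radius=2.35, sigma=4.7, epsilon=0.6))
    ps.add_bead_type(BeadType("C1", 72.0, 0.0, radius=2.35, sigma=4.7, epsilon=1.2))
    for head in ("Q0", "Qa", "Na"):
        ps.set_lj(head, "C1", 4.7, 0.25)
    return ps


def lipid_topology(template: LipidTemplate = None) -> Topology:
    """Single-lipid topology with zero-strain bonded reference values."""
    t = template or lipid_template()
    bonds = [BondTerm(i, j, float(np.linalg.norm(t.coords[i] - t.coords[j])), t.kb)
             for i, j in t.bonds]
    angles = []
    for (i, j, k) in t.angle_triples:
        a = t.coords[i] - t.coords[j]
        b = t.coords[k] - t.coords[j]
        th = np.degrees(np.arccos(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))))
        angles.append(AngleTerm(i, j, k, float(th), t.ktheta))
    topo = Topology(list(t.types), bonds, angles, molecule_name="POPC")
    topo.build_exclusions()
    return topo


def _min_distance_ok(tree_pos, box, new_pos, cutoff=MIN_SEPARATION) -> bool:
    if len(tree_pos) == 0:
        return True
    tree = cKDTree(np.mod(tree_pos, box), boxsize=box)
    d, _ = tree.query(np.mod(new_pos, box), k=1)
    return np.min(d) > cutoff


def build_bilayer(lx: float, ly: float, lz: float,
                  area_per_lipid: float = DEFAULT_APL,
                  template: LipidTemplate = None,
                  seed: int = 0) -> Tuple[ParticleState, Topology]:
    """Planar two-leaflet bilayer normal to z, centred at box mid-height.

    Lipids per leaflet = round(Lx·Ly / area_per_lipid), placed on a
    near-square jittered lattice; the realized area per lipid is
    within 2 % of the request by construction.
    """
    t = template or lipid_template()
    n_leaflet = int(round(lx * ly / area_per_lipid))
    if n_leaflet < 2:
        raise ValueError("box too small: fewer than 2 lipids per leaflet")
    nx = max(1, int(round(np.sqrt(n_leaflet * lx / ly))))
    ny = int(np.ceil(n_leaflet / nx))
    if nx * ny < n_leaflet:
        raise ValueError("cannot pack the requested lipid count")
    rng = stream(seed, "build_bilayer")
    midz = lz / 2.0
    coords = []
    for leaflet in (+1, -1):
        cells = [(ix, iy) for ix in range(nx) for iy in range(ny)]
        sel = rng.permutation(len(cells))[:n_leaflet]
        for s in sel:
            ix, iy = cells[s]
            cx = (ix + 0.5) * lx / nx + rng.uniform(-0.15, 0.15)
            cy = (iy + 0.5) * ly / ny + rng.uniform(-0.15, 0.15)
            ang = rng.uniform(0, 2 * np.pi)
            rot = Rotation.from_euler("z", ang).as_matrix()
            local = t.coords @ rot.T
            local[:, 2] *= leaflet
            coords.append(local + [cx, cy, midz])
    positions = np.concatenate(coords)
    topo = lipid_topology(t).replicate(2 * n_leaflet)
    state = ParticleState(positions, np.array([lx, ly, lz]),
                          species=np.array(t.classes * 2 * n_leaflet),
                          mol_index=topo.mol_index)
    state.wrap()
    return state, topo


def build_random_gas(n_lipids: int, box_l: float, seed: int = 0,
                     template: LipidTemplate = None,
                     max_tries: int = 4000) -> Tuple[ParticleState, Topology]:
    """Whole lipids at seeded random positions/orientations, clash-free
    (all interbead distances above 3 Å)."""
    t = template or lipid_template()
    rng = stream(seed, "build_random_gas")
    placed = np.empty((0, 3))
    box = np.array([box_l] * 3)
    for mol in range(n_lipids):
        for attempt in range(max_tries):
            rot = Rotation.random(rng=rng).as_matrix()
            centre = rng.uniform(0, box_l, 3)
            cand = (t.coords - t.coords.mean(axis=0)) @ rot.T + centre
            if _min_distance_ok(placed, box, cand):
                placed = np.vstack([placed, cand])
                break
        else:
            raise RuntimeError(
                f"random gas placement failed for lipid {mol + 1}/{n_lipids}; "
                "box too crowded")
    topo = lipid_topology(t).replicate(n_lipids)
    state = ParticleState(placed, box,
                          species=np.array(t.classes * n_lipids),
                          mol_index=topo.mol_index)
    state.wrap()
    return state, topo


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * k / n)
    theta = np.pi * (1 + 5**0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


def _rot_z_to(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking ẑ to unit vector v."""
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(z, v)
    return Rotation.from_rotvec(axis / np.linalg.norm(axis) * np.arccos(c)).as_matrix()


def build_vesicle(radius: float, box_l: float,
                  area_per_lipid: float = DEFAULT_APL,
                  template: LipidTemplate = None,
                  seed: int = 0) -> Tuple[ParticleState, Topology]:
    """Two-leaflet spherical vesicle centred in the box.

    ``radius`` runs from the vesicle centre to the centre of the
    bilayer.  The total lipid count is the midplane area over the area
    per lipid (both leaflets); the outer/inner split follows the
    leaflet sphere areas at radius ± half thickness.  Lipids sit on
    Fibonacci-sphere lattices, tails pointing to the midplane.
    """
    t = template or lipid_template()
    half = BILAYER_THICKNESS / 2.0
    if radius <= half + 2.0:
        raise ValueError(f"vesicle radius {radius} Å too small for a "
                         f"{BILAYER_THICKNESS} Å bilayer")
    head_extent = t.coords[:, 2].max()
    if box_l < 2 * (radius + head_extent + 24.0):
        raise ValueError("box does not accommodate vesicle + cutoff clearance")
    n_total = int(round(2 * 4 * np.pi * radius**2 / area_per_lipid))
    a_out = (radius + half) ** 2
    a_in = (radius - half) ** 2
    n_out = int(round(n_total * a_out / (a_out + a_in)))
    n_in = n_total - n_out
    centre = np.full(3, box_l / 2.0)
    coords = []
    for (n_leaf, sign) in ((n_out, +1), (n_in, -1)):
        ref = radius + sign * half  # leaflet phosphate-plane radius
        for v in _fibonacci_sphere(n_leaf):
            rot = _rot_z_to(sign * v)
            local = t.coords.copy()
            if t.stagger_beads:
                local[list(t.stagger_beads), 2] += t.stagger_dz
            # wedge packing: lateral extent shrinks/grows with radial depth
            r_bead = radius + sign * local[:, 2]
            local[:, :2] *= (r_bead / ref)[:, None]
            coords.append(local @ rot.T + centre + radius * v)
    positions = np.concatenate(coords)
    topo = lipid_topology(t).replicate(n_out + n_in)
    state = ParticleState(positions, np.full(3, box_l),
                          species=np.array(t.classes * (n_out + n_in)),
                          mol_index=topo.mol_index)
    state.wrap()
    return state, topo


def build_nanotube(n_rings: int = 11, beads_per_ring: int = 11,
                   diameter: float = 15.0, length: float = 43.1,
                   centre=None, axis=np.array([0.0, 0.0, 1.0]),
                   box=None) -> Tuple[ParticleState, Topology]:
    """Rigid bead nanotube: stacked rings, hydrophilic distal rings,
    hydrophobic inner rings, EN springs among all beads within 8 Å."""
    r = diameter / 2.0
    spacing = length / (n_rings - 1)
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    rot = _rot_z_to(axis)
    coords, types = [], []
    for ring in range(n_rings):
        z = ring * spacing - length / 2.0
        offset = np.pi / beads_per_ring * (ring % 2)  # stagger alternate rings
        polar = ring in (0, n_rings - 1)
        for b in range(beads_per_ring):
            th = 2 * np.pi * b / beads_per_ring + offset
            coords.append([r * np.cos(th), r * np.sin(th), z])
            types.append("NTP" if polar else "NTC")
    coords = np.asarray(coords) @ rot.T
    if centre is not None:
        coords = coords + np.asarray(centre, dtype=float)
    beads = [CGBead("NT", tt, k, c, 36.0) for k, (tt, c) in enumerate(zip(types, coords))]
    en = build_elastic_network(beads, cutoff=8.0, k=5.0)
    topo = Topology(types, bonds=list(en.springs), molecule_name="NTUBE")
    topo.build_exclusions(exclude_13=False)
    state = ParticleState(coords.copy(),
                          np.full(3, 4 * (length + diameter)) if box is None
                          else np.asarray(box, dtype=float),
                          species=np.array(["nanotube"] * len(coords)),
                          mol_index=np.zeros(len(coords), dtype=int),
                          masses=np.full(len(coords), 36.0))
    return state, topo


def pack_interior(vesicle_state: ParticleState, vesicle_topology: Topology,
                  payloads: Sequence[ENModel], seed: int = 0,
                  margin: float = 6.0, max_tries: int = 5000
                  ) -> Tuple[ParticleState, Topology]:
    """Seeded rejection-sampling packing of cargo into the vesicle lumen.

    Every payload centre lands inside (inner leaflet radius − payload
    radius − margin); no bead comes within 3 Å of the membrane or of
    other cargo.  Raises if the payload volume exceeds ~30 % of the
    lumen or placement fails.
    """
    box = vesicle_state.box
    centre = box / 2.0
    radial = np.linalg.norm(vesicle_state.positions - centre, axis=1)
    r_inner = radial.min()  # inner head-bead surface
    lumen_r = r_inner - MIN_SEPARATION
    payload_vol = sum(4.19 * 2.35**3 * p.n for p in payloads)
    if payload_vol > 0.3 * 4.19 * lumen_r**3:
        raise ValueError("payload volume exceeds 30% of lumen volume")
    rng = stream(seed, "pack_interior")
    all_pos = [vesicle_state.positions]
    merged = vesicle_topology
    species = [vesicle_state.species]
    masses = [vesicle_state.masses]
    for nmol, model in enumerate(payloads):
        local = model.positions - model.positions.mean(axis=0)
        size = np.linalg.norm(local, axis=1).max()
        if size + margin >= lumen_r:
            raise ValueError("payload too large for the lumen; use fewer/"
                             "smaller molecules")
        for attempt in range(max_tries):
            rot = Rotation.random(rng=rng).as_matrix()
            shift = centre + rng.uniform(-1, 1, 3) * (lumen_r - size - margin)
            if np.linalg.norm(shift - centre) > lumen_r - size - margin:
                continue
            cand = local @ rot.T + shift
            if _min_distance_ok(np.concatenate(all_pos), box, cand):
                all_pos.append(cand)
                break
        else:
            raise RuntimeError(
                f"packing failed for payload {nmol + 1}; use fewer molecules")
        merged = merged.merge(model.to_topology())
        species.append(np.array([f"payload{nmol}"] * model.n))
        masses.append(model.masses)
    state = ParticleState(np.concatenate(all_pos), box.copy(),
                          species=np.concatenate(species),
                          masses=np.concatenate(masses),
                          mol_index=merged.mol_index)
    return state, merged
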
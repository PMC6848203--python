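"""Elastic-network coarse-grained proteins and peptides.

Proteins are reduced to two bead classes: one backbone bead per
residue at the Cα position and one side-chain (SC) bead per
non-glycine residue at the centroid of the side-chain heavy atoms.
All bead pairs within a distance cutoff (default 8 Å) in the
reference structure are connected by harmonic springs with force
constant k = 5 kcal/(mol Å²) and rest length equal to the reference
distance, keeping the molecule near-rigid.

Cross-interactions with lipids map each lipid bead class onto an
amino-acid SC type (choline → Lys, phosphate → Glu, glycerol → Asn,
tail → Leu) and rescale the SC–SC well depth by f = 0.545.  Backbone
Cα beads interact purely repulsively, with their radius increased by
50% because the whole backbone is collapsed into that single bead.
Real SC–SC parameter files can be loaded in place of the shipped toy
table.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .forcefield.bonded import BondTerm
from .forcefield.params import BeadType, ParameterSet
from .forcefield.topology import Topology

log = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

#: average residue masses (amu); Cα bead carries the 56 amu backbone
RESIDUE_MASS = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.19,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}
CA_MASS = 56.0


@dataclass
class CGBead:
    role: str  # "CA" or "SC"
    residue: str
    resid: int
    position: np.ndarray
    mass: float


@dataclass
class ENModel:
    """Elastic network: beads plus harmonic springs between all
    reference-structure pairs within the cutoff."""

    beads: List[CGBead]
    springs: List[BondTerm] = field(default_factory=list)
    cutoff: float = 8.0
    k: float = 5.0  # kcal/(mol Å²)

    @property
    def n(self) -> int:
        return len(self.beads)

    @property
    def positions(self) -> np.ndarray:
        return np.array([b.position for b in self.beads])

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    def type_names(self, scaling: "InteractionScaling" = None) -> List[str]:
        return [f"CA_{b.residue}" if b.role == "CA" else f"SC_{b.residue}"
                for b in self.beads]

    def to_topology(self) -> Topology:
        topo = Topology(self.type_names(), bonds=list(self.springs),
                        molecule_name="ENP")
        topo.build_exclusions(exclude_13=False)
        return topo

    def energy_forces(self, positions: np.ndarray, box=None):
        """EN energy/forces on free coordinates (vectorised harmonic springs)."""
        from .state import ParticleState

        st = ParticleState(positions, box if box is not None else np.full(3, 1e9))
        from .forcefield.bonded import bond_energy_forces

        return bond_energy_forces(st, self.springs)

    # ---------------- structured-text export/import ----------------
    def to_text(self, stream) -> None:
        stream.write(f"# elastic network: cutoff {self.cutoff} A, k {self.k}\n")
        stream.write("[beads]\n")
        for b in self.beads:
            p = b.position
            stream.write(f"{b.role} {b.residue} {b.resid} "
                         f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f} {b.mass:.2f}\n")
        stream.write("[springs]\n")
        for s in self.springs:
            stream.write(f"{s.i} {s.j} {s.r0:.5f} {s.kb:.4f}\n")

    @classmethod
    def from_text(cls, stream) -> "ENModel":
        beads, springs, section = [], [], None
        header = {"cutoff": 8.0, "k": 5.0}
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]")
                continue
            tok = line.split()
            if section == "beads":
                beads.append(CGBead(tok[0], tok[1], int(tok[2]),
                                    np.array([float(t) for t in tok[3:6]]),
                                    float(tok[6])))
            elif section == "springs":
                springs.append(BondTerm(int(tok[0]), int(tok[1]),
                                        float(tok[2]), float(tok[3])))
        return cls(beads, springs, header["cutoff"], header["k"])


@dataclass
class InteractionScaling:
    """Lipid↔protein cross-interaction rules."""

    f: float = 0.545
    ca_radius_scale: float = 1.5
    lipid_to_sc: Dict[str, str] = field(default_factory=lambda: {
        "choline": "LYS", "phosphate": "GLU", "glycerol": "ASN", "tail": "LEU",
    })

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError("rescale factor f must be > 0")
        required = {"choline", "phosphate", "glycerol", "tail"}
        if not required <= set(self.lipid_to_sc):
            raise ValueError(f"mapping must cover lipid classes {sorted(required)}")


def coarse_grain_structure(source) -> List[CGBead]:
    """Reduce an atomistic structure to Cα + SC beads.

    ``source`` is a PDB path or text stream (ATOM records, first
    model, altloc A).  Each residue contributes a Cα bead; non-glycine
    residues add an SC bead at the arithmetic mean of the side-chain
    heavy-atom coordinates.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    handle = io.StringIO(source) if isinstance(source, str) and "\nATOM" in ("\n" + source) \
        else source
    structure = parser.get_structure("s", handle)
    model = next(structure.get_models())
    beads: List[CGBead] = []
    for chain in model:
        for res in chain:
            if res.id[0].strip():
                continue  # HETATM / water
            resname = res.get_resname()
            atoms = [a for a in res.get_atoms()
                     if a.get_altloc() in (" ", "A") and a.element != "H"]
            ca = [a for a in atoms if a.get_name() == "CA"]
            if not ca:
                raise ValueError(f"residue {resname} {res.id[1]} lacks a CA record")
            beads.append(CGBead("CA", resname, res.id[1],
                                np.array(ca[0].get_coord(), dtype=float), CA_MASS))
            sc_atoms = [a for a in atoms if a.get_name() not in BACKBONE_ATOMS]
            if resname != "GLY" and sc_atoms:
                centroid = np.mean([a.get_coord() for a in sc_atoms], axis=0)
                beads.append(CGBead("SC", resname, res.id[1],
                                    np.asarray(centroid, dtype=float),
                                    max(RESIDUE_MASS.get(resname, 110.0) - CA_MASS, 15.0)))
    return beads


def build_elastic_network(beads: List[CGBead], cutoff: float = 8.0,
                          k: float = 5.0) -> ENModel:
    """Connect all bead pairs within ``cutoff`` by springs at their
    reference distance; energy and gradient are zero at the reference."""
    if len(beads) < 2:
        raise ValueError("elastic network needs at least 2 beads")
    pos = np.array([b.position for b in beads])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    springs = [BondTerm(int(i), int(j), float(np.linalg.norm(pos[i] - pos[j])), k)
               for i, j in pairs]
    n = len(beads)
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        ncomp, labels = connected_components(adj, directed=False)
    else:
        ncomp = n
    if ncomp > 1:
        log.warning("elastic network is disconnected (%d components)", ncomp)
    return ENModel(beads, springs, cutoff, k)


def build_peptide(sequence: str, start=np.zeros(3), axis=np.array([1.0, 0, 0])) -> List[CGBead]:
    """Idealised extended CG peptide: Cα every 3.8 Å along ``axis``,
    SC beads offset 2.5 Å perpendicular (used for substrate models)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0], 0.0])
    if np.linalg.norm(perp) < 1e-9:
        perp = np.array([1.0, 0.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    three = {"A": "ALA", "F": "PHE", "G": "GLY", "L": "LEU", "K": "LYS",
             "E": "GLU", "N": "ASN", "S": "SER", "V": "VAL", "T": "THR"}
    beads = []
    for k, aa in enumerate(sequence):
        resname = three.get(aa.upper(), "ALA")
        ca = np.asarray(start, dtype=float) + k * 3.8 * axis
        beads.append(CGBead("CA", resname, k + 1, ca, CA_MASS))
        if resname != "GLY":
            beads.append(CGBead("SC", resname, k + 1, ca + 2.5 * perp,
                                max(RESIDUE_MASS[resname] - CA_MASS, 15.0)))
    return beads


def load_sc_params(source=None) -> ParameterSet:
    """SC–SC nonbonded parameters from a CSV (name,sigma,epsilon,charge).

    Defaults to the shipped toy table — a physically sensible
    stand-in, not published force-field values; pass a real parameter
    file to override.
    """
    import csv

    if source is None:
        source = resources.files("lbmd.data").joinpath("sc_pairs_toy.csv").open()
    params = ParameterSet()
    for row in csv.DictReader(source):
        params.add_bead_type(BeadType(
            name=row["name"].strip(), mass=float(row["mass"]),
            charge=float(row["charge"]), radius=float(row["sigma"]) / 2.0,
            sigma=float(row["sigma"]), epsilon=float(row["epsilon"])))
    return params


def lipid_protein_pair_params(lipid_class: str, sc_type: str,
                              scaling: InteractionScaling,
                              sc_params: ParameterSet):
    """Nonbonded parameters for a lipid bead vs an SC bead.

    The lipid class is mapped onto its amino-acid SC proxy, the SC–SC
    pair parameters are looked up, and the well depth is rescaled by
    f.  Symmetric in its (mapped) arguments.
    """
    if lipid_class not in scaling.lipid_to_sc:
        raise KeyError(f"no SC mapping for lipid bead class {lipid_class!r}")
    proxy = scaling.lipid_to_sc[lipid_class]
    sigma, eps = sc_params.pair_lj(f"SC_{proxy}", sc_type if sc_type.startswith("SC_")
                                   else f"SC_{sc_type}")
    return sigma, eps * scaling.f
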
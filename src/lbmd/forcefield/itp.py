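"""Gromacs ITP dialect subset: topology and parameter I/O.

Supported sections: ``[defaults]``, ``[atomtypes]``, ``[nonbond_params]``,
``[moleculetype]``, ``[atoms]``, ``[bonds]``, ``[angles]``,
``[exclusions]``.  Anything else is skipped with a logged warning, so
full published CG lipid parameter files are accepted.  Units convert
at this boundary: nm → Å, kJ/mol → kcal/mol; angle function code 2
(the G96 cosine form) is the accepted bonded dialect.  Nonbonded
entries may be (σ, ε) or (C6, C12) depending on the combination rule
declared in ``[defaults]`` (rule 1 = C6/C12, rules 2-3 = σ/ε; Martini
files use rule 1).
"""

from __future__ import annotations

import logging
from typing import List, TextIO, Tuple

import numpy as np

from .bonded import AngleTerm, BondTerm, G96_COSINE
from .params import BeadType, ParameterSet
from .topology import Topology

log = logging.getLogger(__name__)

KJ = 1.0 / 4.184  # kJ/mol → kcal/mol
NM = 10.0

_KNOWN = {"defaults", "atomtypes", "nonbond_params", "moleculetype",
          "atoms", "bonds", "angles", "exclusions"}


class ItpError(ValueError):
    pass


def _c6c12_to_sigma_eps(c6: float, c12: float) -> Tuple[float, float]:
    if c6 <= 0 or c12 <= 0:
        return 0.0, 0.0
    sigma = (c12 / c6) ** (1.0 / 6.0)
    eps = c6 * c6 / (4.0 * c12)
    return sigma, eps


def read_itp(stream: TextIO) -> Tuple[Topology, ParameterSet]:
    """Parse an ITP subset into a (single-molecule) topology + parameters."""
    params = ParameterSet()
    comb_rule = 1
    section = None
    molname = "MOL"
    atom_types: List[str] = []
    atom_charges: List[float] = []
    atom_masses: List[float] = []
    bonds: List[BondTerm] = []
    angles: List[AngleTerm] = []
    exclusions = set()
    pending_pairs = []

    for lineno, raw in enumerate(stream, start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            log.warning("line %d: preprocessor directive skipped: %s", lineno, line)
            continue
        if line.startswith("["):
            section = line.strip("[] \t").lower()
            if section not in _KNOWN:
                log.warning("line %d: unknown section [%s] skipped", lineno, section)
            continue
        if section is None or section not in _KNOWN:
            continue
        tok = line.split()
        try:
            if section == "defaults":
                if len(tok) >= 2:
                    comb_rule = int(tok[1])
            elif section == "atomtypes":
                # name mass charge ptype  V W   (V,W = sigma/eps or C6/C12)
                name = tok[0]
                mass = float(tok[1])
                charge = float(tok[2])
                v, w = float(tok[4]), float(tok[5])
                if comb_rule == 1:
                    sigma, eps = _c6c12_to_sigma_eps(v, w)
                else:
                    sigma, eps = v, w
                params.add_bead_type(BeadType(
                    name, mass, charge, radius=0.5 * sigma * NM if sigma else 2.35,
                    sigma=sigma * NM if sigma else 4.7, epsilon=eps * KJ if eps else 0.5))
            elif section == "nonbond_params":
                a, b = tok[0], tok[1]
                v, w = float(tok[3]), float(tok[4])
                if comb_rule == 1:
                    sigma, eps = _c6c12_to_sigma_eps(v, w)
                else:
                    sigma, eps = v, w
                pending_pairs.append((a, b, sigma * NM, eps * KJ))
            elif section == "moleculetype":
                molname = tok[0]
            elif section == "atoms":
                # nr type resnr residue atom cgnr [charge [mass]]
                atom_types.append(tok[1])
                atom_charges.append(float(tok[6]) if len(tok) > 6 else 0.0)
                atom_masses.append(float(tok[7]) if len(tok) > 7 else float("nan"))
            elif section == "bonds":
                i, j = int(tok[0]) - 1, int(tok[1]) - 1
                b0, kb = float(tok[3]), float(tok[4])
                bonds.append(BondTerm(i, j, b0 * NM, kb * KJ / NM**2))
            elif section == "angles":
                i, j, k = int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2]) - 1
                funct = int(tok[3])
                if funct != 2:
                    raise ItpError(f"angle function code {funct} not supported (G96 only)")
                th0, kth = float(tok[4]), float(tok[5])
                angles.append(AngleTerm(i, j, k, th0, kth * KJ, G96_COSINE))
            elif section == "exclusions":
                i = int(tok[0]) - 1
                for t in tok[1:]:
                    j = int(t) - 1
                    exclusions.add((min(i, j), max(i, j)))
        except ItpError:
            raise
        except (ValueError, IndexError) as exc:
            raise ItpError(f"line {lineno}: malformed [{section}] record: {line!r}") from exc

    for a, b, sigma, eps in pending_pairs:
        params.set_lj(a, b, sigma, eps)

    # register any atom types used but not declared
    for name, charge, mass in zip(atom_types, atom_charges, atom_masses):
        if name not in params.bead_types:
            params.add_bead_type(BeadType(name, mass if np.isfinite(mass) else 72.0, charge))
        elif np.isfinite(mass):
            bt = params.bead_types[name]
            if bt.mass != mass or bt.charge != charge:
                params.add_bead_type(BeadType(name, mass, charge, bt.radius, bt.sigma, bt.epsilon))

    topo = Topology(atom_types, bonds, angles, molecule_name=molname)
    if exclusions:
        topo.exclusions = exclusions | {Topology._pair(t.i, t.j) for t in bonds}
    else:
        topo.build_exclusions()
    return topo, params


def write_itp(stream: TextIO, topology: Topology, params: ParameterSet) -> None:
    """Write a single-molecule topology in the ITP subset (σ/ε dialect)."""
    w = stream.write
    w("[ defaults ]\n; nbfunc comb-rule\n1 2\n\n")
    used = sorted(set(topology.type_names))
    w("[ atomtypes ]\n; name mass charge ptype sigma(nm) epsilon(kJ/mol)\n")
    for name in used:
        bt = params.bead_types[name]
        w(f"{name:6s} {bt.mass:10.4f} {bt.charge:8.4f}  A "
          f"{bt.sigma / NM:12.6f} {bt.epsilon / KJ:12.6f}\n")
    w("\n[ nonbond_params ]\n; i j funct sigma(nm) epsilon(kJ/mol)\n")
    for (a, b), (sigma, eps) in sorted(params.lj_pairs.items()):
        w(f"{a:6s} {b:6s} 1 {sigma / NM:12.6f} {eps / KJ:12.6f}\n")
    w(f"\n[ moleculetype ]\n{topology.molecule_name} 1\n\n")
    w("[ atoms ]\n; nr type resnr residue atom cgnr charge mass\n")
    for k, name in enumerate(topology.type_names, start=1):
        bt = params.bead_types[name]
        w(f"{k:4d} {name:6s} 1 {topology.molecule_name:6s} {name:6s} {k:4d} "
          f"{bt.charge:8.4f} {bt.mass:10.4f}\n")
    w("\n[ bonds ]\n; i j funct b0(nm) kb(kJ/mol/nm2)\n")
    for t in topology.bonds:
        w(f"{t.i + 1:4d} {t.j + 1:4d} 1 {t.r0 / NM:10.5f} {t.kb / KJ * NM**2:12.4f}\n")
    w("\n[ angles ]\n; i j k funct th0(deg) k(kJ/mol)\n")
    for t in topology.angles:
        w(f"{t.i + 1:4d} {t.j + 1:4d} {t.k + 1:4d} 2 {t.theta0:10.3f} {t.ktheta / KJ:10.4f}\n")
    w("\n[ exclusions ]\n")
    for (i, j) in sorted(topology.exclusions):
        w(f"{i + 1:4d} {j + 1:4d}\n")


def read_itp_subset(stream: TextIO):
    """Alias kept for the public API."""
    return read_itp(stream)
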
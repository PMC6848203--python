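"""Molecular topology: bead typing, bonded terms, exclusions, replication."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Set, Tuple

import numpy as np

from .bonded import AngleTerm, BondTerm


@dataclass
class Topology:
    """Beads, bonded terms and nonbonded exclusions of a system.

    ``type_names[b]`` is the bead-type label of bead b; ``mol_index``
    groups beads into molecules.  Exclusions always contain the 1-2
    (bonded) pairs; by default the 1-3 (angle-spanning) pairs are
    excluded as well, which is the dialect of the reference CG lipid
    ecosystem (configurable via ``exclude_13``).
    """

    type_names: List[str]
    bonds: List[BondTerm] = field(default_factory=list)
    angles: List[AngleTerm] = field(default_factory=list)
    exclusions: Set[Tuple[int, int]] = field(default_factory=set)
    mol_index: np.ndarray = None
    molecule_name: str = "MOL"

    def __post_init__(self):
        n = len(self.type_names)
        if self.mol_index is None:
            self.mol_index = np.zeros(n, dtype=int)
        self.mol_index = np.asarray(self.mol_index, dtype=int)
        for t in self.bonds:
            if t.i >= n or t.j >= n:
                raise ValueError(f"bond ({t.i},{t.j}) indexes past {n} beads")
        for t in self.angles:
            if max(t.i, t.j, t.k) >= n:
                raise ValueError(f"angle ({t.i},{t.j},{t.k}) indexes past {n} beads")

    @property
    def n(self) -> int:
        return len(self.type_names)

    @staticmethod
    def _pair(i: int, j: int) -> Tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def build_exclusions(self, exclude_13: bool = True) -> None:
        """(Re)derive exclusions from the bonded terms."""
        self.exclusions = {self._pair(t.i, t.j) for t in self.bonds}
        if exclude_13:
            for t in self.angles:
                self.exclusions.add(self._pair(t.i, t.k))

    def validate(self) -> None:
        bonded = {self._pair(t.i, t.j) for t in self.bonds}
        if not bonded <= self.exclusions:
            raise ValueError("exclusions must contain all 1-2 bonded pairs")

    def replicate(self, copies: int) -> "Topology":
        """Concatenate ``copies`` shifted images of this (single-molecule) topology."""
        n = self.n
        names, bonds, angles, mols = [], [], [], []
        excl: Set[Tuple[int, int]] = set()
        for c in range(copies):
            off = c * n
            names.extend(self.type_names)
            bonds.extend(BondTerm(t.i + off, t.j + off, t.r0, t.kb) for t in self.bonds)
            angles.extend(
                AngleTerm(t.i + off, t.j + off, t.k + off, t.theta0, t.ktheta, t.form)
                for t in self.angles
            )
            excl.update(self._pair(i + off, j + off) for (i, j) in self.exclusions)
            mols.append(self.mol_index + c * (self.mol_index.max() + 1 if n else 1))
        return Topology(names, bonds, angles, excl,
                        np.concatenate(mols) if mols else None, self.molecule_name)

    def merge(self, other: "Topology") -> "Topology":
        """Append another topology's beads after this one's."""
        off = self.n
        mshift = (self.mol_index.max() + 1) if self.n else 0
        return Topology(
            list(self.type_names) + list(other.type_names),
            self.bonds + [BondTerm(t.i + off, t.j + off, t.r0, t.kb) for t in other.bonds],
            self.angles
            + [AngleTerm(t.i + off, t.j + off, t.k + off, t.theta0, t.ktheta, t.form)
               for t in other.angles],
            self.exclusions | {self._pair(i + off, j + off) for (i, j) in other.exclusions},
            np.concatenate([self.mol_index, other.mol_index + mshift]),
            self.molecule_name,
        )
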
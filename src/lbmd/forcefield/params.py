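"""Bead types, nonbonded parameters, and parameter sets.

The force field follows the implicit-solvent Martini convention: ~4
heavy atoms per coarse-grained bead, 12-6 Lennard-Jones interactions
between all bead pairs, and screened short-range electrostatics
between the charged head-group beads (choline +1, phosphate −1) with a
relative dielectric of 15 standing in for the missing solvent.  Both
terms are force-shifted to vanish smoothly at the 12 Å cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np


@dataclass(frozen=True)
class BeadType:
    """A coarse-grained bead species.

    ``radius`` (Å) is used for fluid-velocity smearing and for sizing
    elastic-network beads; ``sigma``/``epsilon`` are the self LJ
    parameters from which unlisted pairs are combined.
    """

    name: str
    mass: float  # amu
    charge: float = 0.0  # e
    radius: float = 2.35  # Å
    sigma: float = 4.7  # Å
    epsilon: float = 0.5  # kcal/mol

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"bead type {self.name}: mass must be > 0")
        if self.radius <= 0:
            raise ValueError(f"bead type {self.name}: radius must be > 0")


@dataclass
class NonbondedParams:
    """Per-pair LJ parameters plus the global electrostatic settings."""

    sigma: float = 4.7  # Å
    epsilon: float = 0.5  # kcal/mol
    dielectric: float = 15.0
    cutoff: float = 12.0  # Å

    def __post_init__(self):
        if self.sigma < 0 or self.epsilon < 0:
            raise ValueError("sigma and epsilon must be >= 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ParameterSet:
    """Bead-type table and pairwise nonbonded parameters.

    Pairs absent from ``lj_pairs`` fall back to Lorentz–Berthelot
    combination of the per-type values.  ``repulsive_pairs`` marks
    pairs whose attractive LJ tail is cut (WCA-style), used for the
    backbone beads of elastic-network proteins.
    """

    bead_types: Dict[str, BeadType] = field(default_factory=dict)
    lj_pairs: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)
    repulsive_pairs: set = field(default_factory=set)
    dielectric: float = 15.0
    cutoff: float = 12.0

    def add_bead_type(self, bt: BeadType) -> None:
        self.bead_types[bt.name] = bt

    def set_lj(self, a: str, b: str, sigma: float, epsilon: float) -> None:
        self.lj_pairs[self._key(a, b)] = (float(sigma), float(epsilon))

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def pair_lj(self, a: str, b: str) -> Tuple[float, float]:
        key = self._key(a, b)
        if key in self.lj_pairs:
            return self.lj_pairs[key]
        ta, tb = self.bead_types[a], self.bead_types[b]
        return 0.5 * (ta.sigma + tb.sigma), float(np.sqrt(ta.epsilon * tb.epsilon))

    def pair_charge_product(self, a: str, b: str) -> float:
        return self.bead_types[a].charge * self.bead_types[b].charge

    def pair_params(self, a: str, b: str) -> NonbondedParams:
        sigma, epsilon = self.pair_lj(a, b)
        return NonbondedParams(sigma, epsilon, self.dielectric, self.cutoff)
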
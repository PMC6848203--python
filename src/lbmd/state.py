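"""Particle state container: positions, velocities, forces in a periodic box."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ParticleState:
    """All beads of a system in a (possibly z-walled) periodic box.

    Units are internal: positions Å, velocities Å/fs, forces
    kcal mol⁻¹ Å⁻¹, masses amu.  ``species`` tags each bead with a label
    used to look up per-species friction coefficients; ``mol_index``
    assigns each bead to a molecule (for per-lipid observables).

    If ``z_walled`` the z direction is bounded by the fluid walls used
    for Couette shear: particles reflect instead of wrapping.
    """

    positions: np.ndarray
    box: np.ndarray
    velocities: np.ndarray = None
    forces: np.ndarray = None
    masses: np.ndarray = None
    species: np.ndarray = None
    mol_index: np.ndarray = None
    z_walled: bool = False

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.positions)
        self.images = np.zeros((n, 3), dtype=int)
        if self.velocities is None:
            self.velocities = np.zeros((n, 3))
        if self.forces is None:
            self.forces = np.zeros((n, 3))
        if self.masses is None:
            self.masses = np.full(n, 72.0)
        if self.species is None:
            self.species = np.array(["bead"] * n)
        if self.mol_index is None:
            self.mol_index = np.arange(n)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")

    @property
    def n(self) -> int:
        return len(self.positions)

    def wrap(self) -> None:
        """Fold positions into the primary box (periodic dims only).

        Crossings are counted in ``images`` so that
        ``unwrapped_positions`` stays continuous for diffusion analysis.
        """
        dims = 2 if self.z_walled else 3
        shift = np.floor(self.positions[:, :dims] / self.box[:dims]).astype(int)
        self.positions[:, :dims] -= self.box[:dims] * shift
        self.images[:, :dims] += shift
        # a tiny negative coordinate can round up to exactly the box edge
        edge = self.positions[:, :dims] >= self.box[:dims]
        self.positions[:, :dims][edge] = 0.0
        self.images[:, :dims][edge] += 1

    @property
    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.images * self.box

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        dr = np.asarray(dr, dtype=float)
        out = dr.copy()
        dims = 2 if self.z_walled else 3
        out[..., :dims] -= self.box[:dims] * np.round(out[..., :dims] / self.box[:dims])
        return out

    def copy(self) -> "ParticleState":
        new = ParticleState(
            positions=self.positions.copy(),
            box=self.box.copy(),
            velocities=self.velocities.copy(),
            forces=self.forces.copy(),
            masses=self.masses.copy(),
            species=self.species.copy(),
            mol_index=self.mol_index.copy(),
            z_walled=self.z_walled,
        )
        new.images = self.images.copy()
        return new
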
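"""Shift-polynomial nonbonded interactions and tabulated potentials.

Electrostatics between charged beads is a screened, short-range
Coulomb term: the bare 1/r is modified by a polynomial switch acting
from r = 0 up to the cutoff r_c so that both the potential and the
force vanish at r_c.  For a power-law term r^(-alpha) the shifted force is

    F_alpha(r) = alpha r^(-(alpha+1)) + A r^2 + B r^3,
    A = -alpha (alpha+4) / r_c^(alpha+3),   B = alpha (alpha+3) / r_c^(alpha+4),

integrated to a potential that is zero at r_c.  For alpha = 1 this gives

    Phi(r) = 1/r + 5 r^3 / (3 r_c^4) - r^4 / r_c^5 - 5/(3 r_c),

which reduces to the bare Coulomb as r -> 0.  The same treatment is
applied to the r^-12 and r^-6 terms of the Lennard-Jones potential, so
every nonbonded term is C1-continuous at the cutoff.  Charged pairs
are evaluated from tables holding LJ + switched Coulomb summed
(exported as three-column text: r, U, F).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..units import COULOMB
from .params import NonbondedParams


def _shift_coeffs(alpha: float, rc: float):
    A = -alpha * (alpha + 4.0) / rc ** (alpha + 3)
    B = alpha * (alpha + 3.0) / rc ** (alpha + 4)
    C = -(rc ** (-alpha) - (A / 3.0) * rc**3 - (B / 4.0) * rc**4)
    return A, B, C


def shifted_power(r, alpha: float, rc: float):
    """Shifted (U, F) for a bare r^-alpha term; both vanish at r >= rc."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    A, B, C = _shift_coeffs(alpha, rc)
    inside = r < rc
    U = np.where(inside, r ** (-alpha) - (A / 3.0) * r**3 - (B / 4.0) * r**4 + C, 0.0)
    F = np.where(inside, alpha * r ** (-(alpha + 1)) + A * r**2 + B * r**3, 0.0)
    return U, F


def switched_coulomb(r, q1q2: float, params: NonbondedParams):
    """Screened electrostatic (U, F) between charges q1·q2 (e²).

    Returns energy in kcal/mol and the radial force −dU/dr in
    kcal mol⁻¹ Å⁻¹ (positive = repulsive for like charges).
    """
    U, F = shifted_power(r, 1.0, params.cutoff)
    scale = COULOMB * q1q2 / params.dielectric
    return scale * U, scale * F


def lj_energy_force(r, sigma: float, epsilon: float, rc: float, shifted: bool = True,
                    repulsive_only: bool = False):
    """12-6 Lennard-Jones (U, F), force-shifted to vanish at the cutoff.

    With ``shifted=False`` the bare truncated LJ is returned (used by
    oracles and tests).  ``repulsive_only`` drops the attractive r^-6
    term entirely (WCA-like, for backbone beads).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    c12 = 4.0 * epsilon * sigma**12
    c6 = 0.0 if repulsive_only else 4.0 * epsilon * sigma**6
    if shifted:
        U12, F12 = shifted_power(r, 12.0, rc)
        U6, F6 = shifted_power(r, 6.0, rc)
        return c12 * U12 - c6 * U6, c12 * F12 - c6 * F6
    inside = r < rc
    U = np.where(inside, c12 * r**-12 - c6 * r**-6, 0.0)
    F = np.where(inside, 12 * c12 * r**-13 - 6 * c6 * r**-7, 0.0)
    return U, F


def pair_energy_force(r, params: NonbondedParams, q1q2: float = 0.0,
                      repulsive_only: bool = False):
    """Total nonbonded (U, F): shifted LJ plus switched Coulomb."""
    U, F = lj_energy_force(r, params.sigma, params.epsilon, params.cutoff,
                           repulsive_only=repulsive_only)
    if q1q2 != 0.0:
        Uc, Fc = switched_coulomb(r, q1q2, params)
        U = U + Uc
        F = F + Fc
    return U, F


@dataclass
class TabulatedPotential:
    """Uniform-grid (r, U, F) table with linear interpolation.

    Invariants: U and F vanish at the last node (the cutoff), and F is
    consistent with −dU/dr at interior nodes.
    """

    r: np.ndarray
    U: np.ndarray
    F: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        dr = np.diff(self.r)
        if len(dr) == 0 or not np.allclose(dr, dr[0], rtol=1e-10):
            raise ValueError("table grid must be uniform")

    @property
    def spacing(self) -> float:
        return float(self.r[1] - self.r[0])

    def evaluate(self, r):
        """Linearly interpolated (U, F); zero beyond the cutoff."""
        r = np.asarray(r, dtype=float)
        U = np.interp(r, self.r, self.U, right=0.0)
        F = np.interp(r, self.r, self.F, right=0.0)
        return U, F

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.r, self.U, self.F]),
                   header="r[A]  U[kcal/mol]  F[kcal/mol/A]")

    @classmethod
    def from_text(cls, path) -> "TabulatedPotential":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1], data[:, 2])


def build_table(params: NonbondedParams, q1q2: float = 0.0, spacing: float = 0.002,
                r_min: float = 0.5, repulsive_only: bool = False) -> TabulatedPotential:
    """Tabulate LJ + switched Coulomb for one bead-type pair.

    Production tables use the default 0.002 Å spacing; the grid ends
    exactly at the cutoff so the zero-at-cutoff invariant holds on the
    nodes by construction.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    n = int(round((params.cutoff - r_min) / spacing))
    r = r_min + spacing * np.arange(n + 1)
    r[-1] = params.cutoff
    U, F = pair_energy_force(r, params, q1q2, repulsive_only=repulsive_only)
    return TabulatedPotential(r, U, F)
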
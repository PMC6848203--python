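"""Bonded terms: harmonic bonds and soft cosine angles.

The lipid model keeps only bond and angle terms (no dihedrals).
Bonds are harmonic, U = ½ k_b (r − r0)².  Angles are very soft cosine
wells; the default dialect is the G96 form

    U_θ = ½ K_θ (cos θ − cos θ0)²,

whose minimum sits at θ = θ0.  The alternative ``cos_squared``
dialect ½ K_θ cos²(θ − θ0) is kept selectable for cross-checks against
other codes (note its minimum lies 90° away from θ0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..state import ParticleState

log = logging.getLogger(__name__)

G96_COSINE = "g96_cosine"
COS_SQUARED = "cos_squared"

_SIN_EPS = 1e-8


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    r0: float  # Å
    kb: float  # kcal/(mol Å²)

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("bond connects a bead to itself")
        if self.r0 <= 0 or self.kb < 0:
            raise ValueError("bond needs r0 > 0 and kb >= 0")


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int  # apex
    k: int
    theta0: float  # degrees
    ktheta: float  # kcal/mol
    form: str = G96_COSINE

    def __post_init__(self):
        if len({self.i, self.j, self.k}) != 3:
            raise ValueError("angle indices must be distinct")
        if not 0.0 <= self.theta0 <= 180.0:
            raise ValueError("theta0 must lie in [0, 180] degrees")
        if self.form not in (G96_COSINE, COS_SQUARED):
            raise ValueError(f"unknown angle form {self.form!r}")


def _bond_arrays(terms):
    idx = np.array([[t.i, t.j] for t in terms], dtype=int).reshape(-1, 2)
    r0 = np.array([t.r0 for t in terms])
    kb = np.array([t.kb for t in terms])
    return idx, r0, kb


def bond_energy_forces(state: ParticleState, terms, arrays=None):
    """Harmonic-bond energy (kcal/mol) and per-bead forces.

    Minimum-image displacements are used, so bonds may span the
    periodic boundary.  Forces are the exact negative gradient of the
    returned energy.
    """
    forces = np.zeros_like(state.positions)
    if arrays is not None:
        idx, r0, kb = arrays
    else:
        if len(terms) == 0:
            return 0.0, forces
        idx, r0, kb = _bond_arrays(terms)
    if len(idx) == 0:
        return 0.0, forces
    dr = state.minimum_image(state.positions[idx[:, 0]] - state.positions[idx[:, 1]])
    r = np.linalg.norm(dr, axis=1)
    if np.any(r == 0.0):
        bad = int(np.argmin(r))
        raise ValueError(f"overlapping beads in bond ({idx[bad, 0]}, {idx[bad, 1]})")
    energy = float(np.sum(0.5 * kb * (r - r0) ** 2))
    fmag = -kb * (r - r0) / r  # along dr on bead i
    fvec = fmag[:, None] * dr
    n = len(forces)
    for d in range(3):
        forces[:, d] += np.bincount(idx[:, 0], weights=fvec[:, d], minlength=n)
        forces[:, d] -= np.bincount(idx[:, 1], weights=fvec[:, d], minlength=n)
    return energy, forces


def _angle_arrays(terms):
    idx = np.array([[t.i, t.j, t.k] for t in terms], dtype=int).reshape(-1, 3)
    theta0 = np.radians(np.array([t.theta0 for t in terms]))
    kth = np.array([t.ktheta for t in terms])
    literal = np.array([t.form == COS_SQUARED for t in terms])
    return idx, theta0, kth, literal


def angle_energy_forces(state: ParticleState, terms, arrays=None):
    """Cosine-angle energy and forces (exact negative gradient).

    Collinear-degenerate triples (|sin θ| below 1e-8) contribute their
    energy but a clamped zero force, with a logged warning; the
    gradient direction is undefined there.
    """
    forces = np.zeros_like(state.positions)
    if arrays is not None:
        idx, theta0, kth, literal = arrays
    else:
        if len(terms) == 0:
            return 0.0, forces
        idx, theta0, kth, literal = _angle_arrays(terms)
    if len(idx) == 0:
        return 0.0, forces

    a = state.minimum_image(state.positions[idx[:, 0]] - state.positions[idx[:, 1]])
    b = state.minimum_image(state.positions[idx[:, 2]] - state.positions[idx[:, 1]])
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    cos_t = np.clip(np.sum(a * b, axis=1) / (na * nb), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))

    U = np.where(
        literal,
        0.5 * kth * np.cos(theta - theta0) ** 2,
        0.5 * kth * (cos_t - np.cos(theta0)) ** 2,
    )
    # dU/d cosθ for each dialect; cos_squared needs 1/sinθ (chain rule).
    degenerate = sin_t < _SIN_EPS
    safe_sin = np.where(degenerate, 1.0, sin_t)
    dU_dcos = np.where(
        literal,
        0.5 * kth * np.sin(2.0 * (theta - theta0)) / safe_sin,
        kth * (cos_t - np.cos(theta0)),
    )
    if np.any(degenerate & literal):
        log.warning("collinear-degenerate angle(s): force clamped to zero")
    dU_dcos = np.where(degenerate & literal, 0.0, dU_dcos)

    inv_ab = 1.0 / (na * nb)
    gi = (b * inv_ab[:, None]) - a * (cos_t / na**2)[:, None]
    gk = (a * inv_ab[:, None]) - b * (cos_t / nb**2)[:, None]
    fi = -dU_dcos[:, None] * gi
    fk = -dU_dcos[:, None] * gk
    n = len(forces)
    for d in range(3):
        forces[:, d] += np.bincount(idx[:, 0], weights=fi[:, d], minlength=n)
        forces[:, d] += np.bincount(idx[:, 2], weights=fk[:, d], minlength=n)
        forces[:, d] -= np.bincount(idx[:, 1], weights=(fi + fk)[:, d],
                                    minlength=n)
    return float(np.sum(U)), forces
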
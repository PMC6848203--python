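"""D3Q19 BGK lattice-Boltzmann fluid with Couette walls and body forcing.

The solver runs in lattice units internally (node spacing = time step
= unit density = 1); a thin conversion layer maps the physical grid
spacing Δx = 3 Å, step Δt = 10 fs and water mass density onto lattice
units and fixes the relaxation time τ from the requested kinematic
viscosity,

    ν0 = c_s² (τ − ½) Δx² / Δt,   c_s² = 1/3.

Collision is single-relaxation-time (BGK) with Guo second-order
forcing for the particle back-reaction; shear is generated by
moving-wall halfway bounce-back at the two z faces (wall velocities
±γ̇ L_z/2 along x), giving linear Couette profiles in steady state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .units import WATER_DENSITY, WATER_NU

log = logging.getLogger(__name__)

CS2 = 1.0 / 3.0
MACH_LIMIT = 0.1

#: D3Q19 velocity set (rest, 6 axis, 12 face-diagonal vectors)
C = np.array(
    [[0, 0, 0],
     [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
     [1, 1, 0], [-1, -1, 0], [1, -1, 0], [-1, 1, 0],
     [1, 0, 1], [-1, 0, -1], [1, 0, -1], [-1, 0, 1],
     [0, 1, 1], [0, -1, -1], [0, 1, -1], [0, -1, 1]],
    dtype=int,
)

W = np.array([1 / 3] + [1 / 18] * 6 + [1 / 36] * 12)

#: index of the opposite velocity, C[OPP[q]] == -C[q]
OPP = np.array([int(np.flatnonzero((C == -c).all(axis=1))[0]) for c in C])


def equilibrium(rho, u):
    """Second-order Maxwell equilibrium populations, shape (19, ...).

    ``rho`` has shape (...,), ``u`` shape (..., 3).  The zeroth and
    first moments of the result equal (ρ, ρu) exactly.  Velocities
    beyond the low-Mach contract (|u| > 0.1) are clamped with a logged
    warning.
    """
    rho = np.asarray(rho, dtype=float)
    u = np.asarray(u, dtype=float)
    speed = np.sqrt(np.sum(u**2, axis=-1))
    if np.any(speed > MACH_LIMIT):
        log.warning("low-Mach contract violated (|u|max = %.3f): clamping", speed.max())
        scale = np.where(speed > MACH_LIMIT, MACH_LIMIT / np.maximum(speed, 1e-300), 1.0)
        u = u * scale[..., None]
    cu = np.tensordot(C, u, axes=([1], [u.ndim - 1]))  # (19, ...)
    u2 = np.sum(u**2, axis=-1)
    w = W.reshape((19,) + (1,) * rho.ndim)
    return w * rho * (1.0 + cu / CS2 + 0.5 * (cu / CS2) ** 2 - 0.5 * u2 / CS2)


@dataclass
class ShearSpec:
    """Couette shear: flow along x, velocity gradient along z."""

    shear_rate: float = 0.0  # fs⁻¹ (physical); use units.shear_rate_per_fs for s⁻¹ input

    def __post_init__(self):
        if self.shear_rate < 0:
            raise ValueError("shear rate must be >= 0")


class LatticeState:
    """D3Q19 population field on a periodic (optionally z-walled) grid."""

    def __init__(self, shape, tau: float, dx: float = 3.0, dt: float = 10.0,
                 rho_phys: float = WATER_DENSITY, walls_z: bool = False):
        if tau <= 0.5:
            raise ValueError("tau must exceed 1/2")
        self.shape = tuple(int(s) for s in shape)
        self.tau = float(tau)
        self.dx = float(dx)
        self.dt = float(dt)
        self.rho_phys = float(rho_phys)
        self.walls_z = walls_z
        self.wall_u = 0.0  # top-wall x velocity (lattice); bottom wall is −wall_u
        rho = np.ones(self.shape)
        u = np.zeros(self.shape + (3,))
        self.f = equilibrium(rho, u)

    # ---------------- unit layer ----------------
    @classmethod
    def for_box(cls, box, nu0: float = WATER_NU, dx: float = 3.0, dt: float = 10.0,
                rho_phys: float = WATER_DENSITY, walls_z: bool = False) -> "LatticeState":
        """Grid covering a physical box (Å) with viscosity ν0 (Å²/fs)."""
        shape = tuple(max(4, int(round(b / dx))) for b in np.atleast_1d(box))
        nu_lat = nu0 * dt / dx**2
        tau = 0.5 + nu_lat / CS2
        return cls(shape, tau, dx, dt, rho_phys, walls_z)

    @property
    def nu_lattice(self) -> float:
        return CS2 * (self.tau - 0.5)

    @property
    def nu_physical(self) -> float:
        """Kinematic viscosity in Å²/fs."""
        return self.nu_lattice * self.dx**2 / self.dt

    @property
    def node_mass(self) -> float:
        """Physical mass (amu) of one lattice mass unit."""
        return self.rho_phys * self.dx**3

    @property
    def velocity_unit(self) -> float:
        """Physical velocity (Å/fs) of one lattice velocity unit."""
        return self.dx / self.dt

    def set_shear(self, spec: ShearSpec) -> None:
        """Configure moving-wall Couette shear (gradient along z)."""
        lz = self.shape[2] * self.dx
        gdot_lat = spec.shear_rate * self.dt  # per lattice step, per node
        self.wall_u = 0.5 * gdot_lat * self.shape[2]
        if abs(self.wall_u) > MACH_LIMIT:
            raise ValueError(
                f"wall speed {self.wall_u:.3f} (lattice) violates the low-Mach "
                f"contract; reduce the shear rate or the box height ({lz:.0f} Å)"
            )
        self.walls_z = True

    # ---------------- macroscopic fields ----------------
    def macroscopic(self, force=None):
        """Density and velocity fields (lattice units).

        With Guo forcing the velocity carries the half-force shift,
        u = (Σ f c + F/2) / ρ.
        """
        rho = np.sum(self.f, axis=0)
        mom = np.tensordot(self.f, C, axes=([0], [0]))
        if force is not None:
            mom = mom + 0.5 * force
        return rho, mom / rho[..., None]

    def momentum(self):
        """Total lattice momentum Σ f c (no half-force shift)."""
        return np.tensordot(self.f, C, axes=([0], [0])).sum(axis=(0, 1, 2))

    def mass(self) -> float:
        return float(np.sum(self.f))

    # ---------------- dynamics ----------------
    def collide_stream(self, force=None) -> None:
        """One BGK collision + streaming step with optional Guo forcing.

        ``force`` is a nodal force field in lattice units, shape
        (nx, ny, nz, 3); the fluid momentum Σ f c increases by exactly
        Σ force in one step (periodic, no walls).
        """
        if not np.all(np.isfinite(self.f)):
            raise FloatingPointError("NaN/Inf populations: unstable LB state")
        rho, u = self.macroscopic(force)
        feq = equilibrium(rho, u)
        fpost = self.f - (self.f - feq) / self.tau
        if force is not None:
            pref = (1.0 - 0.5 / self.tau) * W  # (19,)
            cu = np.tensordot(C, u, axes=([1], [3]))  # (19, nx, ny, nz)
            # (c − u)/cs² + (c·u) c /cs⁴, dotted with F
            cF = np.tensordot(C, force, axes=([1], [3]))
            uF = np.sum(u * force, axis=-1)
            src = pref.reshape(19, 1, 1, 1) * (
                (cF - uF[None]) / CS2 + cu * cF / CS2**2
            )
            fpost = fpost + src
        # streaming (periodic)
        fnew = np.empty_like(fpost)
        for q in range(19):
            fnew[q] = np.roll(fpost[q], shift=tuple(C[q]), axis=(0, 1, 2))
        if self.walls_z:
            self._bounce_back(fpost, fnew)
        self.f = fnew

    def _bounce_back(self, fpost, fnew) -> None:
        """Moving-wall halfway bounce-back at the two z faces."""
        rho_bot = np.sum(fpost[:, :, :, 0], axis=0)
        rho_top = np.sum(fpost[:, :, :, -1], axis=0)
        for q in range(19):
            cz = C[q, 2]
            if cz == 0:
                continue
            qb = OPP[q]
            if cz > 0:  # enters from below: reflect qb (which left through bottom wall)
                corr = 2.0 * W[qb] * rho_bot * (C[qb, 0] * -self.wall_u) / CS2
                fnew[q][:, :, 0] = fpost[qb][:, :, 0] - corr
            else:  # enters from above: top wall moves at +wall_u
                corr = 2.0 * W[qb] * rho_top * (C[qb, 0] * self.wall_u) / CS2
                fnew[q][:, :, -1] = fpost[qb][:, :, -1] - corr

    def run(self, steps: int, force=None) -> None:
        for _ in range(steps):
            self.collide_stream(force)

    # ---------------- I/O ----------------
    def save(self, path) -> None:
        """Checkpoint the population field (self-describing npz container)."""
        np.savez(path, f=self.f, tau=self.tau, dx=self.dx, dt=self.dt,
                 rho_phys=self.rho_phys, walls_z=self.walls_z, wall_u=self.wall_u)

    @classmethod
    def load(cls, path) -> "LatticeState":
        data = np.load(path)
        st = cls(data["f"].shape[1:], float(data["tau"]), float(data["dx"]),
                 float(data["dt"]), float(data["rho_phys"]), bool(data["walls_z"]))
        st.f = data["f"]
        st.wall_u = float(data["wall_u"])
        return st

    def export_velocity_csv(self, path) -> None:
        """Structured-text velocity field (x,y,z node indices + u in Å/fs)."""
        rho, u = self.macroscopic()
        idx = np.indices(self.shape).reshape(3, -1).T
        uu = u.reshape(-1, 3) * self.velocity_unit
        out = np.column_stack([idx * self.dx, uu])
        np.savetxt(path, out, header="x[A] y[A] z[A] ux[A/fs] uy[A/fs] uz[A/fs]",
                   comments="# ", delimiter=",")


def apply_couette(state: LatticeState, spec: ShearSpec, steps: int = None,
                  tol: float = 1e-12) -> LatticeState:
    """Drive the fluid to the steady Couette profile.

    Runs until the x-velocity profile stops changing (max change per
    step below ``tol`` in lattice units) or for a fixed step count.
    """
    state.set_shear(spec)
    if steps is not None:
        state.run(steps)
        return state
    nz = state.shape[2]
    max_steps = 400 * nz * nz
    prev = None
    for k in range(max_steps):
        state.collide_stream()
        if k % 50 == 0:
            _, u = state.macroscopic()
            prof = u[..., 0].mean(axis=(0, 1))
            if prev is not None and np.max(np.abs(prof - prev)) < tol * 50:
                break
            prev = prof
    return state
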
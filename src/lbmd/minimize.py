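"""Capped steepest-descent energy minimisation for freshly built systems."""

from __future__ import annotations

import logging

import numpy as np

from .state import ParticleState

log = logging.getLogger(__name__)


def steepest_descent(state: ParticleState, forcefield, steps: int = 200,
                     max_disp: float = 0.2, alpha0: float = 1e-4,
                     f_tol: float = 10.0) -> float:
    """Relax bad contacts before dynamics.

    Moves each bead along the force with an adaptive step, capping the
    per-bead displacement at ``max_disp`` Å per iteration; stops early
    once the maximum force drops below ``f_tol`` kcal mol⁻¹ Å⁻¹.
    Returns the final potential energy.
    """
    alpha = alpha0
    energy, forces = forcefield.compute(state)
    for it in range(steps):
        fmax = np.max(np.linalg.norm(forces, axis=1))
        if fmax < f_tol:
            break
        step = forces * alpha
        norms = np.linalg.norm(step, axis=1)
        scale = np.minimum(1.0, max_disp / np.maximum(norms, 1e-300))
        trial = state.copy()
        trial.positions += step * scale[:, None]
        trial.wrap()
        e_new, f_new = forcefield.compute(trial)
        if e_new < energy:
            state.positions[:] = trial.positions
            state.images[:] = trial.images
            forcefield.nlist.invalidate()
            energy, forces = e_new, f_new
            alpha *= 1.2
        else:
            alpha *= 0.5
            if alpha < 1e-12:
                break
    log.info("minimisation done: E = %.1f kcal/mol after %d iterations",
             energy, it + 1)
    return energy
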
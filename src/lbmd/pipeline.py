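"""Reproducible build → simulate → analyze pipelines over the library.

Each stage is a plain function of a :class:`~lbmd.config.RunConfig`;
the CLI wraps these.  Runs are deterministic given the config seed:
per-module random streams derive from it by stable hashing, and each
run archives its resolved config, seed and config hash in a
structured JSON log.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Dict, Tuple

import numpy as np

from . import __version__, builders
from .analysis import gyration_tensor, membrane_thickness, rdf
from .config import RunConfig
from .coupling import CouplingParams, LBMDIntegrator
from .forcefield.field import ForceField
from .forcefield.itp import write_itp
from .forcefield.topology import Topology
from .io import XYZTrajectoryWriter, write_gro
from .lb import LatticeState, ShearSpec
from .rng import stream
from .validate import validate_lb
from .state import ParticleState


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def build_system(config: RunConfig) -> Tuple[ParticleState, Topology]:
    """Construct the configured system class (seeded, deterministic)."""
    try:
        if config.kind == "bilayer":
            return builders.build_bilayer(config.box, config.box, config.lz,
                                          config.area_per_lipid, seed=config.seed)
        if config.kind == "gas":
            return builders.build_random_gas(config.n_lipids, config.box,
                                             seed=config.seed)
        if config.kind == "vesicle":
            return builders.build_vesicle(config.radius, config.box,
                                          config.area_per_lipid, seed=config.seed)
        if config.kind == "nanotube":
            return builders.build_nanotube(box=np.full(3, config.box))
        if config.kind == "loaded_vesicle":
            from .protein import build_elastic_network, build_peptide

            ves, topo = builders.build_vesicle(config.radius, config.box,
                                               config.area_per_lipid,
                                               seed=config.seed)
            peptides = [build_elastic_network(build_peptide("AFA"))
                        for _ in range(config.n_payload)]
            return builders.pack_interior(ves, topo, peptides, seed=config.seed)
        raise ValueError(f"unknown system kind {config.kind!r}")
    except Exception as exc:  # noqa: BLE001 - stage attribution contract
        raise StageError("build", exc) from exc


def make_integrator(config: RunConfig, state: ParticleState, topology: Topology,
                    params=None) -> LBMDIntegrator:
    ff = ForceField(topology, params or builders.default_lipid_parameters())
    lattice = None
    if config.hydrodynamics:
        lattice = LatticeState.for_box(state.box, nu0=config.nu0_internal,
                                       dx=config.lb_dx, dt=config.dt)
        if config.shear_rate > 0:
            lattice.set_shear(ShearSpec(config.shear_rate_internal))
            state.z_walled = True
    coupling = CouplingParams(
        gamma=dict(config.gamma), gamma_default=config.gamma_default,
        temperature=config.temperature, hydrodynamics=config.hydrodynamics,
        back_reaction=config.back_reaction)
    return LBMDIntegrator(state, ff, coupling, lattice=lattice, dt=config.dt,
                          n_md_per_lb=config.n_md_per_lb,
                          rng=stream(config.seed, "integrator"))


def simulate(config: RunConfig, state: ParticleState, topology: Topology,
             workdir: Path) -> Dict:
    """Run the configured dynamics, writing trajectory + structured log."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    try:
        if config.minimize_steps:
            from .minimize import steepest_descent

            ff = ForceField(topology, builders.default_lipid_parameters())
            steepest_descent(state, ff, steps=config.minimize_steps)
        integ = make_integrator(config, state, topology)
        traj_path = workdir / "trajectory.xyz"
        with XYZTrajectoryWriter(traj_path, stride=1) as writer:
            writer.write(state, comment="step 0")
            for k in range(config.steps):
                integ.step()
                if (k + 1) % config.traj_stride == 0:
                    writer.write(state, comment=f"step {k + 1}")
        write_gro(workdir / "final.gro", state)
        config.write(workdir / "run.cfg")
        log = {
            "stage": "simulate", "config_hash": config.digest(),
            "seed": config.seed, "version": __version__,
            "steps": config.steps, "n_beads": state.n,
            "kinetic_temperature_K": integ.kinetic_temperature(),
            "wall_time_s": round(time.time() - t0, 3),
        }
        (workdir / "run.log.json").write_text(json.dumps(log, indent=1))
        return log
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc


def analyze(config: RunConfig, state: ParticleState, topology: Topology,
            workdir: Path) -> Dict:
    """Single-frame (or final-state) observables written as tidy CSV."""
    import pandas as pd

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    try:
        out: Dict = {}
        res = gyration_tensor(state.positions, state.masses)
        out["gyration_eigenvalues_A2"] = res.eigenvalues.tolist()
        types = np.array(topology.type_names)
        if config.kind in ("bilayer",):
            out["thickness_A"] = membrane_thickness(state.positions, types == "Qa")
        tails = np.flatnonzero(types == "C1")
        if len(tails) and np.all(state.box >= 30.0):
            r, g = rdf([state.positions], state.box, tails, r_max=14.0, bins=56)
            pd.DataFrame({"r_A": r, "g": g}).to_csv(workdir / "rdf_tails.csv",
                                                    index=False)
            out["rdf_file"] = "rdf_tails.csv"
        pd.DataFrame([{"observable": k, "value": json.dumps(v)}
                      for k, v in out.items()]).to_csv(
            workdir / "observables.csv", index=False)
        return out
    except Exception as exc:  # noqa: BLE001
        raise StageError("analyze", exc) from exc



def run(command: str, config: RunConfig, workdir="runs") -> Dict:
    """Dispatch one pipeline stage; errors carry the stage name."""
    workdir = Path(workdir)
    if command == "build":
        state, topo = build_system(config)
        workdir.mkdir(parents=True, exist_ok=True)
        write_gro(workdir / "system.gro", state)
        with open(workdir / "system.itp", "w") as fh:
            write_itp(fh, topo if topo.n <= 64 else _first_molecule(topo),
                      builders.default_lipid_parameters())
        config.write(workdir / "run.cfg")
        return {"stage": "build", "n_beads": state.n,
                "config_hash": config.digest()}
    if command == "simulate":
        state, topo = build_system(config)
        return simulate(config, state, topo, workdir)
    if command == "analyze":
        state, topo = build_system(config)
        return analyze(config, state, topo, workdir)
    if command == "validate-lb":
        return validate_lb(config.seed)
    raise StageError("dispatch", ValueError(f"unknown command {command!r}"))


def _first_molecule(topology: Topology) -> Topology:
    mask = topology.mol_index == topology.mol_index[0]
    n = int(mask.sum())
    return Topology(topology.type_names[:n],
                    [b for b in topology.bonds if b.i < n and b.j < n],
                    [a for a in topology.angles if max(a.i, a.j, a.k) < n],
                    {p for p in topology.exclusions if max(p) < n},
                    molecule_name=topology.molecule_name)
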
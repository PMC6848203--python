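"""Run configuration: flat, diff-able ``key = value`` text with sections.

Every run archives its resolved configuration verbatim next to its
outputs, together with the seed and a config hash, so results are
reproducible from the archive alone.  Shear rates are accepted in
s⁻¹ and viscosities in m²/s (the units the literature quotes) and
converted at this boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Dict

from .units import shear_rate_per_fs, viscosity_m2s_to_A2fs


@dataclass
class RunConfig:
    # [system]
    kind: str = "gas"  # bilayer | gas | vesicle | nanotube_bilayer | loaded_vesicle
    n_lipids: int = 128
    box: float = 75.0  # Å (cubic; bilayer uses lx=ly=box, lz below)
    lz: float = 120.0
    radius: float = 34.0  # vesicle midplane radius, Å
    area_per_lipid: float = 69.4
    n_payload: int = 0
    # [dynamics]
    temperature: float = 310.0  # K
    dt: float = 10.0  # fs
    steps: int = 10000
    minimize_steps: int = 200
    gamma: Dict[str, float] = field(default_factory=dict)  # fs⁻¹ per species
    gamma_default: float = 0.00025
    hydrodynamics: bool = True
    back_reaction: bool = True
    n_md_per_lb: int = 1
    # [fluid]
    lb_dx: float = 3.0  # Å
    nu0: float = 1.0e-6  # m²/s
    shear_rate: float = 0.0  # s⁻¹
    # [output]
    traj_stride: int = 100
    log_stride: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("temperature", "dt", "lb_dx", "nu0", "area_per_lipid", "box"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.shear_rate < 0:
            raise ValueError("shear_rate must be >= 0")
        if self.steps < 0 or self.minimize_steps < 0:
            raise ValueError("step counts must be >= 0")

    @property
    def nu0_internal(self) -> float:
        """Kinematic viscosity in Å²/fs."""
        return viscosity_m2s_to_A2fs(self.nu0)

    @property
    def shear_rate_internal(self) -> float:
        """Shear rate in fs⁻¹."""
        return shear_rate_per_fs(self.shear_rate)

    # ---------------- text round trip ----------------
    _SECTIONS = {
        "system": ("kind", "n_lipids", "box", "lz", "radius", "area_per_lipid",
                   "n_payload"),
        "dynamics": ("temperature", "dt", "steps", "minimize_steps",
                     "gamma_default", "hydrodynamics", "back_reaction",
                     "n_md_per_lb"),
        "fluid": ("lb_dx", "nu0", "shear_rate"),
        "output": ("traj_stride", "log_stride", "seed"),
    }

    def write(self, dest) -> None:
        close = False
        if not hasattr(dest, "write"):
            dest = open(dest, "w")
            close = True
        for section, keys in self._SECTIONS.items():
            dest.write(f"[{section}]\n")
            for key in keys:
                dest.write(f"{key} = {getattr(self, key)}\n")
            if section == "dynamics":
                for sp, g in sorted(self.gamma.items()):
                    dest.write(f"gamma.{sp} = {g}\n")
            dest.write("\n")
        if close:
            dest.close()

    @classmethod
    def read(cls, src) -> "RunConfig":
        close = False
        if not hasattr(src, "read"):
            src = open(src)
            close = True
        values: Dict[str, str] = {}
        gamma: Dict[str, float] = {}
        for lineno, raw in enumerate(src, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected 'key = value'")
            key, val = (t.strip() for t in line.split("=", 1))
            if key.startswith("gamma."):
                gamma[key[6:]] = float(val)
            else:
                values[key] = val
        if close:
            src.close()
        kwargs = {}
        defaults = cls()
        for key, val in values.items():
            if not hasattr(defaults, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes", "on")
            elif isinstance(current, int):
                kwargs[key] = int(val)
            elif isinstance(current, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(gamma=gamma, **kwargs)

    def digest(self) -> str:
        return hashlib.sha256(repr(sorted(asdict(self).items()))
                              .encode()).hexdigest()[:12]
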
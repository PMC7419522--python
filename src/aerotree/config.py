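"""Run configuration: YAML/JSON loading and unit normalization.

User-facing units are the ones practitioners use — litres per second for
flow, micrometres for particle diameter, degrees for rotation — and are
converted to SI on load.  All library functions speak SI only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .physics import (AIR_BODY, CONSTANTS, DEFAULT_FLOW_RANGE, Fluid,
                      Particle, PhysicalConstants)

__all__ = ["RunConfig", "load_config", "lps_to_m3s", "m3s_to_lps",
           "um_to_m"]


def lps_to_m3s(q_lps: float) -> float:
    return q_lps * 1e-3


def m3s_to_lps(q: float) -> float:
    return q * 1e3


def um_to_m(d_um: float) -> float:
    return d_um * 1e-6


@dataclass(frozen=True)
class RunConfig:
    particle: Particle
    fluid: Fluid = AIR_BODY
    constants: PhysicalConstants = CONSTANTS
    flow_range: tuple[float, float] = DEFAULT_FLOW_RANGE  # m^3/s
    seed: int = 0
    extras: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load a YAML (or JSON) run configuration.

    Schema::

        particle: {diameter_um: 3.5, density_kg_m3: 1000}
        fluid: {viscosity: 1.9e-5, density: 1.14, temperature_K: 310.15,
                mean_free_path_m: 7.0e-8}
        constants: {g: 9.81, k_B: 1.380649e-23}
        flow_range_lps: [0.0001, 1.0]
        seed: 0

    Every block except ``particle`` is optional and defaults to dry air at
    37 °C, standard constants, and the physiological flow range.
    ``particle.diameter_m`` may be given instead of ``diameter_um``.
    """
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    p = doc["particle"]
    if "diameter_m" in p:
        d = float(p["diameter_m"])
    else:
        d = um_to_m(float(p["diameter_um"]))
    particle = Particle(diameter=d, density=float(p.get("density_kg_m3", 1000.0)))
    f = doc.get("fluid", {})
    fluid = Fluid(
        viscosity=float(f.get("viscosity", AIR_BODY.viscosity)),
        density=float(f.get("density", AIR_BODY.density)),
        temperature=float(f.get("temperature_K", AIR_BODY.temperature)),
        mean_free_path=float(f.get("mean_free_path_m", AIR_BODY.mean_free_path)))
    c = doc.get("constants", {})
    constants = PhysicalConstants(
        gravity=float(c.get("g", CONSTANTS.gravity)),
        boltzmann=float(c.get("k_B", CONSTANTS.boltzmann)))
    if "flow_range_lps" in doc:
        lo, hi = doc["flow_range_lps"]
        flow_range = (lps_to_m3s(float(lo)), lps_to_m3s(float(hi)))
    else:
        flow_range = DEFAULT_FLOW_RANGE
    known = {"particle", "fluid", "constants", "flow_range_lps", "seed"}
    extras = {k: v for k, v in doc.items() if k not in known}
    return RunConfig(particle=particle, fluid=fluid, constants=constants,
                     flow_range=flow_range, seed=int(doc.get("seed", 0)),
                     extras=extras)
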
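"""Poiseuille flow partitioning over the airway tree.

Each segment is a laminar resistor ``R = 128 mu L / (pi D^4)``.  The two
daughter subtrees at a bifurcation are in parallel, so the flow entering
each daughter is inversely proportional to that daughter subtree's input
resistance.  Fractional flows depend on geometry only; changing the
inlet flow rescales every local flow linearly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .physics import Fluid, reynolds_number
from .tree import AirwayTree

__all__ = ["FlowState", "poiseuille_resistance", "input_resistance",
           "partition_flows", "rescale_flows"]


def poiseuille_resistance(L: float, D: float, mu: float) -> float:
    """Laminar tube resistance ``128 mu L / (pi D^4)`` (Pa·s/m³)."""
    if L <= 0 or D <= 0 or mu <= 0:
        raise ValueError("L, D and mu must be positive")
    return 128.0 * mu * L / (math.pi * D ** 4)


def _segment_resistances(tree: AirwayTree, mu: float) -> dict[int, float]:
    return {s: poiseuille_resistance(seg.length, seg.diameter, mu)
            for s, seg in tree.segments.items()}


def _input_resistances(tree: AirwayTree, mu: float) -> dict[int, float]:
    """Subtree input resistance for every state, leaf-to-root."""
    r_seg = _segment_resistances(tree, mu)
    r_in: dict[int, float] = {}
    # deepest states first; daughters always have higher state numbers is not
    # guaranteed for file trees, so order by generation instead
    for s in sorted(tree.segments,
                    key=lambda s: tree.segments[s].generation, reverse=True):
        ds = tree.daughters(s)
        if not ds:
            r_in[s] = r_seg[s]
        else:
            d1, d2 = ds
            r_in[s] = r_seg[s] + 1.0 / (1.0 / r_in[d1] + 1.0 / r_in[d2])
    return r_in


def input_resistance(tree: AirwayTree, state: int, mu: float) -> float:
    """Input resistance of the subtree rooted at ``state``.

    Terminal segments contribute only their own resistance (no peripheral
    compliance is modeled); internal segments add the parallel combination
    of their two daughter subtrees.
    """
    if state not in tree.segments:
        raise ValueError(f"unknown state {state}")
    return _input_resistances(tree, mu)[state]


@dataclass(frozen=True)
class FlowState:
    """Inlet flow plus per-segment fractions, flows, velocities, Re."""

    q0: float  # m^3/s
    fractions: dict[int, float]
    flows: dict[int, float]  # m^3/s
    velocities: dict[int, float]  # m/s
    reynolds: dict[int, float]
    viscosity: float  # Pa s used for the partitioning


def partition_flows(tree: AirwayTree, q0: float, fluid: Fluid) -> FlowState:
    """Split the inlet flow through the tree by inverse input resistance.

    At each bifurcation ``f_d1 / f_d2 = R_in(d2) / R_in(d1)`` and the
    daughter fractions sum to the parent fraction, so flow is conserved
    at every node and terminal fractions sum to 1.
    """
    if q0 <= 0:
        raise ValueError("inlet flow must be positive")
    r_in = _input_resistances(tree, fluid.viscosity)
    fractions: dict[int, float] = {tree.root: 1.0}
    for s in sorted(tree.segments, key=lambda s: tree.segments[s].generation):
        ds = tree.daughters(s)
        if ds:
            d1, d2 = ds
            g1, g2 = 1.0 / r_in[d1], 1.0 / r_in[d2]
            fractions[d1] = fractions[s] * g1 / (g1 + g2)
            fractions[d2] = fractions[s] * g2 / (g1 + g2)
    flows = {s: f * q0 for s, f in fractions.items()}
    velocities = {}
    re = {}
    for s, seg in tree.segments.items():
        area = math.pi * (seg.diameter / 2.0) ** 2
        velocities[s] = flows[s] / area
        re[s] = reynolds_number(flows[s], seg.diameter, fluid)
    return FlowState(q0=q0, fractions=fractions, flows=flows,
                     velocities=velocities, reynolds=re,
                     viscosity=fluid.viscosity)


def rescale_flows(flow: FlowState, q0_new: float) -> FlowState:
    """Linear rescaling of all local flows to a new inlet flow."""
    if q0_new <= 0:
        raise ValueError("inlet flow must be positive")
    r = q0_new / flow.q0
    return FlowState(
        q0=q0_new,
        fractions=dict(flow.fractions),
        flows={s: q * r for s, q in flow.flows.items()},
        velocities={s: v * r for s, v in flow.velocities.items()},
        reynolds={s: x * r for s, x in flow.reynolds.items()},
        viscosity=flow.viscosity)
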
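"""Inlet flow policies: optimization and evaluation.

A *flow policy* is the inlet (tracheal) flow as a function of time during
the delivery window of a breath.  Because the chain has no intra-segment
position, policies are naturally indexed by airway generation: step g is
the inlet flow applied while the surviving particle cohort traverses
generation g.  The per-generation optimal policy minimizes each
segment's own capture probability over the admissible local flows,
converts the optima to inlet-equivalent flows through the fixed
fractional-flow field, and averages within each generation.

Residence times convert the generation index into a time axis for the
reported waveform; the window starts when the particle is released at
the trachea, not at the start of inspiration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .flow import FlowState, partition_flows, rescale_flows
from .physics import (CONSTANTS, DEFAULT_FLOW_RANGE, Fluid, Particle,
                      PhysicalConstants, capture_minimizing_flow)
from .tree import AirwayTree

__all__ = ["FlowPolicy", "PolicyStep", "PolicyEvaluation",
           "optimal_generation_flows", "policy_to_time", "evaluate_policy",
           "reference_policies"]


@dataclass(frozen=True)
class PolicyStep:
    generation: int
    q0: float  # m^3/s inlet flow during this step
    t_start: float = math.nan  # s
    t_end: float = math.nan  # s


@dataclass(frozen=True)
class FlowPolicy:
    """Constant or generation-stepped inlet flow."""

    steps: tuple[PolicyStep, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("policy needs at least one step")
        gens = [s.generation for s in self.steps]
        if gens != sorted(gens) or len(set(gens)) != len(gens):
            raise ValueError("policy steps must have strictly increasing generations")
        for s in self.steps:
            if s.q0 <= 0:
                raise ValueError("policy flows must be positive")

    @classmethod
    def constant(cls, q0: float, name: str = "constant") -> "FlowPolicy":
        return cls(steps=(PolicyStep(generation=1, q0=q0),), name=name)

    @classmethod
    def from_generation_flows(cls, flows: dict[int, float] | list[tuple[int, float]],
                              name: str = "") -> "FlowPolicy":
        items = sorted(flows.items()) if isinstance(flows, dict) else sorted(flows)
        return cls(steps=tuple(PolicyStep(generation=g, q0=q) for g, q in items),
                   name=name)

    @property
    def is_constant(self) -> bool:
        return len({s.q0 for s in self.steps}) == 1

    def flow_at_generation(self, g: int) -> float:
        """Inlet flow applied while the cohort sits at generation ``g``.

        Generations beyond the last step reuse the last step's flow.
        """
        q = self.steps[0].q0
        for s in self.steps:
            if s.generation <= g:
                q = s.q0
            else:
                break
        return q


@dataclass(frozen=True)
class PolicyEvaluation:
    escape: float
    deposition: dict[int, float]  # state -> capture probability
    generation_flows: dict[int, float]  # generation -> inlet flow used
    policy: FlowPolicy

    def total(self) -> float:
        return sum(self.deposition.values()) + self.escape


def optimal_generation_flows(tree: AirwayTree, particle: Particle, fluid: Fluid,
                             q_range: tuple[float, float] = DEFAULT_FLOW_RANGE,
                             constants: PhysicalConstants = CONSTANTS,
                             base_flow: FlowState | None = None,
                             ) -> tuple[dict[int, float], dict[int, float]]:
    """Per-generation optimal inlet flows.

    For each segment, the local flow minimizing its capture probability is
    searched over the local admissible range ``f_k * [Q_min, Q_max]``,
    converted to the inlet-equivalent flow ``Q0* = Q*/f_k`` and clipped to
    the admissible inlet range; the reported per-generation optimum is the
    arithmetic mean over the generation's segments.

    Returns ``(per_generation, per_segment)`` inlet-equivalent optima.
    """
    if base_flow is None:
        base_flow = partition_flows(tree, 1.0, fluid)
    q_lo, q_hi = q_range
    per_segment: dict[int, float] = {}
    for s in tree.segments:
        f = base_flow.fractions[s]
        q_star = capture_minimizing_flow(tree.tube(s), particle, fluid,
                                         q_range=(q_lo * f, q_hi * f),
                                         constants=constants)
        per_segment[s] = min(max(q_star / f, q_lo), q_hi)
    per_generation: dict[int, float] = {}
    for g in range(1, tree.n_generations + 1):
        states = tree.generation_states(g)
        if not states:
            warnings.warn(f"generation {g} has no segments; skipped")
            continue
        per_generation[g] = sum(per_segment[s] for s in states) / len(states)
    return per_generation, per_segment


def policy_to_time(gen_flows: dict[int, float], tree: AirwayTree, fluid: Fluid,
                   ) -> FlowPolicy:
    """Attach a time axis to a generation-indexed policy.

    Step g lasts the mean residence time of generation-g segments at that
    step's flows, ``tau_g = mean_k(L_k / U_k)``; cumulative sums give the
    waveform.  Time zero is the release of the particle at the trachea.
    """
    base = partition_flows(tree, 1.0, fluid)
    steps = []
    t = 0.0
    for g in sorted(gen_flows):
        q0 = gen_flows[g]
        if q0 <= 0:
            raise ValueError("policy flows must be positive")
        states = tree.generation_states(g)
        taus = []
        for s in states:
            u = base.velocities[s] * q0  # velocity at inlet flow q0
            taus.append(tree.segments[s].length / u)
        tau = sum(taus) / len(taus)
        steps.append(PolicyStep(generation=g, q0=q0, t_start=t, t_end=t + tau))
        t += tau
    return FlowPolicy(steps=tuple(steps), name="generation-indexed")


def evaluate_policy(tree: AirwayTree, particle: Particle, fluid: Fluid,
                    policy: FlowPolicy,
                    constants: PhysicalConstants = CONSTANTS,
                    base_flow: FlowState | None = None) -> PolicyEvaluation:
    """Propagate a particle cohort generation by generation under a policy.

    At step g the surviving probability mass sits at generation g; all
    tree flows are rescaled to that step's inlet flow, each segment
    captures ``1 - p_e`` of its incoming mass, and survivors split to the
    daughters by fractional flow (terminals send survivors to escape).
    A constant policy reproduces the absorbing-chain solution exactly.
    """
    if base_flow is None:
        base_flow = partition_flows(tree, 1.0, fluid)
    n_gen = tree.n_generations
    if policy.steps[-1].generation < n_gen and not policy.is_constant:
        warnings.warn(
            "policy has fewer steps than tree generations; the last step's "
            "flow is reused for the remaining generations")
    deposition: dict[int, float] = {s: 0.0 for s in tree.segments}
    mass: dict[int, float] = {tree.root: 1.0}
    escape = 0.0
    gen_flows: dict[int, float] = {}
    for g in range(1, n_gen + 1):
        q0 = policy.flow_at_generation(g)
        gen_flows[g] = q0
        flow = rescale_flows(base_flow, q0)
        states = [s for s in tree.generation_states(g) if mass.get(s, 0.0) > 0.0]
        if not states:
            continue
        p_e = _escape_probs_for(tree, flow, particle, fluid, constants, states)
        next_mass: dict[int, float] = {}
        for s in states:
            m = mass[s]
            pe = p_e[s]
            deposition[s] += m * (1.0 - pe)
            ds = tree.daughters(s)
            if not ds:
                escape += m * pe
            else:
                for d in ds:
                    split = flow.fractions[d] / flow.fractions[s]
                    next_mass[d] = next_mass.get(d, 0.0) + m * pe * split
        mass = next_mass
    return PolicyEvaluation(escape=escape, deposition=deposition,
                            generation_flows=gen_flows, policy=policy)


def _escape_probs_for(tree, flow, particle, fluid, constants, states):
    from .physics import ModelValidityWarning, deposition_probabilities
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelValidityWarning)
        for s in states:
            out[s] = deposition_probabilities(flow.flows[s], tree.tube(s),
                                              particle, fluid, constants).p_e
    return out


def reference_policies(tree: AirwayTree, particle: Particle, fluid: Fluid,
                       q_range: tuple[float, float] = DEFAULT_FLOW_RANGE,
                       constants: PhysicalConstants = CONSTANTS,
                       ) -> dict[str, FlowPolicy]:
    """The four standard comparison policies.

    Constant minimum, constant mid (log-midpoint of the admissible
    range), constant maximum, and the per-generation optimal waveform.
    """
    q_lo, q_hi = q_range
    gen_flows, _ = optimal_generation_flows(tree, particle, fluid, q_range,
                                            constants)
    optimal = policy_to_time(gen_flows, tree, fluid)
    optimal = FlowPolicy(steps=optimal.steps, name="optimal")
    return {
        "constant_min": FlowPolicy.constant(q_lo, name="constant_min"),
        "constant_mid": FlowPolicy.constant(math.sqrt(q_lo * q_hi),
                                            name="constant_mid"),
        "constant_max": FlowPolicy.constant(q_hi, name="constant_max"),
        "optimal": optimal,
    }
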
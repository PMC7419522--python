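"""Absorbing Markov chain over airway states.

States 1..N are the airway segments in breadth-first order.  Every
segment also owns an absorbing *capture* state (deposition on its wall),
and one global absorbing *escape* state represents delivery beyond the
terminal bronchioles (the alveolar space).  From a suspended state the
particle either deposits (probability ``1 - p_e``) or transits, with the
transit probability split between the daughters in proportion to their
fractional flows; from a terminal segment the transit probability goes
to the escape state.

Because particles only move root-ward to leaf-ward, the transient block
of the chain is strictly upper triangular in breadth-first order and the
absorption probabilities follow from one sparse triangular solve —
no time stepping, no truncation error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve_triangular

from .flow import FlowState
from .physics import (CONSTANTS, Fluid, ModelValidityWarning, Particle,
                      PhysicalConstants, deposition_probabilities)
from .tree import AirwayTree

__all__ = ["TransitionMatrix", "DepositionResult", "segment_escape_probs",
           "build_transition_matrix", "solve_absorption", "path_escape",
           "total_escape", "monte_carlo_absorption"]


def segment_escape_probs(tree: AirwayTree, flow: FlowState, particle: Particle,
                         fluid: Fluid,
                         constants: PhysicalConstants = CONSTANTS,
                         ) -> dict[int, float]:
    """Per-segment escape probability p_e at each segment's local flow."""
    if set(flow.fractions) != set(tree.segments):
        raise ValueError("flow state does not match tree")
    p_e = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ModelValidityWarning)
        for s in tree.segments:
            probs = deposition_probabilities(flow.flows[s], tree.tube(s),
                                             particle, fluid, constants)
            p_e[s] = probs.p_e
    return p_e


@dataclass(frozen=True)
class TransitionMatrix:
    """Sparse row-stochastic transition matrix.

    Column layout: airway states (positions ``0..N-1`` for states in
    ``order``), then one capture state per segment (same order), then the
    terminal escape state last.
    """

    matrix: sp.csr_matrix
    order: tuple[int, ...]  # airway state ids, breadth-first
    tree: AirwayTree
    flow: FlowState
    escape_probs: dict[int, float]

    @property
    def n_airway(self) -> int:
        return len(self.order)

    def capture_column(self, state: int) -> int:
        return self.n_airway + self.order.index(state)

    @property
    def escape_column(self) -> int:
        return 2 * self.n_airway

    def aggregated(self) -> np.ndarray:
        """Dense (N+2)x(N+2) matrix with a single pooled capture column.

        Matches the compact tabular form: airway states, then one
        "captured" column, then the escape column.
        """
        n = self.n_airway
        M = self.matrix.toarray()
        out = np.zeros((n + 2, n + 2))
        out[:n, :n] = M[:n, :n]
        out[:n, n] = M[:n, n:2 * n].sum(axis=1)
        out[:n, n + 1] = M[:n, 2 * n]
        out[n, n] = 1.0
        out[n + 1, n + 1] = 1.0
        return out


def build_transition_matrix(tree: AirwayTree, flow: FlowState,
                            particle: Particle, fluid: Fluid,
                            constants: PhysicalConstants = CONSTANTS,
                            ) -> TransitionMatrix:
    """Assemble the sparse absorbing chain for one tree/flow/particle."""
    p_e = segment_escape_probs(tree, flow, particle, fluid, constants)
    order = tuple(sorted(tree.segments))
    idx = {s: i for i, s in enumerate(order)}
    n = len(order)
    rows, cols, vals = [], [], []
    for s in order:
        i = idx[s]
        ds = tree.daughters(s)
        if ds:
            for d in ds:
                split = flow.fractions[d] / flow.fractions[s]
                rows.append(i)
                cols.append(idx[d])
                vals.append(p_e[s] * split)
        else:
            rows.append(i)
            cols.append(2 * n)
            vals.append(p_e[s])
        rows.append(i)
        cols.append(n + i)
        vals.append(1.0 - p_e[s])
    for j in range(n, 2 * n + 1):  # absorbing states are sticky
        rows.append(j)
        cols.append(j)
        vals.append(1.0)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(2 * n + 1, 2 * n + 1))
    return TransitionMatrix(matrix=M, order=order, tree=tree, flow=flow,
                            escape_probs=dict(p_e))


@dataclass(frozen=True)
class DepositionResult:
    """Absorption solution: where the particle ends up."""

    capture: dict[int, float]  # state -> deposition probability
    escape: float  # total probability of leaving through the terminals
    escape_by_terminal: dict[int, float]
    start_state: int

    def total(self) -> float:
        return sum(self.capture.values()) + self.escape


def solve_absorption(T: TransitionMatrix, start_state: int | None = None,
                     ) -> DepositionResult:
    """Exact absorption probabilities for a particle released suspended.

    Solves ``(I - Q)^T y = e_start`` for the expected visit counts ``y``
    over the transient (airway) states; the transient block ``Q`` is
    strictly triangular in breadth-first order, so a sparse triangular
    solve gives the exact answer.  Absorption into capture state k is
    ``y_k (1 - p_e_k)``; escape is the sum of ``y_t p_e_t`` over
    terminals ``t``.
    """
    tree = T.tree
    start = tree.root if start_state is None else start_state
    if start not in tree.segments:
        raise ValueError(f"unknown start state {start}")
    n = T.n_airway
    idx = {s: i for i, s in enumerate(T.order)}
    Q = T.matrix[:n, :n]
    A = (sp.identity(n, format="csr") - Q).T.tocsr()
    e = np.zeros(n)
    e[idx[start]] = 1.0
    y = spsolve_triangular(A, e, lower=True)
    capture = {s: float(y[idx[s]] * (1.0 - T.escape_probs[s])) for s in T.order}
    esc_by_t = {t: float(y[idx[t]] * T.escape_probs[t])
                for t in tree.terminals}
    return DepositionResult(capture=capture,
                            escape=float(sum(esc_by_t.values())),
                            escape_by_terminal=esc_by_t,
                            start_state=start)


def path_escape(tree: AirwayTree, flow: FlowState, particle: Particle,
                fluid: Fluid, path: list[int],
                constants: PhysicalConstants = CONSTANTS) -> float:
    """Escape probability along one root-to-terminal path.

    ``P_e = (Q_n / Q_0) * prod_k p_e_k``: the product of segment escape
    probabilities weighted by the terminal segment's fractional flow.
    """
    if not path or path[0] != tree.root:
        raise ValueError("path must start at the root")
    for a, b in zip(path, path[1:]):
        if b not in tree.daughters(a):
            raise ValueError(f"{b} is not a daughter of {a}: disconnected path")
    if tree.daughters(path[-1]):
        raise ValueError("path must end at a terminal segment")
    p_e = segment_escape_probs(tree, flow, particle, fluid, constants)
    prod = 1.0
    for s in path:
        prod *= p_e[s]
    return (flow.fractions[path[-1]] / flow.fractions[tree.root]) * prod


def total_escape(tree: AirwayTree, flow: FlowState, particle: Particle,
                 fluid: Fluid, constants: PhysicalConstants = CONSTANTS,
                 ) -> float:
    """Total tree escape: the sum of path escapes over all terminals."""
    p_e = segment_escape_probs(tree, flow, particle, fluid, constants)
    total = 0.0
    for path in tree.paths():
        prod = 1.0
        for s in path:
            prod *= p_e[s]
        total += flow.fractions[path[-1]] * prod
    return total


def monte_carlo_absorption(T: TransitionMatrix, n_walkers: int, seed: int,
                           start_state: int | None = None,
                           ) -> DepositionResult:
    """Stochastic check of the absorption solve: simulate independent
    walkers through the chain and report empirical absorption fractions.
    """
    tree = T.tree
    start = tree.root if start_state is None else start_state
    rng = np.random.default_rng(seed)
    idx = {s: i for i, s in enumerate(T.order)}
    n = T.n_airway
    M = T.matrix.tocsr()
    states = np.full(n_walkers, idx[start], dtype=np.int64)
    # the chain is feed-forward: depth+1 steps absorb every walker
    for _ in range(tree.n_generations + 1):
        transient = states < n
        if not transient.any():
            break
        for s in np.unique(states[transient]):
            row = M.getrow(int(s))
            sel = states == s
            p = row.data / row.data.sum()
            nexts = rng.choice(row.indices, size=int(sel.sum()), p=p)
            states[sel] = nexts
    counts = np.bincount(states, minlength=2 * n + 1)
    capture = {s: counts[n + idx[s]] / n_walkers for s in T.order}
    escape = counts[2 * n] / n_walkers
    return DepositionResult(capture=capture, escape=float(escape),
                            escape_by_terminal={}, start_state=start)
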
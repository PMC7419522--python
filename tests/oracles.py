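"""Independent oracles used by the test suite.

Each oracle is a deliberately different computational route from the
implementation it checks: a closed-form-trajectory Monte Carlo for
sedimentation, a dense resistor-network linear solve for subtree input
resistances, and a plain log-grid argmin search for the single-tube
optimal flow.
"""

from __future__ import annotations

import numpy as np


def settling_monte_carlo(Q: float, L: float, D: float, v_s: float,
                         n: int = 100_000, seed: int = 0,
                         ) -> tuple[float, float]:
    """Deposition fraction in a horizontal tube by direct particle tracking.

    Particles enter with uniform concentration over the cross-section
    (hence flux-weighted counts), are advected axially by the local
    Poiseuille velocity and settle at constant ``v_s``.  The wall-hit
    time and the axial distance covered by then are both closed-form in
    the entry position, so there is no integration error.  Returns the
    weighted deposition fraction and its standard error.
    """
    rng = np.random.default_rng(seed)
    R = D / 2.0
    r = R * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    y = r * np.cos(phi)  # horizontal offset
    z = r * np.sin(phi)  # vertical offset, gravity along -z
    u_mean = Q / (np.pi * R ** 2)
    # time until the particle, falling at v_s, reaches the wall below
    T = (z + np.sqrt(R ** 2 - y ** 2)) / v_s
    # axial distance: integral of 2*u_mean*(1 - (y^2 + z(t)^2)/R^2) dt
    x = 2.0 * u_mean * (
        T - (y ** 2 * T + z ** 2 * T - z * v_s * T ** 2
             + v_s ** 2 * T ** 3 / 3.0) / R ** 2)
    deposited = x <= L
    w = 2.0 * (1.0 - (r / R) ** 2)  # local-to-mean velocity ratio
    p = float(np.sum(w * deposited) / np.sum(w))
    se = float(np.sqrt(np.sum(w ** 2 * (deposited - p) ** 2)) / np.sum(w))
    return p, se


def resistor_network_input_resistance(tree, mu: float) -> float:
    """Input resistance of the whole tree by a dense nodal linear solve.

    Nodes are segment outlets plus the inlet; every terminal outlet is
    grounded at zero pressure; unit flow is injected at the inlet; the
    inlet pressure then equals the input resistance.  Kirchhoff current
    balance is assembled as a dense linear system, independently of the
    recursive parallel-series reduction it checks.
    """
    states = sorted(tree.segments)
    node = {s: i + 1 for i, s in enumerate(states)}  # node 0 = inlet
    n_nodes = len(states) + 1
    G = np.zeros((n_nodes, n_nodes))
    rhs = np.zeros(n_nodes)
    terminals = set(tree.terminals)

    def conductance(s):
        seg = tree.segments[s]
        return np.pi * seg.diameter ** 4 / (128.0 * mu * seg.length)

    for s in states:
        g = conductance(s)
        a = 0 if tree.segments[s].parent is None else node[tree.segments[s].parent]
        b = node[s]
        G[a, a] += g
        G[b, b] += g
        G[a, b] -= g
        G[b, a] -= g
    rhs[0] = 1.0  # unit inlet flow
    free = [0] + [node[s] for s in states if s not in terminals]
    sol = np.linalg.solve(G[np.ix_(free, free)], rhs[free])
    return float(sol[0])


def grid_argmin_flow(p_c, q_lo: float, q_hi: float, n: int = 2000) -> float:
    """Brute-force argmin of a capture-probability curve on a log grid."""
    grid = np.logspace(np.log10(q_lo), np.log10(q_hi), n)
    vals = np.array([p_c(q) for q in grid])
    return float(grid[int(np.argmin(vals))])
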
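"""Per-segment aerosol deposition kernels.

A particle traversing a cylindrical airway segment can be captured by
three independent mechanisms:

* **gravitational sedimentation** — settling across the lumen during
  transit; controlled by the ratio ``kappa`` of the axial transit time to
  the time to settle one lumen diameter,
* **inertial impaction** — failure to follow curving streamlines;
  controlled by the Stokes number ``Stk``,
* **Brownian diffusion** — radial thermal motion; controlled by the
  dimensionless residence-time parameter ``Delta``.

Each mechanism has a closed-form capture probability for Poiseuille flow
in a tube; the segment escape probability is the product of the three
individual escape probabilities, assuming independence.

All functions take strict SI units (m, kg, s, K, Pa·s, m³/s).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "Particle",
    "Fluid",
    "PhysicalConstants",
    "TubeSpec",
    "DepositionProbs",
    "AIR_BODY",
    "CONSTANTS",
    "DEFAULT_FLOW_RANGE",
    "ModelValidityWarning",
    "cunningham_correction",
    "settling_velocity",
    "sedimentation_probability",
    "stokes_number",
    "impaction_probability",
    "diffusion_parameter",
    "diffusion_probability",
    "escape_probability",
    "reynolds_number",
    "deposition_probabilities",
    "capture_minimizing_flow",
]

# Stokes-number ceiling of the validated linear impaction law.
STK_LINEAR_LIMIT = 0.15
# Diffusion parameter at and above which capture is certain.
DELTA_CUTOFF = 0.16853
# Coefficients of the four-exponential diffusion deposition formula.
_PD_COEFS = ((0.819, 14.63), (0.0967, 89.22), (0.0325, 228.0))
_PD_23_COEF = (0.0509, 125.9)


class ModelValidityWarning(UserWarning):
    """A kernel was evaluated outside its validated regime."""


@dataclass(frozen=True)
class Particle:
    """Spherical aerosol particle: diameter ``d_p`` and density ``rho_p``."""

    diameter: float  # m
    density: float  # kg/m^3

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("particle diameter and density must be positive")


@dataclass(frozen=True)
class Fluid:
    """Carrier gas properties.

    ``mean_free_path`` feeds the Cunningham slip correction; the default
    fluid is dry air at body temperature (37 °C).
    """

    viscosity: float  # Pa s
    density: float  # kg/m^3
    temperature: float  # K
    mean_free_path: float = 0.070e-6  # m

    def __post_init__(self) -> None:
        if min(self.viscosity, self.density, self.temperature,
               self.mean_free_path) <= 0:
            raise ValueError("all fluid properties must be positive")


@dataclass(frozen=True)
class PhysicalConstants:
    gravity: float = 9.81  # m/s^2
    boltzmann: float = 1.380649e-23  # J/K


@dataclass(frozen=True)
class TubeSpec:
    """A straight cylindrical segment.

    ``angle`` is the signed elevation of the tube axis above the
    horizontal plane, in radians.  ``angle = -pi/2`` means the axis is
    parallel to gravity with the flow descending; a horizontal tube has
    ``angle = 0``.
    """

    length: float  # m
    diameter: float  # m
    angle: float = 0.0  # rad, in [-pi/2, pi/2]

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("tube length and diameter must be positive")
        if not -math.pi / 2 - 1e-12 <= self.angle <= math.pi / 2 + 1e-12:
            raise ValueError("gravity angle must lie in [-pi/2, pi/2]")

    @property
    def area(self) -> float:
        return math.pi * (self.diameter / 2.0) ** 2


AIR_BODY = Fluid(viscosity=1.9e-5, density=1.14, temperature=310.15)
CONSTANTS = PhysicalConstants()
# Physiologically admissible inlet flows, 0.0001–1 L/s in SI.
DEFAULT_FLOW_RANGE = (1e-7, 1e-3)


@dataclass(frozen=True)
class DepositionProbs:
    """Capture/escape probabilities of one segment plus diagnostics."""

    p_s: float
    p_i: float
    p_d: float
    p_e: float
    p_c: float
    kappa: float
    stokes: float
    delta: float
    reynolds: float
    mean_velocity: float
    settling_velocity: float
    cunningham: float
    d_s: float


def cunningham_correction(d_p: float, mean_free_path: float = 0.070e-6,
                          a1: float = 1.257, a2: float = 0.4,
                          a3: float = 1.1) -> float:
    """Cunningham slip correction factor.

    ``C_c = 1 + (2 lambda / d_p) (a1 + a2 exp(-a3 d_p / (2 lambda)))``;
    tends to 1 in the continuum limit and grows without bound for
    free-molecular (nanometre) particles.
    """
    if d_p <= 0 or mean_free_path <= 0:
        raise ValueError("d_p and mean_free_path must be positive")
    kn2 = 2.0 * mean_free_path / d_p  # twice the Knudsen number
    return 1.0 + kn2 * (a1 + a2 * math.exp(-a3 / kn2))


def settling_velocity(particle: Particle, fluid: Fluid,
                      constants: PhysicalConstants = CONSTANTS) -> float:
    """Stokes-law terminal settling velocity with slip correction.

    ``v_s = rho_p g d_p^2 C_c / (18 mu)``; air buoyancy is neglected
    (particle density ~1000x the gas density).
    """
    c_c = cunningham_correction(particle.diameter, fluid.mean_free_path)
    return (particle.density * constants.gravity * particle.diameter ** 2
            * c_c / (18.0 * fluid.viscosity))


def _p_s_of_kappa(kappa: float) -> float:
    k = min(max(kappa, 0.0), 1.0)
    if k == 0.0:
        return 0.0
    k13 = k ** (1.0 / 3.0)
    root = math.sqrt(max(1.0 - k13 * k13, 0.0))
    return min(
        (2.0 / math.pi) * (2.0 * k * root - k13 * root + math.asin(min(k13, 1.0))),
        1.0,
    )


def sedimentation_probability(Q: float, tube: TubeSpec, particle: Particle,
                              fluid: Fluid,
                              constants: PhysicalConstants = CONSTANTS,
                              ) -> tuple[float, float, float]:
    """Gravitational capture probability in Poiseuille tube flow.

    Returns ``(p_s, kappa, d_s)`` where ``kappa`` is the settling-to-
    transit time ratio (clipped to [0, 1] before the closed form) and
    ``d_s`` is the particle-diameter validity bound: the closed form
    assumes ``d_p << d_s``.

    At ``Q = 0`` the residence time is infinite and capture is certain
    (``p_s = 1``), except for a vertical tube where settling never
    reaches the wall.
    """
    if Q < 0:
        raise ValueError("flow must be non-negative")
    v_s = settling_velocity(particle, fluid, constants)
    cos_t = abs(math.cos(tube.angle))
    sin_t = abs(math.sin(tube.angle))
    # exact zeros at the vertical/horizontal orientations (float cos(pi/2) ~ 6e-17)
    if cos_t < 1e-12:
        cos_t = 0.0
    if sin_t < 1e-12:
        sin_t = 0.0
    if Q == 0.0:
        kappa = math.inf if cos_t > 0 else 0.0
        return (_p_s_of_kappa(kappa) if math.isfinite(kappa) else
                (1.0 if cos_t > 0 else 0.0)), kappa, 0.0
    u_mean = Q / tube.area
    kappa = 0.75 * (v_s / u_mean) * (tube.length / tube.diameter) * cos_t
    if sin_t > 0:
        d_s = math.sqrt(72.0 * Q * fluid.viscosity
                        / (sin_t * particle.density * constants.gravity
                           * math.pi * tube.diameter ** 2))
        if particle.diameter > 0.1 * d_s:
            warnings.warn(
                "particle diameter is not small relative to the "
                "sedimentation validity bound d_s; p_s may be inaccurate",
                ModelValidityWarning, stacklevel=2)
    else:
        d_s = math.inf
    return _p_s_of_kappa(kappa), kappa, d_s


def stokes_number(Q: float, D: float, particle: Particle, fluid: Fluid) -> float:
    """``Stk = U0 rho_p d_p^2 C_c / (18 mu D)`` with U0 the mean velocity."""
    if D <= 0:
        raise ValueError("diameter must be positive")
    if Q < 0:
        raise ValueError("flow must be non-negative")
    if Q == 0.0:
        return 0.0
    u0 = Q / (math.pi * (D / 2.0) ** 2)
    c_c = cunningham_correction(particle.diameter, fluid.mean_free_path)
    return (u0 * particle.density * particle.diameter ** 2 * c_c
            / (18.0 * fluid.viscosity * D))


def impaction_probability(stk: float) -> float:
    """Linear impaction law ``p_i = 1.606 Stk + 0.0023``, clipped to [0, 1].

    Validated for ``Stk < 0.15``; a warning is emitted above that.
    """
    if stk < 0:
        raise ValueError("Stokes number must be non-negative")
    if stk > STK_LINEAR_LIMIT:
        warnings.warn(
            f"Stk={stk:.3g} exceeds the validated linear range "
            f"(Stk <= {STK_LINEAR_LIMIT})", ModelValidityWarning, stacklevel=2)
    return min(max(1.606 * stk + 0.0023, 0.0), 1.0)


def diffusion_parameter(tube: TubeSpec, Q: float, particle: Particle,
                        fluid: Fluid,
                        constants: PhysicalConstants = CONSTANTS) -> float:
    """Dimensionless diffusion deposition parameter.

    ``Delta = (k_B T C_c / 3 pi mu d_p) * (L / U) / (4 (D/2)^2)`` —
    the Stokes–Einstein diffusivity scaled by residence time and lumen
    cross-section.  ``Q = 0`` gives infinite residence, ``Delta = inf``.
    """
    if Q < 0:
        raise ValueError("flow must be non-negative")
    if Q == 0.0:
        return math.inf
    c_c = cunningham_correction(particle.diameter, fluid.mean_free_path)
    diffusivity = (constants.boltzmann * fluid.temperature * c_c
                   / (3.0 * math.pi * fluid.viscosity * particle.diameter))
    u_mean = Q / tube.area
    return diffusivity * (tube.length / u_mean) / (4.0 * (tube.diameter / 2.0) ** 2)


def diffusion_probability(delta: float) -> float:
    """Diffusional capture probability for Poiseuille tube flow.

    Four-exponential expansion below the cutoff ``Delta = 0.16853``;
    certain capture at or above it.  The printed expansion is ~0.93 just
    below the cutoff, so the rule is discontinuous there; it is applied
    exactly as stated.
    """
    if delta < 0:
        raise ValueError("Delta must be non-negative")
    if delta >= DELTA_CUTOFF:
        return 1.0
    p = 1.0
    for a, b in _PD_COEFS:
        p -= a * math.exp(-b * delta)
    a, b = _PD_23_COEF
    p -= a * math.exp(-b * delta ** (2.0 / 3.0))
    return min(max(p, 0.0), 1.0)


def escape_probability(p_s: float, p_i: float, p_d: float) -> tuple[float, float]:
    """Combine the three capture mechanisms assuming independence.

    Returns ``(p_e, p_c)`` with ``p_e = (1-p_s)(1-p_i)(1-p_d)``.
    """
    for p in (p_s, p_i, p_d):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    p_e = (1.0 - p_s) * (1.0 - p_i) * (1.0 - p_d)
    return p_e, 1.0 - p_e


def reynolds_number(Q: float, D: float, fluid: Fluid) -> float:
    """Tube Reynolds number ``Re = 4 rho Q / (pi D mu)``."""
    if D <= 0:
        raise ValueError("diameter must be positive")
    if Q < 0:
        raise ValueError("flow must be non-negative")
    return 4.0 * fluid.density * Q / (math.pi * D * fluid.viscosity)


def deposition_probabilities(Q: float, tube: TubeSpec, particle: Particle,
                             fluid: Fluid,
                             constants: PhysicalConstants = CONSTANTS,
                             ) -> DepositionProbs:
    """Evaluate all three kernels for one segment at flow ``Q``."""
    p_s, kappa, d_s = sedimentation_probability(Q, tube, particle, fluid, constants)
    stk = stokes_number(Q, tube.diameter, particle, fluid)
    p_i = impaction_probability(stk)
    delta = diffusion_parameter(tube, Q, particle, fluid, constants)
    p_d = diffusion_probability(delta) if math.isfinite(delta) else 1.0
    p_e, p_c = escape_probability(p_s, p_i, p_d)
    return DepositionProbs(
        p_s=p_s, p_i=p_i, p_d=p_d, p_e=p_e, p_c=p_c,
        kappa=kappa, stokes=stk, delta=delta,
        reynolds=reynolds_number(Q, tube.diameter, fluid),
        mean_velocity=Q / tube.area if Q > 0 else 0.0,
        settling_velocity=settling_velocity(particle, fluid, constants),
        cunningham=cunningham_correction(particle.diameter, fluid.mean_free_path),
        d_s=d_s)


def capture_minimizing_flow(tube: TubeSpec, particle: Particle, fluid: Fluid,
                            q_range: tuple[float, float] = DEFAULT_FLOW_RANGE,
                            constants: PhysicalConstants = CONSTANTS,
                            n_grid: int = 200) -> float:
    """Flow minimizing the combined capture probability in one tube.

    The objective 1 - p_e(Q) is smooth but can be nearly flat on a log
    axis, so a log-spaced grid seeds a bounded scalar minimization
    bracketed by the best grid point's neighbours.  Boundary minima are
    legitimate results (e.g. nanoparticles are always best served by the
    maximum admissible flow).
    """
    q_lo, q_hi = q_range
    if not (0 < q_lo < q_hi):
        raise ValueError("flow range must satisfy 0 < lower < upper")

    def p_c(q: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelValidityWarning)
            return deposition_probabilities(q, tube, particle, fluid, constants).p_c

    grid = np.logspace(math.log10(q_lo), math.log10(q_hi), n_grid)
    values = np.array([p_c(q) for q in grid])
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(p_c, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-4 * grid[i]})
    best_q, best_v = float(grid[i]), float(values[i])
    if res.fun < best_v:
        best_q, best_v = float(res.x), float(res.fun)
    # a boundary of the admissible range may beat the refined interior point
    for q_edge, v_edge in ((q_lo, values[0]), (q_hi, values[-1])):
        if v_edge < best_v:
            best_q, best_v = float(q_edge), float(v_edge)
    return best_q
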
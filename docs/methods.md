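# Methods

## Model overview and assumptions

`aerotree` treats particle transport through the conducting airways as a
discrete-state absorbing Markov chain. Each airway segment is one state;
a particle in a segment is either suspended in the lumen flow or
deposited on the wall. Within a segment the particle has no position:
every segment is entered with an (implicitly) uniform cross-sectional
particle distribution, and the three capture mechanisms act
independently, so the per-segment escape probability is the product
`p_e = (1−p_s)(1−p_i)(1−p_d)`. Transit probability is split between the
two daughters in proportion to their fractional flows. Capture states
and the terminal escape state are absorbing. Because transport is
strictly parent→daughter, the transient block of the chain is strictly
upper triangular in breadth-first state order; absorption probabilities
are computed by a single sparse triangular solve (`scipy.sparse`), with
no time-stepping or truncation error. The equivalent path formulation —
total escape as the sum over all root-to-terminal paths of the
flow-weighted product of segment escape probabilities — is implemented
independently and serves as a structural cross-check in the tests.

Key physical assumptions, all deliberate simplifications:

- laminar, fully developed Poiseuille flow in every segment; flow
  partitioning by linear resistance (`R = 128μL/πD⁴`, daughter subtrees
  in parallel), with no inertial or bifurcation-angle corrections;
- rigid airways (no compliance, no dimension changes during the breath)
  and no peripheral compliance differences: a terminal subtree's
  resistance is the terminal segment's own resistance;
- independence of the three capture mechanisms within a segment;
- no exhalation phase and no upper (extrathoracic) airway;
- fractional flows depend on geometry only, so a time-varying inlet flow
  rescales all local flows linearly.

## Deposition kernels

The sedimentation, impaction and diffusion probabilities are the
closed-form Poiseuille-tube results stated in the README. Two auxiliary
quantities are not fixed by those formulas and use standard aerosol
physics:

- **Cunningham slip correction**
  `C_c = 1 + (2λ/d_p)(1.257 + 0.4·exp(−1.1·d_p/2λ))` with mean free
  path `λ = 0.070 µm` (air at body temperature); constants overridable.
- **Settling velocity** by Stokes law, `v_s = ρ_p g d_p² C_c / 18μ`,
  neglecting air buoyancy (particle density ~10³ × gas density).

Defaults (all overridable via config): dry air at 37 °C with
`μ = 1.9e−5 Pa·s`, `ρ = 1.14 kg/m³`, `T = 310.15 K`; `g = 9.81 m/s²`;
`k_B = 1.380649e−23 J/K`; particle density 1000 kg/m³ (water);
admissible inlet flows 0.0001–1 L/s (the physiological range).

Numerical conventions at the edges:

- `κ` uses `|cosθ|` and is clipped to [0, 1] before the sedimentation
  formula (`κ ≥ 1` means settling beats transit: certain capture); at
  exactly vertical orientations the cosine is snapped to zero so
  `p_s = 0` holds exactly in floating point.
- `p_i` is clipped to [0, 1]; a `ModelValidityWarning` is emitted above
  `Stk = 0.15` (outside the validated linear range) and when
  `d_p > 0.1·d_s`, the sedimentation formula's small-particle bound
  (`d_s` uses `|sinθ|` and is infinite for horizontal tubes).
- `Q = 0` means infinite residence: `p_s = p_d = 1` (except `p_s = 0`
  for a vertical tube), `p_i = 0.0023` (the zero-Stokes intercept).
- The diffusion rule is applied exactly as printed: the four-exponential
  expansion below `Δ = 0.16853`, exactly 1 at or above. The expansion
  evaluates to ≈ 0.93 just below the cutoff, so the rule is
  discontinuous there; this is a property of the printed formulation and
  is preserved, not smoothed.

### Single-tube optimal flow

`capture_minimizing_flow` minimizes `1 − p_e(Q)` with a 200-point
log-spaced grid scan followed by bounded scalar minimization between the
best grid point's neighbours (relative tolerance 1e−4 in `Q`); the
admissible-range endpoints are compared explicitly, so boundary minima
(typical for diffusion-dominated nanoparticles) are returned exactly.

A consequence of the printed kernels worth knowing: for a 0.35 µm
particle in the benchmark bronchus the combined capture is *not*
strictly monotone down to the maximum flow — the linear impaction term's
slope overtakes the flattening diffusion decline, leaving a very shallow
interior minimum near 0.16 L/s (capture at 1 L/s is ~9% above the
minimum, invisible at plot resolution). The flow-dependent
sedimentation-plus-diffusion part alone is strictly monotone. The test
suite asserts both the shallow-minimum behavior (unit tests) and the
idealized strict monotonicity (acceptance check, which consequently
fails and documents the model property).

## Airway tree and synthetic generator

Segments carry 3-D start/end coordinates, diameter, a digit label
(trachea `"1"`, daughters append `1`/`2`) and a breadth-first Markov
state index; gravity is a unit vector on the tree (default `(0,0,−1)`),
so body orientation is changed by rigidly rotating branch vectors about
the inlet (the rotation origin is immaterial: only directions enter the
kernels). Trees read from CSV/JSON may be incomplete binary trees;
segments with exactly one daughter are rejected, and file ids are
remapped breadth-first with the lookup recorded on the tree.

The synthetic generator emulates an adult human conducting-airway tree
down to terminal bronchioles: a full binary tree (default 12
generations), trachea 12 cm × 18 mm descending along gravity, daughter
length and diameter ratios 0.78 (major) / 0.70 (minor) with the
major/minor roles assigned randomly left/right, branching half-angles
uniform in [20°, 50°] at uniform azimuth, all driven by a seeded
generator. This reproduces the features the model is sensitive to —
generation-dependent dimensions and flows, asymmetric flow partitioning,
a broad distribution of branch orientations relative to gravity after a
few generations. It does **not** reproduce lobar anatomy, measured
per-branch human morphometry, airway curvature, or the correlation
structure of real branching angles; passing tests therefore validate
the model machinery and its qualitative behaviors (policy orderings,
rotation sensitivity, constriction effects), not quantitative deposition
in any specific human lung, whose published whole-tree escape values
depend on the measured geometry used there.

A deterministic symmetric 3-generation demo tree and the single printed
benchmark tube (6.3 cm × 1.35 cm third-generation bronchus) ship as
constructor functions for worked examples and exact tests.

## Flow policies

A flow policy is the inlet flow per airway generation (equivalently, per
time window). `optimal_generation_flows` minimizes each segment's own
capture over the local admissible range `f_k·[Q_min, Q_max]`, converts
to inlet-equivalent flow `Q₀* = Q*/f_k` (clipped), and averages
arithmetically within each generation — a generation-local scheme, not a
global joint optimization (the geometric mean is a noted alternative;
the arithmetic mean was chosen as the conventional reading of "average
optimal flow"). `policy_to_time` assigns step g the mean residence time
of generation-g segments at that step's flows; time zero is particle
release at the trachea, not the start of inspiration.

`evaluate_policy` propagates a probability cohort generation by
generation: at step g all surviving mass sits at generation g, flows are
rescaled to that step's inlet flow, each segment captures `1 − p_e` of
its incoming mass and survivors split by fractional flow. Stepping is
per-generation rather than per-unit-time because the chain has no
intra-segment position — finer time steps would add nothing. A constant
policy reproduces the absorbing-chain solution exactly (asserted to
1e−10); a policy with fewer steps than the tree depth reuses its last
flow with a warning. Four reference policies are built in: constant
minimum, constant log-midpoint, constant maximum, and the optimal
waveform.

## Scintigraphy-style projection

The deposition solution is mapped to an isotropic voxel grid (default
5 mm). Voxel centers inside a segment's cylinder share that segment's
capture probability uniformly; a voxel center inside two segments (at a
junction) belongs to the deeper-generation segment, deterministically.
Because 5 mm voxels under-resolve thin peripheral segments, each
segment's voxel values are renormalized to sum exactly to its capture
probability, and a segment owning no voxel center deposits its whole
mass in the voxel containing its midpoint — conservation is exact by
construction (asserted to 1e−9). Escape mass exits per terminal as a
uniform 3×3×3 voxel cube at the terminal's distal end; overlapping
cubes add. The coronal projection sums the grid along the
ventral–dorsal (y) axis and divides by pixel area; images are written as
CSV and 16-bit PNG with a JSON sidecar recording the intensity scale.

## Problem sizes and test design

The test suite exercises trees up to 12 generations (4095 segments) and
Monte-Carlo checks with 1e5 particles/walkers, sizes at which every
check runs in seconds while still separating correct from incorrect
implementations by wide margins. Independent oracles live in
`tests/oracles.py`: a settling Monte Carlo with closed-form wall-hit
times and axial integrals (flux-weighted inlet, i.e. uniform entering
concentration carried by the parabolic profile — the setting under which
the sedimentation formula is exact for horizontal tubes); a dense
nodal-analysis resistor solve; stepwise Monte-Carlo walkers on the
transition matrix; and brute-force log-grid argmin searches.

## Known limitations

- Linear-resistance flow partitioning ignores inertial effects at high
  Reynolds numbers in the first generations and the tendency of flow to
  favor aligned daughters; discrepancies grow peripherally at high flow.
- The impaction law is linear and validated only for `Stk < 0.15`
  (particles ≲ 10 µm at physiological flows); larger particles would
  need a saturating (sigmoidal) law.
- No upper-airway (mouth/throat/larynx) filtering: optimal policies
  apply to the central and lower airways only.
- Generation-local policy optimization is not globally optimal for
  asymmetric trees; whole-tree joint optimization is out of scope.
- No exhalation phase, breath-hold targeting, or intra-breath changes
  of airway dimensions.
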
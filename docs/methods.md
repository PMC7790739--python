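# Methods

`cryptdyn` is a multiscale agent-based model of the intestinal crypt
that couples three layers in every epithelial cell: a Wnt/β-catenin
signalling network extended with a Hippo-dependent sequestration term, a
restriction-point cell-cycle module, and cell-centre mechanics on the
unrolled crypt surface. This note records the model equations, the
parameter choices that matter, the numerical scheme, and what the
reduced-scale simulations used in the tests do and do not show.

## Signalling network

Ten species (nM): free Axin `X`, active destruction complex `D`, free
adhesive molecules `A`, free transcription molecules `T`, and five
β-catenin pools — junctional `C_A`, cytoplasmic `C_C`, transcriptional
(nuclear) `C_T`, degradation-marked `C_U`, and the cytoplasmic
YAP-P/β-catenin complex `C_H` — plus the Wnt target protein `Y`.
Kinetics are mass action except for two saturable steps:

* destruction-complex marking of cytoplasmic β-catenin,
  `p_U · D · C_C / (K_D + C_C)`, feeding `C_U`;
* Hippo-driven sequestration, with binding flux

  `B = p̂_H · c₀ · C_C / (K_H + C_C)`,   c₀ = 1 nM,

  out of `C_C` into `C_H`, first-order unbinding `k_off · C_H` back
  into `C_C`, and decay `d_CH · C_H` of the complex. Binding and
  unbinding exactly conserve β-catenin between the two pools (the
  flux-matching identity tested in the suite); the slow decay is the
  net drain that lowers the nuclear pool under contact inhibition.
  With `p̂_H = 0` the system is the Wnt-only baseline.

Wnt enters through the three "tilde" rates of the Axin/destruction-
complex subsystem (`d̃_X`, `d̃_DX`, `d̃_D`), interpolated linearly
between their Wnt-off (`W = 0`) and Wnt-on (`W = 1`) values. Total
transcription molecules are conserved (`T + C_T` constant), so nine
ODEs describe ten species; the conservation is algebraic and therefore
exact.

Defaults put the Wnt-off/Wnt-on steady states at `C_T ≈ 3.3` and
`22.7 nM`, a destruction-complex ratio of ~14 between the two states,
and — with `p_H = 26,000 h⁻¹`, `K_H = 20 nM` — a Hippo-inhibited
Wnt-on state at `C_T ≈ 19.9 nM`.

## Cell cycle

Five ODEs in the Swat restriction-point family: active pRb, E2F1,
inactive/active cyclin D–Cdk4/6, and phosphorylated pRb. Cyclin D
activation is autocatalytic with a small basal rate, so the module is a
relaxation switch: below a threshold mitogenic input the low-E2F1 state
persists (G1 arrest); above it E2F1 crosses the strict `E2F1 > 1`
restriction point after a delay that lengthens sharply near the
threshold. The mitogenic input is linear in transcriptional β-catenin,
`m = γ · C_T` with gain `γ = 0.0118`; a global time-scale factor (19
dimensionless units per hour) sets the clock. S, G2 and M phases have
fixed durations 5, 4 and 1 h; only G1 is ODE-controlled. At division
both daughters restart from a fixed post-mitotic state
`(pRb, E2F1, CycD_i, CycD_a, pRb-p) = (2, 0.1, 0, 0, 0)`.

### Calibration

Three constants are not inherited from the parent models and were fixed
from single-cell behaviour, before any crypt-level statistic was
measured:

* the coupling gain `γ` places the proliferation cut-off at Wnt level
  `W ≈ 0.65` when Hippo is off. This high cut-off is what makes the
  crypt-level geometry self-consistent: in a homeostatic cell-centre
  crypt, mitosis positions smear about one niche-height above the
  region where viable births occur (cells carried upward during one
  cycle), so a 40%-extent gradient yields births below ~14% of the
  crypt and a mitotic drop-off near 30%, while the full gradient keeps
  a proliferative niche reaching ~70% of the crypt height;
* the time scale gives G1 ≈ 11 h (cycle ≈ 21 h) at the Wnt-on state;
* the complex decay `d_CH = 0.027 h⁻¹` was set by bisection so the
  maximal-Wnt cell under full Hippo signalling (`p̂_H = 26,000 h⁻¹`,
  `K_H = 20 nM`) still cycles, at roughly double the baseline G1,
  instead of arresting; cells at even slightly lower Wnt arrest when
  contact inhibited, and raising the binding rate beyond ~40,000 h⁻¹
  arrests the maximal-Wnt cell too.

## Wnt propagation models

* `M_E1` (static imposed gradient): `W(h) = max(0, 1 − h/θ_W)` in the
  height fraction `h`, read once at the cell's birth position.
* `M_E2` (dynamic): the same field read continuously.
* `M_I` (division-based): `W` is a cell-intrinsic quantity. On
  division the mother's level splits into fractions `0.5 ± ξ`,
  `ξ ~ N(0, σ)` rejection-truncated to keep the fraction in [0, 1]
  (rejection rather than clipping preserves the mean split of exactly
  one half); the two daughter levels sum to the mother's level to
  machine precision. Cells in the basal reservoir (bottom fraction ρ
  of the crypt) are refreshed to `W = 1` every step, after the
  mechanics update. There is no diffusion between cells. With σ = 0
  all levels are exactly dyadic (`2^-k` after k divisions), which the
  initial condition respects by seeding the dyadic ladder closest to a
  linear profile.

## Mechanics and contact inhibition

The cylindrical crypt is unrolled to a band, periodic in x
(circumference 8 cell diameters in the standard runs) and bounded below
by a rigid base at y = 0; cells passing the crypt top (height 16
diameters) are removed. Cells are points joined to their Voronoi
neighbours (Delaunay adjacency, periodic images in x, interaction
cutoff 1.5 diameters) by linear springs (stiffness μ = 15, rest length
1 diameter; newly divided siblings ramp from 0.1 to 1 over 1 h) and
move overdamped, `dr = F/η · dt` with η = 1 and dt = 1/120 h (the
documented stability bound is `dt ≤ η/4μ`). The Voronoi tessellation
is clipped by mirror ghosts at the base and half a diameter above the
top, so cell areas are finite and partition the band exactly.

A cell's "volume" is its Voronoi area; the reference `V_eq = √3/2` is
the area per cell of relaxed hexagonal packing at unit spacing.
Contact inhibition is a step: `p̂_H = p_H` when `V < θ_CI · V_eq`
(with θ_CI 0.6 or 0.9), zero otherwise, and always zero for mutants.
The step form is isolated in `effective_hippo_rate` so alternative
volume dependences are one-line swaps.

APC double mutants have the destruction-complex marking flux set to
zero and are never contact inhibited; their cycle runs at the
maximal-proliferation input (the Wnt-on `C_T`), independent of their
actual Wnt level and volume.

## Numerics

Single-cell integrations use adaptive integrators (RK45 at
rtol 10⁻⁶/atol 10⁻⁹ for trajectories; LSODA plus a Newton polish for
steady states, accepted below an RHS norm of 10⁻⁸ nM/h). Inside the
crypt engine all cells' signalling systems advance together with a
fixed-step RK4 vectorised over cells, sub-stepped 12× below the
mechanics step: the Hippo binding term has a linearised rate of
`p_H/K_H = 1300 h⁻¹` near `C_C = 0`, and dt/12 keeps that mode inside
the RK4 stability region. The cycle ODEs are advanced at the mechanics
step. Concentrations are clamped at zero against integrator
undershoot. The neighbour graph and volumes are rebuilt every third
mechanics step and immediately after any division or removal.

The initial population is a hexagonal lattice (bottom row half a
diameter above the base), relaxed during a burn-in that is excluded
from all statistics (10 h by default; 20 h in the wild-type
comparisons; 40 h for the division-based model, whose emergent gradient
needs about one crypt turnover to replace the seeded profile). The
initial cell-cycle states are desynchronised by giving every cell an
independent uniform head start of up to 14 h, implemented by scaling
each cell's clock during a vectorised pre-integration.

Determinism: one `numpy` Generator per simulation, seeded from the
configuration; ensembles derive per-run seeds from (base seed, run
index). Identical seeds give bit-identical event logs.

## Observables

Spatial profiles use 20 height bins over [0, H]. The mitotic index is
the fraction of resident cells in M phase, averaged over post-burn-in
snapshots (1 h apart); empty bins are NaN, not zero. Cell speeds are
minimum-image displacements between consecutive snapshots; "mean crypt
speed" averages over all cells and post-burn-in snapshot pairs.
Velocity profiles report median and quartiles (linear-interpolation
convention) with whiskers at the extremes. Washout ensembles report
`p = k/n` with the normal-approximation 95% CI
`p ± z₀.₉₇₅ √(p(1−p)/n)`, clipped to [0, 1]; timeouts are excluded
from the denominator and reported separately. The dip-then-rise
feature of noiseless division-based runs is located as the
local-minimum bin (above the reservoir) with the largest subsequent
rise, reported midway between that bin and the next.

## Problem sizes and what the tests show

The standard experiment is one 8×16-diameter crypt (~180 cells) per
condition, 120 simulated hours, with matched seeds across compared
conditions; washout/invasion experiments use a 6×8 crypt. These sizes
run on a single CPU. Relative effects (reductions in mitotic index and
mean speed between CI thresholds or gradient extents, the location of
profile features in height fractions) are robust to this choice;
absolute division counts, speeds and washout probabilities are not, and
full washout probabilities in particular require many hundreds of
simulated hours per run to reach fixation — the reduced invasion
experiments measure the mutant lineage's differential expansion
instead. The synthetic crypts also idealise real tissue: no Paneth
cells or explicit Wnt secretion (the reservoir is a proxy), no
apoptosis, anoikis or live-cell extrusion, fixed S/G2/M durations, no
mutant adhesion changes, and a rigid, non-deforming crypt geometry.
Passing tests therefore validate the model's internal structure and its
relative, qualitative claims — not quantitative agreement with any
particular tissue.

## Known limitations

* The Hippo module is phenomenological: no MST/LATS cascade, no
  nuclear YAP activity; `C_H` is a single lumped cytoplasmic pool.
* The arrest boundary is sharp in `C_T` (a saddle-node of the cycle
  switch), so cells near the proliferation cut-off have very long,
  finely parameter-sensitive G1 phases.
* The homeostatic density sits close to the 90% volume threshold, so
  contact inhibition at `θ_CI = 0.9` operates intermittently as cell
  volumes fluctuate around it; this is the mechanism behind the
  partial (rather than total) suppression of division.
* Spatial statistics near the crypt top include cells whose clipped
  Voronoi areas exceed `V_eq` (the open boundary); these cells are
  never contact inhibited.
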
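# Methods

`vsmcabm` simulates the collective response of vascular smooth muscle cells
(VSMC) to two competing cues on a 2D substrate: cyclic stretch, which cells
avoid by favouring orientations perpendicular to the principal strain, and
collagen-fiber structure, which cells align with.  Populations evolve by
strain-biased stochastic apoptosis and age-gated proliferation, so alignment
can emerge either from active reorientation or purely from selective
turnover.  This note records the model, its parameters, the numerical
choices, and what the shipped defaults do and do not represent.

## Model

**Cells.** Each cell is a circle of radius `R_c` (default 0.3888 um) with a
fixed position, an orientation axis `theta` in `(-pi/2, pi/2]`, and an age
in hours.  Cells do not migrate, deform or push each other; the only
interaction is hard-sphere exclusion at seeding and at daughter placement.
The default radius is deliberately much smaller than a physical VSMC
(~13 um): with the physical radius, rigid circles jam long before the cell
densities observed in culture are reached, because real cells deform to
accommodate neighbours.  The physical radius remains available
(`cell_radius=12.96`) for sensitivity studies.

**Strain cue.** The applied cycle is given per component (x, y, shear) at
its two extremes.  The amplitude tensor is decomposed by Mohr's circle into
principal amplitudes `eps_max >= eps_min` and the principal direction
`theta_p`; the strain-avoidance axis is `theta_csa = theta_p + pi/2`.  A
cell oriented at `theta` experiences

    eps_eff = eps_max * |cos(theta - theta_p)|

and the reorientation stimulus is the clamped linear rescaling
`Z_eff = clip((eps_eff - eps_thres) / (eps_max_param - eps_thres), 0, 1)`
with calibrated window `eps_thres = 0.0`, `eps_max_param = 0.4`.

**Amplitude convention.** A cycle labelled "0-10%" is read, by default, as
an amplitude tensor of half the excursion (`(max - min)/2`, so 0.05 along
x): the oscillation about the cycle mean.  The alternative peak-to-peak
reading (0.10) is available via `strain_convention="peak-to-peak"`.  All
shipped turnover parameters are calibrated under the half-range default and
the two must not be mixed.

**Fiber cue.** A structured substrate carries a synthetic orientation
field: `n` random interior vertices plus the domain corners are Delaunay-
triangulated, each vertex gets an axial von Mises draw (mean `theta_fb`,
concentration `kappa`), and angles inside triangles are interpolated with
linear shape functions.  Orientations are axes, so both sampling and
interpolation happen on doubled angles mapped to unit vectors; the
barycentric resultant is halved back.  This avoids wrap artefacts near
+/- pi/2 at the cost of a slight shrinkage of the resultant where vertex
angles disagree.  The scalar fiber density `phi_f` is 0 for bare PDMS and 1
for dense decellularised tissue; the type admits intermediate values but no
experiment constrains them.  Vertex density defaults to 200 interior
vertices per 1 mm^2 domain (unstated in the source experiments;
configurable), which reproduces an input `kappa` of 5 within ~30% when the
field is re-estimated from dense query samples.

**Blending the cues.** The desired orientation interpolates from the local
fiber axis toward the strain-avoidance axis along the shortest axial arc,
weighted by `w(phi_f) = 1 / (1 + M^(10 * (phi_f - phi_thres)))`.  With
`phi_f = 0` strain dominates (`w ~ 1`); with `phi_f = 1` fibers dominate.
`phi_thres` and `M` cannot be calibrated from experiments in which `phi_f`
only takes the values 0 and 1; the defaults (0.5 and 10) exist solely to
make intermediate-density demonstrations runnable and are flagged as
uncalibrated.

**Rotation.** Per tick a cell rotates toward its desired angle by

    phi_f <  phi_thres:  delta = Z_eff * k_rot_c        (k_rot_c = 0.001 rad/tick)
    phi_f >= phi_thres:  delta = |sin(theta_f - theta)| * k_rot_f   (k_rot_f = 0.1)

(the tie at `phi_f = phi_thres` goes to the fiber regime).  The step is
clamped to the remaining axial distance, so cells settle on the target
instead of entering a limit cycle around it; the rotation direction is the
sign of the shortest axial difference, computed modulo pi so that paths
crossing +/- pi/2 rotate the short way.

**Apoptosis.** Per check, each cell dies with percentage probability
`P_AP = A_apop * eps_cyc + B_apop` (clamped to [0, 100]%), with `eps_cyc`
the cell's own `eps_eff` expressed in percent (`A_apop = 1`,
`B_apop = 1.64`).  Using the per-cell strain rather than the global
amplitude is what produces the orientation-selective death bias; a
global-amplitude mode (`per_cell_strain=False`) is retained for comparison.

**Proliferation.** Each cell's doubling time is
`T_d = A_prolif * eps^2 + B_prolif * eps + C_prolif` hours with fractional
strain (`A_prolif = 3500`, `B_prolif = 500`, `C_prolif = 71`,
`sigma_prolif = 9`; 71 +/- 9 h is the measured doubling time of rat aortic
VSMC).  At each proliferation check a cell divides with probability
`P_DT(age) = (1 + erf((age - T_d) / (sigma * sqrt(2)))) / 2` — the
cumulative Gaussian, which is ~0 at age 0, 1/2 at `T_d` and saturates at 1.
(The 1/2 normalisation is required for `P_DT` to be a probability.)  A
dividing parent searches the full 360-degree ring at one-degree increments
for a tangent position (distance `2 R_c`) that is inside the domain and
overlap-free, picks one uniformly at random, and both parent and daughter
reset to age 0; if no position is free the division is skipped.  Daughters
inherit the parent's orientation (`daughter_orientation="uniform"`
randomises instead).  `B_prolif` carries a 450-vs-500 ambiguity in its
source; both are available as presets (`TURNOVER_PRESETS`), the table value
500 being the default.

**Tick loop.** One tick is one hour.  Per tick, in frozen order: sense and
rotate every cell; apoptosis sweep (on its cadence); advance ages and run
proliferation checks (on their cadence) with sequential daughter placement
in id order; record.  Five independent RNG streams (seeding, fiber field,
apoptosis, proliferation, placement) are spawned from the run seed, so
disabling one mechanism does not perturb another's draws, and identical
config + seed reproduces a run bit-for-bit.

## Frozen calibration of the time/unit conventions

The source experiments fix the parameter *values* but not the cadence of
the stochastic checks, the amplitude convention, or the strain units inside
the two turnover laws — and fold-change targets are meaningless until those
are pinned.  We therefore ran a one-time scan (20 replicate seeds per
combination) over apoptosis cadence {2,3,4,6,8,12,24} ticks, proliferation
cadence {1,2,3,6,12,24} ticks and both amplitude conventions, scored
against the nine reference observables (three unstrained day-3 densities
and six strained fold-change cells), and froze the best combination as the
package default:

* apoptosis check every 4 ticks (4 h), at the per-check probability above;
* proliferation check every 3 ticks (3 h);
* half-range amplitude convention;
* apoptosis law in percent strain, doubling-time law in fractional strain;
* initial ages uniform on `[0, C_prolif]` hours.

Under these defaults the simulator reproduces the three unstrained day-3
densities within ~1% and five of the six strained fold-change cells within
0.07 absolute.  These settings are part of the calibrated parameter set:
changing any of them invalidates the shipped turnover constants.

Two reference values are *not* reproducible under any scanned combination,
and we record them as model-reference inconsistencies rather than tuning
toward them:

* the 4-6% / 24 h fold change (reference 1.44).  Both turnover laws are
  monotone against strain, so a strained culture can never outgrow the
  unstrained one; yet 1.44 at 24 h exceeds what the unstrained model itself
  produces in 24 h (~1.3) given a 71 h doubling time and uniform initial
  ages.  With 55 starting cells the per-run fold SD is ~0.1, so a high
  single-run draw is the likely origin.  Our value is ~1.21.
* the 10-day perpendicular fold change at `kappa = 100` (reference 1.72).
  Cells aligned along fibers perpendicular to the strain experience almost
  no effective strain, so 10-day growth approaches the unstrained rate —
  which, extrapolated from the same model's own 3-day fold of ~1.67, is
  ~5x over 10 days, not 1.72.  The two reference numbers are mutually
  inconsistent; our simulator, consistent with its 3-day behaviour, gives
  ~4.1.  The monotone trends in `kappa` (perpendicular increasing, parallel
  decreasing) are reproduced; the parallel branch flattens at ~0.08 for
  `kappa >= 5`, so its ordering beyond that point is within replicate noise.

The initial-age rule also carries a literal-reading alternative
(`uniform_c_times_sigma`, ages up to `C_prolif * sigma_prolif` = 639 h);
it produces an immediate division burst inconsistent with every growth
target and is kept only as an option.

## Problem sizes and replication

The reference experiments do not state construct dimensions or replicate
counts.  We use a 1 mm x 1 mm domain (55-133 cells at the reported seeding
densities of 5.5e3 and 1.33e4 cells/cm^2; 305-799 cells/mm^2 in the
unstrained density experiments) and average acceptance experiments over 24
replicate seeds (tests use 20), which puts the standard error of a
fold-change mean near 0.02.  The `B_apop` calibration sweeps 1.20-2.10 in
0.01 steps with 10 seeds per grid point and common random numbers across
the grid, and recovers 1.64 within ~0.1 under the defaults.  The full
strain-response grid search (8 x 13 x 21 combinations) is implemented with
the same machinery; at 10 seeds per point it is an offline computation
(~10 min on one core) and is exercised in tests on reduced grids.

## What the synthetic conditions do and do not show

All growth targets are reproduced on synthetic populations whose positions
are random, non-overlapping points and whose initial orientations are
uniform; the fiber fields are synthetic von Mises/Delaunay constructs, not
traced micrographs.  Passing tests therefore demonstrate the internal
consistency of the model and its calibration, not fidelity to any
particular tissue image: real collagen fields have spatially correlated
dispersion and density, real cells deform, migrate and signal, and mitosis
takes hours rather than being instantaneous.  Within the model, the tests
do establish the central mechanistic claim: with rotation disabled
entirely (`k_rot_c = 0`), selective turnover alone concentrates the
population perpendicular to the strain axis.

## Numerical choices

* All orientations wrap to `(-pi/2, pi/2]` after every update; angular
  differences are shortest signed axial arcs in `[-pi/2, pi/2)`.
* Equibiaxial amplitude tensors have a degenerate principal direction;
  `theta_p = 0` is reported deterministically.
* Fiber interpolation falls back to the dominant-weight vertex in the
  measure-zero case of a vanishing doubled-angle resultant.
* Point-in-triangle lookup uses Delaunay's deterministic simplex search;
  shared-edge ties resolve reproducibly.
* Daughter-placement distance checks use a relative tolerance of 1e-9 on
  `2 R_c` so exact tangency is not rejected by floating-point error; the
  candidate prefilter only tests cells within `4 R_c` of the parent.
* Seeding rejection-samples positions with a retry cap and reports the
  achievable density on failure.
* `T_d` is floored at 1 h to keep pathological parameter combinations
  finite; `P_AP` is clamped to [0, 1].

## Known limitations

* No migration, deformation, contact signalling, ECM remodelling or
  substrate mechanics; strain is prescribed, not solved.
* `phi_thres` and `M` are uncalibrated placeholders.
* The discussion-level rotation rates ("0.007 degrees/h under strain,
  2.8 degrees/h under structure") quoted alongside the source parameters
  are not mutually consistent with `k_rot_c = 0.001 rad/tick` under any
  single tick duration; we calibrate to the tabulated constants and ignore
  those derived rates.
* Fold-change comparisons beyond ~3 days inherit the reference
  inconsistency described above.
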
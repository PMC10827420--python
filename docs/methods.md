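# Model and methods

## The model

The network is a set of `N_fib` rigid, non-stretching spherocylinders
(length `L_fib`, radius `R_fib`) in a periodic cuboid
`[-L_x/2, L_x/2) × [-L_y/2, L_y/2) × [-L_z/2, L_z/2)`, each described by its
centre `X_k` and a non-oriented unit direction `w_k` (`w ≡ -w`; a rod has no
head).  Inertia is neglected (overdamped regime): velocity and angular
velocity are proportional to the summed pair forces and torques, with
friction coefficients `mu_fib L_fib` (translation) and `mu_fib L_fib^3`
(rotation).  All pair interactions use the minimum-image convention, which is
unambiguous because `L_fib + 2 R_fib < min(L)/2` is asserted at startup.

Three pair interactions act:

* **Hertzian repulsion** between spherocylinders whose segment-segment
  distance `d` is below the contact diameter `2 R_fib`:
  `|F| = alpha_rep (2R - d)^{3/2} (2R)^{-1/2}`, applied at the closest
  points, pushing the axes apart.  The `(2R)^{-1/2}` normalization keeps
  `alpha_rep` in the force-per-unit-length units of the reference parameter
  table and makes the two-fibre separation time independent of `R_fib`
  (see below).
* **Crosslink springs.** A link created between two fibres attaches at their
  closest points *at creation time*; the attachment abscissae then advect
  rigidly with each fibre.  The spring is linear with stiffness `alpha_rest`
  and unloaded length `d_link_eq`, attractive when stretched and repulsive
  when compressed, and exerts torques through its attachment lever arms.
* **Nematic alignment torque** at each link, from the potential
  `V = -(alpha_align/2)(w_a . w_b)^2`:
  `T_a = alpha_align (w_a . w_b)(w_a x w_b) = -T_b`.  It vanishes for
  parallel fibres, is invariant under sign flips of either direction, and
  rotates each fibre towards the nearer of its partner's two poles.
  Perpendicular fibres sit at the potential's maximum where the torque is
  exactly zero — an unstable stationary configuration.

Degenerate geometries are resolved deterministically: parallel segments with
a continuum of closest pairs use the midpoint of the overlap interval, and a
coincident closest-point pair (distance exactly zero, direction undefined)
uses a pseudo-random unit vector seeded by the fibre index pair and
orthogonalized against the first fibre's axis, so that runs remain exactly
reproducible.

**Link kinetics.** Linking and unlinking are independent Poisson processes
with frequencies `nu_link` and `nu_unlink`.  A pair is *eligible* to link
while unlinked and within segment distance `d_link_max`; an existing link is
removed only by the unlinking process (no distance- or force-dependent
breakage).  Within a time step `dt` the clocks are thinned to Bernoulli
trials with `p = 1 - exp(-nu dt)`; `dt` is always far below `1/nu` in the
reference regimes, and this composes naturally with the adaptive step.  The
stationary linked probability of a persistently eligible pair is
`chi_link = nu_link/(nu_link + nu_unlink)`; the model is parametrized by
`(nu_link, chi_link)` and derives `nu_unlink`.  At `t = 0` each eligible
pair is linked with probability `chi_link`, which seeds the network at its
stationary fraction and gives non-dynamical networks (`nu_link = 0`, a model
of permanently crosslinked tissue) a fixed, nontrivial link set — the
reference description does not specify this initial set, and the Bernoulli
choice is the stationary-consistent one.

## Integration

An explicit (forward) Euler scheme with an adaptive step:
`dt = clamp(min(dx_max/max_k|v_k|, dth_max/max_k|dw_k/dt|), dt_min, dt_max)`
with defaults `dx_max = 0.1 R_fib`, `dth_max = 0.05 rad`, `dt_max = 0.1`.
The rotation update applies the literal cross-product form
`w <- w + dt (T ∧ w)/(mu L^3)` followed by renormalization, which removes
the O(dt²) norm drift.  Each step is followed by link creation then link
deletion (the operator order is fixed for reproducibility; with per-step
Bernoulli probabilities it is O(dt)-irrelevant).  A step that would fall
below `dt_min` aborts with a diagnostic rather than silently degrading.
Two-fibre trajectories converge at first order in `dt` to their closed
forms (verified in the test suite).  Neighbour candidates come from a
periodic k-d tree on the centres with a Verlet skin; exact segment-segment
distances are then computed per candidate pair, with a rigorous lower-bound
filter that skips pairs provably outside every interaction threshold.  The
force sums are independent of this search structure (checked against an
all-pairs oracle at 1e-10).

## Characteristic interaction times

For each interaction, the characteristic time is the time for two isolated
fibres in the worst-case initial configuration to reach 99% of equilibrium
under that interaction alone.  With the reference parameters
(`mu_fib = 1`, `L_fib = 6`, `alpha_rep = 12.5`, `alpha_rest = 5`,
`alpha_align = 2`) the closed forms are:

* **Spring**: two fully overlapped fibres linked at their centres; the
  attachment separation obeys `d' = 2 alpha_rest (d_eq - d)/(mu L)`, giving
  `T_rest = ln(10) mu L / alpha_rest = 2.76` time units at 99% of `d_eq`.
* **Repulsion**: two fully overlapped parallel fibres; with the Hertz force
  above, `d' = 2 alpha_rep (2R-d)^{3/2}/((2R)^{1/2} mu L)` integrates to
  `T_rep = 9 mu L / alpha_rep = 4.32` at `d = 0.99·2R`, independent of `R`.
* **Alignment**: two perpendicularly crossing fibres linked at their
  centres.  The relative angle obeys `theta' = -(alpha/mu L^3) sin(2 theta)`,
  so the exactly perpendicular start is an unstable stationary point and the
  99% criterion (relative angle `theta_c = 0.9°`) is only reached from a
  perturbed start.  The package regularizes the start by the offset
  `tan(delta_0) = (pi/4) tan(theta_c)`, the azimuthal-average convention for
  an infinitesimal tilt of the crossing, giving the closed form
  `T_align = (mu L^3 / 2 alpha) ln((4/pi) cot²(theta_c)) = 4.27 mu L^3 /
  alpha_align ≈ 462` time units.  The offset is a reporting convention, not
  a physical parameter: any fixed small tilt changes `T_align` only
  logarithmically.

These three numbers are the calibration anchors of the force laws; the
acceptance script re-measures them by direct integration of the two-fibre
systems rather than evaluating the closed forms.

## Order quantifiers

* **Local alignment `Al_k`** — square root of the eigenvalue gap
  `lambda_1 - lambda_3` of the second-moment tensor `<w w^T>` over the
  neighbourhood of fibre `k` (every fibre within segment distance
  `2 R_fib + d_link_max`, plus the fibre itself).  The gap is zero in
  expectation for isotropic directions, `1/2` for directions uniform in a
  plane, and `1` for a single direction, so the score hits the anchor bands
  0 / ≈0.707 / 1 for uniform / planar / unidirectional neighbourhoods and is
  invariant under global rotations and per-fibre sign flips.  Fibres with no
  neighbours have no defined score and are excluded from the mean `Al_sim`.
  The square root stretches the upper range at the cost of a positively
  biased small-sample baseline: with the ~15-neighbour shells of the
  reference densities, an isotropic system measures `Al_sim ≈ 0.45` rather
  than 0, uniformly across conditions, comfortably below the 0.7
  classification threshold.
* **Stereographic projection and `A_max`** — directions are flipped to the
  hemisphere around a data-driven reference axis (principal eigenvector of
  the nematic tensor `Q = <w w^T> - I/3`) and mapped onto the unit disk by
  the equal-area projection `r = sqrt(2) sin(theta/2)` (axis to centre,
  equator to rim, uniform directions to a uniform disk).  `A_max` is the
  semi-major axis of the 2-sigma covariance ellipse,
  `2 sqrt(lambda_max(cov))`: ≈1 for the uniform disk, and the 0.45
  classification threshold corresponds to an ellipse covering ≈20% of the
  disk area (0.45² ≈ 0.2).  A 1-sigma ellipse would not match that area
  correspondence, which is why the 2-sigma convention is used.
* **Classification** — aligned (`Al_sim ≥ 0.7` and `A_max ≤ 0.45`), curved
  (`Al_sim ≥ 0.7`, `A_max > 0.45`), unorganized (`Al_sim < 0.7`,
  `A_max > 0.45`); the remaining cell is labelled `unnamed` (not observed in
  simulations).
* **Temporal fits** — `tau_Al` is the time at which a saturating-growth fit
  `A0 + (Ainf - A0)(1 - e^{-t/tau})` of `Al_sim(t)` reaches 63% of its
  fitted asymptote; a series whose fitted `tau` exceeds three quarters of
  its span is rejected as non-saturating.  The connectivity law is fitted as
  `Al_mean ≈ alpha log(N_linkperfib) + beta` on the branch below the
  critical connectivity; the critical value `N_critic` is detected as the
  first point falling more than a configurable fraction (default 10%) below
  the expanding-window prediction.

## Synthetic fixtures

Seeded generators provide states with known ground truth: uniform /
unidirectional / planar orientation fields and a Watson concentration
family `~exp(kappa (w·z)²)` interpolating uniform to unidirectional (test
scaffolding for the quantifier anchors and monotonicity); the three
worst-case two-fibre configurations; and link topologies (perfect matching:
`N_linkperfib = 0.5` exactly; Bernoulli(χ) over eligible pairs).  They
emulate the statistical structure of simulation states, not real imaged ECM
geometry — quantifier tests passing on them certify the estimators, not
biological realism.

## Desk-scale study conditions

The full-scale parameter study (30³ box, 1500–3000 fibres, replicated sweep
cells, all observed at the fixed horizon `T_final = 5·10⁴`) is reproduced at
desk scale
with a 15³ box and 300 fibres (volume fraction 0.47, still in the dense
regime between random and ordered spherocylinder packing), slow remodelling
`nu_link = 0.02`, linked fractions spanning 0.1–0.9, and a fixed observation
horizon of 3750 time units.  The horizon plays the same structural role as
in the full-scale protocol: it lies beyond the local-alignment growth phase
of the slowest, sparsest networks but inside the crosslink-accumulation
regime of the most connected ones.  At this scale the emergence
phenomenology reproduces qualitatively: remodelling networks self-organize
into curved or aligned states while non-remodelling (`nu_link = 0`) networks
stay unorganized; `Al_sim(t)` grows monotonically to saturation with a
well-defined time constant; and across the sweep, alignment at the horizon
rises logarithmically with links per fibre below the critical connectivity
(~0.7) and falls in over-connected networks.

Two quantitative differences from full scale are worth stating plainly.
First, a 300-fibre system escapes crosslink constriction entirely if run to
true equilibrium — every remodelling cell eventually reaches `Al_sim ≈ 1` —
so the depressed-alignment state of over-connected networks is a
fixed-horizon observation here (as the full-scale protocol's slowest cells
plausibly are as well).  Second, the connectivity at which the drop is
*detected* sits at the first over-connected cell (links per fibre ≈ 1.5–4)
rather than immediately above 0.7: cells landing at 0.7–1.5 links per fibre
still align fully at this system size.  Full-scale regression coefficients
and outcome counts of the sweep are out of scope at desk scale.

## Known limitations

* Fibres are rigid and non-stretching; flexibility, branching and growth are
  represented only through chains of crosslinked units.
* Unbinding is force-independent (no slip/catch bonds), and there is no
  external load, shear or thermal translational noise; stochasticity enters
  only through link remodelling and initial conditions.
* The explicit Euler scheme with displacement/rotation caps is first-order;
  the default `dt_max = 0.1` is chosen below the stability limit of the
  stiffest common configurations (several simultaneous crosslinks on one
  fibre), and the step controller aborts loudly if a configuration would
  need a step below `dt_min`.
* `Al_k`'s small-sample baseline means absolute values at low neighbour
  counts sit above zero; comparisons across conditions at fixed density are
  unaffected.
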
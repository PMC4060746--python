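# Methods

This package simulates a neural architecture in which the dorsal (Where) and
ventral (What) visual streams cooperate to learn view- and positionally-
invariant object categories and then to use them for goal-directed search.
This note records the model as implemented: the governing equations, the
parameter regime and why it was chosen, the design decisions taken where the
published description leaves the implementation open, what the synthetic
stimuli do and do not emulate, and the known limitations.

## Units, integration, and scale

One model time unit equals one second, so fixation durations (~0.3 s) and
search latencies (hundreds of ms) are directly comparable to published
values.  All coupled dynamics are integrated with explicit Euler at a global
step of 1 ms.  Feedforward stages whose time constants are fast relative to
1 ms (retina/LGN, simple/complex cells, filling-in) are evaluated at their
algebraic equilibria instead of being stepped — the shunting fixed point
`x* = (BE − CI)/(A + E + I)` for the local stages, and a sparse linear solve
for the filling-in lattice.

Scenes are 100×100 px ("desk scale"), divided into a 5×5 grid of 20×20-px
regions; full scale (500×500, 100-px regions) is available through the
config but is not the default.  The scene center, region 13 in row-major
order, is the foveal region.  (The source description is internally
inconsistent about the foveal region's index; we use the geometric center.)
Objects are confined to the central nine regions so they remain in view
after saccades.

## Primitives

* **Shunting dynamics** `dx/dt = −Ax + (B−x)E − (C+x)I` bound every stage to
  `[−C, B]` and give automatic gain control (Weber-law contrast
  normalization at the front end, saturation at the category stages).
* **Habituative transmitter gates** `dz/dt = r(1−z) − d·S·z` multiply signal
  pathways and deplete with use.  They implement inhibition of return on the
  eye-movement map, the slow collapse of the attentional shroud, and the
  transience of the parietal reset burst.
* **Normalized quenching competition** is applied algorithmically (as the
  model itself prescribes): if the largest input exceeds the second largest
  by the winner margin κ = 1.5 the winner takes the whole normalized total
  M = 1; otherwise all nodes at or above half the maximum share M in
  proportion to their inputs.  Ties break to the lowest row-major index for
  determinism.

## Front end

ON/OFF contrast normalization uses on-center/off-surround (and converse)
Gaussian kernels at three scales (center half-widths 1, 2, 4 px; surround
3× wider), with border replication so a uniform field is exactly
discounted.  Oriented simple cells are odd-symmetric derivative-of-Gaussian
kernels at four orientations and two polarities; complex cells pool the
rectified opposite-polarity pair and are exactly polarity-insensitive.

Boundaries are the complex-cell responses with a multiplicative gain
`1 + λ₁·(surface-contour feedback) + λ₂·(category prime) − inhibition·mean`,
so attended or primed objects' boundaries strengthen while others weaken.
The feedback is normalized against the *pure bottom-up* contour amplitude so
that attentional enhancement is not renormalized away.  Two boundary maps
are carried: the pure bottom-up map feeds the What-stream adaptive filter
(it is strictly local, hence exactly translation-equivariant — important
for view categorization, below), while the gain-modulated map gates
filling-in.

Filling-in (the FIDO lattice) is solved at equilibrium as a sparse linear
system: leaky nearest-neighbor diffusion with permeability
`P/(1 + μ·boundary)` (P = 2, μ = 2000) and the ON/OFF contrast signals as
sources.  A closed boundary therefore encloses a near-uniform compartment
whose level is approximately the compartment average of its sources.
Because the equilibrium level is source-determined, boundary *gain* alone
cannot raise a surface's contrast; gain-amplified boundaries therefore also
multiply the source term ("stronger boundaries contain a brighter
surface"), which is what lets a top-down category prime enhance its target
surface on the indirect search routes.  The category-prime gain λ₂ = 4 is
set so a primed surface out-competes the ~3× contrast range of the
synthetic object library; the contour-feedback gain λ₁ = 0.5.

Surface contours are a contrast-sensitive on-center/off-surround readout of
the pooled filled surface: zero in uniform interiors, maximal near
high-curvature rim points — the saccade targets.

## Where stream

Gain fields are exact integer-pixel translations between retinotopic and
head-centric frames, using the *planned* eye position once a saccade is
pending (predictive remapping), so the head-centric shroud is unchanged by
within-object saccades.  The scene itself is maintained in head-centric
coordinates and every retinotopic map is derived from it by translation;
content that leaves the retinal frame during a saccade re-enters when the
eyes move back.

The shroud competition operates on the quench-thresholded, max-normalized
surface input.  Candidate surfaces are connected components of that input;
the winner is the blob with the greatest mean gated drive — a contrast
measure, so a small fresh surface can out-compete a large one whose
transmitters are depleted — and the choice locks for the epoch (the
winner-take-all endpoint of the recurrent competition, applied
algorithmically for robustness).  Within the winning blob the field obeys
shunting dynamics in which recurrent excitation acts as a *gain on the gated
input* rather than as a free-running source: the shroud therefore cannot
sustain itself once its habituative gates deplete.  The gates enter squared
because the surface-shroud resonance loop traverses a gated pathway on both
its bottom-up and top-down legs; gate kinetics (r = 0.05, d = 1.8) are
calibrated so a shroud epoch lasts ~1.25–1.35 s, reproducing the published
attention-shift rhythm, and recovery is slow enough (multi-second) that a
just-attended object loses the next competition.

Reset follows a ratio rule: when the shroud total falls below ε = 0.4 of
its onset peak, a tonically active reset population is disinhibited; its
transmitter-gated output bursts (<0.3 s), nonspecifically inhibits the
shroud (a disinhibitory loop that completes the collapse), and the epoch
closes when the burst's transmitter empties.  The Where-stream output is
this transient burst; the What-stream reset is an ungated latch held until
the next shroud forms.

The eye-movement map accumulates shroud-masked surface contours (plus any
direct-route input) toward a decision threshold under per-position IOR
gates (depleted at fixation, τ ≈ 2 s recovery) and a 50-ms post-saccadic
refractory period.  The contour gain is calibrated so the within-epoch
inter-saccade interval is ~0.3 s, the published fixation duration; the
direct-route gain is twice as effective, making direct searches
correspondingly faster.  Note that the published trio of free-viewing
numbers (7–8 fixations per object, 0.3 s fixations, 1.25–1.35-s epochs) is
mutually inconsistent; the implementation reproduces the fixation interval
and the epoch/reset times, which yields ~4 fixations per epoch.

## What stream

View-specific categories are Fuzzy ART modules, one bank per region
(positional organization).  The input vector pools the *finest-scale*
oriented bottom-up boundary responses on a 10×10 grid over the region crop,
max-normalizes, and complement-codes (city-block norm = d exactly).  The
normalization maximum is taken over the *central* pooled cells only: a
strong neighbor's boundary spillover is confined to the crop's outer ring
and must not set the gain of a weak object's own features (outer-ring cells
clip at 1).  Finest
scale only: the coarser kernels reach into adjacent regions, and at desk
scale that clutter contamination exceeded the vigilance margin between
different objects.  Vigilance ρ = 0.93 sits between the worst cross-object
match (~0.89) and the worst same-object-in-clutter match (~0.97) of the
synthetic library; choice α = 0.01 and fast learning β = 1 are standard.
During *search* (no learning) a region's best-matching committed category
is read out even if it narrowly misses vigilance — vigilance gates
commitment, not recognition — subject to a 0.9 noise floor; the readout
uses the match value, not the choice function, because fast learning shrinks
templates and the choice function would favor small subset templates of the
wrong object.

View category integrators are persistent (τ = 10 s) copies of view-category
activity, cleared only by the What reset.  The invariant layer holds object
nodes with reciprocal adaptive weights per integrator key; bottom-up input
is the weight-weighted sum over active integrators, competition is the
quenching competition, and both weight directions learn at the slow rate
λ = 0.05 per fixation event whenever integrator and winner are coactive.  A
fresh node is recruited when no committed node is supported.  As in the
published simulations, a new position's first (extra-foveal) view
transiently recruits a spurious node that is subsequently out-competed by
the object's established category once a familiar foveal view reactivates
it through the persistent integrators; the map from objects to *argmax*
categories is what becomes one-to-one.

The direct route is a Hebbian association (rate 0.2/event, saturating at 1)
between an extra-foveally active view category and its region's position,
learned whenever category and position are coactive; foveal categories
acquire none.

## Cognitive-emotional circuit

Value (3 nodes), object-value and name layers carry four learned weight
families (conditioned reinforcer ITa→value, incentive value→object-value,
ITa→object-value, name↔object-value), all gated-Hebbian toward 1.
ITa→object-value starts at an innate weak one-to-one scaffold (0.7): with
all-zero initial weights the object-value layer could never fire and no
learning could begin; the scaffold also realizes the stated firing
condition that bottom-up input alone fires the cell weakly.  Object-value
activation is *convergent*: primes act chiefly as a gain on bottom-up input
(`bu·(1 + g·prime) + 0.4·g·prime`), with a small additive share so that a
volitionally enhanced prime can fire its target supraliminally on its own.
Volition switches top-down efficacy g between modulatory (0.3, subthreshold
alone) and driving (1.2).

## Search protocols

A search trial presents the scene and the prime simultaneously at t = 0 and
integrates the category-stage cascade (shunting-saturated activities,
membrane rate 12 s⁻¹ ≈ 13 ms per stage; competition decisions taken on the
stage *inputs* gated by suprathreshold activity, so saturation cannot erase
winner-take-all margins).  Cognitive trials prime a name; motivational
trials drive a value category; bottom-up trials carry the same internal
drive (the state that defines which object is "desired") but it engages
only once the scene has activated object categories — bottom-up selection
must wait for recognition, which is what makes those routes slowest.
Invariant-category evidence arriving from different positions is max-pooled
per node rather than summed: two regions supporting the same object are
alternative hypotheses about one thing, and summing would let a spurious
double identification outrun the resonance.  The
view-category choice must hold a winner-take-all state for 15 consecutive
ms before it drives action.  The direct path then reads the winner's
position association into the eye-movement map; the indirect path re-runs
the front end with the winner's region primed, additionally amplifies the
primed position's surface input at the spatial-attention stage (the
enhanced surface "facilitates its competition" for the shroud), forms a
shroud on it (the re-filtered signal builds with its own 50-ms time
constant), and selects a contour hotspot.  RT is the model time of the
first saccade-threshold crossing; "found" requires that saccade to land in
the target's region.

Volition is on during every search trial, including bottom-up ones (the
closing of the IT–amygdala–orbitofrontal loop requires it); clamping
volition off therefore disables selection on all routes, and the tests
assert the defining case — every top-down route fails without volition.

## Training protocols and problem sizes

The free-viewing trial (three objects, ~4.5 s) and all search trials run at
full millisecond resolution.  The positionally-invariant protocol (24
objects × 9 positions × 40 trials) runs at fixation-event granularity: the
front end is computed once per object (all positions are exact translations
of the foveal maps, by the translation equivariance noted above), the
fixation sequence on each object is produced by the same surface-contour /
IOR machinery, and each event applies the same classification and learning
rules; repeat trials replay the cached event sequence, which is exact
because generator and saccade selection are deterministic given the scene.
This is the package's scheduler design for the slow-weight equilibration
phase; all quantities that depend on timing are measured from the
full-resolution protocols.

The default problem sizes — 100-px scenes, 24 objects (12 in the test
suite), 9 positions, 40 trials per position, one battery scene per object —
are the package's study conditions and match the published protocol except
for the image scale.

## Synthetic stimuli

The generator draws parametric shapes (disk, ring, cross, bar-pair, blob,
polygon) with varied sizes, luminances and structural variants (rotation,
thickness, vertex count) on the 0.5 gray background.  A self-test rejects
object pairs whose pooled oriented-gradient signatures fuzzy-match above
0.92 — a proxy aligned with the view-feature geometry — so the library
plays the role of distinct object categories.  What the stimuli do *not*
emulate: natural image statistics, texture, occlusion, depth, color, or
luminance-polarity identity (the boundary-driven What stream cannot
distinguish a bright disk from a dark disk of equal size; library variants
therefore never differ by polarity alone).  Passing tests demonstrate the
mechanisms — attention cycling, invariant binding, primed search — not
robustness to natural scene variability.

## Numerical choices and degenerate inputs

Empty regions and uniform scenes are guarded by absolute noise floors
(1e-6) before normalization, so numerical residue is never amplified into
signal.  Winner ties break to the lowest row-major index everywhere.  The
filling-in solve is exact (sparse LU), so "non-convergence" cannot occur;
the shroud/eye fields are Euler-stable at dt = 1 ms by the magnitude of
their rates.  All stochastic choices (object shapes, scene placements)
derive from explicit integer seeds; given a seed, every simulation in the
package is bit-deterministic.

## Known limitations

* Scale: the default is a 5×-reduced scene; kernel widths were chosen for
  that scale and full-scale runs require proportionally larger ones.
* The crowding regime is mild: one object per region, nine regions.  The
  vigilance margin was verified for the synthetic library, not for
  arbitrary object sets.
* No boundary completion / illusory contours, no depth or occlusion, no
  cortical magnification: peripheral views are as sharp as foveal ones,
  which is what makes single-fixation extra-foveal categorization possible.
* Reaction times are emergent but their absolute values depend on the
  chosen stage rates; the published values constrain those rates only up to
  the band reported for each route.
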
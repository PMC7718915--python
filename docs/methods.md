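# Methods

`laminmesh` models the nuclear lamina — the filamentous meshwork of lamin
intermediate filaments lining the inner nuclear membrane — as a scale-free
graph of bead-spring filaments adhered to a plane, and asks how the meshwork
topology shapes the mechanics of a single filament pushed transversely, the
way an AFM tip pushes on a lamin filament in situ.

## Meshwork generation

**Topology.** A meshwork is an undirected graph whose edges are filaments
and whose nodes are filament junctions. Generation starts from a
preferential-attachment (Barabási–Albert) graph grown from a complete seed
on *m*+1 nodes with *m* = 2 attachments per new node. A Monte-Carlo rewiring
run (default 1,000,000 proposals) then reshapes the degree distribution
toward a truncated power law P(*k*) ∝ *k*^−λ on [*k*min, *k*max] = [3, 17]:
each proposal picks a random node and either adds an edge to a random
non-neighbor or deletes a random incident edge, and is accepted by a
Metropolis rule on the Kullback–Leibler divergence between the empirical
degree distribution and the target. Moves that would disconnect the graph,
create degree 0, or exceed *k*max are rejected outright. Degrees outside
[*k*min, *k*max] carry a vanishing target probability (10⁻⁸), which drives
the distribution into the band; a final repair pass lifts stragglers below
*k*min.

The fictive temperature of the Metropolis rule is annealed geometrically
from 10⁻³ to 10⁻⁶ over the run. A fixed temperature turned out to be
unworkable in both directions: hot enough to move the bulk of the
distribution it equilibrates far from the target (entropic broadening),
cold enough to hold the head of the distribution it freezes single nodes at
every degree 9–17 because each one-step move of a lone tail node is locally
uphill. The anneal pools the tail first and then freezes the head; at 500
nodes it reaches KL ≈ 0.002, a fitted exponent of 5.59 ± 0.03 against a
target of 5.6, and a mean degree of ≈ 3.36 — the value ⟨k⟩ ≈ 3.3 expected
from the truncated power law itself (Σ k·k^−λ / Σ k^−λ on [3, 17]).

The support [3, 17] reflects the observation that junctions in real laminae
have degree 3 or 4 with a minor hub population up to 17. It is kept for
every exponent in the topology sweep, so the λ = 0.5 meshwork here is a
dense, nearly degree-uniform network (⟨k⟩ ≈ 8.9) rather than a collection
of dangling single filaments; "less connected" at low λ means fewer hubs per
low-degree node, not fewer edges. The directional mechanics contrast (below)
emerges regardless, through strain localization.

**Geometry.** Node coordinates are drawn uniformly in a square box of area
*n*·(12 nm)² — the density at which filaments of the target length tile the
membrane plane. A second Monte Carlo (default 600,000 single-node Gaussian
moves of 1 nm, greedy accept-if-lower) minimizes
(mean(*L*) − 12)² + (sd(*L*) − 3)², driving filament lengths to 12 ± 3 nm.
Topology is untouched by construction.

**Discretization.** Each filament becomes a chain of beads at ≈ 1 nm
spacing: an edge of length *L* carries round(*L*)+1 beads, junction beads
are shared between filaments, and every interior bead centres a bending
triplet. All bonds share the rest length r₀ = 1 nm regardless of the
initial geometric spacing, so the relaxation stage removes the small
discretization strain.

## Force field

Internal units are kcal mol⁻¹ and Å. The bonded tension law is piecewise —
harmonic elastic regime (k₁ = 0.7975 kcal mol⁻¹ Å⁻² above r₀ = 10 Å), a
soft plateau representing α-helix coiled-coil unfolding (k₂ = 0.162 above
r₁ = 15 Å), a stiffening cubic representing the α→β transition (k₃¹ =
1.022, k₃² = 0.365, k₃³ = 0.116 above r₂ = 19 Å) and a force cap R₃ =
113.936 kcal mol⁻¹ Å⁻¹ beyond r₃ = 27.6 Å — multiplied by a Fermi–Dirac
factor [exp((r−r_b)/r_b·Ξ)+1]⁻¹ (r_b = 36 Å, Ξ = 300) that extinguishes the
force smoothly around the breaking distance. The continuity constants R₁ =
3.988 and R₂ = 4.635 follow from the spring constants. Bond strain energy
is obtained by dense trapezoid quadrature of the force law (analytic below
r₁, tabulated above); its finite-difference gradient agrees with the force
to better than 1%. A bond stretched beyond r_b is flagged broken and
excluded permanently — the smoothing factor alone would let a ruptured bond
re-engage on re-approach, which is unphysical for a sheared coiled coil.

Bending is harmonic, φ(θ) = ½·34.32·(θ − θ₀)² kcal mol⁻¹ rad⁻², with θ₀ =
π since filaments are generated straight. Non-bonded bead pairs on
different filament stretches (beads more than two bonds apart) repel
through A[1 + cos(πr/r_c)] with A = 4 kcal mol⁻¹, r_c = 10 Å. The nuclear
membrane is a fixed plane with an integrated van der Waals (9-3) wall per
bead: well depth 20 mJ m⁻² × 1 nm² = 2.88 kcal mol⁻¹ (beads tile filaments
at 1 nm), minimum at 1.5 nm, truncated and shifted at 4.0 nm. Forces are
converted to laboratory units via 1 kcal mol⁻¹ Å⁻¹ = 69.477 pN.

## Simulation protocol

Dynamics are overdamped Langevin (Brownian): x ← x + F·dt/γ + √(2k_BT·dt/γ)·ξ
with γ = 1 and dt = 0.02–0.03 internal time units, stable against the
stiffest branch of the bond law (≈ 33 kcal mol⁻¹ Å⁻²). This integrator is
the natural choice for the quasi-static, heavily damped loading regime; its
validity is asserted by a quasi-static check rather than by a nominal speed
mapping: halving the loading speed changes the measured strength of a
reference meshwork by < 5% (measured ≈ 3.6%).

Relaxation heats the adhered meshwork (600 K then 300 K annealing), then
minimizes the energy with L-BFGS (analytic gradients, non-bonded pair list
refreshed between rounds; residual gradient below ≈ 0.15 nN per bead, far
under the nN force scale of the experiment). Pushing selects a random
filament whose midpoint lies in the central half of the meshwork (limiting
free-edge effects), displacement-clamps its middle bead, and drives it
normal to the plane at constant speed (500–2000 integration steps per nm
depending on profile) while all other beads stay thermostated at 300 K. The
reaction force on the driver, low-pass filtered over 0.1 nm of travel, vs
displacement is the force–extension (FE) curve. The record ends at the
requested displacement or when the pushed filament has parted on both sides
of the driver — beyond that point the signal is contact with other
filaments, not the filament under test. Non-bonded neighbors come from a
KD-tree rebuilt every 250 steps with a 6 Å skin. A constant-force (clamp)
protocol is included as an in-silico mirror of the experimental force-clamp
assay.

Strength is the maximum of the FE curve (nN) and toughness the trapezoidal
area under it (nN·nm), the same definitions applied to the AFM records.

## FE-curve and clamp-trace analysis

The extractor mirrors AFM practice. Peaks are found on a Savitzky–Golay
smoothed curve (≈ 2 nm window) with a 0.2 nN prominence floor — the noise
scale of the plateau-force population — but peak height and position are
read from the raw record so smoothing cannot shave the maximum. The high
stiffness κ_high is a linear fit to the contiguous steep rise between 45%
and 95% of the final peak; any reported stiffness must carry R² ≥ 0.93 or
it is withheld with a flag. The plateau is the dominant force level before
the peak: its level is the mode of the smoothed-force histogram, its extent
is bounded by the intersections of the entropic-rise line and the
stiffening line with that level — an estimator that is exact on clean
piecewise curves and insensitive to noise and smoothing width. Step units
are measured from each raw peak to the intersection of the falling flank
(fit between 20% and 80% of the drop) with the post-drop baseline.
Hysteresis energy integrates F_approach − F_retract over the common
deformation range (1 nN·nm = 10⁻¹⁸ J). Toughness density is E/(πr²L);
engineering strain uses the chord geometry of a transversely deflected
filament, 100·(2√((L/2)² + d²) − L)/L, which reproduces ≈ 250% at the
population means L = 54 nm, d = 91 nm (and 123.6% at d = L, slightly below
the ≈ 126% sometimes quoted for that regime — the residual is a property of
the chord approximation). Clamp traces are segmented by recursive binary
change-point splitting with a 0.5 nm minimum step, below the smallest
reported step class (1.3 ± 0.5 nm).

## Skeleton-to-graph conversion

Rendered filament skeletons arrive as 3D polylines. Crossovers are points
where different polylines approach within 1.3 nm; each contiguous
close-approach run of a polyline pair yields one crossover candidate at the
minimum of the smoothed distance profile (robust when two filaments leave a
junction at a small angle and stay close for many nm). Candidates are
clustered by single linkage at 3× the merge distance — they are noisy
estimates of the same junction — and each polyline is walked through its
ordered vertices (free endpoints included) to produce edges. Three cleanup
passes replace the manual curation used on real tomograms: links shorter
than 3× the merge distance (split-junction artifacts) are contracted,
pass-through vertices of degree 2 removed, and self-loops/duplicate edges
dropped.

The degree-distribution exponent is fitted by discrete maximum likelihood
on the truncated support (k_min = 3 by default, k_max the sample maximum),
with a log-log least-squares slope reported alongside since GUI network
analyzers typically fit that way; no installed package provides the
truncated discrete MLE, so it is implemented here on scipy's scalar
optimizer. Small-world behaviour is summarized by the mean shortest-path
length of breadth-first-grown subgraphs of increasing size.

## Synthetic fixtures

The workbench generates every record the analysis code is tested against,
with known ground truth: FE curves built as linear rise → flat plateau →
linear stiffening → sharp drop with Gaussian noise (defaults at the pooled
AFM population means: plateau 0.30 nN over 54 nm, stiffness 0.30 nN nm⁻¹,
failure 2.4 nN at 91 nm, step 4.3 nm); force-clamp staircases with
configurable step sizes and dwells; and polyline skeletons of known graphs
with smooth tracing jitter. The skeleton round-trip fixture is a perturbed
triangular lattice — planar, junction angles near 60°, minimum degree 3 —
because exact recoverability requires a geometry whose only crossovers are
real junctions; random or Delaunay layouts contain incidental near-crossings
and sub-resolution wedges that no extractor could disambiguate.

What the fixtures deliberately do not emulate: instrument drift, cantilever
dynamics and tip-shape convolution in the FE curves; segmentation gaps and
curvature in the skeletons; membrane curvature and nuclear-pore inclusions
in the meshworks. Passing the round-trip tests therefore demonstrates
correctness of the estimators on clean and moderately noisy morphology, not
robustness to every artifact of real recordings.

## Problem sizes and profiles

Two profiles ship. The `full` profile follows the study conditions: 500-node
meshworks, 1,000,000 rewiring and 600,000 coordinate proposals, 100 pushing
replicates per exponent, 2000 integration steps per nm. The `desk` profile
is the package's single-workstation configuration used by the test suite:
48-node meshworks, 150,000/120,000 Monte-Carlo proposals, 20 replicates, 500
steps per nm, 140 nm maximum displacement. At desk scale the
topology→mechanics contrast between λ = 0.5 and λ = 5.6 is directional and
strongly significant for toughness (Welch t-test); the strength contrast is
directionally positive but with overlapping spreads, consistent with the
marginal significance of that contrast even at full replication. Meshwork
generation targets (mean filament length, fitted exponent, mean degree) are
always verified at the full 500-node scale, where generation takes seconds
per meshwork.

## Known limitations

- The rewiring equilibrium has a small integerization floor: on small
  graphs (≪ 500 nodes) the sparse tail cannot match fractional target
  counts and the fitted exponent is biased low by a few tenths.
- Bond rupture under fast-but-quasi-static loading is dominated by the
  force cap of the tension law, so simulated strengths cluster near
  2 × R₃ × sin α; thermally activated rupture at experimentally slow
  loading rates would spread them downward.
- The overdamped integrator has no inertia; kinetic signatures (stress
  waves after rupture) are outside scope.
- FE feature extraction assumes a single dominant plateau; multi-plateau
  curves report only the longest level region.
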
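# Methods

## Knot detection on open backbones

A knot is only defined on a closed loop, so an open Cα trace is closed
before classification: each terminus is extended along the ray from the
backbone's centre of mass through that terminus out to a sphere of
radius ten times the chain's maximal pairwise extent, and the two far
points are joined by a great-circle arc on that sphere. Because every
added vertex lies far outside the chain's convex hull, the closure
cannot thread the structure; the detected knot is the one that survives
pulling both ends outward, which is the operational definition of
knottedness in an open string. Termini that coincide with the centre of
mass (degenerate ray) are perturbed by 10⁻⁶ of the chain extent.

The closed polygon is simplified by triangle elimination (KMT
reduction): vertex *i* is deleted whenever no other segment of the
curve pierces the triangle spanned by its neighbours, so the chain can
be deformed across that triangle without self-crossing. Passes run in
ascending index order until nothing is removed. The implementation is
conservative in degenerate situations: segments lying in the triangle's
plane are tested in 2D and any overlap blocks deletion, and a collinear
vertex is removed only if it lies between its neighbours. Conservatism
can only leave extra vertices, never change topology.

The reduced curve is projected along a random direction drawn from a
seeded uniform distribution on the sphere. A projection is rejected as
non-generic — and a fresh direction drawn, up to 100 attempts — if a
segment is parallel to the direction, a crossing falls within 10⁻⁹
(relative) of a vertex image, two crossing images coincide, or two
collinear segment images overlap. Crossings are enumerated with
over/under assignment from depth and sign from the right-hand rule;
arcs are delimited by underpasses.

Knot types are identified by the Alexander polynomial evaluated at
t = −1 and t = −2. One row of the crossing/arc matrix is built per
crossing (overpass arc t−1, underpass arcs −t and 1, swapped for
negative crossings, coincident arcs accumulating); one row and column
are deleted and the determinant computed with fraction-free (Bareiss)
integer elimination — exact arithmetic, because floating determinants
misclassify once diagrams grow past a few tens of crossings. The
matrix determinant is only defined up to ±t^k, so the t = −2 value is
normalized by dividing out all factors of 2; the resulting odd part of
|Δ(−2)| is a true invariant. The pair (|Δ(−1)|, odd |Δ(−2)|) separates
every prime knot through six crossings — in particular the figure-eight
knot 4₁ from the torus knot 5₁, which share determinant 5 — and is
looked up in a fixed table (0₁ (1,1), 3₁ (3,7), 4₁ (5,11), 5₁ (5,31),
5₂ (7,1), 6₁ (9,5), 6₂ (11,59), 6₃ (13,67)). Unmatched pairs are
reported as `unclassified` with both determinants preserved. Chirality
is not resolved: the Alexander polynomial cannot distinguish mirror
images, matching the achiral naming convention.

## Knotted cores, fingerprints, slipknots

The knotted core is found by deleting residues one at a time from the
N-terminus, re-closing and re-classifying the remainder after each cut
until the knot vanishes, then scanning the C-terminus; the two scans
alternate until neither boundary moves, which makes the reported core
minimal on both sides simultaneously (a single N-then-C pass does not
guarantee this). Every classification is a majority vote over five
projection seeds derived from the user seed, because closure of a
truncated chain occasionally threads the remaining structure in an
unlucky projection. Each truncation is closed about its own centre of
mass. Core boundaries are reported in author (PDB) numbering, including
negative numbers and insertion codes, and should be read as a guideline:
single-residue shifts between closure conventions are expected.

The knot fingerprint classifies every subchain on a stride grid
(minimum length 10). A chain is called a slipknot when its full-length
closure is trivial but some subchain is knotted.

## The Cα structure-based model

The force field is the standard minimally frustrated native-contact
model:

    V = Σ K_r (r−r₀)² + Σ K_θ (θ−θ₀)²
      + Σ K_φ [(1−cos(φ−φ₀)) + ½(1−cos 3(φ−φ₀))]
      + Σ_native ε [5(σij/r)¹² − 6(σij/r)¹⁰]
      + Σ_non-native ε (σ_rep/r)¹²

with K_r = 100 ε/Å², K_θ = 20 ε/rad², K_φ = 1 ε and ½ ε, σ_rep = 4 Å —
the community defaults for this model lineage, exposed as module
constants. Lengths are in Å, energies in units of the contact depth ε,
temperature is k_BT/ε, masses are 1, and time is τ = √(mÅ²/ε). A native
contact (i, j), |i−j| ≥ 3, is declared when any heavy-atom pair of the
two residues is closer than 4.5 Å (configurable); σij is the native
Cα–Cα distance, so each contact term has depth exactly −ε at the native
geometry and the native state is the global minimum by construction. A
Cα-only builder with a 7.5 Å default cutoff serves synthetic chains and
Cα-only files. No non-native attraction exists anywhere in the model,
so no folding route is biased. All pairs |i−j| ≥ 3 that are not native
contacts interact through the repulsive core only.

Dynamics is Langevin velocity-Verlet (BAOAB splitting), defaults
γ = 1 τ⁻¹ and dt = 0.005 τ; with γ = 0 the integrator reduces exactly
to velocity Verlet, which the energy-conservation test exploits. All
randomness flows from a single seed through `numpy.random.Generator`;
trajectories are bitwise reproducible on one platform. Forces are
analytic (verified against central differences to better than 10⁻⁵
relative) and compiled with numba. Numerical guards: the 1/sin θ factor
in the bend gradient is floored at sin θ = 0.05 so that a transiently
collinear triple (as occurs in near-straight extended starts) cannot
blow up the step; runs abort, returning frames collected so far, when
energy becomes non-finite or coordinates exceed 10⁶ Å. The fraction of
native contacts Q counts a contact as formed below 1.2 σij; the folded
state is Q > 0.9.

## Trajectory analysis

Frames are closed, reduced and classified on a stride; labels are
smoothed with a five-frame persistence window, because closure through
a transiently threading terminus produces single-frame knot flickers
that are artifacts of the closure, not of the dynamics.

Event times are defined through piercing parities. A loop spans a
surface built as the fan triangulation of its polygon about its
centroid, recomputed every frame; a chain segment has threaded the loop
when it pierces that surface an odd net number of times. The threading
time t_c is the first persistent frame with odd parity of the terminal
segment through the loop; the flipping time t_B is the first persistent
frame at which the second loop's parity differs from its initial value.
These parity definitions are one faithful operationalization of events
that the source material describes only visually; they are verified
against brute-force segment/triangle counting on random configurations.
Frames whose loop cannot span a fan surface (a degenerate triangle) are
skipped, carrying the previous parity. All times are integrator steps;
no physical time conversion is attempted.

Routes are classified from the smoothed label series: route I forms the
native knot directly; route II passes through a persistent figure-eight
intermediate before the native Stevedore knot; runs that never fold and
end unknotted are `unfolded`; everything else — in particular a
persistent wrong knot — is `trapped`. Contact formation order reports,
for each native contact, the first step at which it is formed for a
full persistence window (or through the final frame).

## Synthetic curves and fixtures

Torus knots come from the closed-form parametrization; the circle is
the unknot control. Knot types without a convenient parametrization
(4₁, 5₂, 6₁) are rendered as braid closures: strands run along one
axis, each braid letter swaps two neighbours with the over strand
bumped to +z and the under strand to −z, and each strand's end is
returned to its start through an arc lifted to its own z level above
everything — an embedding isotopic to the standard trace closure, since
a return arc lying above the whole diagram can always be slid around
it. Braid words are taken from standard tables and validated against
the determinant oracle in the test suite. Curves are densified by
midpoint subdivision (which keeps every original vertex, hence the
topology) and may receive seeded Gaussian vertex noise; generation
fails loudly if re-classification shows the noise changed the topology.

Open-chain fixtures cut a closed curve at its maximum-radius vertex
(the analog of surface-exposed termini), rescale to the 3.8 Å Cα
spacing, and append straight flanks. The slipknot fixture retraces the
final third of an open trefoil backwards alongside itself and escapes
radially, so the whole chain closes to the unknot while a subchain
remains a trefoil.

The toy knotted mini-protein is a designed ~33-bead open trefoil in a
ring-and-pin architecture: an N-terminal tail runs into a flat 8-bead
ring; the chain exits through a neck that dips back under the tail (the
locking crossing); an excursion arcs over the structure and the
C-terminal pin descends through the ring, hugs the ring's underside and
passes beneath the neck, stacking tail, neck and exit into a
three-layer sandwich. All three crossings are supported by tight
(4–6 Å) contacts; corners are rounded by Chaikin smoothing before
equal-arc-length resampling, giving bond lengths of 3.4–3.9 Å and no
non-bonded pair closer than ~3.2 Å. Construction is validated by
re-classification (it must close to 3₁) after the seeded sub-Å jitter
that breaks the parametric symmetries. The pinned working temperature
(0.5 ε/k_B, with a 6.5 Å Cα contact cutoff) was located by scanning:
the native basin is stable there (Q ≈ 1 over 10⁶-step runs) and
compact states form from extended starts within ~10⁶ steps.

## What the toy shows — and does not show

The synthetic fixtures exercise every pipeline stage without external
data, but they are not proteins: no secondary structure, no side-chain
packing, contact maps from a single Cα cutoff. One consequence is
physical and worth stating plainly: in refolding simulations from
extended starts, the toy reliably collapses (Q up to ~0.95) but
essentially never reaches the *knotted* native state. The reason is
intrinsic to distance-based native-contact models: the pairwise
distance map is almost invariant under flipping one crossing of the
native conformation, so an unknotted "mirror-crossing" impostor
satisfies nearly all contacts; the few contacts that discriminate the
true crossing sign form last, by which time the wrong sign is
kinetically frozen. Topological frustration of exactly this kind is why
knotted folds are rare outcomes in this model class at desk scale, and
why published censuses report success rates of a few percent or less
for all but the smallest real knotted proteins. Statements about
folding mechanisms should therefore rest on analyses of the successful
trajectories, never on raw success rates.

## Problem sizes

Synthetic classification fixtures use 80–300-vertex curves; KMT reduces
protein-scale curves to a handful of vertices in well under a second.
Core scans on ~100-residue chains run in tens of seconds (five-vote
majority per truncation). Folding tests use the 33-bead toy at 10⁶
steps per trajectory; integrator physics checks use a 12-bead chain and
a dimer at up to 4×10⁶ steps. These sizes were chosen so the whole
suite completes on one CPU in a few minutes while every property is
still measured from actual dynamics.
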
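# Methods

This document describes the model implemented by `waterdock`: what is
simulated, the algorithms and their parameters, the numerical choices, and
the limitations. Nothing here claims empirical accuracy beyond what the
test suite and `scripts/acceptance.py` actually compute.

## Problem setting

Small-molecule docking predicts the bound pose of a ligand in a protein
binding site. Crystallographic water molecules frequently bridge
protein–ligand hydrogen bonds, and ignoring them discards real interface
chemistry. `waterdock` implements a desk-scale docking protocol in which a
small number of explicit *interface waters* are sampled alongside the
ligand, in two variants plus a water-free baseline.

A *pose* is a protein `Structure`, a `LigandModel` (atoms plus a bond
graph), and a `WaterSet` of rigid waters (oxygen plus two hydrogens at
O–H 0.9572 Å, H–O–H 104.52°; hydrogens are constructed with a seeded
orientation when absent from the input).

## Interface-water selection

A crystallographic water is classified from its oxygen's distances to the
two partners (default cutoff 3.0 Å, every input atom counted):

* **loose** — within the cutoff of ≥1 protein atom and ≥1 ligand atom;
* **tight** — within the cutoff of ≥2 protein atoms and ≥2 ligand atoms;
* **none** — otherwise.

The tight set is a subset of the loose set by construction.

## Decoy-water placement

For ligands without crystallographic waters, one candidate ("decoy") water
oxygen is placed near each ligand hydrogen-bond donor/acceptor with an XYZ
grid (default spacing 0.15 Å over the ligand bounding box plus a 4 Å
margin): grid points inside any ligand atom's van der Waals sphere are
occupied; the spherical shell 2.75–2.9 Å around the polar atom is
collected; occupied points are removed; the surviving point with the
smallest mean distance to the rest of its set is the water position (ties
broken by lexicographic (x, y, z) order so placement is deterministic).
A decoy used in docking is drawn uniformly from the candidates that do not
clash with the protein (oxygen within the sum of vdW radii of any protein
heavy atom).

## Crowdedness

Predicted polar protein/ligand contacts are donor-capable/acceptor-capable
heavy-atom pairs across the interface at ≤3.6 Å, tightened to 3.2 Å when
either atom has three or more covalently attached heavy neighbors (a
buriedness proxy). *Crowdedness* is the contact count divided by the number
of ligand heavy atoms; it is reported, not thresholded.

## Score function

A deliberately simplified stand-in energy, small enough to verify against
brute-force pair sums (it is **not** a published force field):

* **Lennard-Jones 6-12**, heavy atoms only, minimum at the sum of the two
  vdW radii, well depth ε = 0.2, pair cutoff 6 Å. The curve is split into
  an *attractive* branch (constant −ε inside the minimum) and a *repulsive*
  branch (positive part inside the minimum, capped at 10 per pair).
* **Hydrogen bond** −f(d)·g(θ) per ordered donor→acceptor heavy pair:
  f ramps linearly from 1 at ≤2.8 Å to 0 at 3.6 Å; g is a cosine ramp on
  the donor–H–acceptor angle from 1 at 180° to 0 at 120°, taking the better
  of the donor's (up to two) hydrogens; g = 1 when the donor carries no
  explicit hydrogen, the common case in crystal structures.
* `total = 1.0·attractive + 0.55·repulsive + 1.0·hbond`. Exclusions:
  same/adjacent protein residues, ligand atoms within two bonds, and
  intra-water pairs.

Interface components (`interface_ligand`, `interface_water`) are the
cross-partner pair sums, identical by construction to translating that
partner 500 Å away and re-scoring; the test suite verifies both identities
against an independent double-loop implementation.

Pair bookkeeping depends only on pose topology, so `ScoreFunction` caches
it; batched evaluation of coordinate stacks (`total_batch`) drives the
minimizer's finite-difference gradient in one vectorized pass.

## Low-resolution search

Each model starts from the native pose and applies, per protocol:

* **standard** — ligand translate → ligand rotate → slide-together.
* **protein-centric** — ligand translate → rotate → each water translates
  independently within a ≤4 Å ball (50 tries, clash test on the oxygen,
  lowest-repulsive fallback) and is fully reoriented → slide-together.
* **ligand-centric** — waters ride the ligand's translation, then make
  small independent ≤1 Å moves (up to 50 tries each), rotate with the
  ligand as one rigid body, and are reoriented independently (best of up to
  100 random orientations); slide-together then moves ligand and waters as
  a unit.

Mover details: *translate* draws uniformly from a 5 Å ball about the
original centroid, accepting the first draw whose new centroid is ≥2.25 Å
from every protein atom (50 tries, lowest-repulsive fallback). *Rotate*
draws uniform random orientations about the ligand centroid, accepting the
first with no heavy-atom clash at 0.7×(rᵢ+rⱼ) (1000 tries, best
attractive+repulsive fallback). *Slide-together* steps 0.1 Å along the
line from the ligand centroid to the centroid of protein atoms within 8 Å
of the ligand, stopping at the first van der Waals contact and backing off
one step. Water reorientation optimizes the only orientation-dependent
term of the score, the water-as-donor hydrogen-bond energy against nearby
acceptor-capable atoms.

A pose is flagged *strained* when any ligand heavy atom or water oxygen
still clashes at the 0.7 factor after placement.

## High-resolution refinement

Six Metropolis cycles (temperature 0.6, standard acceptance
min(1, exp(−ΔE/T))) of:

1. **Rigid-body perturbation** — ≤0.1 Å translation and ≤5° rotation of
   the ligand (about its heavy-atom centroid) and of each water
   independently.
2. **Side-chain repacking** over residues within 6 Å of the ligand or any
   water oxygen. Rotamers are three canonical χ₁ means (−60°, 60°, 180°)
   ± 10° sub-rotamers. Normal cycles use *rotamer trials* (per-residue
   argmin, rest fixed); cycle 3 uses a *full repack*: simulated annealing
   over the joint assignment (geometric temperature ladder 2.0→0.05, 60
   proposals) followed by a coordinate-descent polish (sweeping
   per-residue conditional argmins to convergence), which makes the result
   exactly the joint argmin whenever the repacked shells do not interact.
3. **Torsion minimization** of ligand rotatable bonds and interface χ
   angles (see below).

The best-seen pose then receives a final minimization that additionally
frees backbone φ/ψ of residues within 7 Å.

### Minimizer numerics

Steepest descent in torsion space with a batched forward-difference
gradient (h = 1e-4 rad; all displaced conformations scored in one
vectorized call, sharing the common prefix of applied rotations) and an
adaptive step-halving line search (step memory doubled between iterations,
capped at 0.1 rad, floor 1e-4 rad). Iteration stops when an iteration
improves the energy by less than 1e-6 or after 200 iterations. The energy
never increases; the method is local by design (the capped/ramped score is
kinked, which defeats curvature-based line searches — a quasi-Newton
variant was tried and rejected for exactly that reason). Torsion rotations
use componentwise Rodrigues formulas with a scalar path for the tiny
moving sets typical of χ angles.

## Ranking and success

From `n_struct` models (default 1000), the `n_total_cut` lowest by total
score are kept (default 100) and sorted ascending by ligand interface
score; a model's 1-based position is its rank (ties broken by total score,
then model id). A run *succeeds* when the top-ranked model has ligand RMSD
strictly below 2.0 Å. Ligand RMSD is computed over name-matched heavy
atoms with no superposition (the docking frame is shared); water RMSD is
oxygen-only under the optimal (Hungarian) water-to-water assignment.

## Replication statistics

`binomial_tail(n, p, k)` is the exact one-tailed P(X ≥ k), summed in log
space (gammaln + logsumexp) so tails of order 1e-10 and below are accurate.
`resampling_probabilities` estimates how often sampling noise alone flips a
run between success and failure: for each input's model pool, subsamples
are drawn without replacement and re-ranked with the selection cut scaled
to the subsample (cut = max(1, round(0.1·size))); flip frequencies are
aggregated by the full pool's outcome. Observed flip counts between two
protocols are then tested against the binomial null.

## Synthetic fixtures

`make_toy_pocket` builds a deterministic test system: a hemispherical
shell of serine/glycine residues (Fibonacci spiral, small seeded jitter)
around a 10-atom branched ligand with two hydroxyls, one ketone and three
rotatable bonds, optionally with one bridging water placed 2.8 Å from a
ligand hydroxyl and anchored by one (loose) or two (tight) additional
serines. The generator verifies the requested loose/tight label against
the classifier before returning, so the classification holds by
construction. `make_model_ensemble` plants known RMSDs (rigid translations,
for which translation norm equals RMSD exactly) and scores linear in RMSD
plus seeded noise, giving ranking tests a known ground truth.

What the generator emulates: the *shape* of a docking problem — a concave
polar site, a bridging water with the right contact counts, a ligand with
realistic descriptor counts — not the energetics or geometry of any real
complex.

## Determinism

Every stochastic component takes a `numpy.random.Generator`. Each model of
a run uses an independent stream seeded `(seed + model_index) % 2^31`, so
runs are order-independent and bit-reproducible; the run manifest records
the seed and a hash of the full configuration.

## Limitations

* The score is a stand-in: no electrostatics, solvation, or torsional
  strain terms; hydrogen-bond geometry uses a single angular ramp.
* The rotamer library covers χ₁ of SER/CYS/THR/VAL only; larger side
  chains are held fixed (with a warning).
* The minimizer is local; it inherits whatever basin sampling hands it.
* Water placement treats waters as rigid TIP3P-like geometry; no
  protonation-state logic.
* The synthetic pocket is idealized; absolute docking success rates on it
  say nothing about real targets.
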
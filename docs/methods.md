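# Methods

This note records the models, parameter choices and numerical conventions
behind flexscat, and what the synthetic-data experiments do and do not
demonstrate.

## Coordinate model and units

Coordinates are held in nm internally; PDB files (Å) are converted on read
and write.  Waters are dropped, other heteroatoms (notably bound Ca²⁺) are
retained.  Altloc conflicts resolve to the highest-occupancy conformer
(missing occupancy counts as 1.0).  Residue numbering is taken verbatim from
the file; all domain/linker ranges are inclusive.

Rigid domains and flexible linkers are declared by chain + residue range.
Contiguous rigid segments of one chain with no declared linker between them
(e.g. the CUB1-EGF pair that forms the dimer core) move as one body and are
treated as a single unit by the steric filter.

## Sphere models

Atoms are binned on a cubic grid (default cube side 0.55 nm, the classic
sphere-model resolution regime); each occupied cube becomes a sphere whose
volume equals the cube volume.  The dry volume target comes from residue
composition tables (consensus crystallographic volumes, all in
`constants.py`); glycan beads and pseudo-atoms carry per-atom overrides.

Volume matching: an integer search over occupancy cutoffs 1–8 minimizes the
volume error; the cube set is then refined to the exact cube count implied
by the target volume — densest cubes first, ties by grid index — and, for
sparse pseudo-atom models that underfill their interior, topped up with
adjacent cubes (most-buried surface positions first, then grid index).
This keeps the realized volume within half a cube of the target, i.e.
within 1% whenever the target exceeds ~50 cubes; very small models are
accepted at the granularity limit.  An explicitly supplied cutoff disables
the refinement and reproduces plain thresholding.

Hydration adds 0.3 g water per g glycoprotein (converted at 1.0 g/mL) as
spheres on empty cubes adjacent to the filled set, same deterministic
ordering.  The model's R_g includes the single-sphere parallel-axis term
(3/5)a².

## Scattering

The Debye sum over sphere pairs is accelerated by binning pair distances at
0.01 nm and evaluating sinc at each bin's mean distance; this matches the
direct double sum to well within 0.1%.

Guinier fits use weighted least squares of ln I vs Q² with the window
chosen iteratively so max(Q)·R_g ≤ 1.3 (cross-section window: user-chosen,
R_xs = √(−2·slope)); both limits are configurable because the exact windows
used on any given instrument are an analyst's choice.

P(r) from a model is the pair-distance histogram of the sphere centers,
Gaussian-smeared with σ equal to the sphere radius.  The smearing
represents the intra-sphere spread of scattering mass and simultaneously
suppresses the aliasing comb the cubic grid would imprint on the histogram.
P(r) from a curve is a regularized indirect transform: P ≥ 0 on a grid over
[0, dmax] with pinned endpoints, minimizing χ² plus α·‖second
differences‖² (default α = 10⁻⁴).  L is read where P falls below 10⁻³ of
its maximum past the global peak — an operational version of "where P(r)
reaches zero".  Peaks are called on a moving average spanning ≈0.7 nm with
a prominence threshold of 2% of the maximum.

The R factor is R = 100·Σ|I_e − η·I_c|/Σ|I_e| with η optimized by bounded
scalar minimization on log η ∈ [−3, 3] (tolerance 10⁻⁶); the scored Q range
is recorded in every score and defaults to the full overlap.

Replicate curves of a dilution series can be pooled by inverse-variance
averaging after concentration normalization, mirroring how experimental
series are combined before model fitting.

## Monte-Carlo linker search

The search is a generate-and-filter scan, not an equilibrium sampler: every
trial independently resamples all linker dihedrals (flat on (−180°, 180°]
by default; a bounded-step mode exists), so trials are i.i.d. draws from a
conformational prior and no Metropolis criterion applies.  Protein linker
residues vary φ/ψ; single-bead pseudo-residues pivot their downstream chain
about a random axis (ball joint).  Everything downstream rotates rigidly,
so rigid segments are preserved to machine precision, and glycan beads ride
with the domain they are anchored to.  Both chains are sampled
independently — no 2-fold symmetry is imposed.

Steric filtering rejects, at creation, any trial with heavy atoms of
different rigid units closer than 0.25 nm (below van der Waals contact);
linker atoms are exempt, and a glycan shares its host unit.  A neighbor
tree makes the check O(n log n); it is verified against brute force in the
tests.  Searches abort if acceptance falls below 2% over a 5,000-proposal
window (the harder five-linker full-length searches run with a 0.5% floor).

Per-trial random streams derive from (master seed, proposal counter), so
any trial is reproducible in isolation and results are bit-stable.

Selection keeps the n lowest-R-factor trials, ties broken by
|R_g(model) − R_g(target)| then trial index.  Because trials whose R factors
differ by less than the target's own noise floor (estimated as
100·√(2/π)·Σσ/Σ|I|) are statistically indistinguishable, the selection can
treat that band as a tie and rank inside it by R_g agreement first — the
same logic as judging candidate models against the measured R_g where the
curve-fit metric has no discrimination left.  The recovery experiments use
this noise-aware tie band; plain selection (ε = 0) is the default.

## Hydrodynamics

s20,w is predicted with the Kirkwood approximation over one bead per heavy
atom, radius 0.284 nm so that the bead envelope represents the hydrated
structure; water at 20 °C (η = 1.002 mPa·s, ρ = 0.99823 g/mL).  Overlapping
pairs are clamped to r = a in the sum to avoid divergence.  Partial
specific volume comes from residue composition (typically ≈0.73 mL/g); an
override is provided.  The Kirkwood double sum is a desk-scale stand-in for
shell-model programs; agreement with such programs is expected within the
±0.21 S band conventional for model-versus-experiment comparisons of
sedimentation coefficients, and elongation monotonicity (stretching lowers
s at fixed mass) is enforced by test.

Models above 20,000 atoms are reduced by a deterministic uniform subsample
of 5,000 beads; the friction is then evaluated for the full bead count
using the subsample's mean inverse pair distance, an unbiased estimator of
the Kirkwood sum that agrees with the exact evaluation to well under 1%.

## Geometry

Superposition uses the closed-form least-squares rotation (proper rotation
enforced) with iterative outlier trimming: pairs deviating by more than 2×
the current RMSD are dropped and the fit repeated (≤10 rounds), so "over N
residues" counts emerge from the data.  Buried surface area is
SASA(A) + SASA(B) − SASA(AB) with the Shrake–Rupley method (960
points/atom, 1.4 Å probe, packaged group radii); per-molecule BSA above
800 Å² is reported as the stable-dimer rule of thumb.  The bend of a
two-armed dimer is parameterized by d, the distance between the two
end-domain Cα centroids, and θ, the angle they subtend at the pooled
core-domain centroid.  This centroid construction is one operational choice
among several; comparisons against differently defined published angles
should expect offsets of a few degrees.

## Synthetic data

The toy dimer emulates the MASP architecture: two antiparallel arms joined
through a rigid four-domain core, domains as homogeneous pseudo-atom balls
(radii 1.5/1.1/1.5 nm for the fragment; six-domain arms for the full-length
variant) sized to the volumes of their real counterparts, linkers as
0.38 nm-spaced bead chains.  Ball centroids are exactly centered, unit
clearances of 0.3 nm make the straight start sterically valid, and the
requested bend angle is realized by solving a single out-of-plane hinge at
the first (EGF-CUB2-like) linker junction — the same articulation point the
sampler varies — to within 2°.  The fragment toy's dimensions (end-domain
separation ≈11 nm straight, length ≈14 nm, hydrated-model R_g ≈ 3.6–4.0 nm,
mass ≈57 kDa) put it in the regime of real three-domain protease-fragment
dimers.

The noise model is typical dilute-protein synchrotron SAXS: relative errors
growing from 1% at Q_min to 20% at Q_max with a Q^1.5-shaped law, three
concentrations (0.25/0.63/1.26 mg/mL) × three exposures — a nine-curve
series of the size such experiments pool.

The recovery experiment draws its ground truth from the sampler's own
proposal distribution conditioned on the requested bend angle (rejection
sampling to ±1°), rather than using the analytic single-hinge structure.
The orientation-averaged curve defines an equivalence class of shapes, and
an analytically extended truth is an extreme member of its class, which
would bias any sampled reconstruction toward larger angles; a prior-typical
truth makes the recovered ensemble straddle it.  At the study scale (2,000
accepted trials, nine pooled curves) the bend angle is recovered to within
a few degrees typically and ±15° across seeds, with the truth inside the
ensemble mean ± 2 sd.

What the synthetic experiments do not show: the toys have no side-chain
chemistry, no interdomain contacts beyond hard-sphere exclusion, isotropic
homogeneous domains, and Gaussian uncorrelated noise.  Passing them
validates the pipeline's bookkeeping, determinism, ranking logic and the
direction of its inferences (bent ⇒ better curve fit and faster
sedimentation), not the accuracy of any particular real-protein model.

## Problem sizes

The default experiments run on one CPU in a few minutes: fragment searches
use 2,000 accepted trials of a ~730-pseudo-atom dimer (~580 hydrated
spheres), full-length searches 300 accepted trials of ~1,500 pseudo-atoms.
These sizes were chosen as the smallest at which the recovery statistics
are stable across seeds.

## Known limitations

- The Kirkwood friction underestimates shell-model results by a systematic
  few percent for compact particles; predictions should be compared within
  the ±0.21 S band, not at face value.
- The indirect transform's L is sensitive to the assumed dmax when the
  curve is truncated; the `truncated` flag marks forced misfits.
- Sphere-model curves inherit grid quantization noise of order 0.1–0.3 R
  units between rebuilds of the same structure; differences below that are
  not meaningful.
- Guinier R_g of strongly elongated particles is window-truncated and reads
  low relative to the coordinate R_g; this mirrors experimental practice.
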
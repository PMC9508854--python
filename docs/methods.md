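# Methods

## Scope and model resolution

`chromoclutch` analyzes chromatin mechanics at *nucleosome* resolution.  A
configuration is one or two chains of nucleosomes; each nucleosome carries a
rigid-body pose (geometric center plus an orthonormal triad whose `normal`
is the disc axis) and a scalar outer-layer wrap fraction `w ∈ [0.5, 1]`.
The lower bound encodes the assumption that the inner DNA layer never
detaches from the histone core at the forces of interest (≤ 6 pN); only the
outer ~half of the 147 bp wrap is a degree of freedom.  Bead-level
bookkeeping (one bead per amino-acid residue, three interaction sites per
nucleotide with the 5′-terminal phosphates absent) is provided for
cross-checking against residue-level coarse-grained models: a 12-nucleosome
array with 20 bp linkers and 974-residue octamers counts 23 590 sites.

When frames are reduced from bead coordinates, the center is the unweighted
geometric mean of **all** of the nucleosome's beads and the frame comes from
principal components of the bead cloud (normal = smallest-variance axis).
Which beads define the "geometric center" is genuinely ambiguous at bead
level (all beads vs DNA only); using all beads is this package's choice and
is isolated in one function (`frames_from_beads`) so an alternative
convention is a one-line change.

## Collective variables

* `d_stack` — mean |c_i − c_{i+2}| over a chain; small when next-nearest
  nucleosomes stack as in the two-start zigzag fiber.
* `q_wrap` — mean wrap fraction (1 = fully wrapped).  At frame resolution
  the wrap fraction *is* the state variable; a bead-level contact-fraction
  variant would require bead data this model does not carry.
* `alpha` — max/min over the (i, i+2) distances.  Exactly 1 for uniform
  extension; ≫ 1 for clutched configurations.  Only (i, i+2) pairs enter,
  never longer-range pairs.
* `shear`/`normal` — decomposition of an inter-nucleosome displacement
  against the *first* nucleosome's disc plane; `shear² + normal² = |r|²`.
  The decomposition is asymmetric in (i, j) by construction; a symmetrized
  variant (mean over both orderings) is provided.
* `inter_chain_contacts` — number of cross-chain nucleosome pairs with
  center distance strictly below 15 nm.
* `ee_per_nuc` / `ee_z_per_nuc` — DNA end-to-end distance (norm / signed
  z-projection) per nucleosome.  The z-projection is the coordinate
  conjugate to a constant pulling force along z and is the default axis for
  force-extension work.

DNA termini are stored when available and otherwise extrapolated from the
terminal nucleosomes: `e = c_t + u · (L0/2 + λ(1 − w_t))` with `u` the unit
vector away from the neighbour, `L0` the resting linker length and `λ` the
contour released per unit unwrapping (below).

## Toy chromatin simulator

The synthetic-data engine stands in for cluster-scale residue-level
molecular dynamics.  It is a Metropolis Monte Carlo sampler over nucleosome
poses and wrap fractions with a deliberately minimal energy (kcal/mol, nm):

| term | form | default |
|---|---|---|
| stacking | −ε_s · ((n̂_i·û)(n̂_j·û))² · exp(−(r−r_s)²/2w_s²) | ε_s = 8.0, r_s = 6.0, w_s = 1.5 |
| excluded volume | k_rep·(1−s)²_+ per body, s from an ellipsoidal metric | σ = 10 (in-plane) / 5.5 (normal), k_rep = 10 |
| linker spring | ½ k_l (r − L)², L = L0 + λ[(1−w_i)+(1−w_j)] | k_l = 1.0, L0 = 9.0, λ = 13.6 |
| unwrapping | ε_u (1 − w) per nucleosome | ε_u = 8.0 |
| pulling force | −(f/6.948) · z-extension of the DNA termini | f in pN |
| umbrella | ½ k (CV − c)² | layout per experiment |

Unit conventions are fixed as named constants: kB·300 K = 0.596 kcal/mol
and 1 kcal/(mol·nm) = 6.948 pN.

The λ convention: λ is the contour length added to **each** adjacent linker
per unit (1 − w), so fully unwrapping one nucleosome (w: 1 → 0.5) releases
2 · λ · 0.5 = 13.6 nm ≈ 40 bp of DNA in total.

**Calibration.**  The defaults were chosen, once, so the model reproduces
the qualitative mechanics the analysis modules are built to detect:
unwrapping one nucleosome at 4 pN gains ≈ 7.8 kcal/mol of force work
against a 4 kcal/mol penalty (favourable above ≈ 2 pN), while the
8 kcal/mol stacking well keeps face-face contacts intact at those forces.
The equilibrium at 4 pN is therefore *clutched* — stacked groups separated
by unwrapped DNA, clutch ratio α ≈ 7 — whereas freezing wrap at 1
(`allow_unwrap=False`, mirroring control simulations with fully rigid
nucleosomal DNA) forces more uniform extension with an α free-energy
minimum near 3.  A shallower stacking well (ε_s ≈ 3) loses this contrast:
at 4 pN the chain unstacks completely under both conditions and α collapses
to ~1.25, so the well depth was set to 8 during initial calibration and not
revisited.

Moves are single-nucleosome rigid translations (Gaussian, σ = 0.7 nm),
rigid rotations (random axis, Gaussian angle σ = 0.35 rad) and wrap
increments (uniform ±0.05, reflected at the [0.5, 1] bounds).  Interaction
energies are updated incrementally (pairs touching the moved nucleosome,
its two linkers, its unwrap term); bias and force terms are recomputed per
trial.  The accumulated and from-scratch totals agree to < 1e-6 kcal/mol
over 10⁴ moves (tested).  Trajectories are bit-reproducible for a given
seed; umbrella campaigns derive window seeds as base + window index.

Structure generators produce the three reference morphologies analytically:
two-start zigzag fibers (all (i, i+2) distances equal to the stacking
distance, α = 1 exactly), clutched chains (within-clutch spacing intra/2
along z and boundary gaps placed so every bridging (i, i+2) distance equals
`gap` exactly, hence α = gap/intra), and uniformly extended chains.

**What the toy simulator does *not* emulate:** bead-level DNA/protein
interactions and sequence effects, hydrodynamics or any real dynamics
(Monte Carlo time is not physical time), histone-tail-mediated
interactions, and the absolute energy scales of real chromatin.  Tests that
pass on this model validate the *analysis machinery* (estimators,
collective variables, clustering) and the qualitative unwrapping-vs-clutch
mechanism, not quantitative force-extension magnitudes of real fibers.

## Free-energy estimation

`wham` is the standard self-consistent weighted-histogram estimator in log
space, iterated until the window free energies move by < 1e-7 kcal/mol
(default cap 1e5 iterations), on a shared 1D or 2D grid (default 100 / 50×50
bins over the sampled range).  Bins never visited are NaN and stay NaN;
profiles are referenced to min 0.  Center-adjacent windows sharing no
occupied bin trigger a warning and flag the profile `poor_overlap`.
Against an exactly-sampled quadratic truth (8 windows × 5·10⁴ Gaussian
samples) the reconstruction error is ≈ 0.01 kcal/mol RMS over the central
80% of the range, an order of magnitude inside the 0.1 kcal/mol bound the
test asserts.

`block_errors` implements the three-block protocol exactly: each window's
series is cut into three equal contiguous blocks, the estimator runs per
block, and the per-bin error is the ddof-1 standard deviation of the block
estimates.  No autocorrelation correction is applied inside blocks.  For
the *self-consistency benchmark* specifically (reweighting vs direct
simulation), errors come instead from three independent replicas — full
window campaigns and independent direct runs — because contiguous
sub-blocks of one trajectory underestimate the slow collective modes of a
stiff chain; this choice is deliberate and documented here because it
determines what "within error bars" means in that check.

Force-extension: `tilt` subtracts `(f/6.948)·n_scale·x` from an extension
profile (`n_scale` converts a per-nucleosome axis to total extension);
`mean_extension` is the Boltzmann average over defined bins, computed with
a log-sum-exp shift.  Exact identities used as tests: a harmonic profile
shifts its minimum by `f/(6.948 k)` and its Boltzmann mean linearly with
force; a flat profile under force gives a truncated-exponential mean;
`d⟨x⟩/df = Var(x)/kBT ≥ 0` guarantees monotonicity.  `harmonic_fit` fits a
quadratic to bins within 2 kcal/mol of the minimum and flags the fit as
anharmonic when the RMS residual exceeds 0.15 kcal/mol (the threshold is a
package choice; flat-bottomed profiles under strong force trip it).

`debye_length` evaluates κ⁻¹ = sqrt(ε0 εr kB T / (2 NA e² I)) with CODATA
constants (εr = 78.4 by default); four Debye lengths at 150 mM, 300 K is
3.1496 nm.

## Force-matched surrogate

The surrogate maps the vector of pairwise center distances (fixed i < j
order; 66 entries for a 12mer, 6 for a tetranucleosome), z-scored with
training statistics, through a 2×64 tanh MLP to a scalar energy.  Training
minimizes the mean squared deviation between −∇_centers NN and supplied
reference mean forces.  The double-backpropagation this requires (gradients
of a gradient) runs on a ~150-line reverse-mode autodiff written for
exactly the operations in this loss; the loss gradient is verified against
finite differences in the test suite.  Optimization is full-batch Adam,
learning rate 1e-2 decayed exponentially to 1e-3, 2000 epochs, with every
10th example held out for validation.  The stride split (rather than a
random one) makes the fit exactly invariant under duplicating the training
set, which is also tested.  Training is deterministic per seed.

Training ensembles are perturbed zigzag tetranucleosomes: the ideal fiber
geometry plus per-coordinate displacements drawn uniformly in ±3 nm,
rejecting configurations with any center pair closer than 4 nm.  Bounded
uniform noise covers the accessible distance domain, including its edges,
at usable density; unbounded Gaussian displacements were found to leave the
rare far-out configurations (where reference forces are largest) outside
the training hull, which dominated the held-out error.

Energies of arrays longer than the training size are composed as the sum of
sliding 4-mer window evaluations over (i, …, i+3).  This composition is a
design choice, not a uniquely determined transfer rule: it double-counts
nothing at the 2-body level it models but cannot represent interactions
spanning more than four consecutive nucleosomes.  Surrogate Monte Carlo
(`mc_most_probable`) samples centers (and wrap only when a q_wrap umbrella
needs it), rejects moves violating a 4 nm minimum separation to stay inside
the training domain, and returns the lowest-energy configuration visited.
Surrogate proposals are used **only to initialize** toy-simulator sampling;
every reported free energy is recomputed by the simulator plus WHAM.

## Clustering and representatives

Structure comparison uses optimal-superposition RMSD over nucleosome
centers (centroid removal, Kabsch rotation with the proper-rotation
determinant correction via `scipy.spatial.transform.Rotation`).  The
nucleosome-center atom set matches the data model's resolution; note that
superposition RMSD violates the triangle inequality in general, which is
why the single-linkage partition is defined — and implemented — as the
connected components of the dist < cutoff graph (strict inequality), which
coincides with cutting the single-linkage dendrogram.  Cluster ids are
ordered by decreasing size; each cluster's representative is its medoid
(minimum summed RMSD to the other members, ties to the lowest trajectory
index).  `select_representatives` first filters to configurations within a
tolerance of a target per-nucleosome extension, then clusters and returns
medoids of the largest clusters.  The default cutoff of 3 nm is a package
choice, made configurable because no principled value exists at this
resolution.

## Pipeline

`run_experiment` composes the stages from one TOML config: per force,
umbrella windows on the toy simulator (default layout: q_wrap centers
0.45–0.90 step 0.15 at 50 kcal/mol, or d_stack centers 10–30 nm step 5 at
0.05 kcal/(mol·nm²)), WHAM with three-block errors, an unbiased
constant-force run for the α profile and mean extension, and
representative-structure PDBs.  Initial structures default to the zigzag
fiber; `init = "surrogate"` uses a pre-trained surrogate model under the
window's bias.  Window steps default to desk scale (thousands of sweeps);
production runs raise `steps_per_window` in the config.  Every seed is
derived from the config seed, and the manifest records all seeds plus
SHA-256 hashes of every output, so re-running a config is bit-identical
(tested).

## Validation experiment sizes

The packaged validation experiments (`chromoclutch.benchmarks`, also driven
by `scripts/acceptance.py`) use: 8 × 5·10⁴ exact samples for the WHAM
oracle; 2000 tetranucleosome configurations and 2000 epochs for force
matching; 1000 random instances for the clustering oracle; 2 × 3·10⁴ MC
sweeps for the 4 pN clutch contrast; and 3 replicas × 12 windows × 6000
sweeps plus 3 × 3 direct runs of 8000 sweeps for the reweighting
consistency check.  These sizes were chosen so each experiment's
statistical resolution comfortably exceeds the effect it measures on a
single CPU core.

## Known limitations

* The toy model's force-extension curve is not quantitatively comparable to
  single-molecule experiments; only its mechanism (shear-preserving
  compaction at low force, unwrapping-enabled clutch formation near 4 pN)
  is meaningful.
* 1D umbrella sampling on the extension coordinate cannot equilibrate the
  orthogonal fold/unfold coordinate of the toy chain; the reweighting
  consistency check is therefore confined to the folded regime that direct
  1–3 pN simulations occupy.  Mapping the full unfolding surface requires
  2D umbrella layouts (supported by `wham`).
* The surrogate's sliding-window composition is untested against any
  longer-range reference; treat 12mer surrogate energies as initialization
  heuristics only.
* `inter_chain_contacts` uses a strict 15 nm cutoff with no smoothing; it
  is a counting observable, not a biasable CV in the simulator.
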
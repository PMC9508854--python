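# chromoclutch

Nucleosome-resolution analysis of chromatin unfolding under tension and
crowding.

Chromatin in vitro folds into a compact two-start zigzag fiber in which
nucleosome *i* stacks on nucleosome *i+2*; in vivo imaging instead shows
irregular "clutches" — small groups of touching nucleosomes separated by
stretches of exposed DNA.  One proposed reconciliation is mechanical:
pulling forces of a few piconewton, as exerted by molecular motors and
nuclear attachments, unfold the fiber through clutched intermediates in
which some nucleosomes partially unwrap their outer DNA layer to release
contour length while the rest stay stacked.  This package provides the
computational machinery to study that scenario quantitatively at
nucleosome resolution, for computational biophysicists working with
coarse-grained chromatin models:

* **Collective variables** — the stacking distance
  `d_stack = ⟨|c_i − c_{i+2}|⟩`, the wrap fraction `q_wrap`, the clutch
  ratio `α = d_max(i,i+2) / d_min(i,i+2)` (1 for uniform extension, ≫ 1
  for clutched chains), shear/normal decomposition of inter-nucleosome
  displacements, inter-chain contact counts, and end-to-end extension per
  nucleosome.
* **Free energies** — self-consistent WHAM on 1D/2D umbrella-sampling
  grids, three-block error bars, profile tilting by a constant force
  `F_f(x) = F_0(x) − f·x/6.948`, Boltzmann force–extension prediction, and
  harmonic fits near the minimum.
* **A toy chromatin simulator** — Metropolis Monte Carlo over rigid
  nucleosome poses and wrap fractions with stacking, ellipsoidal excluded
  volume, wrap-dependent linker springs, an unwrapping penalty, constant
  z-axis pulling, and umbrella biases; plus analytic generators for fiber,
  clutched, and uniformly extended reference structures.
* **A force-matched surrogate** — a small neural network mapping
  inter-nucleosome distances to free energy, trained so its negative
  gradients reproduce reference mean forces, sampled by Monte Carlo to
  propose most-probable configurations under a bias.
* **Representative structures** — single-linkage clustering under
  optimal-superposition RMSD with medoid extraction.

File formats: frame-table CSV (canonical), extended XYZ trajectories, JSON
window metadata, pseudo-atom PDB output, and an optional LAMMPS-dump
reader.  See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from chromoclutch import colvars
from chromoclutch.freeenergy import debye_cutoff
from chromoclutch.sampling import (Bias, ToyEnergyModel, generate_clutch,
                                   generate_fiber, run_mc)
from chromoclutch.structures import build_topology

topo = build_topology(12, 20)
print(f"12mer bead count: {topo.total_beads}")
print(f"electrostatics cutoff (4 Debye lengths, 150 mM): "
      f"{debye_cutoff(0.15):.2f} nm")

fiber = generate_fiber(12)
print(f"fiber:  d_stack = {colvars.d_stack(fiber):.1f} nm, "
      f"alpha = {colvars.alpha(fiber):.2f}")
clutch = generate_clutch(12, [3, 3, 3, 3], intra=6.0, gap=24.0)
print(f"clutch: d_stack = {colvars.d_stack(clutch):.1f} nm, "
      f"alpha = {colvars.alpha(clutch):.2f}")

traj = run_mc(ToyEnergyModel(), fiber,
              [Bias("constant_force", force_pN=4.0)], steps=8000, seed=1)
s = traj.cv_series.iloc[3000:]
print(f"4 pN equilibrium: alpha = {s['alpha'].mean():.1f}, "
      f"q_wrap = {s['q_wrap'].mean():.2f}, "
      f"extension = {s['ee_z_per_nuc'].mean():.1f} nm/nucleosome")
```

prints

```
12mer bead count: 23590
electrostatics cutoff (4 Debye lengths, 150 mM): 3.15 nm
fiber:  d_stack = 6.0 nm, alpha = 1.00
clutch: d_stack = 16.8 nm, alpha = 4.00
4 pN equilibrium: alpha = 4.2, q_wrap = 0.90, extension = 4.9 nm/nucleosome
```

The bead count is the residue-level size of a 12-nucleosome array (one
bead per amino acid, three sites per nucleotide, 5′-terminal phosphates
omitted).  The ideal fiber has every (i, i+2) pair at the 6 nm stacking
distance, so α is exactly 1; the 4×3-trimer clutch construction bridges
clutches at 24 nm, so α = 24/6 = 4.  Under a 4 pN pull the simulator's
chain partially unwraps (q̄_wrap ≈ 0.90) and adopts clutched configurations
(α ≈ 4) rather than extending uniformly — run the same command with
`ToyEnergyModel(allow_unwrap=False)` and α drops to about 3, with
q_wrap pinned at 1.

A full umbrella-sampling experiment (windows → WHAM → α profile →
representative PDBs, with a seeded manifest) runs from one TOML config:

```sh
chromoclutch report --config experiment.toml
```

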
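# Methods

## Problem and model

`facegrid` predicts partner-specific protein–protein interaction interfaces
from the structures of the two (typically unbound) subunits. The premise is
that an interface can be located from the *complementarity of surface
properties* — opposite charge, mutual hydrophobicity, mutual evolutionary
conservation — largely independently of detailed shape, provided the spatial
neighbourhoods of the properties are preserved. The pipeline therefore
reduces each protein's accessible surface to a small set of 2D images and
searches for the maximally complementary placement of two proteins' images
with standard image-registration machinery:

1. **Surface.** A Shrake–Rupley point cloud samples the solvent-accessible
   surface: each heavy atom's sphere of radius *r*ᵢ + *r*_probe
   (probe 1.4 Å) is covered with quasi-uniform points (Fibonacci spiral,
   240/atom) and points occluded by neighbouring expanded spheres are
   dropped. Residue depth is the mean over a residue's heavy atoms of the
   minimum distance to this cloud; residues with depth < 5 Å are "surface",
   and all of their heavy atoms enter the reduction. The extra 5 Å admits
   sub-surface atoms whose properties still shape the binding site.
2. **Faces.** The surface atoms are partitioned into k = 6 faces by Lloyd's
   K-means seeded at the six axis-extreme atoms (max/min x, y, z). The
   biased seeding makes the segmentation deterministic; empty clusters are
   repaired by re-seeding with the point farthest from its centroid. Because
   an interface may straddle a face boundary, the whole segmentation is
   recomputed after rigidly rotating the protein 45° about x and then y,
   giving a second initialization; optionally the protein is first oriented
   by the principal axes of its heavy-atom cloud (PCA mode).
3. **Grids.** Each face is projected onto its least-squares (PCA) plane —
   the projection preserving Å units, so grid extent tracks cluster extent —
   and binned into 5 Å × 5 Å boxes; each occupied box stores the mean of the
   atomic property over its atoms and remembers which atoms it holds.
   Unoccupied boxes hold 0, which is neutral for every property: charges are
   signed, the Wimley–White interfacial scale is roughly centred on zero,
   and conservation grades are shifted to grade − 5 before gridding
   (switchable to raw grades).
4. **Scoring.** For each property, every pair of faces (6 × 6 = 36), every
   in-plane rotation of the partner grid (10° steps, nearest-neighbour
   resampling that is an exact cell permutation at multiples of 90°), and
   every lag of the full zero-padded 2D cross-correlation is scored by the
   sum of element-wise products. Hydrophobicity and conservation are ranked
   by maximum score; charge by minimum, since complementary charges multiply
   to negative values. Lags with fewer than 4 co-occupied cells are skipped
   (raw correlation over 1–3 cells is noise; configurable down to 1). The
   initialization (unrotated vs 45°-rotated) with the better sum of its top
   10 scores is kept.
5. **Consistency and mapping.** A property's prediction is *consistent* when
   its top 10 placements all involve the same two faces. The final answer is
   the first consistent property in the order charge → conservation →
   hydrophobicity (configurable); in antibody mode the top charge placement
   is used regardless, reflecting the variable region's escape from
   conservation/hydrophobicity signals. The winning placement's overlapping
   occupied cell pairs are traced back through the bin→atom maps (and
   through the rotation's cell map for the partner) to residue sets on both
   proteins. A flag re-runs selection excluding the winning face pair to
   expose a second interface.

## Significance and evaluation

The extreme-value (shuffle) test permutes the property values uniformly
among each protein's surface atoms — geometry, depths and faces fixed —
rebuilds the grids, and repeats the *entire* scoring procedure, including
the choice between the two initializations, recording each replicate's top
score. This point matters: the observed score is the outcome of a selection
over initializations, so replicates must make the same selection, otherwise
the null is stochastically too weak and p-values concentrate near zero. With
the full procedure replicated, the p-value of an unstructured (random)
property is uniform to within the 1/n granularity of an empirical tail
probability. p is reported as the plain empirical tail k/n (a (k+1)/(n+1)
small-sample correction is available by flag), with ≥ for max-type
properties and ≤ for charge.

A *true* interface residue has any heavy atom within 5 Å of a heavy atom of
the partner in the bound complex (10 Å available as a forgiving variant).
Predictions are scored as residue-level confusion matrices over all residues
of each subunit — precision TP/(TP+FP), recall TP/(TP+FN), accuracy
(TP+TN)/total, F1 the harmonic mean — with zero-denominator metrics defined
as 0. Partner metrics are macro-averaged by default; pooling is a flag.

## Synthetic data

The fixture generator builds toy proteins: `n_residues` residue centres on a
Fibonacci lattice over a sphere/ellipsoid/two-lobe surface of radius
`radius`, each residue contributing `atoms_per_residue` pseudo-atoms with
Gaussian jitter (σ = 0.5 Å), written as alanine so every property path runs.
Defaults — 64 residues × 4 atoms on a 10 Å sphere, posed at a 1.0 Å surface
gap — were chosen so that a 5 Å contact patch spans ≈ 5–7 residues
(≈ 20–26 atoms), comfortably inside one face of the 6-face segmentation:
the engineered-interface construction (planting +1 on one partner's true
contact atoms and −1 on the other's, zero elsewhere) is then solvable by
design, which is exactly what it is for — a positive control with known
ground truth.

Structural distortion is emulated by a sum of three seeded long-wavelength
sinusoidal displacement modes (wavelength twice the structure diameter),
rescaled so the RMSD over each residue's first atom — the Cα stand-in —
hits the requested target exactly. This reproduces the relevant stressor of
normal-mode-style distortion (coherent, smooth, low-frequency motion at
controlled amplitude) without an elastic-network eigensolver; an anisotropic
network model is noted as future work.

What the fixtures do *not* emulate: real backbone/side-chain geometry and
chemistry, non-convex surfaces with deep clefts, heterogeneous residue
composition, and realistic conservation patterns. Passing fixture tests
demonstrates the machinery's correctness and the method's behaviour under
its own assumptions, not benchmark-level accuracy on crystal structures.

## Numerical choices

- Cross-correlation is direct vectorized summation
  (`sliding_window_view` + `einsum`); a brute-force double loop and
  `scipy.signal.correlate2d` serve as independent cross-checks in tests
  (agreement exact on integers, 1e-8 on floats).
- Ties: K-means assignment ties go to the lowest face label; biased seeds
  take the lowest atom index; score ties break lexicographically by
  (face_a, face_b, rotation, lag); initialization ties go to the unrotated
  start; modal-face-pair ties go to the earliest-ranked hit.
- Projection-plane axis signs are fixed by making the skewness of each
  projected coordinate non-negative, so reflections cannot flip grids
  between runs.
- Degenerate inputs: single-atom faces project to a 1×1 grid; collinear
  clouds make PCA orientation fail loudly; coincident points make the
  6-face K-means fail loudly rather than emit empty faces.
- When no property is consistent, the fallback "best-scoring" property is
  the one with the largest |top score| (scores are not comparable across
  properties; the absolute value accommodates charge's negative
  convention), with the configured property order breaking ties.
- All randomness flows from a single `Config.rng_seed` through
  `numpy.random.default_rng`; the pipeline itself is deterministic — only
  fixture generation and the shuffle test consume randomness.

## Problem sizes

Tests and the acceptance script run the full pipeline on the default
64-residue fixtures: 10 seeds for recovery and distortion checks, 200
permutation replicates for planted/constant shuffle calibration, and 50
runs × 60 replicates (at 30° rotation steps) for the null-uniformity check
— sizes at which each quantity is stable to well within its acceptance
margin.

## Known limitations

- The 2D projection of a non-convex face can fold distant atoms onto the
  same bin; the PCA plane minimizes but does not eliminate this.
- In-plane grid rotation approximates 3D re-orientation; only the 45°/45°
  re-initialization samples genuinely different 3D segmentations.
- Raw (unnormalized) correlation favours larger overlaps for max-type
  properties; the min-overlap threshold bounds, but does not remove, this
  bias.
- Centred conservation rewards variable–variable alignment as much as
  conserved–conserved (both products are positive); raw-grade mode trades
  that for occupancy-size bias instead.
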
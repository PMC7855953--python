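# facegrid

Partner-specific prediction of protein–protein interaction interfaces from
reduced 2D surface property grids.

## The problem

Most structure-based interface predictors score the propensity of a single
protein's surface patches and ignore the partner. `facegrid` is
*partner-specific*: given the structures of two proteins believed to
interact (typically in their unbound forms), it asks where their surfaces
are maximally **complementary** in charge, hydrophobicity, or evolutionary
conservation — and returns the interface residues on *both* partners. The
reduced representation deliberately discards fine shape detail, which makes
the prediction tolerant of conformational change and of the coordinate
uncertainty of homology models, and cheap enough to use as a pre-filter for
docking or for assembling large multi-subunit complexes.

## The method

Each protein's solvent-accessible surface (Shrake–Rupley point cloud,
probe radius 1.4 Å) defines residue depths; residues with mean heavy-atom
depth < 5 Å form the surface. The surface atoms are partitioned into
**k = 6 faces** by K-means seeded at the six axis-extreme atoms, each face
is projected onto its PCA plane and binned into 5 Å × 5 Å boxes holding the
mean atomic property, so the protein becomes six small images per property.

For two proteins A and B the method evaluates the full zero-padded 2D
cross-correlation

&nbsp;&nbsp;&nbsp;&nbsp;S(Δ) = Σᵢⱼ Aᵢⱼ · B<sub>(i,j)−Δ</sub>

for all 36 face pairs, all in-plane rotations of B's grid in 10° steps, and
all lags Δ — once for the native K-means initialization and once after
rotating the protein 45° about x and y (so an interface split across a face
boundary gets a second chance). Hydrophobic and conserved complementarity
maximize S; charge complementarity minimizes it (opposite signs multiply to
negative values). The initialization with the better top-10 score sum is
kept, and a prediction is **consistent** when all top-10 placements involve
the same two faces. The winning placement is mapped back through each bin's
atom list to residue sets on both partners.

Significance is an extreme-value permutation test: property values are
shuffled among each protein's surface atoms, the whole scoring procedure is
re-run (1000 replicates by default), and the empirical tail probability of
the observed top score is reported. Predictions are evaluated against the
bound complex as residue-level confusion matrices, where a true interface
residue has any heavy atom within 5 Å of the partner.

## Worked example

Generate a synthetic contact pair with an engineered charge interface
(+1 on A's true contact atoms, −1 on B's, 0 elsewhere), predict, evaluate,
and test significance:

```bash
facegrid fixtures --seed 3 --engineer-charges --out-dir pair
facegrid predict pair/partner_a.pdb pair/partner_b.pdb \
    --pqr-a pair/partner_a.pqr --pqr-b pair/partner_b.pqr \
    --property charge --out-dir out
```

```
winning property charge (consistent=True), faces 1-2, score -3.27
report written to out/report.json
```

All ten top placements fell on the same face pair (1 of A against 2 of B),
so the prediction is consistent; the score is negative because opposite
charges multiply to negative products. Evaluating against the bound pose
(`bound.pdb` is simply the two posed partners in one file):

```bash
facegrid evaluate out/report.json bound.pdb --chains-a A --chains-b B
```

```
partner tp  fp  fn  tn  precision  recall  accuracy  f1
a       4   2   2   56  0.6667     0.6667  0.9375    0.6667
b       7   1   2   54  0.8750     0.7778  0.9531    0.8235
combined -  -   -   -   0.7708     0.7222  0.9453    0.7451
```

Of A's 6 true interface residues the prediction recovered 4 with 2 false
positives; macro-averaged F1 is 0.75. The permutation test confirms the
placement is no accident of geometry:

```bash
facegrid shuffle-test pair/partner_a.pdb pair/partner_b.pdb \
    --pqr-a pair/partner_a.pqr --pqr-b pair/partner_b.pqr \
    --property charge --seed 3 --n-shuffles 200
```

```
observed -3.27, p = 0 (200 shuffles)
```

None of 200 shuffles of the same charges over the same surface reached the
observed complementarity.

The same workflow runs on real structures: pass the unbound PDB files (plus
PQR and/or ConSurf grade files for the properties you want), and evaluate
against the bound complex with `--chains-a/--chains-b` naming each
partner's chains. The library API (`facegrid.predict_interface`,
`facegrid.shuffle_test`, `facegrid.evaluate_prediction`, ...) exposes every
stage individually; see `docs/methods.md` for the model, parameter
defaults, and design decisions.

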
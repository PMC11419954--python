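# Methods

`neoasurf` is a desk-scale library for three linked problems in
structural neoantigen analysis: representing peptide–HLA class I
(pHLA-I) complexes, featurizing the TCR-exposed molecular surface of
the bound peptide, and scoring the *foreignness* of a mutant peptide
against its wild-type (WT) counterpart. Everything runs on synthetic
fixtures generated in-package; no experimental structures or curated
immunogenicity corpora are bundled or required.

## The pHLA-I data model

A complex is two chains: the HLA heavy chain restricted to residues
1–180 (the α1/α2 binding-groove domain; the α3/β2m part plays no role
in peptide presentation geometry) and a short peptide of 7–14 residues
(up to 16 accepted). Peptide sequences are padded to a fixed length of
16 tokens over the 20-letter alphabet plus a PAD sentinel, matching the
fixed model width. PDB I/O goes through gemmi; author residue numbering
is used throughout (the groove anchors Gln72/Thr143/Tyr159 are named by
author number), insertion codes are rejected, and for alternate
conformers the highest-occupancy altloc is kept with a deterministic
tie-break on the altloc letter. Chain roles default to: longest chain =
HLA; among chains of 7–16 residues, the one spatially nearest the HLA
is the peptide; explicit chain-id overrides are available for
multi-copy crystal files.

## Structural metrics

* **Kabsch superposition** (SVD with a determinant correction) returns
  a proper rotation, translation and RMSD; scipy's `align_vectors` and
  a brute-force rotation-grid search serve as independent cross-checks
  in the tests.
* **TM-score** uses the Zhang–Skolnick normalization
  d0 = 1.24·(L−15)^{1/3} − 1.8, floored at 0.5 Å because the standard
  formula is invalid for the ≤16-residue peptides this package handles.
  The superposition search seeds from every contiguous fragment of ≥4
  residues plus the global Kabsch fit and iterates re-superposition on
  the closer half of residues to convergence; an exhaustive
  random-restart search validates it on fixtures.
* **lDDT** is the superposition-free fraction of preserved
  inter-residue atom distances (15 Å inclusion radius; 0.5/1/2/4 Å
  thresholds), scaled to [0, 100].
* **pLDDT filtering** retains predictions with aggregate (unweighted
  per-residue mean) ≥ 92; the boundary is inclusive because only
  strictly low-confidence samples are discarded. 92 is the operating
  point at which self-estimated confidence tracks true structural
  accuracy closely enough for self-distillation.
* **Interaction strength** of a peptide residue is 1/d² where d is the
  minimum distance from any of its atoms to any HLA atom, floored at
  0.1 Å so clashed synthetic input stays finite.
* AUROC (Mann–Whitney, ties half credit) and AUPRC (step-wise
  precision–recall integration) come from scikit-learn; exhaustive
  concordant-pair counting is the in-test oracle.

## Molecular surface and features

The solvent-excluded surface is approximated by an internal backend so
no external binary is needed: each atom contributes a Gaussian density
exp(−B(|x−xᵢ|²/Rᵢ² − 1)) with Rᵢ its van der Waals radius, and the
isosurface at level 1 is extracted by marching cubes. For an isolated
atom this surface is exactly the vdW sphere; the blobbyness
B = 6/probe_radius controls how readily neighboring atoms bridge,
emulating the probe's smoothing role. Faces are oriented so normals
point along decreasing density (outward).

Meshes are regularized to a target edge length of 1.0 Å by an
isotropic remesher: edges longer than 4/3 of the target are split at
midpoints (marked globally, so adjacent faces split consistently),
edges shorter than 4/5 are collapsed under the standard link condition
plus a guard against "diamond" configurations that would duplicate
faces, followed by tangential Laplacian smoothing. Edge flips are not
implemented; a final fin-removal pass guarantees an edge-manifold
result. The median edge length lands within 25% of the target.

Per-vertex geometry: principal curvatures come from a quadric fit
(h = Dx + Ey + Ax² + Bxy + Cy²) over the 2-ring in the vertex tangent
frame, with Gaussian distance weights of width 0.5× the mesh
resolution — unweighted fits overestimate curvature by ~25% on tightly
curved surfaces (radius ≈ 2 Å) because distant 2-ring points leave the
parabolic regime. Curvatures are signed so convex regions are positive.
The **shape index** is (2/π)·arctan((κ₁+κ₂)/(κ₁−κ₂)) with κ₁ ≥ κ₂,
giving values in [−1, 1]; umbilic points map to sign(κ₁) (0 if flat).
Note the denominator convention: with κ₁ ≥ κ₂ the (κ₁−κ₂) denominator
yields +1 for domes and −1 for cups. The **distance-dependent
curvature** between patch center i and member j is
θ(|rⱼ+nⱼ−rᵢ−nᵢ| − d)·|nⱼ−nᵢ|/d, with θ a ±1 sign step separating
convex (normal tips spreading) from concave geometry; it is computed
center-to-member within each patch.

Chemical features, each normalized to [−1, 1]: Kyte–Doolittle
hydropathy of the residue owning the nearest atom (scaled by 1/4.5);
Coulomb electrostatics with a distance-dependent dielectric ε(r) = 4r
over bundled formal charges (Arg/Lys +1, Asp/Glu −1, chain termini ±1),
clamped — an acknowledged approximation to a Poisson–Boltzmann solver,
with a hook (`electrostatics_solver`) to substitute one; and a
hydrogen-bond feature counting donor (+) and acceptor (−) heavy atoms
with linear falloff over 3.5 Å.

Patches are geodesic balls of radius 6.0 Å (Dijkstra over mesh edges;
exact geodesics are out of scope and unnecessary at 1.0 Å resolution).
Polar coordinates per member: ρ = geodesic distance, φ = angle in the
center's tangent plane measured from the projected κ₁ eigendirection
(a seeded random tangent at umbilic centers, keeping the decomposition
deterministic). Grids are 5 radial × 16 angular bins, mean-pooled per
bin, with an occupancy mask channel for empty bins.

## Groove plane and the outer surface

TCRs dock on top of the complex, so only peptide surface facing away
from the groove is relevant for recognition. A virtual plane through
the Cα atoms of HLA residues 72, 143 and 159 is oriented toward the
peptide centroid; vertices with signed distance strictly greater than
4.0 Å form the outer surface, and a patch survives iff its center
vertex does. The sign convention means vertices below the groove plane
can never count as exposed. The six channels fed onward (shape index,
DDC, hydropathy, electrostatics, H-bond, plane distance) are recorded
in configuration rather than hard-coded.

## The conformation engine (`pepconf`)

The trainable model is a deliberately small, CPU-sized miniature of a
template-based attention architecture; what is implemented *exactly*
is the machinery the loss composition depends on:

* the peptide–HLA spatial distance matrix — (p+h)×(p+h) pairwise Cβ
  (Cα for Gly) distances with PAD masking — computed after embedding
  and injected as an attention bias (RBF-featurized) in both the
  peptide self-attention and the peptide→HLA cross-attention;
* backbone rigid frames by Gram–Schmidt on N–Cα–C;
* the loss composition, exactly:
  L = L_pep + L_pHLA, L_pep = L_FAPE + 0.3·L_dist + L_angle + L_viol,
  L_pHLA = 9.5·L_pHLA-FAPE + 0.5·L_pHLA-dist.

FAPE uses clamp 10 Å / scale 10 Å; distograms use 64 bins on [2, 22) Å
with the last bin open — both standard conventions for this model
family. The intermolecular FAPE measures peptide atoms in *fixed HLA*
frames, which is what anchors the predicted peptide in the groove: it
is deliberately not invariant to moving the peptide alone. The torsion
loss is squared chord distance on the unit circle for raw (cos, sin)
pairs plus a 0.02-weighted normalization penalty; the violation loss
applies one-sided penalties for backbone bond lengths (±0.2 Å
tolerance), the N-Cα-C angle (±0.15 on the cosine) and non-bonded
pairs closer than 2.0 Å. The pLDDT head is 50 equal bins on [0, 100]
with the expectation as point estimate.

HLA coordinates are always inputs (templates), never predicted. The
decoder realizes all heavy atoms: carbonyl O and Cβ from ideal local
geometry, side chains by NeRF extension using a bundled
internal-coordinate topology (idealized average bond lengths/angles;
the proline ring is built open rather than closed) driven by up to four
predicted χ torsions, so the atom count per residue matches the
standard heavy-atom topology.

All neural components run on a compact in-package reverse-mode autodiff
over numpy arrays (`neoasurf.autodiff`); analytic gradients are checked
against central differences to 1e-4 relative in the suite. Training
uses SGD with momentum 0.9 (default lr 1e-3) or Adam; the
single-example overfitting demonstrations use Adam at lr 1e-2 for 500
steps, which suffices to drive the loss below 10% of its initial value
and the peptide Cα trace within 0.5 Å of the target. One integer seed
controls all weight initialization and data order.

## The foreignness engine (`pepfore`)

Three comparison blocks process a WT/Mut pair:

1. **Outer-surface block.** Patch grids from both peptides pass a
   shared-weight 3×3 convolution, spatial mean pooling and a projection
   to per-patch descriptors, pooled (mean by default, max available)
   to one descriptor per peptide. The descriptors x (Mut) and y (WT)
   are compared by the quadruple-linear difference
   w·[x; y; x⊙y − 1; |x−y|]. The third part is read as elementwise
   product minus the scalar one; a configuration switch
   offers the elementwise-inverse reading for sensitivity analysis,
   since the expression is ambiguous as written.
2. **Structure block.** The cross distance matrix M[i,j] between Mut
   residue-centroid i and WT residue-centroid j, both structures in a
   common HLA frame (an HLA-Cα Kabsch fit aligns them when the
   templates differ), padded to 16×16 and passed through a small CNN
   and dense layer. Diagonal asymmetry of M grows with conformational
   change, which is the signal this block exploits.
3. **Atom-group block.** "Atom group" is resolved at residue-token
   granularity (20 letters + PAD). Per-position embeddings e_w, e_m
   form two position×position channel maps via the symmetric outer
   broadcast B(x)[i,j] = x[i] + x[j]: Concat(B(e_w⊙e_m), |B(e_w−e_m)|).
   This reading is chosen because it is the one under which the
   difference channels vanish exactly for identical sequences and a
   single substitution is supported on one row/column band — both
   properties the suite asserts.

A projection block concatenates the three outputs, applies a dense
tanh layer and a sigmoid, and the score in [0, 1] is trained with an
L2 loss against binary immunogenicity labels (not cross-entropy — the
scoring rule is part of the method). Ablation replaces a named block's
output with zeros at fusion. All widths (descriptor 16, conv channels
8, hidden 32, embedding 8) are configuration defaults, not claims.

## Synthetic fixtures: what they emulate and what they do not

* **Groove** (`make_groove`): 180 backbone-only glycine residues tiling
  a floor plane with two wall ridges; residues 72/143/159 sit at
  specified non-collinear anchor coordinates so the groove plane is
  recoverable by construction. Backbone-only keeps meshing fast; tests
  needing side-chain chemistry use peptide chains with real identities.
* **Arch peptide** (`make_arch_peptide`): Cα along a parabola with low
  termini (default 1.0 Å, the HLA-anchored ends) and a high central
  bulge (default 6.0 Å, chosen above the 4.0 Å exposure cutoff so an
  outer surface exists); N/C/O/Cβ placed by idealized local offsets
  with 3.8 Å Cα spacing. This reproduces the characteristic bound-
  peptide geometry — termini anchored, center bulged toward the TCR —
  qualitatively, not any real peptide's conformation.
* **Pair corpora** (`make_pair_corpus`): random 9-mer WT peptides; one
  substitution (plus a label-neutral A↔G swap in 25% of pairs, so
  mismatch counts span {1, 2}); a latent ±1 signal sets the
  substitution target and the label is Bernoulli(σ(effect·s + noise)).
  With the signal in the *atom-group* block the targets are Thr vs Ser
  — nearly identical hydropathy and H-bond chemistry — so surface and
  structure carry (almost) no label information and ablation contrasts
  are clean. A *structure* signal instead displaces the mutant's
  central residues (2.0 vs 0.1 Å). A sequence-mediated "surface"
  signal is unavoidably also visible to the atom-group block, which is
  why the ablation demonstrations use the other two placements.
* **Perturbation** (`perturb_structure`): isotropic Gaussian atom
  displacement over all/C-terminal/central residues; expected RMSD
  √3·σ.

One global seed fans out to fixed per-generator substreams (groove=1,
arch=2, corpus=3, perturb=4), so generators are bit-reproducible and
adding one never shifts existing fixtures.

Passing tests on these fixtures demonstrate *mechanistic* correctness
— exact loss algebra, invariances, oracle agreement, signal recovery
under controlled conditions. They do not demonstrate accuracy on real
pHLA structures or real immunogenicity data: the fixtures have
idealized backbone geometry, no rotamer diversity, no real binding
chemistry, and labels generated by construction.

## Numerical choices and problem sizes

FAPE norms are ε-stabilized (ε = 1e-12 inside the square root), so
"zero" FAPE is bounded by ~1e-6 after scaling. Distance-matrix PAD
entries are zeroed and masked out of every loss. The overfitting runs
use a 9-mer on a 180-residue toy groove, 500 Adam steps; the
foreignness recovery runs use 500 pairs (350 train / 150 held out),
8 outer patches per peptide, 200 training steps at batch 32, three
seeds with the median reported. Curvature recovery is evaluated on a
radius-5 icosphere, a radius-2 cylinder and a plane, all meshed at
about 1.0 Å.

## Known limitations

No mmCIF, HLA class II, non-standard residues or insertion codes; the
electrostatics is a clamped Coulomb approximation; geodesics are graph
shortest paths; the conformation model is a miniature whose encoder
internals (block count, single-head attention, widths) are package
choices, not a reconstruction of any published network's internals;
and none of the reported numbers transfer to real data without
retraining on real corpora.
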
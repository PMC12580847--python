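# Methods

`tsflow` generates 3D transition-state (TS) geometries for single-step
gas-phase reactions directly from atom-mapped 2D reaction graphs. This note
documents the model, its assumptions, the parameters that matter, what the
synthetic data emulates, and the numerical choices made where the design was
genuinely open.

## Problem setup and representation

A reaction is an atom-mapped `reactant>>product` SMILES pair over a shared
atom set (all hydrogens explicit and mapped). The single row-order convention
throughout the package is ascending atom-map number: coordinate row *i* is
the atom with map number *i*+1.

The 2D condition is the **condensed graph of reaction (CGR)**: reactant and
product graphs superimposed on the shared atom set, every atom and bond
carrying dual before/after labels. Node features concatenate an element
one-hot (`H,C,N,O` by default, extensible) with six RDKit-derived
descriptors — aromaticity, formal charge, hybridization (one-hot over
S/SP/SP2/SP3/other), number of bonds (sum of bond orders), degree, ring
membership — computed once on the reactant side and once on the product
side. Bond features are dual bond-order categories over
`{absent, single, double, triple, aromatic}`, so breaking and forming bonds
are first-class. Sanitization is lenient on purpose: homolysis products,
carbenes and zwitterions are legitimate TS-adjacent species, and parsing
enforces atom-map consistency rather than valence rules.

## Generative model

TS coordinates are modelled with **conditional flow matching on the optimal
transport (OT) path**. Let p₀ be an easy base distribution over N×3
coordinates and p₁ the distribution of TS geometries for the given CGR. A
pair (x₀, x₁) is connected by the linear interpolant

    x_t = (1 − t)·x₀ + t·x₁,      t ∈ [0, 1],

whose conditional velocity is the constant x₁ − x₀. A network
u_θ(x_t, t | CGR) is regressed onto that target with a mean squared error
over atoms. Sampling integrates dx/dt = u_θ(x, t) with explicit Euler on the
left-endpoint grid t_k = k/n from a fresh base draw.

**OT pairing (Align).** Before forming the interpolant, both endpoints are
moved to the zero-centroid subspace and x₀ is rotationally aligned onto x₁
with the Kabsch algorithm restricted to proper rotations (det = +1; the SVD
sign-correction branch handles degenerate point sets and breaks ties toward
+1). Alignment never increases the transport cost and empirically shortens
the average target velocity substantially, which is the point: straighter
conditional paths are easier to regress and need fewer Euler steps.
Centroids are unweighted. "Center of mass" is read as the geometric centroid
because atomic masses play no role anywhere else in the model; this is a
documented interpretation, not a physical claim.

**Base distributions.** Two modes:
* `gaussian` — i.i.d. standard normal per coordinate, then centered. The
  default for training and for the `goflow-1`/`goflow-25` presets.
* `reactant_noise` — the reactant conformer plus isotropic Gaussian noise
  with μ = 0, σ² = 0.25 Å², then centered (`goflow-25-r` preset). Starting
  near the reactant biases samples toward its chirality.

t is drawn once per reaction per draw from Uniform(0, 1); no schedule.

## The equivariant vector field

The velocity network is an E(3)-equivariant attention network over the CGR:

* **Features.** Invariant scalar channels per node (width *w*, default 256)
  and per edge (width *w*), plus steerable per-node features: degree-1
  vectors and degree-2 traceless symmetric tensors (5-component basis), with
  `vec_channels` channels each (default *w*/4). L_max = 2 by default;
  L_max = 1 drops the tensor track.
* **Geometry input.** Only relative positions enter: distances through a
  Gaussian radial basis (20 functions over 0–10 Å) and directions through
  real spherical harmonics Y¹ (= r̂) and Y². Translation invariance is
  therefore structural, not learned.
* **Layers.** Each of `n_layers` (default 4) blocks computes per-edge
  invariants from LayerNorm'd node/edge scalars and the radial basis, a
  multi-head softmax attention over incoming edges, scalar messages, and
  steerable messages of the form α·(g₁·Yˡ + g₂·X⁽ˡ⁾_src) with invariant
  gates g — linear in the steerable inputs, so equivariance is exact and no
  Clebsch–Gordan tensor products are needed. Steerable channels are mixed by
  bias-free channel matrices (a bias would break equivariance). Edge scalars
  are refined with the invariant projection ⟨V_dst, r̂⟩ (geometry-aware
  attention input for the next layer). Degree-2 information reaches scalars
  only through channel norms.
* **Head.** The velocity is a gated linear readout of the degree-1 features.
  Under reflections Y¹ is odd and Y² even, so the output transforms as a
  proper vector under all of O(3): mirroring the input mirrors the predicted
  velocity. A mirror-image condition therefore yields the mirror-image TS —
  the enantiomer failure mode that distance-based metrics cannot detect —
  and a test asserts exactly this behaviour.
* **Time conditioning.** A transformer-style interleaved sin/cos embedding
  of t (geometric frequency ladder, dimension = width) is added to both the
  projected node features and the projected edge features.
* **Edge set.** Union of all pairs within 10 Å of the *current* flow state
  and all pairs within 3 hops in the CGR union graph (a breaking bond stays
  a message path). Radius edges are recomputed at every network call by
  default (`recompute_edges`); a config switch freezes them at t = 0.

At width 256 the network has ≈4.6 M trainable parameters; width 64 (used in
all desk-scale runs) has ≈0.14 M.

**Numerical backend.** The network, its training loop, and a small
reverse-mode automatic-differentiation core are implemented directly on
NumPy float64 arrays (`tsflow.nn`): the op set is exactly what batched
message passing needs (broadcast arithmetic, matmul, axis reductions, row
gather, segment scatter-add, segment softmax, LayerNorm). Gradients are
validated against finite differences in the test suite. Molecules in a batch
are processed as one disjoint-union graph. Equivariance of the field holds
to ~1e-15, i.e. float64 round-off.

## Training

Adam (default lr 5e-4 at full scale; desk-scale runs use 5e-3–1e-2) with a
cosine learning-rate decay and global gradient-norm clipping at 10. Each
epoch draws `draws_per_reaction` (t, x₀) pairs per reaction, shuffles all
pairs, and chunks them into `batch_size` gradient steps; a fixed seed makes
runs bit-reproducible. Divergence (non-finite loss) raises an error carrying
the epoch index. No data augmentation is used anywhere — equivariance makes
rotational augmentation redundant by construction.

## Inference and aggregation

`generate` draws S base samples (default 25), integrates each with n Euler
steps (default 25), re-centering the centroid after every step (the field
cannot produce net translation, but float drift can), and aggregates:
compute the coordinate-wise **median** geometry across samples (atoms
identified by map number), then return the sample with the smallest
Frobenius distance to that median. The ground truth is never consulted.
Median beats mean aggregation when the sample distribution is multimodal.
For even S the median is the midpoint convention; argmin ties break toward
the lowest sample index. Samples generated from Gaussian noise carry
independent global orientations, and coordinate-wise medians are not
rotation-equivariant across mixed orientations — the aggregate is therefore
used only as a selection anchor (the returned object is always an actual
sample). A config flag (`mutual_align`) optionally Kabsch-aligns all samples
onto the first before aggregation; the default leaves samples untouched.

## Metrics

* **D-MAE** — mean absolute error over all N(N−1)/2 interatomic distances;
  invariant to rigid motions *and* reflections of either argument (blind to
  enantiomer errors by construction).
* **RMSD** — after optimal superposition over proper rotations only, so
  mirror-image predictions score high.
* **Angle error** — mean absolute bond-angle difference (degrees) over all
  bonded triplets of the CGR union graph; diatomics have no triplet and
  return NaN, excluded from aggregates. Per-reaction means are averaged over
  the dataset (a pooled-triplet alternative would weight large molecules
  more; the per-reaction convention is this package's documented choice).
* **Steric clash** — repulsion-only Lennard-Jones score Σ 4ε(σ/r)¹² over
  pairs with r ≤ 0.7 Å, ε = 0.25 kcal/mol, σ = 0.7 Å; zero beyond the
  cutoff, +inf for coincident atoms. No bonded-pair exclusion: only contacts
  at or below the shortest realistic bond length (H₂, 0.74 Å) register at
  all. Dataset aggregate is the mean over reactions of per-reaction sums.

## Dataset splitting

Three strategies, default fractions 0.8/0.1/0.1:

1. **Random** — seeded shuffle; floor sizes for val/test, remainder train.
2. **Reaction core** — the core is the set of atoms incident to any bond
   whose dual (reactant, product) order differs, including aromaticity
   changes; the core key is a Weisfeiler–Lehman hash of the dual-labelled
   induced subgraph (element node labels, "r>p" edge labels), so isomorphic
   cores collide regardless of atom-map numbering. Whole cores are assigned
   greedily to test, then val; no core key ever spans two sets. Explicit
   hydrogens are part of the core by default (H-transfer templates differ
   precisely in their hydrogens); `include_h=False` drops them.
3. **Barrier height** — rank by barrier, reserve the upper and lower decile
   for val/test (pooled, then randomly halved, seeded — keeping val and test
   distributionally similar), train on the contiguous inner 80%. Boundary
   ties break by reaction id.

## Synthetic data: what it emulates and what it does not

`tsflow.fixtures` generates toy reactions shaped like a small-molecule
gas-phase TS dataset: H/C/N/O, 3–7 heavy atoms plus explicit hydrogens,
fully atom-mapped, one TS geometry and one reactant conformer per reaction,
and a lognormal synthetic barrier height. Reactions come from a parametric
template library (homolytic bond breaking, double→single demotion,
1,2-H shifts across a double bond, instantiated over element pairs); each
template produces a structurally identical reaction core, so core-split
machinery sees clean clusters, and cluster sizes follow a power law (a few
large clusters, many singletons). TS geometries are reactant conformers
(RDKit distance geometry) relaxed by least squares onto target distances
with breaking/forming bonds stretched to 1.3× equilibrium length, plus
0.02 Å jitter; a 0.8 Å minimum interatomic distance is enforced, which
keeps every ground-truth TS strictly below the 0.7 Å clash cutoff.

These geometries are **not** saddle points on any potential-energy surface.
They are smooth, graph-determined distribution targets. Passing tests
therefore demonstrate that the generative machinery — pairing, training,
integration, aggregation, metrics, splits — works end to end; they say
nothing about accuracy on quantum-chemistry datasets.

One fixture is special: `make_overfit_fixture` builds a formic-acid O–H
homolysis in which every atom has a distinct graph environment. Molecules
with interchangeable hydrogens (CH₂, CH₃, NH₂) make the conditional OT
target multimodal — graph-symmetric atoms occupy distinct target positions,
and which atom goes where is decided only by the noise draw — which caps
single-reaction memorization accuracy well above what an asymmetric molecule
reaches. A memorization sanity check should exercise the machinery, not that
ambiguity, so it uses the automorphism-free fixture.

## Desk-scale problem sizes

All self-checks run on one CPU with the NumPy backend, so they use reduced
sizes chosen as this package's own test conditions: width 64, 3 layers;
memorization uses 200 epochs × 64 draws on one 5-atom reaction; the
ODE-step trend uses the default 200-reaction dataset (random split), a
30-epoch model, and S = 25 sampling at 1/3/5/10/25 Euler steps with three
sampling seeds. The trend assertion allows a 1.10 factor between consecutive
seed-averaged D-MAE means (sampling noise at the plateau) and additionally
requires a ≥2× improvement from 1 to 25 steps and no clash increase.

## Known limitations

* Graph-symmetric hydrogens make conditional targets multimodal; no
  symmetry-aware pairing is attempted (matching the method being
  implemented).
* Median aggregation across independently oriented Gaussian-initialized
  samples selects among samples but the median itself is not an equivariant
  object; `mutual_align` exists for users who want a coherent ensemble.
* The W-L core key is isomorphism-faithful in one direction (isomorphic →
  equal); hash collisions between non-isomorphic cores are possible in
  principle but negligible at these sizes.
* Barrier heights are treated as opaque per-reaction scalars; nothing is
  recomputed from geometry.
* No stereochemistry perception from SMILES wedge bonds; chirality enters
  only through 3D coordinates.
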
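# tsflow

Transition-state (TS) geometries determine activation energies and reaction
rates, but locating them with quantum chemistry is expensive and fragile.
`tsflow` generates 3D TS geometries for single-step reactions **directly from
the atom-mapped 2D reaction graph** — no reactant or product 3D structures
required — for computational chemists who need TS guess structures in
high-throughput settings (reaction-network exploration, barrier-height
featurization, initializing saddle-point optimizations).

## Method

A reaction `R>>P` (every atom mapped, hydrogens explicit) is encoded as a
**condensed graph of reaction (CGR)**: one graph over the shared atom set
whose atoms and bonds carry dual before/after labels. Conditioned on the
CGR, TS coordinates are modelled with **optimal-transport conditional flow
matching**: a base sample x₀ (centered Gaussian noise, or the reactant
geometry plus σ² = 0.25 Å² noise) is paired with the reference TS x₁ by
centroid removal and Kabsch rotation (proper rotations only), and a network
uθ(x, t | CGR) is regressed onto the constant conditional velocity of the
linear path

    x_t = (1 − t)·x₀ + t·x₁,        dx_t/dt = x₁ − x₀.

The field is a time-conditioned **E(3)-equivariant attention network**:
invariant scalar features per atom and edge, steerable features up to
degree 2 built from spherical harmonics of relative positions, no
Clebsch–Gordan tensor products. Translation invariance and O(3)
equivariance are exact by construction (mirror input ⇒ mirror output).

Sampling integrates the learned field with explicit Euler from t = 0 to 1
(default 25 steps), draws S = 25 samples, and returns the sample closest
(Frobenius) to the coordinate-wise **median geometry** — ground truth is
never consulted at selection time.

The package also ships the surrounding machinery: reaction/XYZ/dataset I/O,
evaluation metrics (D-MAE over interatomic distances, proper-rotation RMSD,
bond-angle error, repulsion-only Lennard-Jones steric-clash score), three
dataset splits (random, leakage-free reaction-core, barrier-height tails),
and a deterministic synthetic-reaction generator used by the test suite.
The neural network and training loop run on a NumPy reverse-mode autodiff
core (`tsflow.nn`) — no GPU or deep-learning framework required.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Memorize a single 5-atom reaction (formic-acid O–H homolysis) and
regenerate its TS from pure noise:

```python
from tsflow import FieldConfig, FieldNet, TrainConfig, d_mae, train
from tsflow.fixtures import make_overfit_fixture
from tsflow.sampler import generate

rxn = make_overfit_fixture(seed=0)          # reaction + reference TS
net = FieldNet(FieldConfig(width=64, n_layers=3, seed=0))
cfg = TrainConfig(epochs=200, lr=1e-2, draws_per_reaction=64,
                  batch_size=8, seed=0)
net, history = train([rxn], net, cfg)
print(f"loss {history[0]['loss']:.3f} -> {history[-1]['loss']:.4f}")

ens = generate(net, rxn, n_samples=25, n_steps=25, seed=1)
print(f"D-MAE {d_mae(ens.final, rxn.ts_geometry.coords):.4f} A")
print(f"selected sample {ens.selected_index} of 25")
```

Output (≈40 s on one CPU):

```
loss 3.767 -> 0.0667
D-MAE 0.0084 A
selected sample 23 of 25
```

The training loss drops to ~2% of its initial value and the aggregated
25-sample prediction reproduces the reference TS's interatomic distances to
about a hundredth of an Ångström — memorization working end to end, from 2D
graph and Gaussian noise to 3D geometry.

### Command line

```bash
tsflow fixtures --n-reactions 200 --seed 0 --out-dir data      # toy dataset
tsflow split    --reactions data/reactions.csv --strategy core --seed 0 --out-dir splits
tsflow train    --reactions data/reactions.csv --xyz-dir data/xyz \
                --epochs 30 --width 64 --seed 0 --out-dir run
tsflow sample   --checkpoint run/checkpoint.npz --reactions data/reactions.csv \
                --xyz-dir data/xyz --preset goflow-25 --seed 0 --out-dir preds
tsflow eval     --pred preds --reactions data/reactions.csv \
                --truth data/xyz --out-dir report
```

Presets mirror the standard sampling configurations: `goflow-1` (1 sample,
25 steps), `goflow-25` (25 samples, 25 steps), `goflow-25-r` (25 samples,
25 steps, reactant-noise initialization).

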
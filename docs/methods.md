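# Methods

## The model

`molcycle` performs molecular optimization by unpaired set translation in a
reversible latent embedding. Two compound sets are given: `X`, molecules
lacking a desired property, and `Y`, molecules possessing it. Each molecule is
embedded as a point in a d-dimensional latent space (the posterior mean of a
junction-tree variational autoencoder in the real-chemistry workflow; the
synthetic grid backend in desk-scale runs). Two generators are trained,
G: X→Y and F: Y→X, together with two least-squares discriminators D_X, D_Y,
on the objective

    L(G, F, D_X, D_Y) = L_GAN(G, D_Y, X, Y) + L_GAN(F, D_X, Y, X)
                        + λ1 L_cyc(G, F) + λ2 L_id(G, F)

with

    L_GAN(G, D_Y, X, Y) = ½ E_y[(D_Y(y) − 1)²] + ½ E_x[D_Y(G(x))²]
    L_cyc(G, F)         = E_y‖G(F(y)) − y‖₁ + E_x‖F(G(x)) − x‖₁
    L_id(G, F)          = E_y‖F(y) − y‖₁ + E_x‖G(x) − x‖₁

solved as a minimax over generators (min) and discriminators (max).
Expectations are estimated as per-batch means over independently drawn X and
Y batches (the sets are unpaired). The generator side of the least-squares
game minimizes ½ E_x[(D_Y(G(x)) − 1)²]; discriminators are trained with real
targets 1 and fake targets 0 and with gradients blocked from the generators.

At inference a molecule m is optimized by encoding it to x, computing G(x),
decoding K = 80 equally spaced points along the segment from x to G(x), and —
in the constrained setting — reporting the decoded molecule with the best
property score among those with similarity sim(m, m′) ≥ δ that are distinct
from m. The unconstrained setting iterates G directly on latent coordinates
(z_{k+1} = G(z_k)) without decode/re-encode between iterations; a `reencode`
switch provides the alternative reading.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| λ1 (cycle weight) | 0.3 | restricts the mapping family; enforces approximate invertibility |
| λ2 (identity weight) | 0.1 | keeps G(x) close to x; raising it trades property improvement for similarity |
| learning rate | 1e-4 | Adam, β1 = 0.9, β2 = 0.999, for all four networks |
| epochs | 100 (structural) / 300 (physicochemical) | one pass over the larger set per epoch |
| batch size | 32 | per-step sample count from each set |
| generator_steps | 10 | generator updates per discriminator update (see below) |
| K | 80 | decoded points along the optimization path |
| intermediate steps | 10 | equally spaced decodes for the step-wise transform mode |
| Morgan fingerprint | radius 2, 2048 bits | similarity and oracle features (recorded in every report) |
| δ | task-dependent (0–0.6) | Tanimoto similarity constraint for success |

Architectures: the structural generator is one fully connected residual block
(dense d→d → batch norm → leaky-ReLU(0.1), added to its input) followed by a
linear dense layer; the physicochemical generator is four residual blocks.
All generator layers have width d (56 in the reference configuration).
Discriminators are dense stacks 56-42-28-14-7-1 (structural) or
48-36-28-18-12-7-1 (physicochemical) with leaky-ReLU(0.1) hidden activations
and a linear final unit.

## Numerical and design choices

The networks are small dense stacks (at most a few thousand parameters), so
the package ships its own NumPy layer engine with explicit reverse-mode
gradients rather than a deep-learning framework; the analytic gradients are
validated against central finite differences in the test suite. L1 terms use
the subgradient sign(·), with sign(0) = 0.

**Batch normalization lives in the generators only.** The discriminators are
deliberately norm-free: they are always evaluated on homogeneous all-real or
all-fake batches, and per-batch standardization of such batches cancels
exactly the population-level differences (most obviously a pure translation
between X and Y) that the discriminator exists to detect. With batch norm in
the discriminators, training on the synthetic task measurably collapses: the
learned shift decays to zero once the discriminators converge. Generator
batch-norm statistics are frozen at inference, so trained models are
deterministic functions.

**Asymmetric update schedule.** Adam bounds every parameter's per-update
movement by roughly the learning rate, so the total distance the generators
can travel scales with the number of updates, not with gradient magnitude.
Large compound sets (tens of thousands of molecules) provide thousands of
updates per epoch; a desk-scale set of 2000 provides 63. The default schedule
therefore performs 10 generator updates per discriminator update, restoring
the generators' movement budget while keeping the discriminators fresh. With
a 1:1 schedule at desk scale the generators stall far short of the target
population within the standard epoch budget.

**Initialization** is seeded fan-in-scaled Gaussian for all dense layers. An
exact-identity start for the generators was evaluated and rejected: it places
the fakes in a flat region of the least-squares discriminator where the L1
identity/cycle subgradients pin the generators at the identity map.

Other conventions: one pass per epoch over the larger set with the smaller
set sampled with replacement per step (unequal |X|, |Y| supported); the last
short batch of each epoch is kept; ties in the constrained argmax break
toward higher similarity, then the earlier path index; the starting molecule
is excluded from candidates even when it reappears mid-path; quantile
thresholds use linear interpolation and ties at a median split fall on the X
(below-median) side; duplicate molecules are removed by canonical SMILES
before set construction; molecules satisfying both or neither of the X/Y
predicates are excluded from both sets. The trailing dense layer of the
structural generator is linear (no activation). No history buffer of past
fakes is used for discriminator updates. "CN" and "CF3" in the bioisostere
task are interpreted as SMARTS `C#N` (nitrile) and `C(F)(F)F`; both are
configurable. "Diversity" in reports is the fraction of unique generated
molecules, i.e. the same statistic as uniqueness.

## The synthetic task

The generator's statistical premise — two latent populations separated along
a property direction — is emulated directly: X ~ N(μ_x, σ²I) and
Y ~ N(μ_y, σ²I) in d = 8 dimensions with shared isotropic spread (matching
the multivariate-normal prior of the autoencoder latent space), means 4σ
apart along the property direction w (first basis vector), property
f(z) = w·z, and membership threshold t at the midpoint w·(μ_x + μ_y)/2.
Rejection sampling enforces f ≤ t for every X row and f > t for every Y row.
Defaults: 2000 training and 400 test points per set, σ = 1, seed-controlled.

Decoding uses a grid backend: "molecules" are tokens naming the nearest grid
cell (spacing 0.5), so decode∘encode is the identity on tokens, encode∘decode
is the idempotent nearest-grid projection, and every decode is valid — the
synthetic counterpart of the graph decoder's 100% validity. Token similarity
is 1/(1 + L1 latent distance), which is 1 exactly on identical tokens.

The toy task is solvable by the affine map z ↦ z + (μ_y − μ_x), giving
closed-form checks: the trained G's mean displacement should align with
μ_y − μ_x, and f(G(x)) should cross t for most held-out X. What the synthetic
task does **not** emulate: chemical grammar, the non-linear geometry of a
real autoencoder latent space, decoder many-to-one collapse away from the
training manifold, and any correlation structure between property and
off-direction coordinates. Passing synthetic tests therefore demonstrates the
correctness of the losses, training dynamics, path decoding and metrics — not
chemistry-level performance, which additionally depends on the quality of the
pretrained embedding.

## Problem sizes used in validation

The shipped test suite and the acceptance script train at the synthetic
defaults (d = 8, 2000 + 2000 training points, 100 epochs, batch 32) across
five seeds, evaluate on 400 held-out X points, and run constrained
optimization with K = 80 on 100 starting molecules per δ ∈ {0, 0.2, 0.4,
0.6}. The identity-weight trade-off compares λ2 = 0.1 and λ2 = 10 on
identical data and seeds. These sizes were chosen so a full validation runs
in minutes on one CPU core while keeping every population-level effect
(separation, shift, trade-off) several standard errors wide.

## Known limitations

* The equilibrium shift is deliberately smaller than the full population gap:
  λ1 and λ2 hold G(x) near x, so success rates on a well-separated synthetic
  task settle around 0.55–0.8 by seed rather than near 1. This is the
  designed improvement/similarity balance, not a convergence failure.
* The least-squares game gives vanishing generator gradients far from the
  decision boundary; training relies on the transient early phase to move the
  fake population into the discriminator's sloped region. Very large
  separations (≫ 4σ) may stall.
* The real-chemistry workflow requires an external reversible embedding
  satisfying the backend contract (deterministic posterior-mean encode, total
  decode); none is bundled.
* Penalized logP uses the fragment-based synthetic-accessibility score as
  shipped with RDKit; molecules outside its fragment table raise a scoring
  error rather than receiving a silent default.
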
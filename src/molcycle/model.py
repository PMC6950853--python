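"""The latent-space CycleGAN: losses, architectures, and checkpoints.

Two generators map between the latent populations — G: X→Y and F: Y→X — and
two discriminators D_X, D_Y score whether a latent point looks like a member
of the corresponding set. Training minimizes

    L(G, F, D_X, D_Y) = L_GAN(G, D_Y, X, Y) + L_GAN(F, D_X, Y, X)
                        + λ1 · L_cyc(G, F) + λ2 · L_identity(G, F)

over the generators while the discriminators maximize the adversarial terms.
The adversarial loss is the least-squares (LS-GAN) form — real targets 1,
fake targets 0 — and the cycle and identity terms are per-sample L1 norms
averaged over the batch. Default weights λ1 = 0.3, λ2 = 0.1 trade off
property improvement against similarity to the starting molecule.

Architectures (layer widths follow the 56-unit reference design; width always
equals the latent dimension):

* structural generator — one fully connected residual block followed by one
  (linear) dense layer;
* physicochemical generator — four fully connected residual blocks;
* discriminators — dense stacks of sizes 56,42,28,14,7,1 (structural) or
  48,36,28,18,12,7,1 (physicochemical), hidden activations leaky-ReLU(0.1),
  final layer linear, no normalization (see :func:`build_discriminator`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import BatchNorm, Dense, LeakyReLU, Residual, Sequential

__all__ = [
    "LEAKY_ALPHA",
    "GeneratorSpec",
    "DiscriminatorSpec",
    "LossWeights",
    "CycleGANModel",
    "build_generator",
    "build_discriminator",
    "adversarial_loss",
    "discriminator_loss",
    "generator_adversarial_loss",
    "cycle_loss",
    "identity_loss",
    "total_generator_loss",
    "l1_term",
]

LEAKY_ALPHA = 0.1

STRUCTURAL_DISC_SIZES = (56, 42, 28, 14, 7, 1)
PHYSCHEM_DISC_SIZES = (48, 36, 28, 18, 12, 7, 1)


@dataclass(frozen=True)
class GeneratorSpec:
    """Generator architecture: residual block count and trailing dense layer."""

    variant: str = "structural"
    residual_blocks: int = 1
    units: int = 56
    trailing_dense: bool = True

    def __post_init__(self):
        if self.variant not in ("structural", "physicochemical"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "structural" and not (
            self.residual_blocks == 1 and self.trailing_dense
        ):
            raise ValueError(
                "structural generator is one residual block plus a trailing dense layer"
            )
        if self.variant == "physicochemical" and self.residual_blocks != 4:
            raise ValueError("physicochemical generator has four residual blocks")
        if self.units < 1:
            raise ValueError("units must be positive")

    @classmethod
    def structural(cls, units: int = 56) -> "GeneratorSpec":
        return cls("structural", 1, units, True)

    @classmethod
    def physicochemical(cls, units: int = 56) -> "GeneratorSpec":
        return cls("physicochemical", 4, units, False)

    @classmethod
    def for_variant(cls, variant: str, units: int = 56) -> "GeneratorSpec":
        if variant == "structural":
            return cls.structural(units)
        if variant == "physicochemical":
            return cls.physicochemical(units)
        raise ValueError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Discriminator architecture as a tuple of dense layer sizes (last = 1)."""

    layer_sizes: tuple[int, ...] = STRUCTURAL_DISC_SIZES

    def __post_init__(self):
        object.__setattr__(self, "layer_sizes", tuple(int(s) for s in self.layer_sizes))
        if not self.layer_sizes or self.layer_sizes[-1] != 1:
            raise ValueError("discriminator must end in a single output unit")
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")

    @classmethod
    def for_variant(cls, variant: str) -> "DiscriminatorSpec":
        if variant == "structural":
            return cls(STRUCTURAL_DISC_SIZES)
        if variant == "physicochemical":
            return cls(PHYSCHEM_DISC_SIZES)
        raise ValueError(f"unknown variant {variant!r}")


@dataclass(frozen=True)
class LossWeights:
    """Cycle (λ1) and identity (λ2) loss weights."""

    lambda1: float = 0.3
    lambda2: float = 0.1

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")


def build_generator(spec: GeneratorSpec, dimension: int, rng: np.random.Generator) -> Sequential:
    """Construct a generator network for a given latent dimension.

    Each residual block is dense(d→d) → batch norm → leaky-ReLU added to its
    input; the structural variant appends one linear dense layer. Parameters
    start from seeded fan-in-scaled Gaussians: the initial random warp gives
    the least-squares adversarial game a non-degenerate starting point (an
    exact-identity start sits in a flat region of the discriminator where
    the L1 identity/cycle subgradients pin the generator in place).
    """
    if dimension != spec.units:
        spec = GeneratorSpec(spec.variant, spec.residual_blocks, dimension, spec.trailing_dense)
    d = dimension
    layers: list = [
        Residual([Dense(d, d, rng), BatchNorm(d), LeakyReLU(LEAKY_ALPHA)])
        for _ in range(spec.residual_blocks)
    ]
    if spec.trailing_dense:
        layers.append(Dense(d, d, rng))
    return Sequential(layers)


def build_discriminator(
    input_dim: int, spec: DiscriminatorSpec, rng: np.random.Generator
) -> Sequential:
    """Dense stack with leaky-ReLU activations and a linear head.

    Discriminators carry no batch normalization: they are always fed
    homogeneous all-real or all-fake batches, and per-batch standardization
    of such batches cancels exactly the population-level differences (e.g. a
    pure translation between X and Y) that the discriminator must detect.
    Batch norm therefore lives in the generators only.
    """
    layers: list = []
    prev = input_dim
    for size in spec.layer_sizes[:-1]:
        layers += [Dense(prev, size, rng), LeakyReLU(LEAKY_ALPHA)]
        prev = size
    layers.append(Dense(prev, 1, rng))
    return Sequential(layers)


# --- losses -----------------------------------------------------------------

def _scores(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} batch must be non-empty")
    return arr


def adversarial_loss(real_scores, fake_scores) -> float:
    """Least-squares adversarial loss: ½·mean((D(real)−1)²) + ½·mean(D(fake)²)."""
    r = _scores(real_scores, "real")
    f = _scores(fake_scores, "fake")
    return float(0.5 * np.mean((r - 1.0) ** 2) + 0.5 * np.mean(f**2))


#: The discriminator minimizes the same least-squares form it contributes to
#: the minimax objective: real scores toward 1, generator fakes toward 0.
discriminator_loss = adversarial_loss


def generator_adversarial_loss(fake_scores) -> float:
    """Generator side of the LS-GAN game: ½·mean((D(G(x)) − 1)²)."""
    f = _scores(fake_scores, "fake")
    return float(0.5 * np.mean((f - 1.0) ** 2))


def l1_term(a, b) -> float:
    """Mean over the batch of per-sample L1 norms ‖a_i − b_i‖₁."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    return float(np.abs(a - b).sum(axis=1).mean())


def cycle_loss(x_batch, fx_of_gx, y_batch, gy_of_fy) -> float:
    """Cycle consistency: E‖F(G(x)) − x‖₁ + E‖G(F(y)) − y‖₁."""
    return l1_term(fx_of_gx, x_batch) + l1_term(gy_of_fy, y_batch)


def identity_loss(x_batch, g_of_x, y_batch, f_of_y) -> float:
    """Identity mapping: E‖G(x) − x‖₁ + E‖F(y) − y‖₁."""
    return l1_term(g_of_x, x_batch) + l1_term(f_of_y, y_batch)


def total_generator_loss(
    adv_g: float, adv_f: float, cyc: float, idn: float, weights: LossWeights
) -> float:
    """Full generator objective: adv_G + adv_F + λ1·cycle + λ2·identity."""
    if weights.lambda1 < 0 or weights.lambda2 < 0:
        raise ValueError("loss weights must be non-negative")
    return float(adv_g + adv_f + weights.lambda1 * cyc + weights.lambda2 * idn)


# --- the model ---------------------------------------------------------------

@dataclass
class CycleGANModel:
    """Generators G, F and discriminators D_X, D_Y over a d-dimensional latent space."""

    G: Sequential
    F: Sequential
    D_X: Sequential
    D_Y: Sequential
    weights: LossWeights
    dimension: int
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    seed: int = 0

    @classmethod
    def create(
        cls,
        dimension: int,
        variant: str = "structural",
        weights: LossWeights | None = None,
        seed: int = 0,
        gen_spec: GeneratorSpec | None = None,
        disc_spec: DiscriminatorSpec | None = None,
    ) -> "CycleGANModel":
        """Build a freshly initialized model (seeded, reproducible)."""
        gen_spec = gen_spec or GeneratorSpec.for_variant(variant, dimension)
        disc_spec = disc_spec or DiscriminatorSpec.for_variant(variant)
        rng = np.random.default_rng(seed)
        return cls(
            G=build_generator(gen_spec, dimension, rng),
            F=build_generator(gen_spec, dimension, rng),
            D_X=build_discriminator(dimension, disc_spec, rng),
            D_Y=build_discriminator(dimension, disc_spec, rng),
            weights=weights or LossWeights(),
            dimension=dimension,
            gen_spec=gen_spec,
            disc_spec=disc_spec,
            seed=seed,
        )

    def _apply(self, net: Sequential, Z) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        single = Z.ndim == 1
        out = net.predict(np.atleast_2d(Z))
        return out[0] if single else out

    def transform_x(self, Z) -> np.ndarray:
        """G(x): push X-latents toward the Y population (inference mode)."""
        return self._apply(self.G, Z)

    def transform_y(self, Z) -> np.ndarray:
        """F(y): push Y-latents toward the X population (inference mode)."""
        return self._apply(self.F, Z)

    def networks(self) -> dict[str, Sequential]:
        return {"G": self.G, "F": self.F, "D_X": self.D_X, "D_Y": self.D_Y}

    # --- checkpointing ------------------------------------------------------
    def save(self, directory) -> None:
        """Write a checkpoint directory: JSON manifest + weight arrays (NPZ)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "dimension": self.dimension,
            "seed": self.seed,
            "weights": {"lambda1": self.weights.lambda1, "lambda2": self.weights.lambda2},
            "generator": {
                "variant": self.gen_spec.variant,
                "residual_blocks": self.gen_spec.residual_blocks,
                "units": self.gen_spec.units,
                "trailing_dense": self.gen_spec.trailing_dense,
            },
            "discriminator": {"layer_sizes": list(self.disc_spec.layer_sizes)},
            "arrays": "weights.npz",
        }
        with open(directory / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        arrays = {}
        for name, net in self.networks().items():
            arrays.update({f"{name}/{k}": v for k, v in net.state().items()})
        np.savez(directory / "weights.npz", **arrays)

    @classmethod
    def load(cls, directory) -> "CycleGANModel":
        """Restore a checkpoint; inference outputs are bit-identical to save time."""
        directory = Path(directory)
        with open(directory / "manifest.json") as fh:
            manifest = json.load(fh)
        gen_spec = GeneratorSpec(
            variant=manifest["generator"]["variant"],
            residual_blocks=manifest["generator"]["residual_blocks"],
            units=manifest["generator"]["units"],
            trailing_dense=manifest["generator"]["trailing_dense"],
        )
        disc_spec = DiscriminatorSpec(tuple(manifest["discriminator"]["layer_sizes"]))
        model = cls.create(
            dimension=manifest["dimension"],
            weights=LossWeights(**manifest["weights"]),
            seed=manifest["seed"],
            gen_spec=gen_spec,
            disc_spec=disc_spec,
        )
        with np.load(directory / manifest["arrays"]) as data:
            for name, net in model.networks().items():
                prefix = f"{name}/"
                net.load_state(
                    {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
                )
        return model
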
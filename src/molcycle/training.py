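"""Alternating adversarial training of the latent-space translation model.

Each step draws an X batch and a Y batch (unpaired), updates the
discriminators on the least-squares adversarial loss (real → 1, generator
fakes → 0, gradients blocked from the generators), then updates both
generators jointly on the full objective adv_G + adv_F + λ1·cycle +
λ2·identity. Optimizer: Adam, learning rate 1e-4 (β1/β2 at their
conventional 0.9/0.999). Defaults: 100 epochs for the structural variant,
300 for the physicochemical one, batch size 32.

The generator/discriminator update ratio is asymmetric by default
(``generator_steps = 10`` generator updates per discriminator update).
Adam bounds each parameter's movement per update by roughly the learning
rate, so with small training sets (few steps per epoch) a 1:1 schedule
cannot carry the generators across a well-separated latent gap within the
standard epoch budget; several generator updates per discriminator update
restore the movement budget that large training sets provide through sheer
step count, while keeping the discriminators fresh.

Training is fully reproducible: identical data, config and seed give
bit-identical trained weights.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .model import CycleGANModel, l1_term
from .nn import Adam

__all__ = [
    "TrainingConfig",
    "TrainingLog",
    "TrainingDiverged",
    "make_batches",
    "train",
    "DEFAULT_EPOCHS",
]

DEFAULT_EPOCHS = {"structural": 100, "physicochemical": 300}


class TrainingDiverged(RuntimeError):
    """A loss became non-finite during training."""


@dataclass
class TrainingConfig:
    variant: str = "structural"
    learning_rate: float = 1e-4
    epochs: int | None = None  # None → variant default (100 / 300)
    batch_size: int = 32
    generator_steps: int = 10  # generator updates per discriminator update
    seed: int = 0

    def __post_init__(self):
        if self.variant not in DEFAULT_EPOCHS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.epochs is None:
            self.epochs = DEFAULT_EPOCHS[self.variant]
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")
        if self.generator_steps < 1:
            raise ValueError("generator_steps must be at least 1")


@dataclass
class TrainingLog:
    """One record per completed epoch: mean losses and wall time."""

    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def make_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    """Seeded permutation of range(n) chunked into batches (last short batch kept)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if batch_size < 1:
        raise ValueError("batch_size must be at least 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    return [perm[i : i + batch_size] for i in range(0, n, batch_size)]


def _check_matrix(Z, dim: int, name: str) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] == 0:
        raise ValueError(f"{name} must be a non-empty 2-D matrix")
    if Z.shape[1] != dim:
        raise ValueError(f"{name} has dimension {Z.shape[1]}, model expects {dim}")
    if not np.all(np.isfinite(Z)):
        raise ValueError(f"{name} contains non-finite values")
    return Z


def _discriminator_update(model: CycleGANModel, opts: dict[str, Adam], xb, yb) -> dict:
    """Update D_X and D_Y on the least-squares loss; fakes are constants."""
    G, F, DX, DY = model.G, model.F, model.D_X, model.D_Y
    for net in (G, F, DX, DY):
        net.zero_grads()
    gx, _ = G.forward(xb, training=True)
    fy, _ = F.forward(yb, training=True)

    ry, t_ry = DY.forward(yb, training=True)
    fk, t_fk = DY.forward(gx, training=True)
    loss_dy = 0.5 * np.mean((ry - 1.0) ** 2) + 0.5 * np.mean(fk**2)
    DY.backward(t_ry, (ry - 1.0) / ry.size)
    DY.backward(t_fk, fk / fk.size)
    opts["D_Y"].step()

    rx, t_rx = DX.forward(xb, training=True)
    fx, t_fx = DX.forward(fy, training=True)
    loss_dx = 0.5 * np.mean((rx - 1.0) ** 2) + 0.5 * np.mean(fx**2)
    DX.backward(t_rx, (rx - 1.0) / rx.size)
    DX.backward(t_fx, fx / fx.size)
    opts["D_X"].step()
    return {"loss_D_X": float(loss_dx), "loss_D_Y": float(loss_dy)}


def _generator_update(model: CycleGANModel, opts: dict[str, Adam], xb, yb) -> dict:
    """Update G and F jointly on the full objective (D parameters frozen)."""
    G, F, DX, DY = model.G, model.F, model.D_X, model.D_Y
    lam1, lam2 = model.weights.lambda1, model.weights.lambda2
    n_x, n_y = len(xb), len(yb)

    for net in (G, F, DX, DY):
        net.zero_grads()
    gx, tg1 = G.forward(xb, training=True)
    fy, tf1 = F.forward(yb, training=True)
    fgx, tf2 = F.forward(gx, training=True)
    gfy, tg2 = G.forward(fy, training=True)
    sy, tdy = DY.forward(gx, training=True)
    sx, tdx = DX.forward(fy, training=True)

    adv_g = 0.5 * np.mean((sy - 1.0) ** 2)
    adv_f = 0.5 * np.mean((sx - 1.0) ** 2)
    cyc = l1_term(fgx, xb) + l1_term(gfy, yb)
    idn = l1_term(gx, xb) + l1_term(fy, yb)
    total = adv_g + adv_f + lam1 * cyc + lam2 * idn

    # gradient w.r.t. G(x): adversarial head, cycle through F, identity term
    g_gx = DY.backward(tdy, (sy - 1.0) / sy.size)
    g_gx = g_gx + F.backward(tf2, lam1 * np.sign(fgx - xb) / n_x)
    g_gx = g_gx + lam2 * np.sign(gx - xb) / n_x
    # gradient w.r.t. F(y), symmetrically (cycle flows back through G)
    g_fy = DX.backward(tdx, (sx - 1.0) / sx.size)
    g_fy = g_fy + G.backward(tg2, lam1 * np.sign(gfy - yb) / n_y)
    g_fy = g_fy + lam2 * np.sign(fy - yb) / n_y

    G.backward(tg1, g_gx)
    F.backward(tf1, g_fy)
    opts["G"].step()
    opts["F"].step()

    return {
        "adv_G": float(adv_g),
        "adv_F": float(adv_f),
        "cycle": float(cyc),
        "identity": float(idn),
        "total": float(total),
    }


def _train_step(
    model: CycleGANModel, opts: dict[str, Adam], xb, yb, generator_steps: int = 1
) -> dict:
    """One alternating update; returns the step's loss components."""
    stats = _discriminator_update(model, opts, xb, yb)
    for _ in range(generator_steps):
        stats.update(_generator_update(model, opts, xb, yb))
    return stats


def train(
    x_latents,
    y_latents,
    model: CycleGANModel,
    cfg: TrainingConfig,
) -> tuple[CycleGANModel, TrainingLog]:
    """Train the model in place on two unpaired latent matrices.

    Each epoch iterates once over the larger set in seeded shuffled batches;
    the smaller set is sampled with replacement per step, so unequal |X| and
    |Y| are handled without discarding data. Raises :class:`TrainingDiverged`
    if any loss becomes non-finite. Zero epochs leave the model untouched and
    return an empty log.
    """
    X = _check_matrix(x_latents, model.dimension, "x_latents")
    Y = _check_matrix(y_latents, model.dimension, "y_latents")
    rng = np.random.default_rng(cfg.seed)
    opts = {
        name: Adam(net, lr=cfg.learning_rate)
        for name, net in model.networks().items()
    }
    log = TrainingLog()

    x_primary = X.shape[0] >= Y.shape[0]
    primary, other = (X, Y) if x_primary else (Y, X)

    for epoch in range(cfg.epochs):
        t0 = time.perf_counter()
        sums: dict[str, float] = {}
        batches = make_batches(primary.shape[0], cfg.batch_size, rng)
        for step, idx in enumerate(batches):
            other_idx = rng.integers(0, other.shape[0], size=len(idx))
            pb, ob = primary[idx], other[other_idx]
            xb, yb = (pb, ob) if x_primary else (ob, pb)
            stats = _train_step(model, opts, xb, yb, cfg.generator_steps)
            if not all(np.isfinite(v) for v in stats.values()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {step}: {stats}"
                )
            for k, v in stats.items():
                sums[k] = sums.get(k, 0.0) + v
        record = {"epoch": epoch}
        record.update({k: v / len(batches) for k, v in sums.items()})
        record["wall_time_s"] = time.perf_counter() - t0
        log.records.append(record)

    return model, log
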
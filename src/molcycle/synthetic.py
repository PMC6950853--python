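"""Synthetic latent tasks with the statistical structure the method assumes.

The translation model expects two latent populations separated along a
property direction: molecules lacking the property (X) and possessing it (Y).
This module emulates exactly that — two isotropic Gaussian clouds
N(μ_x, σ²I) and N(μ_y, σ²I) in d dimensions, matching the multivariate-normal
prior of the autoencoder latent space the method builds on, with the scalar
property f(z) = w·z and a threshold t midway between the population means.
Rejection sampling enforces exact set membership (every X row has f ≤ t,
every Y row f > t), and the grid :class:`~molcycle.backend.ToyBackend`
supplies the reversible decode so the whole train → optimize → evaluate
pipeline runs with no external data.

Defaults: d = 8, unit σ, means separated by 4σ along w (the first basis
vector), 2000 training and 400 test points per set.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable

import numpy as np

from .backend import ToyBackend, as_latent
from .evaluation import TransformRecord, non_identity, success_rate, uniqueness
from .model import CycleGANModel, LossWeights
from .optimize import ConstrainedResult, decode_path, select_under_delta
from .training import TrainingConfig, TrainingLog, train

__all__ = ["ToyTaskSpec", "ToyTask", "ToyGenerationError", "make_toy_task", "end_to_end_check"]


class ToyGenerationError(RuntimeError):
    """Rejection sampling could not populate a set (unreachable threshold)."""


@dataclass
class ToyTaskSpec:
    """Parameters of a synthetic two-population latent task.

    ``separation`` is the distance between the population means in units of σ
    along the property direction ``w``. The membership threshold defaults to
    the midpoint w·(μ_x + μ_y)/2, giving symmetric, well-separated sets at
    the default 4σ separation.
    """

    dimension: int = 8
    n_x_train: int = 2000
    n_y_train: int = 2000
    n_x_test: int = 400
    n_y_test: int = 400
    sigma: float = 1.0
    separation: float = 4.0
    resolution: float = 0.5
    property_weights: np.ndarray | None = None
    mu_x: np.ndarray | None = None
    mu_y: np.ndarray | None = None
    threshold: float | None = None
    seed: int = 0
    max_reject_rounds: int = 1000

    def __post_init__(self):
        if self.dimension < 1:
            raise ValueError("dimension must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.property_weights is None:
            w = np.zeros(self.dimension)
            w[0] = 1.0
            self.property_weights = w
        else:
            self.property_weights = as_latent(self.property_weights, self.dimension)
        if self.mu_x is None:
            self.mu_x = np.zeros(self.dimension)
        else:
            self.mu_x = as_latent(self.mu_x, self.dimension)
        if self.mu_y is None:
            w_hat = self.property_weights / np.linalg.norm(self.property_weights)
            self.mu_y = self.mu_x + self.separation * self.sigma * w_hat
        else:
            self.mu_y = as_latent(self.mu_y, self.dimension)
        if self.threshold is None:
            self.threshold = float(self.property_weights @ (self.mu_x + self.mu_y) / 2.0)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        for k in ("property_weights", "mu_x", "mu_y"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_jsonable(cls, payload: dict) -> "ToyTaskSpec":
        payload = dict(payload)
        for k in ("property_weights", "mu_x", "mu_y"):
            if payload.get(k) is not None:
                payload[k] = np.asarray(payload[k], dtype=float)
        return cls(**payload)


@dataclass
class ToyTask:
    """A realized synthetic task: latent matrices, property, and membership."""

    spec: ToyTaskSpec
    backend: ToyBackend
    x_train: np.ndarray
    x_test: np.ndarray
    y_train: np.ndarray
    y_test: np.ndarray

    @property
    def direction(self) -> np.ndarray:
        """The affine shift μ_y − μ_x that solves the task exactly."""
        return self.spec.mu_y - self.spec.mu_x

    def f(self, molecule_or_z) -> float:
        """The known property f(z) = w·z (accepts tokens or latent points)."""
        return self.backend.property(molecule_or_z)

    def is_target(self, molecule_or_z) -> bool:
        """Membership predicate of the Y set: f(z) > t."""
        return self.f(molecule_or_z) > self.spec.threshold


def _rejection_sample(
    rng: np.random.Generator,
    n: int,
    mu: np.ndarray,
    sigma: float,
    keep: Callable[[np.ndarray], np.ndarray],
    max_rounds: int,
    label: str,
) -> np.ndarray:
    rows: list[np.ndarray] = []
    have = 0
    for _ in range(max_rounds):
        draw = rng.normal(mu, sigma, size=(max(2 * n, 256), mu.shape[0]))
        kept = draw[keep(draw)]
        if kept.size:
            rows.append(kept)
            have += kept.shape[0]
        if have >= n:
            return np.vstack(rows)[:n]
    raise ToyGenerationError(
        f"could not sample {n} {label} points after {max_rounds} rounds; "
        "the membership threshold is unreachable for these population parameters"
    )


def make_toy_task(spec: ToyTaskSpec) -> ToyTask:
    """Generate the four latent matrices of a synthetic task, seeded.

    X rows satisfy f(z) ≤ t and Y rows f(z) > t exactly (rejection sampling);
    train and test draws are separate, so the sets are disjoint almost surely.
    """
    rng = np.random.default_rng(spec.seed)
    w, t = spec.property_weights, spec.threshold
    below = lambda Z: Z @ w <= t
    above = lambda Z: Z @ w > t
    x_train = _rejection_sample(rng, spec.n_x_train, spec.mu_x, spec.sigma, below,
                                spec.max_reject_rounds, "X_train")
    x_test = _rejection_sample(rng, spec.n_x_test, spec.mu_x, spec.sigma, below,
                               spec.max_reject_rounds, "X_test")
    y_train = _rejection_sample(rng, spec.n_y_train, spec.mu_y, spec.sigma, above,
                                spec.max_reject_rounds, "Y_train")
    y_test = _rejection_sample(rng, spec.n_y_test, spec.mu_y, spec.sigma, above,
                               spec.max_reject_rounds, "Y_test")
    backend = ToyBackend(
        dimension=spec.dimension,
        resolution=spec.resolution,
        weights=spec.property_weights,
    )
    return ToyTask(spec, backend, x_train, x_test, y_train, y_test)


def end_to_end_check(
    spec: ToyTaskSpec,
    cfg: TrainingConfig | None = None,
    weights: LossWeights | None = None,
    deltas: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6),
    n_constrained: int = 100,
    K: int = 80,
    model_seed: int | None = None,
) -> tuple[dict, CycleGANModel, ToyTask, TrainingLog]:
    """Run the full pipeline on a synthetic task and report its metrics.

    Generates the task, trains the model, transforms the held-out X set, and
    computes the structural metrics (success rate, non-identity, uniqueness),
    the displacement diagnostics (cosine of the mean G-displacement with
    μ_y − μ_x, mean L1 shift), and constrained-optimization summaries at each
    δ on the first ``n_constrained`` test molecules.
    """
    from .evaluation import constrained_report

    task = make_toy_task(spec)
    cfg = cfg or TrainingConfig(variant="structural", seed=spec.seed)
    model = CycleGANModel.create(
        dimension=spec.dimension,
        variant=cfg.variant,
        weights=weights or LossWeights(),
        seed=model_seed if model_seed is not None else cfg.seed,
    )
    model, log = train(task.x_train, task.y_train, model, cfg)

    backend = task.backend
    GX = model.transform_x(task.x_test)
    records = [
        TransformRecord(backend.decode(x), backend.decode(gx))
        for x, gx in zip(task.x_test, GX)
    ]
    displacement = (GX - task.x_test).mean(axis=0)
    direction = task.direction
    cosine = float(
        displacement @ direction
        / (np.linalg.norm(displacement) * np.linalg.norm(direction))
    )
    report: dict = {
        "spec": task.spec.to_jsonable(),
        "transform": {
            "success_rate": success_rate(records, task.is_target),
            "non_identity": non_identity(records),
            "uniqueness": uniqueness(records),
            "displacement_cosine": cosine,
            "mean_l1_shift": float(np.abs(GX - task.x_test).sum(axis=1).mean()),
            "mean_property_before": float(np.mean(task.x_test @ task.spec.property_weights)),
            "mean_property_after": float(np.mean(GX @ task.spec.property_weights)),
            "n_test": int(task.x_test.shape[0]),
        },
        "constrained": {},
    }
    if n_constrained > 0:
        tokens = [backend.decode(x) for x in task.x_test[:n_constrained]]
        # decode each path once, then re-filter at every delta
        per_token = [
            decode_path(tok, model, backend, task.f, K=K)[1] for tok in tokens
        ]
        for delta in deltas:
            results = []
            for tok, candidates in zip(tokens, per_token):
                best = select_under_delta(candidates, delta)
                start_score = task.f(tok)
                if best is None:
                    results.append(
                        ConstrainedResult(
                            tok, start_score, None, float("nan"), float("nan"),
                            False, None, delta,
                        )
                    )
                else:
                    results.append(
                        ConstrainedResult(
                            tok, start_score, best.molecule,
                            best.score - start_score, best.similarity,
                            True, best.path_index, delta,
                        )
                    )
            rep = constrained_report(results, delta)
            report["constrained"][str(delta)] = {
                "success_percent": rep.success_percent,
                "improvement_mean": rep.improvement_mean,
                "improvement_sd": rep.improvement_sd,
                "similarity_mean": rep.similarity_mean,
                "similarity_sd": rep.similarity_sd,
            }
    return report, model, task, log
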
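"""Inference-time molecular optimization along latent paths.

Given a trained generator G and a reversible embedding, a starting molecule m
defines an optimization path: the straight segment from x = encode(m) to
G(x), sampled at K equally spaced points (K = 80 by default). Decoding every
point yields candidate molecules; constrained optimization reports the
candidate with the best property score among those at Tanimoto similarity
≥ δ to the start and distinct from it. The intermediate-step mode decodes a
small number of equally spaced points (10 by default), and unconstrained
optimization iterates G directly in latent space: z₀ = encode(m),
z_{k+1} = G(z_k), decoding each iterate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .backend import EmbeddingBackend, as_latent
from .chem import canonical_key
from .model import CycleGANModel

__all__ = [
    "OptimizationPath",
    "PathCandidate",
    "ConstrainedResult",
    "latent_path",
    "decode_path",
    "select_under_delta",
    "constrained_optimize",
    "intermediate_transform",
    "iterative_optimize",
    "default_similarity",
]

DEFAULT_K = 80
DEFAULT_INTERMEDIATE_STEPS = 10


def latent_path(x, gx, K: int) -> np.ndarray:
    """K points from x to G(x) in equal steps: xᵢ = x + (i/(K−1))·(G(x) − x)."""
    if K < 2:
        raise ValueError("K must be at least 2")
    x = as_latent(x)
    gx = as_latent(gx, x.shape[0])
    frac = np.arange(K, dtype=float)[:, None] / (K - 1)
    return x[None, :] + frac * (gx - x)[None, :]


@dataclass
class PathCandidate:
    """A decoded path point with its score and similarity to the start."""

    molecule: object
    score: float
    similarity: float
    path_index: int


@dataclass
class OptimizationPath:
    """A decoded optimization path from x to G(x)."""

    start: np.ndarray
    end: np.ndarray
    points: np.ndarray  # (K, d)
    decoded: list
    scores: list[float]

    @property
    def K(self) -> int:
        return self.points.shape[0]


@dataclass
class ConstrainedResult:
    """Outcome of constrained optimization for one starting molecule.

    ``success`` requires a candidate with similarity ≥ δ that is distinct
    from the starting molecule; on failure ``best_molecule`` is None and the
    improvement/similarity statistics are NaN. ``candidates`` retains every
    distinct decoded path molecule (other than the start) so the same path
    can be re-filtered at a stricter δ.
    """

    start_molecule: object
    start_score: float
    best_molecule: object | None
    improvement: float
    similarity: float
    success: bool
    path_index: int | None
    delta: float
    candidates: list[PathCandidate] = field(default_factory=list, repr=False)


def default_similarity(backend) -> Callable[[object, object], float]:
    """Similarity measure for a backend: Tanimoto for real molecules, the
    backend's own latent similarity otherwise."""
    sim = getattr(backend, "similarity", None)
    if sim is not None:
        return sim
    from .evaluation import tanimoto

    return tanimoto


def decode_path(
    m,
    model: CycleGANModel,
    backend: EmbeddingBackend,
    scorer: Callable[[object], float],
    K: int = DEFAULT_K,
    sim_fn: Callable[[object, object], float] | None = None,
) -> tuple[OptimizationPath, list[PathCandidate]]:
    """Decode all K path points and collect deduplicated scored candidates.

    Candidates exclude the starting molecule itself (even when it reappears
    mid-path); duplicates keep their earliest path index.
    """
    sim_fn = sim_fn or default_similarity(backend)
    z = as_latent(backend.encode(m), backend.dimension)
    gz = as_latent(model.transform_x(z), backend.dimension)
    points = latent_path(z, gz, K)
    decoded = [backend.decode(p) for p in points]
    scores = [float(scorer(d)) for d in decoded]
    path = OptimizationPath(start=z, end=gz, points=points, decoded=decoded, scores=scores)

    start_key = canonical_key(m)
    seen: set[str] = set()
    candidates: list[PathCandidate] = []
    for i, (mol, score) in enumerate(zip(decoded, scores)):
        key = canonical_key(mol)
        if key == start_key or key in seen:
            continue
        seen.add(key)
        candidates.append(
            PathCandidate(mol, score, float(sim_fn(m, mol)), i)
        )
    return path, candidates


def select_under_delta(
    candidates: Sequence[PathCandidate], delta: float
) -> PathCandidate | None:
    """Best-scoring candidate with similarity ≥ δ.

    Ties in score break toward higher similarity, then toward the earlier
    path index. Returns None when no candidate satisfies the constraint.
    """
    eligible = [c for c in candidates if c.similarity >= delta]
    if not eligible:
        return None
    return max(eligible, key=lambda c: (c.score, c.similarity, -c.path_index))


def constrained_optimize(
    m,
    model: CycleGANModel,
    backend: EmbeddingBackend,
    scorer: Callable[[object], float],
    delta: float,
    K: int = DEFAULT_K,
    sim_fn: Callable[[object, object], float] | None = None,
) -> ConstrainedResult:
    """Optimize one molecule under the similarity constraint sim(m, m′) ≥ δ.

    Encodes m, decodes K points along the path to G(encode(m)), and reports
    the distinct decoded molecule with the highest score among those meeting
    the constraint. A run with no qualifying candidate is a failure, not an
    error.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    _, candidates = decode_path(m, model, backend, scorer, K=K, sim_fn=sim_fn)
    start_score = float(scorer(m))
    best = select_under_delta(candidates, delta)
    if best is None:
        return ConstrainedResult(
            start_molecule=m,
            start_score=start_score,
            best_molecule=None,
            improvement=float("nan"),
            similarity=float("nan"),
            success=False,
            path_index=None,
            delta=delta,
            candidates=candidates,
        )
    return ConstrainedResult(
        start_molecule=m,
        start_score=start_score,
        best_molecule=best.molecule,
        improvement=best.score - start_score,
        similarity=best.similarity,
        success=True,
        path_index=best.path_index,
        delta=delta,
        candidates=candidates,
    )


def intermediate_transform(
    m,
    model: CycleGANModel,
    backend: EmbeddingBackend,
    steps: int = DEFAULT_INTERMEDIATE_STEPS,
) -> list:
    """Decode `steps` equally spaced points along (x, G(x)), endpoints included.

    Returns molecules in path order; consecutive duplicates are retained so
    callers can see where along the path the decode actually changes.
    """
    z = as_latent(backend.encode(m), backend.dimension)
    gz = as_latent(model.transform_x(z), backend.dimension)
    return [backend.decode(p) for p in latent_path(z, gz, steps)]


def iterative_optimize(
    m,
    model: CycleGANModel,
    backend: EmbeddingBackend,
    iterations: int,
    reencode: bool = False,
) -> list:
    """Unconstrained optimization: apply G repeatedly, decoding each iterate.

    The generated latent representation is fed straight back into G
    (z_{k+1} = G(z_k)); set ``reencode=True`` to instead re-encode the decoded
    molecule between iterations. Returns [decode(z₁), …, decode(z_iterations)].
    """
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    z = as_latent(backend.encode(m), backend.dimension)
    out = []
    for _ in range(iterations):
        z = as_latent(model.transform_x(z), backend.dimension)
        decoded = backend.decode(z)
        out.append(decoded)
        if reencode:
            z = as_latent(backend.encode(decoded), backend.dimension)
    return out
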
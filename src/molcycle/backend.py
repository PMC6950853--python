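"""Reversible molecular embeddings: the backend contract and a toy grid backend.

The translation model never sees molecules directly — it operates on fixed-
dimension latent vectors produced by a reversible embedding (in the real
workflow, the posterior mean of a junction-tree VAE). This module defines that
contract (:class:`EmbeddingBackend`), a fully synthetic :class:`ToyBackend`
whose "molecules" are quantized grid-cell tokens (so encode/decode round-trips
are exact and every decode is valid, mirroring the 100% decoding validity of
the graph-based autoencoder), and CSV/NPZ persistence for latent matrices.

An adapter for an externally trained autoencoder only needs to satisfy the
``dimension`` / ``encode`` / ``decode`` surface; nothing in the core imports
one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "BackendError",
    "TokenParseError",
    "EmbeddingBackend",
    "ToyBackend",
    "as_latent",
    "encode_set",
    "save_latents",
    "load_latents",
    "save_latents_npz",
    "load_latents_npz",
]

DEFAULT_DIMENSION = 56  # width of every layer in the reference architecture


class BackendError(ValueError):
    """Contract violation between a backend and its caller."""


class TokenParseError(BackendError):
    """A toy token string is malformed."""


def as_latent(z, dimension: int | None = None) -> np.ndarray:
    """Validate and return a latent point as a 1-D float array.

    Checks finiteness and, when given, the expected dimension.
    """
    arr = np.asarray(z, dtype=float)
    if arr.ndim != 1:
        raise BackendError(f"latent point must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise BackendError("latent point has non-finite coordinates")
    if dimension is not None and arr.shape[0] != dimension:
        raise BackendError(
            f"latent point has dimension {arr.shape[0]}, expected {dimension}"
        )
    return arr


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Contract for a reversible molecular embedding.

    ``encode`` must be deterministic (posterior mean, never a sample) and
    ``decode`` must always return a valid molecule object.
    """

    dimension: int

    def encode(self, molecule) -> np.ndarray: ...

    def decode(self, z) -> object: ...


_TOKEN_RE = re.compile(r"^z:-?\d+(?:,-?\d+)*$")


@dataclass
class ToyBackend:
    """Synthetic embedding over a quantized grid.

    "Molecules" are tokens ``"z:i0,i1,..."`` naming a grid cell; ``encode``
    maps a token to its cell center (index × resolution) and ``decode`` maps
    any latent point to the token of the nearest cell. Hence
    ``decode(encode(t)) == t`` for every token, and ``encode(decode(z))`` is
    the idempotent nearest-grid projection. The scalar property
    ``f(z) = w · z`` is exactly computable for any latent point.

    Parameters
    ----------
    dimension : latent dimensionality.
    resolution : grid spacing per coordinate.
    weights : property direction ``w``; defaults to the first basis vector.
    """

    dimension: int = 8
    resolution: float = 0.5
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.dimension < 1:
            raise BackendError("dimension must be positive")
        if not self.resolution > 0:
            raise BackendError("resolution must be positive")
        if self.weights is None:
            w = np.zeros(self.dimension)
            w[0] = 1.0
            self.weights = w
        else:
            self.weights = as_latent(self.weights, self.dimension)

    def encode(self, molecule) -> np.ndarray:
        """Grid-cell center of a toy token."""
        token = str(molecule)
        if not _TOKEN_RE.match(token):
            raise TokenParseError(f"malformed toy token: {token!r}")
        idx = np.array([int(s) for s in token[2:].split(",")], dtype=float)
        if idx.shape[0] != self.dimension:
            raise BackendError(
                f"token has {idx.shape[0]} coordinates, expected {self.dimension}"
            )
        return idx * self.resolution

    def decode(self, z) -> str:
        """Token of the nearest grid cell; total — never fails on finite input."""
        arr = as_latent(z, self.dimension)
        idx = np.rint(arr / self.resolution).astype(int)
        return "z:" + ",".join(str(int(i)) for i in idx)

    def property(self, molecule_or_z) -> float:
        """Toy property f(z) = w·z, accepting a token or a latent point."""
        if isinstance(molecule_or_z, str):
            z = self.encode(molecule_or_z)
        else:
            z = as_latent(molecule_or_z, self.dimension)
        return float(self.weights @ z)

    def similarity(self, a, b) -> float:
        """Similarity in (0, 1]: 1 / (1 + L1 latent distance); 1 iff identical."""
        za = self.encode(a) if isinstance(a, str) else as_latent(a, self.dimension)
        zb = self.encode(b) if isinstance(b, str) else as_latent(b, self.dimension)
        return float(1.0 / (1.0 + np.abs(za - zb).sum()))


def encode_set(members: Iterable, backend: EmbeddingBackend) -> np.ndarray:
    """Encode a molecule set into an (n, d) latent matrix, order preserved."""
    mols = list(getattr(members, "members", members))
    rows = []
    for m in mols:
        try:
            rows.append(as_latent(backend.encode(m), backend.dimension))
        except Exception as exc:
            raise BackendError(f"backend failed to encode {m!r}: {exc}") from exc
    if not rows:
        return np.zeros((0, backend.dimension))
    return np.vstack(rows)


# --- persistence -----------------------------------------------------------

def save_latents(path, Z: np.ndarray, molecules: Iterable | None = None) -> None:
    """Write a latent matrix as CSV (columns z0..z{d−1}).

    When ``molecules`` is given, a leading ``molecule`` column records the
    row↔molecule mapping (canonical SMILES or toy token).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    df = pd.DataFrame(Z, columns=[f"z{i}" for i in range(Z.shape[1])])
    if molecules is not None:
        from .chem import canonical_key

        df.insert(0, "molecule", [canonical_key(m) for m in molecules])
    df.to_csv(path, index=False)


def load_latents(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a latent CSV; returns (matrix, molecule keys or None)."""
    df = pd.read_csv(path, comment="#")
    mols = None
    if "molecule" in df.columns:
        mols = [str(v) for v in df.pop("molecule")]
    cols = sorted((c for c in df.columns if c.startswith("z")), key=lambda c: int(c[1:]))
    return df[cols].to_numpy(dtype=float), mols


def save_latents_npz(path, **matrices: np.ndarray) -> None:
    """Persist one or more latent matrices in NumPy's compressed container."""
    np.savez_compressed(path, **{k: np.asarray(v, dtype=float) for k, v in matrices.items()})


def load_latents_npz(path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
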
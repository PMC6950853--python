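"""SMILES I/O, structural predicates, properties, and X/Y compound sets.

The translation model learns from two unpaired compound sets: ``X`` (molecules
lacking a property) and ``Y`` (molecules possessing it). This module builds
those sets from a molecule collection using declarative :class:`SetDefinition`
rules — SMARTS include/exclude lists, aromatic-ring counts, and property
thresholds or quantile splits (e.g. a penalized-logP median split) — and
handles the plain-text formats the sets live in (.smi, CSV).
"""

from __future__ import annotations

import json
import operator
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, rdMolDescriptors

from .sa import sa_score

__all__ = [
    "Molecule",
    "PropertyRule",
    "SetDefinition",
    "MoleculeSet",
    "SplitSets",
    "SmilesParseError",
    "SmartsError",
    "SizingError",
    "canonicalize",
    "canonical_key",
    "matches_any_smarts",
    "count_aromatic_rings",
    "penalized_logp",
    "build_sets",
    "read_smi",
    "read_smiles_csv",
    "HALOGEN_SMARTS",
    "NITRILE_SMARTS",
    "CF3_SMARTS",
    "halogen_defs",
    "bioisostere_defs",
    "cf3_defs",
    "aromatic_ring_defs",
    "median_split_defs",
    "top_quantile_defs",
]

#: SMARTS indicating halogen moieties plus the nitrile group; a molecule is in
#: the halogen-task Y set iff it matches at least one of them.
HALOGEN_SMARTS: tuple[str, ...] = ("[!#1]Cl", "[!#1]F", "[!#1]I", "C#N")

#: The CN group of the bioisostere task, read as a nitrile (configurable).
NITRILE_SMARTS = "C#N"

#: Trifluoromethyl group.
CF3_SMARTS = "C(F)(F)F"


class SmilesParseError(ValueError):
    """Input string is not a valid SMILES."""


class SmartsError(ValueError):
    """A SMARTS pattern failed to compile."""


class SizingError(ValueError):
    """Not enough qualifying molecules for the requested split sizes."""


class Molecule:
    """A molecule identified by its canonical SMILES.

    Construction parses and canonicalizes; invalid SMILES are rejected
    immediately. Equality and hashing are by canonical SMILES, so a
    :class:`Molecule` can key sets and dictionaries.
    """

    __slots__ = ("smiles", "_mol")

    def __init__(self, smiles: str):
        if not isinstance(smiles, str) or not smiles.strip():
            raise SmilesParseError(f"not a valid SMILES: {smiles!r}")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(f"not a valid SMILES: {smiles!r}")
        self.smiles: str = Chem.MolToSmiles(mol)
        self._mol = mol

    @property
    def mol(self) -> Chem.Mol:
        """Underlying RDKit molecule."""
        return self._mol

    def __eq__(self, other) -> bool:
        return isinstance(other, Molecule) and self.smiles == other.smiles

    def __hash__(self) -> int:
        return hash(self.smiles)

    def __repr__(self) -> str:
        return f"Molecule({self.smiles!r})"


def canonicalize(smiles: str) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` with canonical SMILES."""
    return Molecule(smiles)


def canonical_key(m) -> str:
    """Canonical identity of a molecule-like object.

    Real molecules compare by canonical SMILES; synthetic-backend tokens (plain
    strings) compare verbatim. Used by every uniqueness / identity metric.
    """
    if isinstance(m, Molecule):
        return m.smiles
    return str(m)


@lru_cache(maxsize=4096)
def _compile_smarts(pattern: str) -> Chem.Mol:
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise SmartsError(f"invalid SMARTS pattern: {pattern!r}")
    return query


def matches_any_smarts(m: Molecule, patterns: Sequence[str]) -> bool:
    """True iff at least one SMARTS pattern has a substructure match in *m*."""
    queries = [_compile_smarts(p) for p in patterns]
    return any(m.mol.HasSubstructMatch(q) for q in queries)


def count_aromatic_rings(m: Molecule) -> int:
    """Number of aromatic rings under RDKit ring perception."""
    return int(rdMolDescriptors.CalcNumAromaticRings(m.mol))


def penalized_logp(m: Molecule) -> float:
    """Penalized logP: octanol-water logP minus the SA score, logP(m) − SA(m)."""
    return float(Crippen.MolLogP(m.mol)) - sa_score(m.mol)


#: Named property functions usable in :class:`PropertyRule`.
PROPERTY_FUNCTIONS: dict[str, Callable[[Molecule], float]] = {
    "penalized_logp": penalized_logp,
    "logp": lambda m: float(Crippen.MolLogP(m.mol)),
    "sa": lambda m: sa_score(m.mol),
    "aromatic_rings": lambda m: float(count_aromatic_rings(m)),
}

_COMPARATORS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
}


@dataclass(frozen=True)
class PropertyRule:
    """Threshold rule on a named molecular property.

    Exactly one of ``threshold`` (absolute cut) or ``quantile`` (cut computed
    on the full input collection, linear interpolation) must be given. A
    quantile rule must be resolved against concrete values before membership
    can be evaluated.
    """

    name: str
    comparator: str
    threshold: float | None = None
    quantile: float | None = None

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
        if (self.threshold is None) == (self.quantile is None):
            raise ValueError("exactly one of threshold / quantile must be set")
        if self.quantile is not None and not 0.0 <= self.quantile <= 1.0:
            raise ValueError("quantile must lie in [0, 1]")

    def resolve(self, values: Sequence[float]) -> "PropertyRule":
        """Turn a quantile rule into a concrete threshold rule."""
        if self.quantile is None:
            return self
        cut = float(np.quantile(np.asarray(values, dtype=float), self.quantile))
        return replace(self, threshold=cut, quantile=None)

    def applies(self, value: float) -> bool:
        if self.threshold is None:
            raise ValueError(
                f"quantile rule on {self.name!r} must be resolved before use"
            )
        return _COMPARATORS[self.comparator](value, self.threshold)


@dataclass(frozen=True)
class SetDefinition:
    """Declarative membership predicate for a compound set.

    A molecule belongs iff it matches at least one ``include_smarts`` (when
    given), matches none of ``exclude_smarts``, has an aromatic-ring count in
    ``ring_counts`` (when given), and satisfies ``property_rule`` (when given).
    Membership is deterministic per molecule.
    """

    include_smarts: tuple[str, ...] = ()
    exclude_smarts: tuple[str, ...] = ()
    ring_counts: frozenset[int] | None = None
    property_rule: PropertyRule | None = None

    def __post_init__(self):
        object.__setattr__(self, "include_smarts", tuple(self.include_smarts))
        object.__setattr__(self, "exclude_smarts", tuple(self.exclude_smarts))
        if self.ring_counts is not None:
            object.__setattr__(self, "ring_counts", frozenset(self.ring_counts))
        if not (
            self.include_smarts
            or self.exclude_smarts
            or self.ring_counts is not None
            or self.property_rule is not None
        ):
            raise ValueError("SetDefinition requires at least one criterion")
        for p in (*self.include_smarts, *self.exclude_smarts):
            _compile_smarts(p)  # fail fast on bad patterns

    def resolve(self, values: Sequence[float] | None) -> "SetDefinition":
        """Resolve a quantile property rule against the full value collection."""
        if self.property_rule is None or self.property_rule.quantile is None:
            return self
        if values is None:
            raise ValueError("property values required to resolve quantile rule")
        return replace(self, property_rule=self.property_rule.resolve(values))

    def matches(self, m: Molecule, prop_value: float | None = None) -> bool:
        if self.include_smarts and not matches_any_smarts(m, self.include_smarts):
            return False
        if self.exclude_smarts and matches_any_smarts(m, self.exclude_smarts):
            return False
        if self.ring_counts is not None and count_aromatic_rings(m) not in self.ring_counts:
            return False
        if self.property_rule is not None:
            if prop_value is None:
                prop_value = PROPERTY_FUNCTIONS[self.property_rule.name](m)
            if not self.property_rule.applies(prop_value):
                return False
        return True

    # --- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        payload: dict = {
            "include_smarts": list(self.include_smarts),
            "exclude_smarts": list(self.exclude_smarts),
            "ring_counts": sorted(self.ring_counts) if self.ring_counts is not None else None,
            "property_rule": None,
        }
        if self.property_rule is not None:
            r = self.property_rule
            payload["property_rule"] = {
                "name": r.name,
                "comparator": r.comparator,
                "threshold": r.threshold,
                "quantile": r.quantile,
            }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SetDefinition":
        payload = json.loads(text)
        rule = None
        if payload.get("property_rule"):
            rule = PropertyRule(**payload["property_rule"])
        ring_counts = payload.get("ring_counts")
        return cls(
            include_smarts=tuple(payload.get("include_smarts") or ()),
            exclude_smarts=tuple(payload.get("exclude_smarts") or ()),
            ring_counts=frozenset(ring_counts) if ring_counts is not None else None,
            property_rule=rule,
        )


@dataclass
class MoleculeSet:
    """A labelled compound set (one of X_train / X_test / Y_train / Y_test)."""

    label: str
    members: list[Molecule] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def smiles(self) -> list[str]:
        return [m.smiles for m in self.members]

    def to_csv(self, path) -> None:
        pd.DataFrame({"smiles": self.smiles(), "label": self.label}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, label: str | None = None) -> "MoleculeSet":
        df = pd.read_csv(path, comment="#")
        lab = label or (str(df["label"].iloc[0]) if "label" in df else "unlabelled")
        return cls(lab, [Molecule(s) for s in df["smiles"]])


@dataclass
class SplitSets:
    """The four train/test compound sets of one task."""

    x_train: MoleculeSet
    x_test: MoleculeSet
    y_train: MoleculeSet
    y_test: MoleculeSet

    def __iter__(self):
        return iter((self.x_train, self.x_test, self.y_train, self.y_test))


def _needed_property(defs: Iterable[SetDefinition]) -> str | None:
    names = {d.property_rule.name for d in defs if d.property_rule is not None}
    if len(names) > 1:
        raise ValueError(f"set definitions reference multiple properties: {names}")
    return next(iter(names), None)


def build_sets(
    molecules: Sequence[Molecule],
    x_def: SetDefinition,
    y_def: SetDefinition,
    sizes: Mapping[str, int] | Sequence[int],
    seed: int,
    property_values: Sequence[float] | None = None,
) -> SplitSets:
    """Construct the four X/Y train/test sets from a molecule collection.

    Duplicates are removed by canonical SMILES first. Quantile property rules
    are resolved on the full deduplicated collection before splitting.
    Molecules satisfying neither or both of the X/Y predicates are excluded
    from both sets (the sets are mutually exclusive by construction). Sampling
    is uniform without replacement under ``seed``; train and test sets of the
    same letter are disjoint.

    ``sizes`` is either a mapping with keys ``x_train, x_test, y_train,
    y_test`` or a 4-sequence in that order. ``property_values``, if given,
    supplies precomputed values (aligned with ``molecules``) for the property
    the rules reference.
    """
    if isinstance(sizes, Mapping):
        want = {k: int(sizes[k]) for k in ("x_train", "x_test", "y_train", "y_test")}
    else:
        xa, xb, ya, yb = (int(v) for v in sizes)
        want = {"x_train": xa, "x_test": xb, "y_train": ya, "y_test": yb}

    # dedupe by canonical SMILES, order-preserving
    seen: dict[str, int] = {}
    uniq: list[Molecule] = []
    uniq_vals: list[float] = []
    prop_name = _needed_property((x_def, y_def))
    for i, m in enumerate(molecules):
        if m.smiles in seen:
            continue
        seen[m.smiles] = i
        uniq.append(m)
        if prop_name is not None:
            if property_values is not None:
                uniq_vals.append(float(property_values[i]))
            else:
                uniq_vals.append(PROPERTY_FUNCTIONS[prop_name](m))

    vals = uniq_vals if prop_name is not None else None
    x_res = x_def.resolve(vals)
    y_res = y_def.resolve(vals)

    x_pool: list[Molecule] = []
    y_pool: list[Molecule] = []
    for i, m in enumerate(uniq):
        v = uniq_vals[i] if prop_name is not None else None
        in_x = x_res.matches(m, v)
        in_y = y_res.matches(m, v)
        if in_x and not in_y:
            x_pool.append(m)
        elif in_y and not in_x:
            y_pool.append(m)
        # both / neither: excluded from both sets

    n_x = want["x_train"] + want["x_test"]
    n_y = want["y_train"] + want["y_test"]
    if len(x_pool) < n_x or len(y_pool) < n_y:
        raise SizingError(
            f"requested {n_x} X and {n_y} Y molecules but only "
            f"{len(x_pool)} X-qualifying and {len(y_pool)} Y-qualifying available"
        )

    rng = np.random.default_rng(seed)
    x_idx = rng.permutation(len(x_pool))[:n_x]
    y_idx = rng.permutation(len(y_pool))[:n_y]
    x_sel = [x_pool[i] for i in x_idx]
    y_sel = [y_pool[i] for i in y_idx]

    return SplitSets(
        x_train=MoleculeSet("X_train", x_sel[: want["x_train"]]),
        x_test=MoleculeSet("X_test", x_sel[want["x_train"]:]),
        y_train=MoleculeSet("Y_train", y_sel[: want["y_train"]]),
        y_test=MoleculeSet("Y_test", y_sel[want["y_train"]:]),
    )


# --- task presets ---------------------------------------------------------

def halogen_defs() -> tuple[SetDefinition, SetDefinition]:
    """Halogen task: X has none of the halogen/nitrile SMARTS, Y at least one."""
    return (
        SetDefinition(exclude_smarts=HALOGEN_SMARTS),
        SetDefinition(include_smarts=HALOGEN_SMARTS),
    )


def bioisostere_defs(
    cn: str = NITRILE_SMARTS, cf3: str = CF3_SMARTS
) -> tuple[SetDefinition, SetDefinition]:
    """Bioisostere task: X has CN without CF3; Y has CF3 without CN."""
    return (
        SetDefinition(include_smarts=(cn,), exclude_smarts=(cf3,)),
        SetDefinition(include_smarts=(cf3,), exclude_smarts=(cn,)),
    )


def cf3_defs(cf3: str = CF3_SMARTS) -> tuple[SetDefinition, SetDefinition]:
    """CF3-addition task: X lacks the group, Y contains it."""
    return (
        SetDefinition(exclude_smarts=(cf3,)),
        SetDefinition(include_smarts=(cf3,)),
    )


def aromatic_ring_defs() -> tuple[SetDefinition, SetDefinition]:
    """Aromatic-ring task: X has exactly two aromatic rings, Y one or three."""
    return (
        SetDefinition(ring_counts=frozenset({2})),
        SetDefinition(ring_counts=frozenset({1, 3})),
    )


def median_split_defs(
    prop: str = "penalized_logp",
) -> tuple[SetDefinition, SetDefinition]:
    """Median split on a property; ties at the median fall on the X side."""
    return (
        SetDefinition(property_rule=PropertyRule(prop, "<=", quantile=0.5)),
        SetDefinition(property_rule=PropertyRule(prop, ">", quantile=0.5)),
    )


def top_quantile_defs(
    prop: str = "penalized_logp", q: float = 0.8
) -> tuple[SetDefinition, SetDefinition]:
    """X is everything below the q-quantile; Y is the top (1−q) fraction."""
    return (
        SetDefinition(property_rule=PropertyRule(prop, "<", quantile=q)),
        SetDefinition(property_rule=PropertyRule(prop, ">=", quantile=q)),
    )


# --- file I/O --------------------------------------------------------------

def read_smi(path) -> list[Molecule]:
    """Read a .smi file (one SMILES per line, optional whitespace-separated name)."""
    out: list[Molecule] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(Molecule(line.split()[0]))
    return out


def read_smiles_csv(path, smiles_column: str = "smiles") -> list[Molecule]:
    """Read molecules from a CSV with a configurable SMILES column."""
    df = pd.read_csv(path, comment="#")
    if smiles_column not in df.columns:
        raise KeyError(f"column {smiles_column!r} not found in {path}")
    return [Molecule(s) for s in df[smiles_column]]
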
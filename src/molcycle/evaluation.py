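"""Evaluation metrics and the pluggable activity oracle.

Structural tasks are scored by three set-level rates over (origin, generated)
pairs: *success rate* — the fraction of generated molecules satisfying the
target-set predicate; *non-identity* — the fraction distinct from their
origin; *uniqueness* — the fraction of distinct molecules among the generated
set. *Diversity* is reported as the same fraction-of-unique statistic.
Similarity between real molecules is Tanimoto over Morgan (ECFP-style)
fingerprints, radius 2 / 2048 bits by default. Constrained-optimization runs
are summarized as mean ± sd of improvement and similarity over successful
cases plus the overall success percentage. The activity oracle is a random
forest on ECFP bit vectors returning the predicted probability of the active
class, with a three-fold cross-validated ROC AUC reported at fit time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .chem import Molecule, SetDefinition, canonical_key

__all__ = [
    "TransformRecord",
    "EvaluationReport",
    "ActivityOracle",
    "morgan_fingerprint",
    "tanimoto",
    "success_rate",
    "non_identity",
    "uniqueness",
    "diversity",
    "constrained_report",
    "read_labelled_csv",
    "fit_activity_oracle",
    "activity_report",
    "plot_similarity_density",
]

MORGAN_RADIUS = 2
MORGAN_NBITS = 2048


@dataclass(frozen=True)
class TransformRecord:
    """One (origin, generated) molecule pair from a direction X→G(X) or Y→F(Y)."""

    origin: object
    generated: object
    direction: str = "X->G(X)"


@dataclass
class EvaluationReport:
    """Per-task metric bundle; rates live in [0, 1], sd ≥ 0 (NaN = undefined)."""

    success_rate: float | None = None
    non_identity: float | None = None
    uniqueness: float | None = None
    diversity: float | None = None
    improvement_mean: float = float("nan")
    improvement_sd: float = float("nan")
    similarity_mean: float = float("nan")
    similarity_sd: float = float("nan")
    success_percent: float | None = None
    fingerprint: dict = field(
        default_factory=lambda: {"radius": MORGAN_RADIUS, "n_bits": MORGAN_NBITS}
    )

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def _fp_generator(radius: int, n_bits: int):
    return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)


def morgan_fingerprint(m: Molecule, radius: int = MORGAN_RADIUS, n_bits: int = MORGAN_NBITS):
    """Morgan bit-vector fingerprint (ECFP{2·radius} analogue)."""
    return _fp_generator(radius, n_bits).GetFingerprint(m.mol)


def tanimoto(
    m1: Molecule,
    m2: Molecule,
    radius: int = MORGAN_RADIUS,
    n_bits: int = MORGAN_NBITS,
) -> float:
    """Tanimoto similarity of Morgan fingerprints: |b1 ∧ b2| / |b1 ∨ b2|.

    When both fingerprints are empty (e.g. single heavy atoms) the ratio is
    undefined; it is reported as 1.0 for identical canonical molecules and
    0.0 otherwise, with a warning.
    """
    fp1 = morgan_fingerprint(m1, radius, n_bits)
    fp2 = morgan_fingerprint(m2, radius, n_bits)
    if fp1.GetNumOnBits() == 0 and fp2.GetNumOnBits() == 0:
        warnings.warn(
            "both Morgan fingerprints are empty; similarity defined by canonical identity",
            stacklevel=2,
        )
        return 1.0 if canonical_key(m1) == canonical_key(m2) else 0.0
    return float(DataStructs.TanimotoSimilarity(fp1, fp2))


def _require_records(records: Sequence[TransformRecord]):
    if not records:
        raise ValueError("records must be non-empty")


def success_rate(
    records: Sequence[TransformRecord],
    predicate: SetDefinition | Callable[[object], bool],
) -> float:
    """Fraction of generated molecules satisfying the target-set predicate."""
    _require_records(records)
    if isinstance(predicate, SetDefinition):
        check = predicate.matches
    else:
        check = predicate
    return float(np.mean([bool(check(r.generated)) for r in records]))


def non_identity(records: Sequence[TransformRecord]) -> float:
    """Fraction of pairs whose generated molecule differs from the origin."""
    _require_records(records)
    return float(
        np.mean(
            [canonical_key(r.generated) != canonical_key(r.origin) for r in records]
        )
    )


def uniqueness(records: Sequence[TransformRecord]) -> float:
    """Fraction of unique molecules in the generated set (≥ 1/n)."""
    _require_records(records)
    keys = [canonical_key(r.generated) for r in records]
    return len(set(keys)) / len(keys)


#: Diversity is reported as the fraction of unique generated molecules.
diversity = uniqueness


def constrained_report(results: Sequence, delta: float) -> EvaluationReport:
    """Summarize constrained-optimization outcomes at one δ.

    Improvement and similarity statistics (mean, sample sd) are computed over
    successful results only; the success percentage is over all results. With
    zero successes the means are NaN and success is 0%.
    """
    if not results:
        raise ValueError("results must be non-empty")
    succ = [r for r in results if r.success]
    report = EvaluationReport(success_percent=100.0 * len(succ) / len(results))
    if succ:
        imp = np.array([r.improvement for r in succ], dtype=float)
        sim = np.array([r.similarity for r in succ], dtype=float)
        report.improvement_mean = float(imp.mean())
        report.similarity_mean = float(sim.mean())
        report.improvement_sd = float(imp.std(ddof=1)) if len(succ) > 1 else 0.0
        report.similarity_sd = float(sim.std(ddof=1)) if len(succ) > 1 else 0.0
    return report


@dataclass
class ActivityOracle:
    """Random-forest activity scorer over ECFP bit vectors.

    ``score(m)`` is the predicted probability of the active class;
    deterministic once fitted. ``cv_auc`` is the three-fold cross-validated
    ROC AUC measured on the training table at fit time.
    """

    classifier: RandomForestClassifier
    radius: int
    n_bits: int
    cv_auc: float
    manifest: dict

    def _features(self, mols: Sequence[Molecule]) -> np.ndarray:
        gen = _fp_generator(self.radius, self.n_bits)
        return np.vstack([gen.GetFingerprintAsNumPy(m.mol) for m in mols]).astype(float)

    def score(self, m: Molecule) -> float:
        return float(self.score_many([m])[0])

    def score_many(self, mols: Sequence[Molecule]) -> np.ndarray:
        X = self._features(mols)
        active_col = int(np.where(self.classifier.classes_ == 1)[0][0])
        return self.classifier.predict_proba(X)[:, active_col]


def read_labelled_csv(path, smiles_column: str = "smiles", label_column: str = "label"):
    """Read a labelled activity table (CSV with smiles and active/inactive labels)."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return [(Molecule(s), str(lab)) for s, lab in zip(df[smiles_column], df[label_column])]


def fit_activity_oracle(
    labelled: Sequence[tuple[Molecule, str | int]],
    seed: int = 0,
    n_estimators: int = 500,
    radius: int = MORGAN_RADIUS,
    n_bits: int = MORGAN_NBITS,
    cv_folds: int = 3,
) -> ActivityOracle:
    """Fit the activity oracle from a labelled molecule table.

    Labels may be "active"/"inactive" strings or 1/0 integers; both classes
    must be present. The forest is seeded, so refitting with the same seed
    reproduces identical scores.
    """
    mols = [m for m, _ in labelled]
    y = np.array(
        [1 if str(lab).lower() in ("active", "1", "true") else 0 for _, lab in labelled]
    )
    if len(set(y)) < 2:
        raise ValueError("labelled data must contain both active and inactive molecules")

    gen = _fp_generator(radius, n_bits)
    X = np.vstack([gen.GetFingerprintAsNumPy(m.mol) for m in mols]).astype(float)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    auc = float(np.mean(cross_val_score(clf, X, y, cv=cv, scoring="roc_auc")))
    clf.fit(X, y)
    manifest = {
        "model": "random_forest",
        "n_estimators": n_estimators,
        "seed": seed,
        "fingerprint": {"radius": radius, "n_bits": n_bits},
        "cv_folds": cv_folds,
        "cv_roc_auc": auc,
    }
    return ActivityOracle(clf, radius, n_bits, auc, manifest)


def activity_report(
    x_set: Sequence[Molecule],
    generated: Sequence[Molecule],
    oracle,
    threshold: float = 0.5,
) -> dict:
    """Activity summary: mean predicted activity before/after, gain, and rates.

    ``oracle`` is anything exposing ``score(molecule) → float`` (the fitted
    random forest, or a synthetic property function wrapped accordingly).
    Success counts a generated molecule whose predicted activity exceeds the
    threshold.
    """
    if len(x_set) != len(generated) or not x_set:
        raise ValueError("x_set and generated must be equal-length and non-empty")
    score = oracle.score if hasattr(oracle, "score") else oracle
    before = np.array([float(score(m)) for m in x_set])
    after = np.array([float(score(m)) for m in generated])
    records = [TransformRecord(o, g) for o, g in zip(x_set, generated)]
    return {
        "mean_activity_before": float(before.mean()),
        "mean_activity_after": float(after.mean()),
        "mean_gain": float((after - before).mean()),
        "success_rate": float(np.mean(after > threshold)),
        "diversity": diversity(records),
        "non_identity": non_identity(records),
        "threshold": threshold,
    }


def plot_similarity_density(similarities: dict[str, Sequence[float]], path) -> None:
    """Write a density plot of Tanimoto similarity distributions to ``path``.

    ``similarities`` maps a legend label (e.g. "X vs G(X)", "X vs random") to
    a sequence of similarity values.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(0.0, 1.0, 200)
    for label, values in similarities.items():
        values = np.asarray(list(values), dtype=float)
        if values.size > 1 and values.std() > 0:
            ax.plot(grid, gaussian_kde(values)(grid), label=label)
        else:
            ax.axvline(values.mean() if values.size else 0.0, label=label)
    ax.set_xlabel("Tanimoto similarity")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
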
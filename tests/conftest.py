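"""Shared fixtures: molecule collections, hand-built generators, trained toy runs."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from molcycle.chem import Molecule
from molcycle.model import CycleGANModel, LossWeights
from molcycle.synthetic import ToyTaskSpec, end_to_end_check, make_toy_task
from molcycle.training import TrainingConfig, train


def _substituted(scaffold: str, subs: list[str]) -> list[str]:
    return [scaffold.format(sub) for sub in subs]


@pytest.fixture(scope="session")
def toy_smiles() -> list[str]:
    """~50 distinct small molecules spanning halogens, nitriles, CF3 and 0–3 aromatic rings."""
    acyclic = [
        "CCO", "CCCC", "CCN", "CC(=O)O", "CCOC", "CCCl", "CCF", "CCI",
        "CC#N", "CC(F)(F)F", "CCCCO", "CC(C)C", "CCS", "C=CC", "CC(=O)C", "CCCCC",
        "OCC(O)CO", "CCCN", "CCC#N", "ClCCCl", "FC(F)(F)CC#N",
    ]
    one_ring = _substituted("{}c1ccccc1", ["C", "Cl", "N#C", "FC(F)(F)", "O", "CC", "N", "CCO"])
    one_ring += ["c1ccccc1", "c1ccncc1", "Cc1ccco1"]
    two_ring = _substituted("{}c1ccc(-c2ccccc2)cc1", ["", "Cl", "N#C", "FC(F)(F)", "C", "O"])
    two_ring += ["c1ccc2ccccc2c1", "Cc1ccc2ccccc2c1", "c1ccc(Cc2ccccc2)cc1",
                 "c1ccc(-c2ccncc2)cc1", "Clc1ccc2ccccc2c1"]
    three_ring = _substituted("{}c1ccc(-c2ccc(-c3ccccc3)cc2)cc1", ["", "Cl", "N#C", "C", "O"])
    three_ring += ["c1ccc2cc3ccccc3cc2c1", "c1ccc(-c2ccc(Cc3ccccc3)cc2)cc1"]
    smiles = acyclic + one_ring + two_ring + three_ring
    # keep distinct by canonical form
    seen, out = set(), []
    for s in smiles:
        m = Molecule(s)
        if m.smiles not in seen:
            seen.add(m.smiles)
            out.append(s)
    assert len(out) >= 50
    return out[:50]


@pytest.fixture(scope="session")
def toy_molecules(toy_smiles) -> list[Molecule]:
    return [Molecule(s) for s in toy_smiles]


def make_shift_model(dimension: int, shift) -> CycleGANModel:
    """A model whose G is exactly z ↦ z + shift at inference (F untouched)."""
    model = CycleGANModel.create(dimension=dimension, variant="structural", seed=0)
    res, dense = model.G.layers
    bn = res.layers[1]
    bn.gamma[...] = 0.0
    bn.beta[...] = 0.0
    dense.W[...] = np.eye(dimension)
    dense.b[...] = np.asarray(shift, dtype=float)
    return model


@pytest.fixture()
def shift_model_factory():
    return make_shift_model


@pytest.fixture(scope="session")
def toy_runs():
    """Five full trainings of the default synthetic task (seeds 0–4).

    Shared by the distribution-shift, parameter-recovery, iterative-similarity
    and end-to-end acceptance checks so the expensive trainings run once.
    """
    runs = []
    for seed in range(5):
        spec = ToyTaskSpec(seed=seed)
        report, model, task, log = end_to_end_check(
            spec, deltas=(0.0, 0.2, 0.4, 0.6), n_constrained=50
        )
        runs.append({"seed": seed, "spec": spec, "task": task, "model": model,
                     "report": report, "log": log})
    return runs


@pytest.fixture(scope="session")
def lambda_sweep(toy_runs):
    """Paired mean L1(x, G(x)) on X_test for λ2 = 0.1 vs λ2 = 10, seeds 0–2."""
    out = []
    for run in toy_runs[:3]:
        seed, task = run["seed"], run["task"]
        low = run["model"]
        GX = low.transform_x(task.x_test)
        l1_low = float(np.abs(GX - task.x_test).sum(axis=1).mean())

        high = CycleGANModel.create(
            dimension=task.spec.dimension, weights=LossWeights(0.3, 10.0), seed=seed
        )
        cfg = TrainingConfig(seed=seed)
        high, _ = train(task.x_train, task.y_train, high, cfg)
        GXh = high.transform_x(task.x_test)
        l1_high = float(np.abs(GXh - task.x_test).sum(axis=1).mean())
        out.append({"seed": seed, "l1_low_lambda2": l1_low, "l1_high_lambda2": l1_high})
    return out
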
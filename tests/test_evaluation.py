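"""Similarity, set-level metrics, constrained reports, and the activity oracle."""

import numpy as np
import pytest

from molcycle.chem import Molecule, SetDefinition
from molcycle.evaluation import (
    TransformRecord,
    activity_report,
    constrained_report,
    diversity,
    fit_activity_oracle,
    morgan_fingerprint,
    non_identity,
    plot_similarity_density,
    read_labelled_csv,
    success_rate,
    tanimoto,
    uniqueness,
)
from molcycle.optimize import ConstrainedResult


class TestTanimoto:
    def test_identity_is_one(self):
        m = Molecule("c1ccccc1CCO")
        assert tanimoto(m, m) == 1.0
        assert tanimoto(Molecule("OCC"), Molecule("CCO")) == 1.0

    def test_symmetric(self):
        a, b = Molecule("c1ccccc1"), Molecule("CCO")
        assert tanimoto(a, b) == tanimoto(b, a)

    def test_matches_independent_bit_set_computation(self):
        a, b = Molecule("c1ccccc1"), Molecule("CCO")
        fa = set(morgan_fingerprint(a).GetOnBits())
        fb = set(morgan_fingerprint(b).GetOnBits())
        expected = len(fa & fb) / len(fa | fb)
        assert tanimoto(a, b) == pytest.approx(expected)

    def test_bounded(self):
        pairs = [("CCO", "CCCO"), ("c1ccccc1", "Cc1ccccc1"), ("CC#N", "CC(F)(F)F")]
        for s1, s2 in pairs:
            v = tanimoto(Molecule(s1), Molecule(s2))
            assert 0.0 <= v < 1.0


def _records(pairs):
    return [TransformRecord(o, g) for o, g in pairs]


class TestSetMetrics:
    def test_success_rate_counts_target_membership(self):
        target = SetDefinition(include_smarts=("[!#1]Cl",))
        recs = _records([
            (Molecule("CCO"), Molecule("CCCl")),
            (Molecule("CCO"), Molecule("CCBr")),
            (Molecule("CCN"), Molecule("ClCCCl")),
            (Molecule("CCN"), Molecule("CCOC")),
        ])
        assert success_rate(recs, target) == pytest.approx(0.5)
        assert success_rate(recs[:3], target) == pytest.approx(2 / 3)

    def test_success_rate_extremes(self):
        target = SetDefinition(include_smarts=("[!#1]Cl",))
        all_in = _records([(Molecule("C"), Molecule("CCl"))] * 3)
        none_in = _records([(Molecule("C"), Molecule("CC"))] * 3)
        assert success_rate(all_in, target) == 1.0
        assert success_rate(none_in, target) == 0.0

    def test_success_rate_accepts_callable_predicate(self):
        recs = _records([("z:0,0", "z:3,0"), ("z:0,0", "z:1,0")])
        assert success_rate(recs, lambda t: t == "z:3,0") == pytest.approx(0.5)

    def test_non_identity(self):
        same = Molecule("CCO")
        recs = _records([(same, Molecule("OCC"))] + [(same, Molecule("CCN"))] * 4)
        assert non_identity(recs) == pytest.approx(0.8)
        assert non_identity(_records([(same, same)])) == 0.0

    def test_uniqueness_counting(self):
        a, b = Molecule("CCO"), Molecule("CCN")
        recs = _records([(a, a)] * 4)
        assert uniqueness(recs) == pytest.approx(0.25)
        assert uniqueness(_records([(a, a), (a, a), (a, b)])) == pytest.approx(2 / 3)
        assert diversity is uniqueness

    def test_uniqueness_lower_bound(self):
        rng = np.random.default_rng(0)
        toks = [f"z:{i}" for i in rng.integers(0, 3, size=12)]
        recs = _records([("z:0", t) for t in toks])
        assert uniqueness(recs) >= 1 / len(recs)

    def test_empty_records_rejected(self):
        for fn in (non_identity, uniqueness):
            with pytest.raises(ValueError):
                fn([])


def _result(success, improvement=np.nan, similarity=np.nan):
    return ConstrainedResult("start", 0.0, "best" if success else None,
                             improvement, similarity, success,
                             0 if success else None, 0.0)


class TestConstrainedReport:
    def test_all_failures_flagged_undefined(self):
        rep = constrained_report([_result(False)] * 4, delta=0.4)
        assert rep.success_percent == 0.0
        assert np.isnan(rep.improvement_mean) and np.isnan(rep.similarity_mean)

    def test_sample_statistics_over_successes_only(self):
        results = [_result(True, 1.0, 0.5), _result(True, 3.0, 0.7), _result(False)]
        rep = constrained_report(results, delta=0.2)
        assert rep.success_percent == pytest.approx(100 * 2 / 3)
        assert rep.improvement_mean == pytest.approx(2.0)
        assert rep.improvement_sd == pytest.approx(np.std([1.0, 3.0], ddof=1))
        assert rep.similarity_mean == pytest.approx(0.6)

    def test_single_success_has_zero_sd(self):
        rep = constrained_report([_result(True, 2.0, 0.9)], delta=0.0)
        assert rep.improvement_sd == 0.0


@pytest.fixture(scope="module")
def labelled():
    actives = ["CCCl", "CCCCl", "CC(C)Cl", "ClCCCl", "Clc1ccccc1",
               "CCOCCl", "ClCCN", "CC(Cl)CC", "ClCc1ccccc1", "CCC(Cl)C",
               "ClCCCCl", "CCCCCl"]
    inactives = ["CCO", "CCCC", "CCN", "CCOC", "c1ccccc1", "CCS",
                 "CC(C)C", "OCCO", "CCCCO", "Cc1ccccc1", "CCCN", "CC(=O)C"]
    return [(Molecule(s), "active") for s in actives] + [
        (Molecule(s), "inactive") for s in inactives]


def test_read_labelled_csv(tmp_path):
    import pandas as pd

    p = tmp_path / "activity.csv"
    pd.DataFrame({"smiles": ["CCO", "CCCl"], "label": ["inactive", "active"]}).to_csv(
        p, index=False)
    rows = read_labelled_csv(p)
    assert [(m.smiles, lab) for m, lab in rows] == [("CCO", "inactive"), ("CCCl", "active")]


class TestActivityOracle:

    def test_separable_toy_set_has_high_cv_auc(self, labelled):
        oracle = fit_activity_oracle(labelled, seed=0, n_estimators=100)
        assert oracle.cv_auc > 0.9

    def test_scores_are_probabilities(self, labelled):
        oracle = fit_activity_oracle(labelled, seed=0, n_estimators=50)
        for m, _ in labelled:
            assert 0.0 <= oracle.score(m) <= 1.0

    def test_refit_same_seed_identical_scores(self, labelled):
        o1 = fit_activity_oracle(labelled, seed=3, n_estimators=50)
        o2 = fit_activity_oracle(labelled, seed=3, n_estimators=50)
        probe = Molecule("CCCCCCl")
        assert o1.score(probe) == o2.score(probe)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_activity_oracle([(Molecule("CCO"), "inactive")] * 5, seed=0)

    def test_manifest_records_hyperparameters(self, labelled):
        oracle = fit_activity_oracle(labelled, seed=1, n_estimators=50)
        assert oracle.manifest["n_estimators"] == 50
        assert oracle.manifest["fingerprint"] == {"radius": 2, "n_bits": 2048}


class TestActivityReport:
    def test_identity_generator_zero_gain(self):
        mols = [Molecule("CCO"), Molecule("CCCl")]

        class Flat:
            def score(self, m):
                return 0.4

        rep = activity_report(mols, mols, Flat())
        assert rep["mean_gain"] == 0.0
        assert rep["non_identity"] == 0.0

    def test_constant_oracle_means(self):
        x = [Molecule("CCO")]
        g = [Molecule("CCN")]

        class Half:
            def score(self, m):
                return 0.5

        rep = activity_report(x, g, Half())
        assert rep["mean_activity_before"] == rep["mean_activity_after"] == 0.5
        assert rep["success_rate"] == 0.0  # strictly above threshold required

    def test_gain_reflects_scorer_difference(self):
        scores = {"CCO": 0.1, "CCCl": 0.9}

        class Lookup:
            def score(self, m):
                return scores[m.smiles]

        rep = activity_report([Molecule("CCO")], [Molecule("CCCl")], Lookup())
        assert rep["mean_gain"] == pytest.approx(0.8)
        assert rep["success_rate"] == 1.0


def test_similarity_density_plot_written(tmp_path):
    rng = np.random.default_rng(0)
    out = tmp_path / "sims.png"
    plot_similarity_density(
        {"X vs G(X)": rng.uniform(0.4, 0.9, size=50),
         "X vs random": rng.uniform(0.0, 0.3, size=50)}, out)
    assert out.exists() and out.stat().st_size > 0
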
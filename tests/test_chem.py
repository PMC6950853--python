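"""Molecule handling, structural predicates, and compound-set construction."""

import numpy as np
import pytest

from molcycle import chem
from molcycle.chem import (
    CF3_SMARTS,
    HALOGEN_SMARTS,
    NITRILE_SMARTS,
    Molecule,
    MoleculeSet,
    PropertyRule,
    SetDefinition,
    SizingError,
    SmartsError,
    SmilesParseError,
    aromatic_ring_defs,
    bioisostere_defs,
    build_sets,
    canonicalize,
    count_aromatic_rings,
    halogen_defs,
    matches_any_smarts,
    median_split_defs,
    penalized_logp,
    read_smi,
    read_smiles_csv,
    top_quantile_defs,
)


class TestMolecule:
    def test_canonicalization_matches_toolkit(self):
        from rdkit import Chem as RDChem

        expected = RDChem.MolToSmiles(RDChem.MolFromSmiles("C1=CC=CC=C1"))
        assert canonicalize("C1=CC=CC=C1").smiles == expected == "c1ccccc1"

    def test_canonicalization_idempotent(self, toy_smiles):
        for s in toy_smiles:
            once = canonicalize(s).smiles
            assert canonicalize(once).smiles == once

    @pytest.mark.parametrize("bad", ["C1CC", "not_a_smiles", "", "  ", "C(C"])
    def test_invalid_smiles_rejected(self, bad):
        with pytest.raises(SmilesParseError):
            Molecule(bad)

    def test_equality_and_hash_by_canonical_form(self):
        assert Molecule("C1=CC=CC=C1") == Molecule("c1ccccc1")
        assert len({Molecule("OCC"), Molecule("CCO")}) == 1


class TestPredicates:
    @pytest.mark.parametrize(
        "smiles,patterns,expected",
        [
            ("CCCl", ["[!#1]Cl"], True),
            ("CCO", list(HALOGEN_SMARTS), False),
            ("N#CC", ["C#N"], True),
            ("CC(F)(F)F", [CF3_SMARTS], True),
            ("CCF", [CF3_SMARTS], False),
        ],
    )
    def test_matches_any_smarts(self, smiles, patterns, expected):
        assert matches_any_smarts(Molecule(smiles), patterns) is expected

    def test_smarts_match_agrees_with_toolkit(self, toy_molecules):
        from rdkit import Chem as RDChem

        q = RDChem.MolFromSmarts("C#N")
        for m in toy_molecules:
            assert matches_any_smarts(m, ["C#N"]) == m.mol.HasSubstructMatch(q)

    def test_invalid_smarts_is_configuration_error(self):
        with pytest.raises(SmartsError):
            matches_any_smarts(Molecule("CCO"), ["[[["])

    @pytest.mark.parametrize(
        "smiles,n",
        [("c1ccccc1", 1), ("CCCC", 0), ("c1ccc2ccccc2c1", 2),
         ("c1ccc(-c2ccccc2)cc1", 2), ("C1CCCCC1", 0)],
    )
    def test_count_aromatic_rings(self, smiles, n):
        assert count_aromatic_rings(Molecule(smiles)) == n


class TestPenalizedLogP:
    def test_matches_independent_toolkit_computation(self):
        import importlib.util
        import os

        from rdkit.Chem import Crippen, RDConfig

        path = os.path.join(RDConfig.RDContribDir, "SA_Score", "sascorer.py")
        spec = importlib.util.spec_from_file_location("sascorer_oracle", path)
        sascorer = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(sascorer)

        for s in ("CCO", "c1ccccc1", "CC(F)(F)c1ccc2ccccc2c1"):
            m = Molecule(s)
            expected = Crippen.MolLogP(m.mol) - sascorer.calculateScore(m.mol)
            assert penalized_logp(m) == pytest.approx(expected, abs=1e-12)

    def test_is_logp_minus_sa_with_mocked_scorer(self, monkeypatch):
        monkeypatch.setattr(chem, "sa_score", lambda mol: 3.0)
        monkeypatch.setattr(chem.Crippen, "MolLogP", lambda mol: 2.0)
        assert penalized_logp(Molecule("CCO")) == pytest.approx(-1.0)

    def test_deterministic(self):
        m = Molecule("CC(F)(F)F")
        assert penalized_logp(m) == penalized_logp(Molecule("CC(F)(F)F"))


class TestPropertyRule:
    def test_exactly_one_of_threshold_quantile(self):
        with pytest.raises(ValueError):
            PropertyRule("penalized_logp", ">=", threshold=1.0, quantile=0.5)
        with pytest.raises(ValueError):
            PropertyRule("penalized_logp", ">=")

    def test_quantile_resolution_linear_interpolation(self):
        rule = PropertyRule("penalized_logp", ">=", quantile=0.8)
        values = list(range(100))
        resolved = rule.resolve(values)
        assert resolved.threshold == pytest.approx(np.quantile(values, 0.8))
        assert resolved.applies(resolved.threshold)

    def test_unresolved_quantile_rejected_at_membership(self):
        rule = PropertyRule("penalized_logp", ">=", quantile=0.8)
        with pytest.raises(ValueError):
            rule.applies(1.0)


class TestSetDefinition:
    def test_requires_a_criterion(self):
        with pytest.raises(ValueError):
            SetDefinition()

    def test_json_round_trip(self):
        x_def, _ = bioisostere_defs()
        assert SetDefinition.from_json(x_def.to_json()) == x_def
        rule_def = SetDefinition(
            property_rule=PropertyRule("penalized_logp", ">", quantile=0.5),
            ring_counts=frozenset({1, 3}),
        )
        assert SetDefinition.from_json(rule_def.to_json()) == rule_def

    def test_membership_deterministic(self, toy_molecules):
        y_def = SetDefinition(include_smarts=HALOGEN_SMARTS)
        first = [y_def.matches(m) for m in toy_molecules]
        assert [y_def.matches(m) for m in toy_molecules] == first


class TestBuildSets:
    def test_halogen_containment(self, toy_molecules):
        x_def, y_def = halogen_defs()
        split = build_sets(toy_molecules, x_def, y_def, (6, 3, 6, 3), seed=7)
        for m in list(split.x_train) + list(split.x_test):
            assert not matches_any_smarts(m, HALOGEN_SMARTS)
        for m in list(split.y_train) + list(split.y_test):
            assert matches_any_smarts(m, HALOGEN_SMARTS)

    def test_bioisostere_sets_exclusive(self, toy_molecules):
        x_def, y_def = bioisostere_defs()
        split = build_sets(toy_molecules, x_def, y_def, (2, 1, 2, 1), seed=0)
        for m in list(split.x_train) + list(split.x_test):
            assert matches_any_smarts(m, [NITRILE_SMARTS])
            assert not matches_any_smarts(m, [CF3_SMARTS])
        for m in list(split.y_train) + list(split.y_test):
            assert matches_any_smarts(m, [CF3_SMARTS])
            assert not matches_any_smarts(m, [NITRILE_SMARTS])

    def test_molecule_with_both_groups_excluded(self):
        both = Molecule("N#CCC(F)(F)F")  # nitrile and CF3 at once
        fillers = [Molecule(s) for s in ("CC#N", "CCC#N", "CC(F)(F)F", "FC(F)(F)CC")]
        x_def, y_def = bioisostere_defs()
        split = build_sets([both] + fillers, x_def, y_def, (1, 1, 1, 1), seed=0)
        all_members = {m.smiles for s in split for m in s}
        assert both.smiles not in all_members

    def test_aromatic_ring_task_membership(self, toy_molecules):
        x_def, y_def = aromatic_ring_defs()
        split = build_sets(toy_molecules, x_def, y_def, (4, 2, 4, 2), seed=1)
        for m in list(split.x_train) + list(split.x_test):
            assert count_aromatic_rings(m) == 2
        for m in list(split.y_train) + list(split.y_test):
            assert count_aromatic_rings(m) in {1, 3}

    def test_top_quantile_pool_is_exactly_top_fraction(self, toy_molecules):
        values = [penalized_logp(m) for m in toy_molecules]
        x_def, y_def = top_quantile_defs(q=0.8)
        # request the entire Y pool (50 molecules -> top 10)
        split = build_sets(toy_molecules, x_def, y_def, (10, 5, 8, 2), seed=3)
        top10 = {m.smiles for m, _ in sorted(
            zip(toy_molecules, values), key=lambda p: p[1], reverse=True)[:10]}
        y_members = {m.smiles for m in list(split.y_train) + list(split.y_test)}
        assert y_members <= top10 and len(y_members) == 10

    def test_median_split_balanced(self, toy_molecules):
        values = [penalized_logp(m) for m in toy_molecules]
        x_def, y_def = median_split_defs()
        median = np.quantile(values, 0.5)
        below = sum(v <= median for v in values)
        above = sum(v > median for v in values)
        assert abs(below - above) <= 1
        split = build_sets(toy_molecules, x_def, y_def, (below - 1, 1, above - 1, 1), seed=0)
        for m in list(split.x_train) + list(split.x_test):
            assert penalized_logp(m) <= median
        for m in list(split.y_train) + list(split.y_test):
            assert penalized_logp(m) > median

    def test_reproducible_under_seed(self, toy_molecules):
        x_def, y_def = halogen_defs()
        a = build_sets(toy_molecules, x_def, y_def, (6, 3, 6, 3), seed=11)
        b = build_sets(toy_molecules, x_def, y_def, (6, 3, 6, 3), seed=11)
        for sa, sb in zip(a, b):
            assert sa.smiles() == sb.smiles()

    def test_train_test_disjoint(self, toy_molecules):
        x_def, y_def = halogen_defs()
        split = build_sets(toy_molecules, x_def, y_def, (6, 3, 6, 3), seed=5)
        assert not set(split.x_train.smiles()) & set(split.x_test.smiles())
        assert not set(split.y_train.smiles()) & set(split.y_test.smiles())

    def test_insufficient_molecules_reports_counts(self, toy_molecules):
        x_def, y_def = halogen_defs()
        with pytest.raises(SizingError, match="available"):
            build_sets(toy_molecules, x_def, y_def, (1000, 10, 10, 10), seed=0)

    def test_duplicates_removed_before_split(self):
        mols = [Molecule("CCO"), Molecule("OCC"), Molecule("CCCl"), Molecule("ClCC")]
        x_def, y_def = halogen_defs()
        split = build_sets(mols, x_def, y_def, (1, 0, 1, 0), seed=0)
        assert split.x_train.smiles() == [Molecule("CCO").smiles]
        assert split.y_train.smiles() == [Molecule("CCCl").smiles]


class TestFileIO:
    def test_smi_round_trip(self, tmp_path, toy_smiles):
        path = tmp_path / "mols.smi"
        path.write_text("\n".join(f"{s} name{i}" for i, s in enumerate(toy_smiles[:5])))
        mols = read_smi(path)
        assert [m.smiles for m in mols] == [Molecule(s).smiles for s in toy_smiles[:5]]

    def test_csv_round_trip(self, tmp_path, toy_smiles):
        import pandas as pd

        path = tmp_path / "mols.csv"
        pd.DataFrame({"structure": toy_smiles[:5]}).to_csv(path, index=False)
        mols = read_smiles_csv(path, smiles_column="structure")
        assert len(mols) == 5
        with pytest.raises(KeyError):
            read_smiles_csv(path, smiles_column="smiles")

    def test_molecule_set_csv(self, tmp_path):
        ms = MoleculeSet("X_train", [Molecule("CCO"), Molecule("CCCl")])
        ms.to_csv(tmp_path / "set.csv")
        back = MoleculeSet.from_csv(tmp_path / "set.csv")
        assert back.label == "X_train" and back.smiles() == ms.smiles()
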
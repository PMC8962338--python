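"""Interpretation, screening and drug-likeness tests.

The propensity sign rule is validated against the 29 published class-based
mean pairs of the two reference models (typed in as fixture inputs)."""

import numpy as np
import pandas as pd
import pytest

from ptml import conditions_dataset as cd
from ptml import ptml_model as pm
from ptml.chemgraph import parse_smiles
from ptml.interpret_design import (
    class_propensities,
    design_guidelines,
    drug_likeness,
    moriguchi_logp,
    propensity_direction,
    screen,
    sensitivity_values,
)
from ptml.pipeline import model_features_of

# published class-based means (active, inactive, printed direction) for the
# 15 deviation descriptors of the first reference model ...
MODEL1_CLASS_MEANS = [
    ("D(NSM(Hyd)3)ma", -2.3485e-2, 1.0631e-1, "Decrease"),
    ("D(NXv(P)4)ma", 6.6912e-3, 5.5922e-3, "Increase"),
    ("D(Ne(P)1)ma", -3.2309e-4, 8.6125e-2, "Decrease"),
    ("D(Ne(P)2)ma", -4.7514e-2, 1.4992e-1, "Decrease"),
    ("D(Ne(Ch)6)ma", -4.1335e-2, 1.7654e-1, "Decrease"),
    ("D(SM(Hyd)7)tg", 3.1706e-2, -2.5668e-1, "Increase"),
    ("D(e(Ch)5)tg", 5.2858e-3, -4.9427e-2, "Increase"),
    ("D(NSM(Psa)1)tg", 2.2379e-2, -1.9481e-2, "Increase"),
    ("D(NSM(Gas)3)tg", 2.8122e-2, -1.3897e-1, "Increase"),
    ("D(NXv(P)1)tg", -1.2919e-2, 1.1367e-1, "Decrease"),
    ("D(Xv(Ch)6)ei", -4.9125e-3, -7.1198e-2, "Increase"),
    ("D(NSM(Hyd)1)ei", -5.5366e-2, 2.3959e-1, "Decrease"),
    ("D(NSM(Mol)1)ei", -4.2905e-2, 2.2042e-1, "Decrease"),
    ("D(Ne(P)5)ei", -1.2401e-2, -5.6792e-2, "Increase"),
    ("D(Ne(PC)6)ei", 3.4465e-2, -2.3273e-1, "Increase"),
]

# ... and the 14 of the second reference model
MODEL2_CLASS_MEANS = [
    ("D(ASq4(Hyd)G)ma", -5.4750e-3, -4.6447e-3, "Decrease"),
    ("D(ASq3(Hyd)Y)ma", 2.6348e-2, -1.8596e-1, "Increase"),
    ("D(ASq4(Hyd)Y)ma", 3.5673e-2, -1.3724e-1, "Increase"),
    ("D(ASq2(E)Y)ma", 5.0259e-2, -2.2849e-1, "Increase"),
    ("D(ASq1(Psa)Y)ma", 3.8557e-3, 6.3789e-2, "Decrease"),
    ("D(ASq1(Aw)C)tg", 5.9744e-2, -3.4756e-1, "Increase"),
    ("D(ASq0(Ku)G)tg", 3.9557e-3, 1.1249e-1, "Decrease"),
    ("D(ASq4(Psa)Y)tg", 3.1247e-2, -1.2646e-1, "Increase"),
    ("D(ASq1(Hyd)G)ei", -1.1160e-2, 4.0920e-2, "Decrease"),
    ("D(ASq2(Hyd)G)ei", 5.8725e-4, 3.3683e-2, "Decrease"),
    ("D(ASq2(Aw)G)ei", 9.2750e-3, 1.9038e-2, "Decrease"),
    ("D(ASq1(Hyd)M)ei", 2.6208e-2, -1.7829e-1, "Increase"),
    ("D(ASq1(Ku)M)ei", 2.8400e-2, -3.0151e-1, "Increase"),
    ("D(ASq0(Hyd)Y)ei", 1.3478e-2, -2.1995e-2, "Increase"),
]


class TestPropensities:
    @pytest.mark.parametrize("row", MODEL1_CLASS_MEANS + MODEL2_CLASS_MEANS)
    def test_published_sign_rule(self, row):
        _, active, inactive, printed = row
        assert propensity_direction(active, inactive) == printed

    def test_tie(self):
        assert propensity_direction(1.0, 1.0) == "Tie"

    def test_class_means_computed_from_data(self):
        x = pd.DataFrame({"D(X(P)1)ma": [1.0, 3.0, 0.0, 2.0]})
        y = np.array([1, 1, -1, -1])
        table = class_propensities(x, y)
        assert table.loc["D(X(P)1)ma", "active_mean"] == pytest.approx(2.0)
        assert table.loc["D(X(P)1)ma", "inactive_mean"] == pytest.approx(1.0)
        assert table.loc["D(X(P)1)ma", "propensity"] == "Increase"

    def test_requires_both_classes(self):
        x = pd.DataFrame({"D(X(P)1)ma": [1.0, 2.0]})
        with pytest.raises(ValueError):
            class_propensities(x, np.array([1, 1]))

    def test_guidelines_skip_ties(self):
        table = pd.DataFrame(
            {
                "active_mean": [1.0, 0.0],
                "inactive_mean": [0.0, 0.0],
                "propensity": ["Increase", "Tie"],
            },
            index=["D(X(P)1)ma", "D(X(P)2)tg"],
        )
        lines = design_guidelines(table)
        assert len(lines) == 1 and "increase" in lines[0]


class TestSensitivityValues:
    @staticmethod
    def _zero_weight_bundle():
        # linear model that provably ignores its second feature
        return pm.ClassifierBundle(
            algorithm="lda",
            feature_names=["D(X(P)1)ma", "D(X(P)2)tg"],
            weights=[np.array([[5.0], [0.0]])],
            biases=[np.array([0.0])],
            hidden_width=0,
            seed=0,
            ad_ranges={"D(X(P)1)ma": (-9, 9), "D(X(P)2)tg": (-9, 9)},
            feature_means={"D(X(P)1)ma": 0.0, "D(X(P)2)tg": 0.0},
        )

    def test_ignored_feature_sv_is_one(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(
            rng.normal(size=(200, 2)), columns=["D(X(P)1)ma", "D(X(P)2)tg"]
        )
        y = np.where(x["D(X(P)1)ma"] + rng.normal(scale=1.0, size=200) > 0, 1, -1)
        bundle = self._zero_weight_bundle()
        sv = sensitivity_values(bundle, x, y)
        assert sv.loc["D(X(P)2)tg", "sv"] == pytest.approx(1.0)
        assert sv.loc["D(X(P)1)ma", "sv"] > 1.0
        assert sv.loc["D(X(P)1)ma", "rank"] == 1

    def test_zero_baseline_flagged(self):
        x = pd.DataFrame(
            {"D(X(P)1)ma": [3.0, -3.0, 3.0, -3.0], "D(X(P)2)tg": [0.1, 0.2, 0.3, 0.4]}
        )
        y = np.array([1, -1, 1, -1])
        sv = sensitivity_values(self._zero_weight_bundle(), x, y)
        assert sv["baseline_zero"].all()
        assert sv["sv"].isna().all()
        assert sv.index[0] == "D(X(P)1)ma"  # ranked by perturbed error

    def test_deterministic(self, synth_run):
        train = synth_run.records[synth_run.records["split"] == "train"]
        x = synth_run.features.loc[train.index, synth_run.selected]
        a = sensitivity_values(synth_run.mlp, x, train["label"])
        b = sensitivity_values(synth_run.mlp, x, train["label"])
        pd.testing.assert_frame_equal(a, b)


class TestScreening:
    def test_row_count_and_columns(self, synth_run):
        mols = [("cand1", parse_smiles("Nc1nc(N)cc(-c2ccc(F)cc2)n1"))]
        stats = synth_run.stats
        result = screen(
            mols,
            synth_run.mlp,
            stats,
            model_features_of(synth_run.mlp),
            conditions=[
                cd.ExperimentalCondition(row["ma"], row["tg"], row["ei"])
                for _, row in synth_run.records[["ma", "tg", "ei"]]
                .drop_duplicates()
                .iterrows()
            ],
        )
        n_conditions = len(synth_run.records[["ma", "tg", "ei"]].drop_duplicates())
        assert len(result) == n_conditions
        assert set(result["proba_active"].between(0, 1)) == {True}
        assert "cand1" in result.attrs["summary"]

    def test_training_active_recovered_under_own_condition(self, synth_run):
        records = synth_run.records
        train = records[records["split"] == "train"]
        x = synth_run.features.loc[train.index, synth_run.selected]
        proba = synth_run.mlp.predict_proba(x)
        hit = train.iloc[int(np.argmax(proba * (train["label"].to_numpy() == 1)))]
        mols = [("hit", parse_smiles(hit["smiles"]))]
        result = screen(
            mols,
            synth_run.mlp,
            synth_run.stats,
            model_features_of(synth_run.mlp),
            conditions=[cd.ExperimentalCondition(hit["ma"], hit["tg"], hit["ei"])],
        )
        assert result.loc[0, "proba_active"] > 0.5
        assert result.loc[0, "predicted"] == 1

    def test_out_of_ad_still_reported(self, synth_run):
        # a molecule far outside the training chemistry: a long perfluoro
        # chain pushes deviation features beyond the training ranges
        mols = [("alien", parse_smiles("FC(F)(F)C(F)(F)C(F)(F)C(F)(F)F"))]
        conds = [
            cd.ExperimentalCondition(row["ma"], row["tg"], row["ei"])
            for _, row in synth_run.records[["ma", "tg", "ei"]].drop_duplicates().iterrows()
        ]
        result = screen(
            mols, synth_run.mlp, synth_run.stats, model_features_of(synth_run.mlp), conds
        )
        assert len(result) == len(conds)
        assert result["tsad"].min() < len(synth_run.selected)
        assert (~result["in_ad"]).any()

    def test_concordance_filter(self, synth_run):
        mols = [("cand", parse_smiles("O=C(N)Nc1ccc(Cl)cc1"))]
        conds = [
            cd.ExperimentalCondition(row["ma"], row["tg"], row["ei"])
            for _, row in synth_run.records[["ma", "tg", "ei"]].drop_duplicates().iterrows()
        ]
        result = screen(
            mols,
            synth_run.mlp,
            synth_run.stats,
            model_features_of(synth_run.mlp),
            conds,
            filter_bundle=synth_run.lda,
            filter_stats=synth_run.stats,
            filter_features=model_features_of(synth_run.lda),
        )
        assert {"proba_filter", "predicted_filter", "concordant"} <= set(result.columns)
        assert result["concordant"].dtype == bool

    def test_empty_condition_roster_rejected(self, synth_run):
        with pytest.raises(ValueError):
            screen(
                [("m", parse_smiles("CCO"))],
                synth_run.mlp,
                synth_run.stats,
                model_features_of(synth_run.mlp),
                conditions=[],
            )


class TestDrugLikeness:
    def test_ethanol(self):
        profile = drug_likeness(parse_smiles("CCO"))
        assert profile.n_h_donors == 1
        assert profile.n_h_acceptors == 1
        assert profile.rbn == 0
        assert profile.lipinski
        assert not profile.ghose  # MW far below 160

    def test_decane_rotatable_bonds(self):
        profile = drug_likeness(parse_smiles("CCCCCCCCCC"))
        assert profile.rbn == 7
        assert profile.veber

    def test_oversized_molecule_fails_lipinski(self):
        profile = drug_likeness(parse_smiles("C" * 40))
        assert profile.mw > 500
        assert not profile.lipinski

    def test_mw_monotonicity_of_verdicts(self):
        # growing a chain only ever flips MW-bounded verdicts pass -> fail
        mws, lip = [], []
        for n in (10, 20, 30, 40, 50):
            p = drug_likeness(parse_smiles("C" * n))
            mws.append(p.mw)
            lip.append(p.lipinski)
        assert mws == sorted(mws)
        assert lip == sorted(lip, reverse=True)

    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCCCCCCC", 4.2299),  # hand: -1.014 + 1.244*8^0.6 + 0.912
            ("c1ccccc1", 2.2819),  # hand: -1.014 + 1.244*6^0.6 - 0.145*3^0.8
        ],
    )
    def test_moriguchi_hand_values(self, smiles, expected):
        from rdkit import Chem

        assert moriguchi_logp(Chem.MolFromSmiles(smiles)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_moriguchi_polarity_ordering(self):
        from rdkit import Chem

        octane = moriguchi_logp(Chem.MolFromSmiles("CCCCCCCC"))
        octanol = moriguchi_logp(Chem.MolFromSmiles("CCCCCCCCO"))
        assert octanol < octane
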
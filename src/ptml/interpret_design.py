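"""Model interpretation and fragment-guided design support.

Three instruments turn a fitted classifier back into chemistry:

* **class propensities** — per-feature means over actives vs inactives;
  a feature whose active mean exceeds its inactive mean should be
  *increased* to favor activity, and vice versa;
* **sensitivity values (SV)** — importance of each feature as the ratio of
  the classification error with that feature clamped to its training mean
  over the baseline error (uninformative features give SV near 1);
* **multi-condition screening** — a candidate molecule's raw descriptors
  are deviated against every experimental condition in the roster and
  scored, with the range-based applicability domain evaluated per case and
  an optional second model acting as a concordance filter.

Drug-likeness profiling (Lipinski, Ghose, Veber) rounds out the design
loop; it includes an in-package Moriguchi logP (MlogP) since the filters
are usually quoted against it alongside the Ghose-Crippen AlogP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors, rdmolops

from .chemgraph import MolecularGraph
from .conditions_dataset import (
    BoxJenkinsStats,
    CutoffTable,
    ExperimentalCondition,
    transform_condition,
)
from .descriptors import gti_block
from .ptml_model import ClassifierBundle

# ---------------------------------------------------------------------------
# propensities and sensitivity


def propensity_direction(active_mean: float, inactive_mean: float) -> str:
    if active_mean > inactive_mean:
        return "Increase"
    if active_mean < inactive_mean:
        return "Decrease"
    return "Tie"


def class_propensities(
    features: pd.DataFrame, labels, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature class-based means and the Increase/Decrease propensity."""
    y = np.asarray(labels)
    if (y == 1).sum() == 0 or (y == -1).sum() == 0:
        raise ValueError("both classes must be present")
    cols = feature_names if feature_names is not None else list(features.columns)
    active = features.loc[y == 1, cols].mean()
    inactive = features.loc[y == -1, cols].mean()
    return pd.DataFrame(
        {
            "active_mean": active,
            "inactive_mean": inactive,
            "propensity": [
                propensity_direction(a, i) for a, i in zip(active, inactive)
            ],
        }
    )


def sensitivity_values(
    bundle: ClassifierBundle, features: pd.DataFrame, labels
) -> pd.DataFrame:
    """SV per feature: error with the feature clamped to its training mean,
    divided by the baseline error; ranked descending.

    With a zero baseline error the ratio is undefined: SVs are reported as
    NaN with ``baseline_zero`` flagged and the ranking falls back to the
    perturbed error itself.
    """
    y = np.asarray(labels)
    base_err = float((bundle.predict(features) != y).mean())
    rows = []
    for name in bundle.feature_names:
        perturbed = features.copy()
        perturbed[name] = bundle.feature_means.get(name, features[name].mean())
        err = float((bundle.predict(perturbed) != y).mean())
        rows.append((name, err))
    out = pd.DataFrame(rows, columns=["feature", "perturbed_error"]).set_index(
        "feature"
    )
    out["baseline_zero"] = base_err == 0.0
    out["sv"] = np.nan if base_err == 0.0 else out["perturbed_error"] / base_err
    sort_col = "perturbed_error" if base_err == 0.0 else "sv"
    out = out.sort_values(sort_col, ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["baseline_error"] = base_err
    return out


def design_guidelines(propensities: pd.DataFrame, sv: pd.DataFrame | None = None) -> list[str]:
    """Human-readable fragment-design guidance: which deviation features to
    push up or down, ordered by sensitivity when available."""
    order = list(sv.index) if sv is not None else list(propensities.index)
    lines = []
    for name in order:
        if name not in propensities.index:
            continue
        direction = propensities.loc[name, "propensity"]
        if direction == "Tie":
            continue
        verb = "increase" if direction == "Increase" else "decrease"
        lines.append(f"{name}: {verb} to favor activity across conditions")
    return lines


# ---------------------------------------------------------------------------
# multi-condition screening


def screen(
    molecules: list[tuple[str, MolecularGraph]],
    bundle: ClassifierBundle,
    stats: BoxJenkinsStats,
    model_features: list[tuple[str, str]],
    conditions: list[ExperimentalCondition] | None = None,
    *,
    filter_bundle: ClassifierBundle | None = None,
    filter_stats: BoxJenkinsStats | None = None,
    filter_features: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Score each molecule under every experimental condition.

    Returns one row per molecule x condition with the active-class
    probability, predicted label, TSAD and in-AD flag; when a second model
    is attached as a concordance filter its prediction and an agreement
    flag are appended.  Out-of-AD predictions are still reported, flagged.
    """
    if conditions is None:
        conditions = CutoffTable.default().conditions()
    if not conditions:
        raise ValueError("empty condition roster")
    specs = sorted({spec for spec, _ in model_features})
    f_specs = (
        sorted({spec for spec, _ in filter_features}) if filter_features else []
    )
    rows = []
    for mol_id, graph in molecules:
        gti = pd.Series(gti_block(graph, specs))
        f_gti = pd.Series(gti_block(graph, f_specs)) if f_specs else None
        for cond in conditions:
            feats = transform_condition(gti, cond, stats, model_features)
            proba = float(bundle.predict_proba(feats.to_frame().T[bundle.feature_names])[0])
            tsad = int(bundle.tsad(feats.to_frame().T[bundle.feature_names])[0])
            row = {
                "molecule": mol_id,
                "ma": cond.ma,
                "tg": cond.tg,
                "ei": cond.ei,
                "proba_active": proba,
                "predicted": 1 if proba >= 0.5 else -1,
                "tsad": tsad,
                "in_ad": tsad == len(bundle.feature_names),
            }
            if filter_bundle is not None:
                ffeats = transform_condition(
                    f_gti, cond, filter_stats or stats, filter_features or model_features
                )
                fproba = float(
                    filter_bundle.predict_proba(
                        ffeats.to_frame().T[filter_bundle.feature_names]
                    )[0]
                )
                row["proba_filter"] = fproba
                row["predicted_filter"] = 1 if fproba >= 0.5 else -1
                row["concordant"] = row["predicted"] == row["predicted_filter"]
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["summary"] = (
        out.groupby("molecule")["predicted"].apply(lambda s: float((s == 1).mean()))
    ).to_dict()
    return out


# ---------------------------------------------------------------------------
# drug-likeness


@dataclass
class DrugLikenessProfile:
    n_h_donors: int
    n_h_acceptors: int
    mw: float
    mlogp: float
    alogp: float
    mr: float
    n_atoms: int  # including hydrogens
    rbn: int
    psa: float
    lipinski: bool = field(init=False)
    ghose: bool = field(init=False)
    veber: bool = field(init=False)

    def __post_init__(self):
        self.lipinski = (
            self.mw <= 500
            and (self.mlogp <= 4.15 or self.alogp <= 5)
            and self.n_h_donors <= 5
            and self.n_h_acceptors <= 10
        )
        self.ghose = (
            160 <= self.mw <= 480
            and -0.4 <= self.alogp <= 5.6
            and 40 <= self.mr <= 130
            and 20 <= self.n_atoms <= 70
        )
        self.veber = self.rbn <= 10 and self.psa <= 140

    def to_dict(self) -> dict:
        return {
            "nHDon": self.n_h_donors,
            "nHAcc": self.n_h_acceptors,
            "MW": self.mw,
            "MlogP": self.mlogp,
            "AlogP": self.alogp,
            "MR": self.mr,
            "nAT": self.n_atoms,
            "RBN": self.rbn,
            "PSA": self.psa,
            "lipinski": self.lipinski,
            "ghose": self.ghose,
            "veber": self.veber,
        }


def drug_likeness(graph: MolecularGraph) -> DrugLikenessProfile:
    """Global physicochemical profile with Lipinski/Ghose/Veber verdicts."""
    mol = graph.mol
    return DrugLikenessProfile(
        n_h_donors=Lipinski.NumHDonors(mol),
        n_h_acceptors=Lipinski.NumHAcceptors(mol),
        mw=float(Descriptors.MolWt(mol)),
        mlogp=moriguchi_logp(mol),
        alogp=float(Crippen.MolLogP(mol)),
        mr=float(Crippen.MolMR(mol)),
        n_atoms=Chem.AddHs(mol).GetNumAtoms(),
        rbn=int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        psa=float(rdMolDescriptors.CalcTPSA(mol)),
    )


# -- Moriguchi logP ----------------------------------------------------------

_CX_WEIGHTS = {"C": 1.0, "F": 0.5, "Cl": 1.0, "Br": 1.5, "I": 2.0}

_PAT_NO2 = Chem.MolFromSmarts("[N+](=O)[O-]")
_PAT_NO2_NEUTRAL = Chem.MolFromSmarts("N(=O)=O")
_PAT_NCS = Chem.MolFromSmarts("N=C=S")
_PAT_SCN = Chem.MolFromSmarts("SC#N")
_PAT_AMIDE = Chem.MolFromSmarts("[NX3][CX3]=[OX1]")
_PAT_SULFONAMIDE = Chem.MolFromSmarts("[NX3][SX4](=[OX1])=[OX1]")
_PAT_QN = Chem.MolFromSmarts("[N+X4]")
_PAT_NOXIDE = Chem.MolFromSmarts("[N+][O-]")
_PAT_ALPHA_AMINO_ACID = Chem.MolFromSmarts("[NX3;H2,H1][CX4][CX3](=O)[OX2H1,OX1-]")
_PAT_AMINOBENZOIC = Chem.MolFromSmarts("[NX3;H2,H1]c1ccccc1C(=O)[OX2H1,OX1-]")
_PAT_PYRIDINE_ACID = Chem.MolFromSmarts("c1ccncc1C(=O)[OX2H1,OX1-]")
_PAT_BETA_LACTAM = Chem.MolFromSmarts("[NX3R]1[CX4][CX4][CX3R]1=O")
_PAT_INTRA_HB = Chem.MolFromSmarts("[OX2H,NX3H1,NX3H2]-[c,C]:,=[c,C]-[CX3]=[OX1]")


def _moriguchi_parameters(mol: Chem.Mol) -> dict[str, float]:
    params: dict[str, float] = {}
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    params["CX"] = sum(_CX_WEIGHTS.get(s, 0.0) for s in symbols)
    params["NO"] = sum(1 for s in symbols if s in ("N", "O"))

    # proximity effect: N/O pairs at topological distance 1 score 2, at
    # distance 2 score 1; amide and sulfonamide groups get a +1 bonus so
    # the group counts 2 in total
    no_idx = [i for i, s in enumerate(symbols) if s in ("N", "O")]
    dmat = rdmolops.GetDistanceMatrix(mol)
    prx = 0.0
    for a_pos, i in enumerate(no_idx):
        for j in no_idx[a_pos + 1 :]:
            d = dmat[i, j]
            if d == 1:
                prx += 2.0
            elif d == 2:
                prx += 1.0
    prx += len(mol.GetSubstructMatches(_PAT_AMIDE))
    prx += len(mol.GetSubstructMatches(_PAT_SULFONAMIDE))
    params["PRX"] = prx

    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)
    nitro_bonds = set()
    for pat in (_PAT_NO2, _PAT_NO2_NEUTRAL):
        for match in kek.GetSubstructMatches(pat):
            for i in match:
                for j in match:
                    if i < j and kek.GetBondBetweenAtoms(i, j) is not None:
                        nitro_bonds.add((i, j))
    ub = 0
    for bond in kek.GetBonds():
        if bond.GetBondTypeAsDouble() > 1.0:
            key = tuple(sorted((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())))
            if key not in nitro_bonds:
                ub += 1
    params["UB"] = ub

    params["HB"] = 1.0 if mol.HasSubstructMatch(_PAT_INTRA_HB) else 0.0

    # aromatic polar substituents: N, O or halogen atoms (or carbonyl
    # carbons) directly attached to an aromatic atom
    pol = 0
    for atom in mol.GetAtoms():
        if atom.GetIsAromatic():
            continue
        if not any(n.GetIsAromatic() for n in atom.GetNeighbors()):
            continue
        s = atom.GetSymbol()
        if s in ("N", "O", "F", "Cl", "Br", "I", "S", "P"):
            pol += 1
        elif s == "C" and any(
            b.GetBondTypeAsDouble() == 2.0
            and b.GetOtherAtom(atom).GetSymbol() in ("O", "N", "S")
            for b in atom.GetBonds()
        ):
            pol += 1
    params["POL"] = pol

    amp = 0.0
    if mol.HasSubstructMatch(_PAT_ALPHA_AMINO_ACID):
        amp = 1.0
    elif mol.HasSubstructMatch(_PAT_AMINOBENZOIC) or mol.HasSubstructMatch(
        _PAT_PYRIDINE_ACID
    ):
        amp = 0.5
    params["AMP"] = amp

    is_hydrocarbon = all(s in ("C", "H") for s in symbols)
    no_aromatic = not any(a.GetIsAromatic() for a in mol.GetAtoms())
    no_triple = all(b.GetBondTypeAsDouble() < 3.0 for b in kek.GetBonds())
    params["ALK"] = float(is_hydrocarbon and no_aromatic and no_triple and ub <= 1)

    ring_info = mol.GetRingInfo()
    rng = 0.0
    for ring in ring_info.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() and a.GetSymbol() == "C" for a in atoms):
            rng = 1.0
            break
    params["RNG"] = rng

    qn = 0.0
    if mol.HasSubstructMatch(_PAT_QN):
        qn = 1.0
    elif mol.HasSubstructMatch(_PAT_NOXIDE):
        qn = 0.5
    params["QN"] = qn

    params["NO2"] = float(
        len(mol.GetSubstructMatches(_PAT_NO2)) + len(mol.GetSubstructMatches(_PAT_NO2_NEUTRAL))
    )
    ncs = 1.0 * len(mol.GetSubstructMatches(_PAT_NCS)) + 0.5 * len(
        mol.GetSubstructMatches(_PAT_SCN)
    )
    params["NCS"] = ncs
    params["BLM"] = 1.0 if mol.HasSubstructMatch(_PAT_BETA_LACTAM) else 0.0
    return params


def moriguchi_logp(mol: Chem.Mol) -> float:
    """Moriguchi octanol/water logP from 13 topological/structural counts.

    The rarely-triggered correction terms (intramolecular hydrogen bond,
    amphotericity, beta-lactam) use simplified SMARTS definitions.
    """
    p = _moriguchi_parameters(mol)
    return float(
        -1.014
        + 1.244 * p["CX"] ** 0.6
        - 1.017 * p["NO"] ** 0.9
        + 0.406 * p["PRX"]
        - 0.145 * p["UB"] ** 0.8
        + 0.511 * p["HB"]
        + 0.268 * p["POL"]
        - 2.215 * p["AMP"]
        + 0.912 * p["ALK"]
        - 0.392 * p["RNG"]
        - 3.684 * p["QN"]
        + 0.474 * p["NO2"]
        + 1.582 * p["NCS"]
        + 0.773 * p["BLM"]
    )
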
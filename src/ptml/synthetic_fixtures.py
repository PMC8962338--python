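"""Reproducible synthetic multi-condition bioactivity datasets.

The generator emulates the shape of a curated multi-target inhibition
table: a few thousand (here: configurable) cases, each a chemical assayed
under an experimental condition (ma, tg, ei) with an IC50 value in nM.  A
structure-activity signal is planted through a fragment grammar: chemicals
assembled around heteroatom-rich motifs (2-aminopyrimidines, triazines,
ureas, morpholines, 4-halophenyl decorations) are enriched among actives,
while plain alkyl/aromatic hydrocarbons are enriched among inactives.
Activity values are drawn multiplicatively around each condition's cutoff
with at least a 20% margin, so the cutoff annotation always recovers the
planted label.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .conditions_dataset import CutoffTable, ExperimentalCondition, SCHEMA_COLUMNS

# fragment grammar: heteroatom/halogen-rich motifs for the active-enriched
# pool, hydrocarbon chains and bare rings for the inactive-enriched pool
_ACTIVE_TEMPLATES = [
    "Nc1nc({0})cc({1})n1",      # pyrimidin-2-amine
    "Nc1nc({0})nc({1})n1",      # 1,3,5-triazin-2-amine
    "O=C(N{0})N{1}",            # urea
    "O=C(O{0})N{1}",            # carbamate
    "NCC(=O)N{0}{1}",           # glycinamide
]
_ACTIVE_SUBS = [
    "N", "O", "NC", "OC", "NCC", "OCC", "CO", "CN",
    "c1ccc(F)cc1", "c1ccc(Cl)cc1", "N1CCOCC1", "N1CCNCC1",
]
_INACTIVE_TEMPLATES = [
    "{0}CC{1}", "{0}CCCC{1}", "{0}C(C)C{1}", "C1CC({0})CC({1})C1", "c1cc({0})ccc1{1}",
]
_INACTIVE_SUBS = ["C", "CC", "CCC", "CCCC", "CC(C)C", "C1CCCCC1", "Cc1ccccc1", "C=C"]

DEFAULT_CONDITIONS = [
    ExperimentalCondition("IC50(nM)p", "Caspase-1", "B (single protein format)"),
    ExperimentalCondition("IC50(nM)p", "Caspase-1", "B (assay format)"),
    ExperimentalCondition("IC50(nM)p", "TNF-alpha", "B (single protein format)"),
    ExperimentalCondition("IC50(nM)p", "IGF1R", "B (single protein format)"),
    ExperimentalCondition("IC50(nM)c", "PSN1", "F (cell-based format)"),
    ExperimentalCondition("IC50(nM)c", "MIA-PaCa-2", "F (cell-based format)"),
    ExperimentalCondition("IC50(nM)c", "BxPC-3", "F (cell-based format)"),
]


def _pool(templates: list[str], subs: list[str]) -> list[str]:
    """Deterministic, validity-checked SMILES pool from a template grammar."""
    out: list[str] = []
    seen: set[str] = set()
    for tpl, pair in itertools.product(templates, itertools.product(subs, repeat=2)):
        try:
            smi = tpl.format(*pair)
        except IndexError:
            smi = tpl.format(pair[0])
        mol = Chem.MolFromSmiles(smi)
        if mol is None or mol.GetNumHeavyAtoms() < 2 or mol.GetNumHeavyAtoms() > 28:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical not in seen:
            seen.add(canonical)
            out.append(canonical)
    return out


@dataclass
class SyntheticConfig:
    """Generator settings.  The defaults define the study conditions used
    throughout the test suite: ~160 chemicals spread over 7 experimental
    conditions, a 0.4 active fraction per condition, an 85% concordance
    between fragment pool and planted label, and value noise that keeps
    every activity at least 20% away from its cutoff."""

    seed: int = 0
    n_chemicals: int = 160
    conditions: list[ExperimentalCondition] = field(
        default_factory=lambda: list(DEFAULT_CONDITIONS)
    )
    active_fraction: float = 0.4
    signal_fidelity: float = 0.85
    mean_conditions_per_chemical: float = 2.5
    cutoffs: CutoffTable = field(default_factory=CutoffTable.default)

    def __post_init__(self):
        if not self.conditions:
            raise ValueError("at least one experimental condition is required")
        if not 0 < self.active_fraction < 1:
            raise ValueError("active_fraction must be in (0, 1)")
        if not 0.5 <= self.signal_fidelity <= 1:
            raise ValueError("signal_fidelity must be in [0.5, 1]")


def generate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a bioactivity table plus a ground-truth sidecar.

    Returns ``(records, truth)`` where records follow the bioactivity CSV
    schema and truth maps each chemical to its fragment pool and each case
    to its planted label.  Identical configs give identical output.
    """
    rng = np.random.default_rng(config.seed)
    active_pool = _pool(_ACTIVE_TEMPLATES, _ACTIVE_SUBS)
    inactive_pool = _pool(_INACTIVE_TEMPLATES, _INACTIVE_SUBS)

    n_active_chems = int(round(config.n_chemicals * config.active_fraction))
    n_inactive_chems = config.n_chemicals - n_active_chems
    if n_active_chems > len(active_pool) or n_inactive_chems > len(inactive_pool):
        raise ValueError("requested more chemicals than the fragment grammar provides")
    chems = [
        (smi, "active-like")
        for smi in rng.choice(active_pool, n_active_chems, replace=False)
    ] + [
        (smi, "inactive-like")
        for smi in rng.choice(inactive_pool, n_inactive_chems, replace=False)
    ]
    order = rng.permutation(len(chems))
    chems = [chems[i] for i in order]

    # assign each chemical to >= 1 conditions
    p_extra = min(
        0.95, (config.mean_conditions_per_chemical - 1) / max(len(config.conditions) - 1, 1)
    )
    cases: list[tuple[int, ExperimentalCondition]] = []
    for ci in range(len(chems)):
        mask = rng.random(len(config.conditions)) < p_extra
        mask[rng.integers(len(config.conditions))] = True
        for j, m in enumerate(mask):
            if m:
                cases.append((ci, config.conditions[j]))

    # per condition: hit the target active count, preferring active-pool
    # chemicals (with a fidelity-controlled chance of swapping pools)
    rows = []
    truth_cases = []
    by_condition: dict[ExperimentalCondition, list[int]] = {}
    for case_idx, (ci, cond) in enumerate(cases):
        by_condition.setdefault(cond, []).append(case_idx)
    labels = np.zeros(len(cases), dtype=int)
    for cond, case_idxs in by_condition.items():
        n_c = len(case_idxs)
        if n_c < 4:
            raise ValueError(
                f"condition {cond} received only {n_c} cases; increase n_chemicals"
            )
        n_act = int(round(config.active_fraction * n_c))
        n_act = min(max(n_act, 2), n_c - 2)
        keys = []
        for case_idx in case_idxs:
            pool = chems[cases[case_idx][0]][1]
            pref_active = pool == "active-like"
            if rng.random() > config.signal_fidelity:
                pref_active = not pref_active
            keys.append((0 if pref_active else 1, rng.random(), case_idx))
        keys.sort()
        for rank, (_, _, case_idx) in enumerate(keys):
            labels[case_idx] = 1 if rank < n_act else -1

    for case_idx, (ci, cond) in enumerate(cases):
        smi, pool = chems[ci]
        cutoff = config.cutoffs.cutoff(cond.ma, cond.tg)
        if labels[case_idx] == 1:
            factor = np.exp(rng.uniform(np.log(0.15), np.log(0.8)))
        else:
            factor = np.exp(rng.uniform(np.log(1.3), np.log(6.0)))
        rows.append(
            {
                "compound_id": f"SYN{ci:04d}",
                "smiles": smi,
                "ma": cond.ma,
                "tg": cond.tg,
                "ei": cond.ei,
                "value": round(cutoff * factor, 4),
                "units": "nM",
            }
        )
        truth_cases.append(int(labels[case_idx]))

    records = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    truth = {
        "chemicals": {f"SYN{i:04d}": pool for i, (_, pool) in enumerate(chems)},
        "planted_labels": truth_cases,
        "seed": config.seed,
    }
    return records, truth


def write_dataset(config: SyntheticConfig, csv_path, truth_path=None) -> None:
    records, truth = generate_dataset(config)
    records.to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)


# ---------------------------------------------------------------------------
# hand-checked micro fixture


MICRO_SPECS = ["X(P)1", "SM(Ato)1", "Ne(P)1"]
MICRO_FEATURES = [("X(P)1", "ma"), ("SM(Ato)1", "tg"), ("Ne(P)1", "ei")]

_MICRO_ROWS = [
    # (id, smiles, ma, tg, ei, value)
    ("M1", "CC", "IC50(nM)p", "Caspase-1", "B (single protein format)", 500.0),
    ("M2", "CCC", "IC50(nM)p", "Caspase-1", "B (single protein format)", 800.0),
    ("M3", "CCCC", "IC50(nM)p", "Caspase-1", "B (single protein format)", 2000.0),
    ("M4", "CC(C)C", "IC50(nM)p", "Caspase-1", "B (single protein format)", 5000.0),
    ("M5", "CCO", "IC50(nM)p", "TNF-alpha", "B (single protein format)", 400.0),
    ("M6", "COC", "IC50(nM)p", "TNF-alpha", "B (single protein format)", 1500.0),
    ("M7", "C1CC1", "IC50(nM)p", "TNF-alpha", "B (single protein format)", 3000.0),
    ("M8", "CCN", "IC50(nM)p", "TNF-alpha", "B (single protein format)", 8000.0),
]


def generate_worked_micro_dataset() -> pd.DataFrame:
    """An 8-molecule, 2-condition fixture small enough that every raw
    descriptor, Box-Jenkins statistic and deviation value has been worked
    out by hand; the expected numbers ship as a companion data file
    (``micro_expected.json``) used by the test suite."""
    rows = [
        dict(zip(["compound_id", "smiles", "ma", "tg", "ei", "value"], r))
        for r in _MICRO_ROWS
    ]
    df = pd.DataFrame(rows)
    df["units"] = "nM"
    return df[SCHEMA_COLUMNS]


def micro_expected() -> dict:
    """Hand-derived expected values for the micro fixture."""
    from importlib import resources

    path = resources.files("ptml.data").joinpath("micro_expected.json")
    with path.open() as fh:
        return json.load(fh)
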
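"""Experimental conditions, bioactivity curation and the Box-Jenkins
condition-deviation transform.

Each bioactivity case is one chemical assayed under an experimental
condition c_j = (ma, tg, ei): the activity measure (e.g. a protein or
cell-viability IC50 in nM), the target (a protein or a cell line) and the
assay-information annotation.  A cutoff table maps (ma, tg) to the nM
threshold at or below which a case is labeled active (IA = 1, else -1).

The Box-Jenkins two-step transform turns a raw molecular descriptor (GTI)
into one condition-deviation feature per condition element:

    D(GTI)_e = (GTI - avg(GTI)_e) / (std(GTI) * ps_e)

where avg(GTI)_e is the mean over the *training actives* sharing element
value e (applied separately to ma, tg and ei), std(GTI) is the sample
standard deviation over all training cases, and ps_e = n_e / NT_e is the a
priori probability of an active among the training cases with element
value e.  A deviation feature therefore measures how far a chemical sits
from the actives of its own assay context, in units that shrink for
elements where activity is common.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from rdkit import Chem

from .specs import feature_name

ELEMENT_KINDS = ("ma", "tg", "ei")
SCHEMA_COLUMNS = ["compound_id", "smiles", "ma", "tg", "ei", "value", "units"]


@dataclass(frozen=True)
class ExperimentalCondition:
    ma: str
    tg: str
    ei: str

    def __post_init__(self):
        if not (self.ma and self.tg and self.ei):
            raise ValueError("all three condition elements must be non-empty")


class CutoffError(KeyError):
    """No activity cutoff resolves for a (ma, tg) pair."""


class CutoffTable:
    """Map from (ma, tg) to the nM cutoff at or below which a case is
    active, together with the full roster of known conditions."""

    def __init__(self, conditions: pd.DataFrame):
        required = {"ma", "tg", "ei", "cutoff_nM"}
        if not required.issubset(conditions.columns):
            raise ValueError(f"cutoff table needs columns {sorted(required)}")
        self._df = conditions.reset_index(drop=True)
        self._cutoffs: dict[tuple[str, str], float] = {}
        for _, row in self._df.iterrows():
            key = (row["ma"], row["tg"])
            cut = float(row["cutoff_nM"])
            if key in self._cutoffs and self._cutoffs[key] != cut:
                raise ValueError(f"conflicting cutoffs for {key}")
            self._cutoffs[key] = cut

    @classmethod
    def default(cls) -> "CutoffTable":
        path = resources.files("ptml.data").joinpath("default_conditions.csv")
        with path.open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path) -> "CutoffTable":
        return cls(pd.read_csv(path))

    def cutoff(self, ma: str, tg: str) -> float:
        try:
            return self._cutoffs[(ma, tg)]
        except KeyError:
            raise CutoffError(f"no cutoff for (ma={ma!r}, tg={tg!r})") from None

    def conditions(self) -> list[ExperimentalCondition]:
        return [
            ExperimentalCondition(row["ma"], row["tg"], row["ei"])
            for _, row in self._df.iterrows()
        ]

    def __len__(self) -> int:
        return len(self._df)


def load_bioactivity_table(
    path, *, sep: str | None = None, accepted_units: tuple[str, ...] = ("nM",)
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Load and curate a bioactivity CSV/TSV.

    Rows missing SMILES, activity value or units, with non-positive values,
    or with unparseable SMILES are dropped and counted in the returned log.
    A unit that is present but not accepted raises (no silent conversion).
    SMILES are canonicalized so duplicate detection is structure-based.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bioactivity table missing columns: {missing}")
    log = {"rows_in": len(df), "missing_fields": 0, "bad_value": 0, "bad_smiles": 0}

    keep_rows = []
    for _, row in df.iterrows():
        if any(
            pd.isna(row[c]) or str(row[c]).strip() == ""
            for c in ("smiles", "value", "units")
        ):
            log["missing_fields"] += 1
            continue
        units = str(row["units"]).strip()
        if units not in accepted_units:
            raise ValueError(f"unknown activity units {units!r} (accepted: {accepted_units})")
        try:
            value = float(row["value"])
        except ValueError:
            log["bad_value"] += 1
            continue
        if value <= 0 or not np.isfinite(value):
            log["bad_value"] += 1
            continue
        mol = Chem.MolFromSmiles(str(row["smiles"]))
        if mol is None or mol.GetNumHeavyAtoms() < 2:
            log["bad_smiles"] += 1
            continue
        keep_rows.append(
            {
                "compound_id": str(row["compound_id"]),
                "smiles": Chem.MolToSmiles(mol),
                "ma": str(row["ma"]),
                "tg": str(row["tg"]),
                "ei": str(row["ei"]),
                "value": value,
                "units": units,
            }
        )
    out = pd.DataFrame(keep_rows, columns=SCHEMA_COLUMNS)
    log["rows_kept"] = len(out)
    return out, log


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Among cases sharing (canonical SMILES, condition), keep only the one
    with the lowest activity value (first seen wins ties)."""
    if records.empty:
        return records.copy()
    idx = records.groupby(["smiles", "ma", "tg", "ei"], sort=False)["value"].idxmin()
    return records.loc[sorted(idx)].reset_index(drop=True)


def annotate_activity(records: pd.DataFrame, cutoffs: CutoffTable) -> pd.DataFrame:
    """Attach the dichotomous activity label: 1 when value <= cutoff
    (boundary inclusive), else -1."""
    labeled = records.copy()
    labeled["label"] = [
        1 if row["value"] <= cutoffs.cutoff(row["ma"], row["tg"]) else -1
        for _, row in records.iterrows()
    ]
    return labeled


def split_dataset(
    records: pd.DataFrame, test_fraction: float = 0.25, seed: int = 0
) -> pd.DataFrame:
    """Tag cases train/test, stratified by label within each condition.

    Raises if any condition-element value ends with zero training actives
    (the Box-Jenkins averages would be undefined there).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if "label" not in records.columns:
        raise ValueError("records must be annotated before splitting")
    rng = np.random.default_rng(seed)
    tagged = records.copy()
    tagged["split"] = "train"
    for _, idx in tagged.groupby(["ma", "tg", "ei", "label"], sort=False).groups.items():
        idx = np.asarray(sorted(idx))
        n_test = int(round(len(idx) * test_fraction))
        chosen = rng.permutation(idx)[:n_test]
        tagged.loc[chosen, "split"] = "test"
    train = tagged[tagged["split"] == "train"]
    for kind in ELEMENT_KINDS:
        for value, sub in train.groupby(kind, sort=False):
            if (sub["label"] == 1).sum() == 0:
                raise ValueError(
                    f"condition element {kind}={value!r} has no training actives; "
                    "re-split with another seed or merge elements"
                )
    return tagged


@dataclass
class BoxJenkinsStats:
    """Per condition-element Box-Jenkins statistics.

    ``avg[kind][element]`` is a per-descriptor Series of means over the
    training actives of that element value; ``ps[kind][element]`` the
    training active fraction there; ``std`` the per-descriptor sample
    standard deviation over all training cases.
    """

    descriptors: list[str]
    std: pd.Series
    avg: dict[str, dict[str, pd.Series]] = field(default_factory=dict)
    counts: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def ps(self, kind: str, element: str) -> float:
        n, nt = self.counts[kind][element]
        return n / nt

    def to_dict(self) -> dict:
        return {
            "descriptors": self.descriptors,
            "std": self.std.to_dict(),
            "avg": {
                kind: {e: s.to_dict() for e, s in per.items()}
                for kind, per in self.avg.items()
            },
            "counts": {
                kind: {e: list(c) for e, c in per.items()}
                for kind, per in self.counts.items()
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "BoxJenkinsStats":
        descriptors = payload["descriptors"]
        return cls(
            descriptors=descriptors,
            std=pd.Series(payload["std"]).reindex(descriptors),
            avg={
                kind: {
                    e: pd.Series(s).reindex(descriptors)
                    for e, s in per.items()
                }
                for kind, per in payload["avg"].items()
            },
            counts={
                kind: {e: (int(c[0]), int(c[1])) for e, c in per.items()}
                for kind, per in payload["counts"].items()
            },
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "BoxJenkinsStats":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def case_gti(records: pd.DataFrame, gti: pd.DataFrame) -> pd.DataFrame:
    """Per-case GTI matrix: each case inherits the descriptor row of its
    canonical SMILES."""
    missing = set(records["smiles"]) - set(gti.index)
    if missing:
        raise KeyError(f"{len(missing)} SMILES missing from the GTI table")
    return gti.loc[records["smiles"]].set_axis(records.index)


def fit_box_jenkins(train_records: pd.DataFrame, gti: pd.DataFrame) -> BoxJenkinsStats:
    """Fit condition-element averages, the global descriptor standard
    deviation and the a priori active probabilities on the training set.

    ``gti`` is indexed by canonical SMILES with one column per raw
    descriptor; only rows tagged (or assumed) training are passed in.
    """
    if len(train_records) < 2:
        raise ValueError("Box-Jenkins fit needs at least 2 training cases")
    x = case_gti(train_records, gti)
    descriptors = list(gti.columns)
    std = x.std(ddof=1)
    degenerate = std[(std == 0) | ~np.isfinite(std)]
    if len(degenerate):
        raise ValueError(
            f"zero/degenerate training std for descriptors: {list(degenerate.index)}"
        )
    stats = BoxJenkinsStats(descriptors=descriptors, std=std)
    for kind in ELEMENT_KINDS:
        stats.avg[kind] = {}
        stats.counts[kind] = {}
        for element, idx in train_records.groupby(kind, sort=False).groups.items():
            idx = list(idx)
            active_idx = [i for i in idx if train_records.loc[i, "label"] == 1]
            if not active_idx:
                raise ValueError(
                    f"condition element {kind}={element!r} has no training actives"
                )
            stats.avg[kind][element] = x.loc[active_idx].mean()
            stats.counts[kind][element] = (len(active_idx), len(idx))
    return stats


def transform(
    records: pd.DataFrame,
    gti: pd.DataFrame,
    stats: BoxJenkinsStats,
    model_features: list[tuple[str, str]],
) -> pd.DataFrame:
    """Build the condition-deviation feature matrix.

    ``model_features`` lists (raw descriptor spec, condition-element kind)
    pairs; the output column for each is named ``D(<spec>)<kind>``.  An
    element value unseen during fitting raises (no silent imputation).
    """
    x = case_gti(records, gti)
    out = pd.DataFrame(index=records.index)
    for spec, kind in model_features:
        if spec not in stats.descriptors:
            raise KeyError(f"descriptor {spec!r} not present in fitted stats")
        col = np.empty(len(records))
        for pos, (i, row) in enumerate(records.iterrows()):
            element = row[kind]
            if element not in stats.avg[kind]:
                raise KeyError(
                    f"unseen condition element {kind}={element!r}; "
                    "refit or extend the training conditions"
                )
            avg = stats.avg[kind][element][spec]
            ps = stats.ps(kind, element)
            col[pos] = (x.at[i, spec] - avg) / (stats.std[spec] * ps)
        out[feature_name(spec, kind)] = col
    return out


def transform_condition(
    gti_row: pd.Series | dict,
    condition: ExperimentalCondition,
    stats: BoxJenkinsStats,
    model_features: list[tuple[str, str]],
) -> pd.Series:
    """Deviation features of a single molecule under one condition (the
    screening path)."""
    values = {}
    for spec, kind in model_features:
        element = getattr(condition, kind)
        if element not in stats.avg[kind]:
            raise KeyError(f"unseen condition element {kind}={element!r}")
        avg = stats.avg[kind][element][spec]
        ps = stats.ps(kind, element)
        values[feature_name(spec, kind)] = (gti_row[spec] - avg) / (
            stats.std[spec] * ps
        )
    return pd.Series(values)
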
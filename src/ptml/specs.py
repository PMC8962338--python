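"""Descriptor specification grammar.

A :class:`DescriptorSpec` names one graph-theoretical invariant (GTI):

* ``SM(PP)k``   — spectral moment of order ``k`` of the bond adjacency
  matrix with diagonal weighted by atomic property ``PP``;
* ``X(s)o`` / ``Xv(s)o`` — Kier-Hall simple / valence connectivity index
  over order-``o`` subgraphs of type ``s`` in {P, C, PC, Ch};
* ``e(s)o``     — edge (bond) connectivity index, the same construction on
  the line graph;
* ``ASqm(x)T``  — local stochastic quadratic index of order ``m`` with
  property ``x`` restricted to atom group ``T``;
* a leading ``N`` marks division by the bond count (size normalization).

The string forms round-trip through :meth:`DescriptorSpec.parse` /
``str()`` and match the naming convention used in the model summaries,
e.g. ``NSM(Hyd)3``, ``Xv(Ch)6``, ``Ne(PC)6``, ``ASq4(Hyd)G``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .chemgraph import GROUP_CODES, PROPERTY_CODES

SUBGRAPH_TYPES = ("P", "C", "PC", "Ch")

_ASQ_RE = re.compile(r"^(N?)ASq(\d+)\((\w+)\)([A-Za-z]+)$")
_SM_RE = re.compile(r"^(N?)SM\((\w+)\)(\d+)$")
_CONN_RE = re.compile(r"^(N?)(Xv|X|e)\((P|C|PC|Ch)\)(\d+)$")


@dataclass(frozen=True)
class DescriptorSpec:
    family: str  # SM | X | Xv | e | ASq
    order: int
    prop: str | None = None  # property code (SM, ASq)
    subgraph: str | None = None  # subgraph type (X, Xv, e)
    group: str | None = None  # atom group (ASq)
    normalized: bool = False

    def __post_init__(self):
        if self.family not in ("SM", "X", "Xv", "e", "ASq"):
            raise ValueError(f"unknown descriptor family {self.family!r}")
        if self.order < 0:
            raise ValueError("descriptor order must be >= 0")
        if self.family in ("SM", "ASq"):
            if self.prop is not None and self.prop not in PROPERTY_CODES + ("none",):
                raise ValueError(f"unknown property code {self.prop!r}")
        if self.family in ("X", "Xv", "e") and self.subgraph not in SUBGRAPH_TYPES:
            raise ValueError(f"unknown subgraph type {self.subgraph!r}")
        if self.family == "ASq" and self.group not in GROUP_CODES:
            raise ValueError(f"unknown atom-group code {self.group!r}")

    @classmethod
    def parse(cls, text: str) -> "DescriptorSpec":
        text = text.strip()
        m = _ASQ_RE.match(text)
        if m:
            return cls(
                family="ASq",
                order=int(m.group(2)),
                prop=m.group(3),
                group=m.group(4),
                normalized=bool(m.group(1)),
            )
        m = _SM_RE.match(text)
        if m:
            return cls(
                family="SM",
                order=int(m.group(3)),
                prop=m.group(2),
                normalized=bool(m.group(1)),
            )
        m = _CONN_RE.match(text)
        if m:
            return cls(
                family=m.group(2),
                order=int(m.group(4)),
                subgraph=m.group(3),
                normalized=bool(m.group(1)),
            )
        raise ValueError(f"unparseable descriptor spec {text!r}")

    def __str__(self) -> str:
        n = "N" if self.normalized else ""
        if self.family == "ASq":
            return f"{n}ASq{self.order}({self.prop}){self.group}"
        if self.family == "SM":
            return f"{n}SM({self.prop}){self.order}"
        return f"{n}{self.family}({self.subgraph}){self.order}"


# The raw GTIs and condition-element kinds behind the two published model
# blocks (15 deviation descriptors for Model 1, 14 for Model 2).
MODEL1_SPECS: list[tuple[str, str]] = [
    ("NSM(Hyd)3", "ma"),
    ("NXv(P)4", "ma"),
    ("Ne(P)1", "ma"),
    ("Ne(P)2", "ma"),
    ("Ne(Ch)6", "ma"),
    ("SM(Hyd)7", "tg"),
    ("e(Ch)5", "tg"),
    ("NSM(Psa)1", "tg"),
    ("NSM(Gas)3", "tg"),
    ("NXv(P)1", "tg"),
    ("Xv(Ch)6", "ei"),
    ("NSM(Hyd)1", "ei"),
    ("NSM(Mol)1", "ei"),
    ("Ne(P)5", "ei"),
    ("Ne(PC)6", "ei"),
]

MODEL2_SPECS: list[tuple[str, str]] = [
    ("ASq4(Hyd)G", "ma"),
    ("ASq3(Hyd)Y", "ma"),
    ("ASq4(Hyd)Y", "ma"),
    ("ASq2(E)Y", "ma"),
    ("ASq1(Psa)Y", "ma"),
    ("ASq1(Aw)C", "tg"),
    ("ASq0(Ku)G", "tg"),
    ("ASq4(Psa)Y", "tg"),
    ("ASq1(Hyd)G", "ei"),
    ("ASq2(Hyd)G", "ei"),
    ("ASq2(Aw)G", "ei"),
    ("ASq1(Hyd)M", "ei"),
    ("ASq1(Ku)M", "ei"),
    ("ASq0(Hyd)Y", "ei"),
]


def model_specs(model: int) -> list[tuple[str, str]]:
    if model == 1:
        return list(MODEL1_SPECS)
    if model == 2:
        return list(MODEL2_SPECS)
    raise ValueError("model must be 1 or 2")


def feature_name(spec: str, kind: str) -> str:
    """Deviation-feature column name, e.g. ``D(NSM(Hyd)3)ma``."""
    if kind not in ("ma", "tg", "ei"):
        raise ValueError(f"unknown condition-element kind {kind!r}")
    return f"D({spec}){kind}"


def feature_kind(name: str) -> str:
    """Condition-element kind encoded in a deviation-feature name."""
    for kind in ("ma", "tg", "ei"):
        if name.endswith(kind):
            return kind
    raise ValueError(f"feature name {name!r} carries no ma/tg/ei suffix")


def parse_feature_name(name: str) -> tuple[str, str]:
    """Invert :func:`feature_name`: ``D(NSM(Hyd)3)ma`` -> (``NSM(Hyd)3``, ``ma``)."""
    kind = feature_kind(name)
    if not (name.startswith("D(") and name.endswith(")" + kind)):
        raise ValueError(f"not a deviation-feature name: {name!r}")
    spec = name[2 : -(len(kind) + 1)]
    DescriptorSpec.parse(spec)  # validates
    return spec, kind


def candidate_features(model: int) -> list[tuple[str, str]]:
    """The full (spec, element-kind) candidate grid a model selects from:
    every raw descriptor of the block crossed with ma, tg and ei."""
    specs = [s for s, _ in model_specs(model)]
    return [(s, k) for s in specs for k in ("ma", "tg", "ei")]
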
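"""Hydrogen-suppressed molecular graphs and atomic property schemes.

Every descriptor family in this package works on the heavy-atom (hydrogen
suppressed) graph of a molecule, decorated with one per-atom physicochemical
property at a time:

``Hyd``
    Ghose/Wildman-Crippen atomic hydrophobicity (logP) contribution.
``Mol``
    Ghose/Wildman-Crippen atomic molar-refractivity contribution.
``Psa``
    Ertl topological polar-surface-area contribution of the atom.
``Gas``
    Gasteiger-Marsili partial charge (iterative partial equalization of
    orbital electronegativity; hydrogen charges folded into the heavy atom).
``Ato`` / ``Aw``
    Standard atomic weight.
``E``
    Pauling electronegativity.
``Pol``
    Atomic dipole polarizability (1e-24 cm^3).
``Ku``
    Kupchik's modified vertex degree, (r_C / r_X) * (Zv - h) with r the
    single-bond covalent radius, Zv the valence-electron count and h the
    number of attached hydrogens.

Atoms are additionally classified into the typed groups used by the local
quadratic indices: halogens (G), heteroatoms N/O/S/P/Se (Y), aliphatic
carbons (C), methyl carbons (M, a subset of C) and aromatic carbons (A).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, rdMolDescriptors, rdPartialCharges

RDLogger.DisableLog("rdApp.*")

PROPERTY_CODES = ("Hyd", "Psa", "Mol", "Gas", "Ato", "Aw", "E", "Pol", "Ku")
GROUP_CODES = ("G", "Y", "C", "M", "A")

_HALOGENS = {"F", "Cl", "Br", "I"}
_HETEROATOMS = {"N", "O", "S", "P", "Se"}


class ParseError(ValueError):
    """A structure could not be parsed into a valid molecular graph."""


class PropertyTableError(KeyError):
    """An element has no entry in the requested property table."""


def _load_element_table() -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    path = resources.files("ptml.data").joinpath("element_properties.csv")
    with path.open() as fh:
        for row in csv.DictReader(fh):
            table[row["symbol"]] = {
                k: float(v) for k, v in row.items() if k != "symbol"
            }
    return table


ELEMENT_TABLE = _load_element_table()


@dataclass(frozen=True)
class Atom:
    symbol: str
    aromatic: bool
    formal_charge: int
    n_hydrogens: int


@dataclass
class MolecularGraph:
    """Hydrogen-suppressed labeled molecular graph.

    ``bonds`` are unordered heavy-atom index pairs with a bond-order tag;
    ``n_bonds`` counts bonds without multiplicity (a double bond is one
    bond), the size normalizer used throughout the descriptor modules.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, str]]
    mol: Chem.Mol = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, i: int) -> int:
        return sum(1 for a, b, _ in self.bonds if i in (a, b))

    def degrees(self) -> list[int]:
        deg = [0] * self.n_atoms
        for a, b, _ in self.bonds:
            deg[a] += 1
            deg[b] += 1
        return deg

    def neighbors(self, i: int) -> Iterator[int]:
        for a, b, _ in self.bonds:
            if a == i:
                yield b
            elif b == i:
                yield a

    def ring_bond_flags(self) -> list[bool]:
        return [
            self.mol.GetBondBetweenAtoms(a, b).IsInRing()
            for a, b, _ in self.bonds
        ]

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


def parse_smiles(
    smiles: str,
    *,
    keep_largest_component: bool = True,
    min_heavy_atoms: int = 2,
) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed graph.

    Multi-component (dot-disconnected) inputs keep the largest component by
    default; molecules with fewer than ``min_heavy_atoms`` heavy atoms are
    rejected because the size normalization divides by the bond count.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        if not keep_largest_component:
            raise ParseError(f"multi-component SMILES rejected: {smiles!r}")
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    if mol.GetNumHeavyAtoms() < min_heavy_atoms:
        raise ParseError(
            f"molecule has fewer than {min_heavy_atoms} heavy atoms: {smiles!r}"
        )
    return _from_rdkit(mol)


def _from_rdkit(mol: Chem.Mol) -> MolecularGraph:
    atoms = [
        Atom(
            symbol=a.GetSymbol(),
            aromatic=a.GetIsAromatic(),
            formal_charge=a.GetFormalCharge(),
            n_hydrogens=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        (
            b.GetBeginAtomIdx(),
            b.GetEndAtomIdx(),
            str(b.GetBondType()),
        )
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, mol=mol)


def read_smi(path) -> list[tuple[str, MolecularGraph]]:
    """Read a .smi file: one SMILES plus an optional whitespace-separated id
    per line.  Returns (id, graph) pairs; ids default to ``mol{lineno}``."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            out.append((mol_id, parse_smiles(smiles)))
    return out


def read_sdf(path) -> list[tuple[str, MolecularGraph]]:
    """Read an SDF (V2000) file into hydrogen-suppressed graphs."""
    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"unparseable record {i} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
        out.append((name or f"mol{i + 1}", _from_rdkit(mol)))
    return out


def assign_properties(
    graph: MolecularGraph, scheme: str, *, gasteiger_iterations: int = 12
) -> list[float]:
    """One property value per heavy atom under the requested scheme.

    Table-driven schemes are deterministic lookups; ``Gas`` runs the
    Gasteiger-Marsili damped charge-equalization iteration (hydrogen charges
    are folded into their heavy atom so a neutral molecule sums to ~0).
    """
    if scheme not in PROPERTY_CODES:
        raise ValueError(f"unknown property scheme {scheme!r}; expected one of {PROPERTY_CODES}")
    mol = graph.mol
    if scheme == "Hyd":
        return [c[0] for c in rdMolDescriptors._CalcCrippenContribs(mol)]
    if scheme == "Mol":
        return [c[1] for c in rdMolDescriptors._CalcCrippenContribs(mol)]
    if scheme == "Psa":
        return list(rdMolDescriptors._CalcTPSAContribs(mol))
    if scheme == "Gas":
        rdPartialCharges.ComputeGasteigerCharges(mol, nIter=gasteiger_iterations)
        return [
            a.GetDoubleProp("_GasteigerCharge") + a.GetDoubleProp("_GasteigerHCharge")
            for a in mol.GetAtoms()
        ]
    values = []
    for atom in graph.atoms:
        entry = ELEMENT_TABLE.get(atom.symbol)
        if entry is None:
            raise PropertyTableError(
                f"element {atom.symbol!r} has no entry for scheme {scheme!r}"
            )
        values.append(_table_value(entry, scheme, atom))
    return values


def _table_value(entry: dict[str, float], scheme: str, atom: Atom) -> float:
    if scheme in ("Ato", "Aw"):
        return entry["atomic_weight"]
    if scheme == "E":
        return entry["pauling_electronegativity"]
    if scheme == "Pol":
        return entry["polarizability"]
    # Ku: Kupchik's modified vertex degree
    r_c = ELEMENT_TABLE["C"]["covalent_radius"]
    return (r_c / entry["covalent_radius"]) * (
        entry["valence_electrons"] - atom.n_hydrogens
    )


@dataclass
class AtomTypeGroups:
    """Typed atom-group memberships for the local quadratic indices."""

    G: frozenset[int]  # halogens
    Y: frozenset[int]  # heteroatoms (N, O, S, P, Se and other non-C, non-halogen)
    C: frozenset[int]  # aliphatic carbons
    M: frozenset[int]  # methyl carbons (subset of C)
    A: frozenset[int]  # aromatic carbons

    def members(self, code: str) -> frozenset[int]:
        if code not in GROUP_CODES:
            raise ValueError(f"unknown atom-group code {code!r}")
        return getattr(self, code)


def atom_groups(graph: MolecularGraph) -> AtomTypeGroups:
    """Classify every heavy atom into exactly one of halogen (G), heteroatom
    (Y), aliphatic carbon (C) or aromatic carbon (A); methyl carbons (M) are
    the aliphatic carbons with one heavy neighbor and >= 3 hydrogens."""
    g, y, c, m, a = set(), set(), set(), set(), set()
    for i, atom in enumerate(graph.atoms):
        if atom.symbol in _HALOGENS:
            g.add(i)
        elif atom.symbol == "C":
            if atom.aromatic:
                a.add(i)
            else:
                c.add(i)
                if graph.degree(i) == 1 and atom.n_hydrogens >= 3:
                    m.add(i)
        else:
            # canonical heteroatom set is N, O, S, P, Se; any other
            # non-carbon heavy element falls back to the heteroatom group
            y.add(i)
    return AtomTypeGroups(
        G=frozenset(g), Y=frozenset(y), C=frozenset(c), M=frozenset(m), A=frozenset(a)
    )
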
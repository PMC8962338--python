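"""Model-1 descriptor families: spectral moments of the property-weighted
bond adjacency matrix, Kier-Hall simple/valence connectivity indices, edge
(bond) connectivity indices, and the bond-count size normalization.

The bond adjacency matrix is indexed by bonds: off-diagonal entries are 1
when two bonds share an atom (the line-graph adjacency) and the diagonal
carries bond weights w(i,j) = p_i/d_i + p_j/d_j, the atomic property of each
bond endpoint divided by its heavy-atom degree (the TOPS-MODE convention).
The spectral moment of order k is the trace of the k-th matrix power, i.e.
a sum over closed walks of length k in the weighted line graph.

Connectivity indices are Randic-style sums over connected subgraphs with
``o`` bonds: for each subgraph, the product over its atoms of
delta^(-1/2), with delta the (simple or valence) degree taken in the whole
molecule.  Subgraphs are classified by the Kier-Hall scheme into paths (P),
clusters (C), path-clusters (PC) and chains (Ch, cyclic).  Edge
connectivity indices evaluate the same construction on the line graph.
"""

from __future__ import annotations

from math import prod, sqrt

import numpy as np

from .chemgraph import ELEMENT_TABLE, MolecularGraph, assign_properties
from .specs import SUBGRAPH_TYPES, DescriptorSpec

MAX_SUBGRAPH_ORDER = 8  # exact enumeration cap; published blocks need <= 7


# ---------------------------------------------------------------------------
# subgraph machinery


def connected_vertex_subsets(adj: list[set[int]], k: int) -> list[frozenset[int]]:
    """All size-``k`` vertex subsets inducing a connected subgraph (ESU
    enumeration; each subset reported exactly once)."""
    if k < 1:
        raise ValueError("subset size must be >= 1")
    results: list[frozenset[int]] = []

    def extend(sub: list[int], ext: set[int], root: int) -> None:
        if len(sub) == k:
            results.append(frozenset(sub))
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            closed = set(sub)
            for u in sub:
                closed |= adj[u]
            new_ext = ext | {u for u in adj[w] if u > root and u not in closed}
            extend(sub + [w], new_ext, root)

    for v in range(len(adj)):
        extend([v], {u for u in adj[v] if u > v}, v)
    return results


def line_graph_adjacency(bonds: list[tuple[int, int]]) -> list[set[int]]:
    """Adjacency lists of the line graph: vertices are bonds, two bonds are
    adjacent when they share an atom."""
    n = len(bonds)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        ai, bi = bonds[i]
        for j in range(i + 1, n):
            aj, bj = bonds[j]
            if {ai, bi} & {aj, bj}:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def connected_edge_subsets(
    n_vertices: int, edges: list[tuple[int, int]], o: int
) -> list[tuple[tuple[int, int], ...]]:
    """All connected subgraphs with exactly ``o`` edges, as edge tuples.

    A connected edge subset of a graph corresponds one-to-one to a connected
    vertex subset of its line graph, so enumeration runs ESU there.
    """
    if o > MAX_SUBGRAPH_ORDER:
        raise ValueError(f"subgraph order {o} exceeds enumeration cap {MAX_SUBGRAPH_ORDER}")
    lg = line_graph_adjacency(edges)
    return [
        tuple(sorted(edges[i] for i in subset))
        for subset in connected_vertex_subsets(lg, o)
    ]


def classify_subgraph(edge_set: tuple[tuple[int, int], ...]) -> str:
    """Kier-Hall subgraph type: Ch (contains a cycle); otherwise P (no
    branching vertex), C (branched with no two bridging edges in series,
    i.e. no degree-2 vertex) or PC (mixed)."""
    deg: dict[int, int] = {}
    for a, b in edge_set:
        deg[a] = deg.get(a, 0) + 1
        deg[b] = deg.get(b, 0) + 1
    if len(edge_set) >= len(deg):  # connected with |E| >= |V| -> cyclic
        return "Ch"
    degrees = deg.values()
    if max(degrees) <= 2:
        return "P"
    if 2 not in degrees:
        return "C"
    return "PC"


def enumerate_subgraphs(
    graph: MolecularGraph, s: str, o: int
) -> list[tuple[tuple[int, int], ...]]:
    """Connected order-``o`` subgraphs (edge lists) of type ``s``."""
    if s not in SUBGRAPH_TYPES:
        raise ValueError(f"unknown subgraph type {s!r}")
    bonds = [(a, b) for a, b, _ in graph.bonds]
    return [
        sub
        for sub in connected_edge_subsets(graph.n_atoms, bonds, o)
        if classify_subgraph(sub) == s
    ]


# ---------------------------------------------------------------------------
# bond adjacency and spectral moments


def bond_weights(graph: MolecularGraph, prop: str) -> list[float]:
    """Per-bond diagonal weights w(i,j) = p_i/d_i + p_j/d_j."""
    values = assign_properties(graph, prop)
    deg = graph.degrees()
    return [
        values[a] / deg[a] + values[b] / deg[b] for a, b, _ in graph.bonds
    ]


def bond_adjacency(graph: MolecularGraph, prop: str = "none") -> np.ndarray:
    """Property-weighted bond adjacency matrix (dimension = bond count)."""
    if graph.n_bonds < 1:
        raise ValueError("molecule has no bonds")
    bonds = [(a, b) for a, b, _ in graph.bonds]
    lg = line_graph_adjacency(bonds)
    n = len(bonds)
    mat = np.zeros((n, n))
    for i, nbrs in enumerate(lg):
        for j in nbrs:
            mat[i, j] = 1.0
    if prop != "none":
        np.fill_diagonal(mat, bond_weights(graph, prop))
    return mat


def spectral_moment(matrix: np.ndarray, k: int) -> float:
    """Trace of the k-th power of the bond adjacency matrix; k = 0 gives
    the bond count (trace of the identity)."""
    if k < 0:
        raise ValueError("moment order must be >= 0")
    return float(np.trace(np.linalg.matrix_power(matrix, k)))


# ---------------------------------------------------------------------------
# connectivity indices


def simple_deltas(graph: MolecularGraph) -> list[float]:
    return [float(d) for d in graph.degrees()]


def valence_deltas(graph: MolecularGraph) -> list[float]:
    """Kier-Hall valence degree: Zv - h for second-row atoms, and
    (Zv - h)/(Z - Zv - 1) for heavier elements."""
    out = []
    for i, atom in enumerate(graph.atoms):
        entry = ELEMENT_TABLE.get(atom.symbol)
        if entry is None:
            raise ValueError(f"no valence data for element {atom.symbol!r}")
        zv = entry["valence_electrons"]
        z = entry["atomic_number"]
        dv = zv - atom.n_hydrogens
        if z > 10:
            dv = dv / (z - zv - 1)
        if dv <= 0:
            raise ValueError(
                f"non-positive valence degree for atom {i} ({atom.symbol})"
            )
        out.append(float(dv))
    return out


def _subgraph_sum(
    subgraphs: list[tuple[tuple[int, int], ...]], deltas: list[float]
) -> float:
    total = 0.0
    for sub in subgraphs:
        vertices = {v for edge in sub for v in edge}
        for v in vertices:
            if deltas[v] <= 0:
                raise ValueError(f"non-positive degree for vertex {v}")
        total += prod(1.0 / sqrt(deltas[v]) for v in vertices)
    return total


def connectivity_index(
    graph: MolecularGraph, s: str, o: int, variant: str = "simple"
) -> float:
    """Kier-Hall connectivity index X(s)o (simple) or Xv(s)o (valence)."""
    if variant not in ("simple", "valence"):
        raise ValueError(f"unknown variant {variant!r}")
    deltas = simple_deltas(graph) if variant == "simple" else valence_deltas(graph)
    return _subgraph_sum(enumerate_subgraphs(graph, s, o), deltas)


def edge_connectivity_index(graph: MolecularGraph, s: str, o: int) -> float:
    """Edge connectivity index e(s)o: the connectivity construction on the
    line graph, with vertex degrees the line-graph degrees."""
    if s not in SUBGRAPH_TYPES:
        raise ValueError(f"unknown subgraph type {s!r}")
    bonds = [(a, b) for a, b, _ in graph.bonds]
    lg = line_graph_adjacency(bonds)
    lg_edges = sorted(
        (i, j) for i, nbrs in enumerate(lg) for j in nbrs if j > i
    )
    deltas = [float(len(nbrs)) for nbrs in lg]
    subs = [
        sub
        for sub in connected_edge_subsets(len(lg), lg_edges, o)
        if classify_subgraph(sub) == s
    ]
    return _subgraph_sum(subs, deltas)


def normalize_descriptor(value: float, n_bonds: int) -> float:
    """Size normalization: the raw index divided by the bond count."""
    if n_bonds < 1:
        raise ValueError("normalization undefined for a molecule with no bonds")
    return value / n_bonds


# ---------------------------------------------------------------------------
# block evaluation


def descriptor_value(graph: MolecularGraph, spec: DescriptorSpec | str) -> float:
    """Evaluate one SM/X/Xv/e descriptor spec on a molecule."""
    if isinstance(spec, str):
        spec = DescriptorSpec.parse(spec)
    if spec.family == "SM":
        value = spectral_moment(bond_adjacency(graph, spec.prop), spec.order)
    elif spec.family in ("X", "Xv"):
        variant = "valence" if spec.family == "Xv" else "simple"
        value = connectivity_index(graph, spec.subgraph, spec.order, variant)
    elif spec.family == "e":
        value = edge_connectivity_index(graph, spec.subgraph, spec.order)
    else:
        raise ValueError(
            f"spec family {spec.family!r} is not a Model-1 (SM/X/Xv/e) descriptor"
        )
    if spec.normalized:
        value = normalize_descriptor(value, graph.n_bonds)
    return value


def model1_block(
    graph: MolecularGraph, specs: list[str] | None = None
) -> dict[str, float]:
    """Raw GTI values for the Model-1 block (defaults to the 15 published
    spectral-moment/connectivity specs)."""
    from .specs import MODEL1_SPECS

    if specs is None:
        specs = [s for s, _ in MODEL1_SPECS]
    out: dict[str, float] = {}
    for spec_str in specs:
        spec = DescriptorSpec.parse(spec_str)
        if spec.family == "ASq":
            raise ValueError(f"{spec_str!r} is not a Model-1 descriptor")
        out[str(spec)] = descriptor_value(graph, spec)
    return out
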
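"""Model-2 descriptor family: atom-based local stochastic quadratic indices.

The row-stochastic adjacency S is the heavy-atom adjacency matrix with each
row divided by the atom's degree, so [S^m]_ij sums the probabilities of all
length-m walks from atom i to atom j with per-step weight 1/degree.  The
local quadratic index of order m, property vector x and atom group T is the
row-restricted quadratic form

    ASq_m(x)_T = sum_{i in T} x_i * [S^m x]_i ,

i.e. the property of each group atom multiplied by the walk-weighted
property of the atoms m steps away.  m = 0 degenerates to the sum of
squared properties over the group; an empty group gives 0.
"""

from __future__ import annotations

import numpy as np

from .chemgraph import MolecularGraph, assign_properties, atom_groups
from .specs import DescriptorSpec

MAX_ORDER = 6


def stochastic_matrix(graph: MolecularGraph) -> np.ndarray:
    """Row-normalized heavy-atom adjacency; every row sums to 1."""
    if graph.n_atoms < 2:
        raise ValueError("stochastic adjacency needs at least 2 heavy atoms")
    n = graph.n_atoms
    adj = np.zeros((n, n))
    for a, b, _ in graph.bonds:
        adj[a, b] = 1.0
        adj[b, a] = 1.0
    row_sums = adj.sum(axis=1)
    if np.any(row_sums == 0):
        isolated = int(np.flatnonzero(row_sums == 0)[0])
        raise ValueError(f"isolated heavy atom {isolated}: cannot row-normalize")
    return adj / row_sums[:, None]


def local_quadratic_index(
    graph: MolecularGraph,
    x: list[float] | np.ndarray,
    m: int,
    group: str | frozenset[int],
) -> float:
    """ASq_m(x)_T for one property vector and atom group."""
    if not 0 <= m <= MAX_ORDER:
        raise ValueError(f"order m must be in [0, {MAX_ORDER}]")
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_atoms,):
        raise ValueError("property vector length must equal heavy-atom count")
    members = (
        atom_groups(graph).members(group) if isinstance(group, str) else group
    )
    if not members:
        return 0.0
    s_m = np.linalg.matrix_power(stochastic_matrix(graph), m)
    sx = s_m @ x
    idx = sorted(members)
    return float(np.dot(x[idx], sx[idx]))


def descriptor_value(graph: MolecularGraph, spec: DescriptorSpec | str) -> float:
    """Evaluate one ASq descriptor spec on a molecule."""
    if isinstance(spec, str):
        spec = DescriptorSpec.parse(spec)
    if spec.family != "ASq":
        raise ValueError(f"{spec} is not a local quadratic (ASq) descriptor")
    x = assign_properties(graph, spec.prop)
    value = local_quadratic_index(graph, x, spec.order, spec.group)
    if spec.normalized:
        from .topo_descriptors import normalize_descriptor

        value = normalize_descriptor(value, graph.n_bonds)
    return value


def model2_block(
    graph: MolecularGraph, specs: list[str] | None = None
) -> dict[str, float]:
    """Raw GTI values for the Model-2 block (defaults to the 14 published
    local-quadratic specs over properties Hyd/E/Psa/Aw/Ku and groups
    G/Y/C/M, orders 0-4)."""
    from .specs import MODEL2_SPECS

    if specs is None:
        specs = [s for s, _ in MODEL2_SPECS]
    groups = atom_groups(graph)
    s_powers: dict[int, np.ndarray] = {}
    props: dict[str, np.ndarray] = {}
    out: dict[str, float] = {}
    for spec_str in specs:
        spec = DescriptorSpec.parse(spec_str)
        if spec.family != "ASq":
            raise ValueError(f"{spec_str!r} is not a Model-2 descriptor")
        if spec.prop not in props:
            props[spec.prop] = np.asarray(assign_properties(graph, spec.prop))
        if spec.order not in s_powers:
            s_powers[spec.order] = np.linalg.matrix_power(
                stochastic_matrix(graph), spec.order
            )
        x = props[spec.prop]
        members = sorted(groups.members(spec.group))
        if members:
            sx = s_powers[spec.order] @ x
            value = float(np.dot(x[members], sx[members]))
        else:
            value = 0.0
        if spec.normalized:
            value /= graph.n_bonds
        out[str(spec)] = value
    return out
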
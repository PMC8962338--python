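"""Model-1 descriptor tests, including the brute-force oracles: naive
closed-walk counting for spectral moments and exhaustive edge-subset
enumeration for the connectivity families."""

import itertools
import math

import numpy as np
import pytest

from ptml.chemgraph import parse_smiles
from ptml.topo_descriptors import (
    bond_adjacency,
    classify_subgraph,
    connectivity_index,
    connected_edge_subsets,
    edge_connectivity_index,
    enumerate_subgraphs,
    line_graph_adjacency,
    model1_block,
    normalize_descriptor,
    spectral_moment,
)

from .conftest import SMALL_MOLECULES


# ---------------------------------------------------------------------------
# independent oracles


def walk_trace_oracle(matrix: np.ndarray, k: int) -> float:
    """Trace of matrix^k by explicit walk enumeration (no linear algebra):
    sum over closed index sequences of entry products."""
    n = matrix.shape[0]
    if k == 0:
        return float(n)
    total = 0.0

    def walk(start: int, current: int, length: int, product: float) -> None:
        nonlocal total
        if length == k:
            total += product * matrix[current, start]
            return
        for nxt in range(n):
            if matrix[current, nxt] != 0:
                walk(start, nxt, length + 1, product * matrix[current, nxt])

    for start in range(n):
        walk(start, start, 1, 1.0)
    return total


def brute_force_edge_subsets(edges, o):
    """All connected o-edge subgraphs by filtering every combination."""
    out = []
    for combo in itertools.combinations(range(len(edges)), o):
        chosen = [edges[i] for i in combo]
        vertices = {v for e in chosen for v in e}
        # connectivity via union-find
        parent = {v: v for v in vertices}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        for a, b in chosen:
            parent[find(a)] = find(b)
        if len({find(v) for v in vertices}) == 1:
            out.append(tuple(sorted(chosen)))
    return out


def classify_oracle(edge_set):
    """Independent subgraph-type classification from first principles."""
    vertices = {v for e in edge_set for v in e}
    if len(edge_set) >= len(vertices):
        return "Ch"
    deg = {v: sum(v in e for e in edge_set) for v in vertices}
    if max(deg.values()) <= 2:
        return "P"
    if all(d != 2 for d in deg.values()):
        return "C"
    return "PC"


# ---------------------------------------------------------------------------
# bond adjacency and spectral moments


class TestBondAdjacency:
    def test_single_bond_unweighted(self):
        mat = bond_adjacency(parse_smiles("CC"))
        assert mat.shape == (1, 1)
        assert mat[0, 0] == 0

    def test_propane_offdiagonal(self):
        mat = bond_adjacency(parse_smiles("CCC"))
        assert np.array_equal(mat, [[0, 1], [1, 0]])

    def test_ethanol_atomic_weight_diagonal(self):
        # C-C bond: 12.011/1 + 12.011/2; C-O bond: 12.011/2 + 15.999/1
        mat = bond_adjacency(parse_smiles("CCO"), "Ato")
        assert sorted(np.diag(mat)) == pytest.approx([18.0165, 22.0045])

    def test_symmetry_and_dimension(self):
        for smi in SMALL_MOLECULES:
            g = parse_smiles(smi)
            mat = bond_adjacency(g, "Ato")
            assert mat.shape == (g.n_bonds, g.n_bonds)
            assert np.allclose(mat, mat.T)

    def test_unknown_property(self):
        with pytest.raises(ValueError):
            bond_adjacency(parse_smiles("CC"), "Zap")


class TestSpectralMoments:
    def test_order_zero_is_bond_count(self):
        for smi in ("CCC", "c1ccccc1", "CC(C)C"):
            g = parse_smiles(smi)
            assert spectral_moment(bond_adjacency(g), 0) == g.n_bonds

    def test_single_weighted_bond_first_moment(self):
        mat = np.array([[3.7]])
        assert spectral_moment(mat, 1) == pytest.approx(3.7)

    def test_propane_second_moment(self):
        assert spectral_moment(bond_adjacency(parse_smiles("CCC")), 2) == pytest.approx(2.0)

    @pytest.mark.parametrize("prop", ["none", "Ato", "Hyd"])
    def test_walk_counting_oracle(self, prop):
        """Spectral moments equal naive closed-walk sums for every test
        molecule with <= 8 bonds, k <= 6."""
        for smi in SMALL_MOLECULES:
            g = parse_smiles(smi)
            if g.n_bonds > 8:
                continue
            mat = bond_adjacency(g, prop if prop != "none" else "none")
            for k in range(7):
                assert spectral_moment(mat, k) == pytest.approx(
                    walk_trace_oracle(mat, k), abs=1e-9, rel=1e-9
                )


# ---------------------------------------------------------------------------
# subgraph enumeration and connectivity indices


class TestSubgraphEnumeration:
    @pytest.mark.parametrize(
        "smiles,s,o,count",
        [
            ("CCCC", "P", 2, 2),
            ("C1CCCCC1", "Ch", 6, 1),
            ("CC(C)(C)C", "C", 3, 4),  # neopentane: four K1,3 stars
            ("CC(C)C", "C", 3, 1),  # isobutane: the single star
            ("CCCC", "C", 3, 0),
        ],
    )
    def test_known_counts(self, smiles, s, o, count):
        assert len(enumerate_subgraphs(parse_smiles(smiles), s, o)) == count

    def test_exhaustive_oracle(self):
        """ESU enumeration and type classification agree with filtering
        every edge combination, for molecules <= 8 heavy atoms, o <= 6."""
        for smi in SMALL_MOLECULES:
            g = parse_smiles(smi)
            if g.n_atoms > 8:
                continue
            edges = [(a, b) for a, b, _ in g.bonds]
            for o in range(1, 7):
                brute = brute_force_edge_subsets(edges, o)
                mine = connected_edge_subsets(g.n_atoms, edges, o)
                assert sorted(mine) == sorted(brute)
                for s in ("P", "C", "PC", "Ch"):
                    expected = [e for e in brute if classify_oracle(e) == s]
                    assert sorted(enumerate_subgraphs(g, s, o)) == sorted(expected)

    def test_classification_partition(self):
        for smi in SMALL_MOLECULES:
            g = parse_smiles(smi)
            edges = [(a, b) for a, b, _ in g.bonds]
            for o in (2, 3, 4):
                all_subs = connected_edge_subsets(g.n_atoms, edges, o)
                by_type = sum(
                    len(enumerate_subgraphs(g, s, o)) for s in ("P", "C", "PC", "Ch")
                )
                assert by_type == len(all_subs)

    def test_order_cap(self):
        with pytest.raises(ValueError):
            enumerate_subgraphs(parse_smiles("CCCCCCCCCC"), "P", 9)


class TestConnectivityIndices:
    @pytest.mark.parametrize(
        "smiles,s,o,variant,expected",
        [
            ("CC", "P", 1, "simple", 1.0),
            ("CCCC", "P", 1, "simple", 2 / math.sqrt(2) + 0.5),
            ("C1CCCCC1", "Ch", 6, "simple", 2 ** -3),
            # ethanol valence: deltas CH3=1, CH2=2, OH=5
            ("CCO", "P", 1, "valence", 1 / math.sqrt(2) + 1 / math.sqrt(10)),
        ],
    )
    def test_known_values(self, smiles, s, o, variant, expected):
        value = connectivity_index(parse_smiles(smiles), s, o, variant)
        assert value == pytest.approx(expected, abs=1e-9)

    def test_oracle_via_brute_force_products(self):
        """Index values recomputed from the brute-force subgraph list and
        an independently coded degree product."""
        for smi in SMALL_MOLECULES:
            g = parse_smiles(smi)
            if g.n_atoms > 8:
                continue
            deg = g.degrees()
            edges = [(a, b) for a, b, _ in g.bonds]
            for o in (1, 2, 3):
                for s in ("P", "C", "PC", "Ch"):
                    subs = [
                        e
                        for e in brute_force_edge_subsets(edges, o)
                        if classify_oracle(e) == s
                    ]
                    expected = sum(
                        math.prod(
                            1 / math.sqrt(deg[v]) for v in {x for e in sub for x in e}
                        )
                        for sub in subs
                    )
                    assert connectivity_index(g, s, o) == pytest.approx(
                        expected, abs=1e-9
                    )

    @pytest.mark.parametrize(
        "smiles,s,o,expected",
        [
            ("CCC", "P", 1, 1.0),
            ("CCCC", "P", 1, 2 / math.sqrt(2)),
            ("c1ccccc1", "Ch", 6, 0.125),
        ],
    )
    def test_edge_connectivity_known_values(self, smiles, s, o, expected):
        assert edge_connectivity_index(parse_smiles(smiles), s, o) == pytest.approx(
            expected, abs=1e-9
        )

    def test_edge_connectivity_oracle(self):
        """Edge connectivity equals the simple-connectivity construction
        evaluated on an explicitly built line graph."""
        for smi in SMALL_MOLECULES:
            g = parse_smiles(smi)
            if g.n_bonds > 8:
                continue
            lg = line_graph_adjacency([(a, b) for a, b, _ in g.bonds])
            lg_edges = [(i, j) for i, nb in enumerate(lg) for j in nb if j > i]
            lg_deg = [len(nb) for nb in lg]
            for o in (1, 2):
                for s in ("P", "C", "PC", "Ch"):
                    subs = [
                        e
                        for e in brute_force_edge_subsets(lg_edges, o)
                        if classify_oracle(e) == s
                    ]
                    expected = sum(
                        math.prod(
                            1 / math.sqrt(lg_deg[v])
                            for v in {x for e in sub for x in e}
                        )
                        for sub in subs
                    )
                    assert edge_connectivity_index(g, s, o) == pytest.approx(
                        expected, abs=1e-9
                    )


class TestNormalizationAndBlock:
    def test_normalize(self):
        assert normalize_descriptor(10, 5) == 2
        assert normalize_descriptor(0, 3) == 0
        with pytest.raises(ValueError):
            normalize_descriptor(1.0, 0)

    def test_butane_normalized_connectivity(self):
        g = parse_smiles("CCCC")
        raw = connectivity_index(g, "P", 1)
        assert normalize_descriptor(raw, g.n_bonds) == pytest.approx(1.9142135 / 3, abs=1e-6)

    def test_model1_block_shape_and_finiteness(self):
        block = model1_block(parse_smiles("Nc1nc(N2CCOCC2)cc(-c2ccc(F)cc2)n1"))
        assert len(block) == 15
        assert all(np.isfinite(v) for v in block.values())

    def test_block_rejects_quadratic_specs(self):
        with pytest.raises(ValueError):
            model1_block(parse_smiles("CC"), ["ASq1(Hyd)G"])

    def test_relabeling_invariance(self):
        """Every Model-1 descriptor is identical for alternative SMILES
        writings of the same molecule."""
        pairs = [
            ("CCO", "OCC"),
            ("CC(C)C", "C(C)(C)C"),
            ("c1ccccc1C", "Cc1ccccc1"),
            ("NCCN", "C(N)CN"),
        ]
        for a, b in pairs:
            ba = model1_block(parse_smiles(a))
            bb = model1_block(parse_smiles(b))
            for key in ba:
                assert ba[key] == pytest.approx(bb[key], abs=1e-9)

    def test_pendant_atom_monotonicity(self):
        # adding a pendant atom adds a bond, so the order-1 path count
        # (the X(P)1 subgraph count) never decreases
        chains = ["CC", "CCC", "CCCC", "CCCCC"]
        counts = [
            len(enumerate_subgraphs(parse_smiles(s), "P", 1)) for s in chains
        ]
        assert counts == sorted(counts)
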
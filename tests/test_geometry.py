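"""Bonded-tree construction, angle/dihedral enumeration and center
classification."""

import networkx as nx
from hypothesis import given, settings
from hypothesis import strategies as st

from ffport.geometry import (
    LINEAR,
    PLANAR,
    TETRAHEDRAL,
    THREEFOLD,
    adjacency_from_bonds,
    build_tree,
    classify_center,
    enumerate_angles_dihedrals,
    enumerate_residue_terms,
    perceive_residue,
)
from ffport.model import AtomRecord, ResidueTopology


def brute_force_paths(bonds, length):
    """Independent oracle: all simple paths with `length` edges, deduplicated
    under reversal, via exhaustive graph search."""
    g = nx.Graph(bonds)
    found = set()
    for a in g.nodes:
        for b in g.nodes:
            if a == b:
                continue
            for path in nx.all_simple_paths(g, a, b, cutoff=length):
                if len(path) == length + 1:
                    t = tuple(path)
                    key = min(tuple(map(str, t)), tuple(map(str, t[::-1])))
                    found.add(key)
    return found


def _canon_set(terms):
    return {min(tuple(map(str, t)), tuple(map(str, t[::-1]))) for t in terms}


def test_linear_chain_tree_layers():
    adj = adjacency_from_bonds([("A", "B"), ("B", "C"), ("C", "D")])
    tree = build_tree(adj, "A", max_depth=3)
    assert [sorted(a for a, _p in layer) for layer in tree.layers] == [
        ["A"], ["B"], ["C"], ["D"]
    ]


def test_triangle_ring_avoidance():
    bonds = [("A", "B"), ("B", "C"), ("C", "A")]
    adj = adjacency_from_bonds(bonds)
    tree = build_tree(adj, "A", max_depth=3)
    # expansion stops before revisiting A: no path of 3 bonds exists
    assert all(len(p) <= 3 for p in tree.paths)
    angles, dihedrals = enumerate_angles_dihedrals(bonds)
    assert _canon_set(angles) == brute_force_paths(bonds, 2)
    assert dihedrals == []


def test_toy_residue_angles_and_dihedrals():
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O"), ("CA", "CB")]
    angles, dihedrals = enumerate_angles_dihedrals(bonds)
    assert _canon_set(angles) == {
        ("C", "CA", "N"), ("CB", "CA", "N"), ("C", "CA", "CB"), ("CA", "C", "O"),
    }
    assert _canon_set(dihedrals) == {("N", "CA", "C", "O"), ("CB", "CA", "C", "O")}


def test_single_bond_has_no_angles_or_dihedrals():
    angles, dihedrals = enumerate_angles_dihedrals([("A", "B")])
    assert angles == [] and dihedrals == []


def test_enumeration_order_is_deterministic():
    bonds = [("A", "B"), ("B", "C"), ("C", "D"), ("B", "E")]
    first = enumerate_angles_dihedrals(bonds)
    second = enumerate_angles_dihedrals(bonds)
    assert first == second


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_random_graphs_match_brute_force(data):
    """Set equality with the exhaustive simple-path oracle on random
    connected graphs (<=12 nodes, <=16 edges)."""
    n = data.draw(st.integers(2, 12))
    nodes = list(range(n))
    tree_edges = [
        (i, data.draw(st.integers(0, i - 1), label=f"p{i}")) for i in range(1, n)
    ]
    extra = data.draw(
        st.lists(
            st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(
                lambda e: e[0] != e[1]
            ),
            max_size=max(0, 16 - len(tree_edges)),
        )
    )
    bonds = list({frozenset(e) for e in tree_edges + extra})
    bonds = [tuple(sorted(b)) for b in bonds]
    angles, dihedrals = enumerate_angles_dihedrals(bonds)
    assert _canon_set(angles) == brute_force_paths(bonds, 2)
    assert _canon_set(dihedrals) == brute_force_paths(bonds, 3)
    # no reversed duplicates
    assert len(_canon_set(angles)) == len(angles)
    assert len(_canon_set(dihedrals)) == len(dihedrals)


# ---------------------------------------------------------------------------
# chain closure
# ---------------------------------------------------------------------------


def _chain_residue():
    res = ResidueTopology(name="R", total_charge=0.0)
    res.atoms = [
        AtomRecord("N", "N", 0.0, 0),
        AtomRecord("CA", "CT", 0.0, 0),
        AtomRecord("C", "C", 0.0, 0),
    ]
    res.bonds = [("-C", "N"), ("N", "CA"), ("CA", "C")]
    res.chainable = True
    return res


def test_homopolymer_junction_angle_present():
    res = _chain_residue()
    angles, _d = enumerate_residue_terms(res, res)
    assert ("-C", "N", "CA") in {tuple(a) for a in angles} | {
        tuple(reversed(a)) for a in angles
    }


def test_junction_terms_one_sided_canonical():
    """Crossing terms are expressed once, from the minus side, regardless of
    which copy they were walked from."""
    res = _chain_residue()
    angles, dihedrals = enumerate_residue_terms(res, res)
    all_terms = [*angles, *dihedrals]
    assert all_terms
    for term in all_terms:
        plus = sum(1 for n in term if n.startswith("+"))
        minus = sum(1 for n in term if n.startswith("-"))
        unpref = len(term) - plus - minus
        assert unpref >= max(plus, minus)
    # every physical junction term appears exactly once
    assert len(set(all_terms)) == len(all_terms)


def test_dihedral_across_junction():
    res = _chain_residue()
    _a, dihedrals = enumerate_residue_terms(res, res)
    canon = {min(t, tuple(reversed(t))) for t in dihedrals}
    assert ("-C", "N", "CA", "C") in canon or ("C", "CA", "N", "-C") in canon


# ---------------------------------------------------------------------------
# classification cascade
# ---------------------------------------------------------------------------


def test_classification_on_fixture(conversion):
    geoms = conversion.geometries
    # amide nitrogen: improper with psi0 = 0 -> planar (criterion 1)
    assert geoms["ALX"].classification["N"] == PLANAR
    # sp3 carbon with three n=3 torsions -> threefold/tetrahedral family
    assert geoms["ALX"].classification["CB"] in (THREEFOLD, TETRAHEDRAL)
    # alkyne carbons are linear, but bear no hydrogens in this fixture;
    # the methyl carbon next to the triple bond is threefold
    assert geoms["BTY"].classification["C1"] in (THREEFOLD, TETRAHEDRAL)
    # planar nitrogen without improper falls through to the mean-angle rule
    assert geoms["IMX"].classification["N1"] == PLANAR


def test_linear_center_detected(conversion):
    """An explicit classification call on the alkyne carbon reports linear."""
    geom = conversion.geometries["BTY"]
    assert classify_center("C2", geom) == LINEAR
    assert classify_center("C3", geom) == LINEAR


def test_equilibrium_assignment_and_wildcards(conversion):
    geom = conversion.geometries["ETX"]
    # every angle of the fully parameterized residue got a theta0
    assert all(v is not None for v in geom.angles.values())
    # the hydroxyl torsion only exists as a wildcard entry
    assert geom.wildcard_dihedrals
    assert not geom.missing_dihedrals


def test_missing_dihedral_recorded_not_fatal(conversion):
    geom = conversion.geometries["BTY"]
    assert geom.missing_dihedrals  # the across-the-triple-bond torsion
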
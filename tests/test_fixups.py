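"""Collinear-dihedral dummies and improper-permutation replication."""

import pytest

from ffport.energy import build_configuration, build_coordinates, energy_charmm_form
from ffport.fixups import (
    MissingTermReport,
    check_completeness,
    find_missing_dihedrals,
    resolve_improper_permutations,
)
from ffport.geometry import perceive_residue
from ffport.model import FFError
import numpy as np


def test_collinear_fixture_yields_exactly_one_dummy(conversion):
    dummies = conversion.fixreport.dummy_dihedraltypes
    assert len(dummies) == 1
    d = dummies[0]
    assert d.kchi == 0.0 and d.n == 1 and d.delta == 0.0
    assert set(d.types) == {"CT", "CY"}  # across the triple bond


def test_dummy_is_energy_neutral(conversion):
    """Adding the dummy type changes the total energy by exactly zero: the
    term is omitted from the sum rather than evaluated at k=0 on an undefined
    torsion angle."""
    src = conversion.source
    res = src.residues["BTY"]
    rng = np.random.default_rng(11)
    cfg = build_configuration([res], [build_coordinates(res, src.params, rng)])
    dummies = {d.types for d in conversion.fixreport.dummy_dihedraltypes}
    with_dummy = energy_charmm_form(cfg, src.params, dummy_dihedrals=dummies)
    # strip the collinear torsion manually: the reference has no such term
    collinear = [
        q
        for q in cfg.dihedrals
        if {cfg.types[i] for i in q} <= {"CT", "CY"}
        and [cfg.types[i] for i in q[1:3]] == ["CY", "CY"]
    ]
    cfg_stripped = cfg
    cfg_stripped.dihedrals = [q for q in cfg.dihedrals if q not in collinear]
    without = energy_charmm_form(cfg_stripped, src.params, dummy_dihedrals=dummies)
    assert with_dummy["proper"] - without["proper"] == 0.0


def test_fully_parameterized_residue_yields_no_dummies(conversion):
    src = conversion.source
    geoms = {"ETX": conversion.geometries["ETX"]}
    out = find_missing_dihedrals(
        {"ETX": src.residues["ETX"]}, geoms, src.params
    )
    assert out == []


def test_noncollinear_missing_dihedral_is_hard_error(conversion):
    """A dihedral across an ordinary (109.5-degree) angle with no parameter
    must not be papered over with a dummy."""
    src = conversion.source
    res = src.residues["ETX"].copy()
    geom = perceive_residue(res, src)
    # forge: pretend a tetrahedral torsion lost its parameter
    victim = next(iter(geom.dihedrals))
    geom.missing_dihedrals.append(victim)
    with pytest.raises(FFError, match="missing dihedral"):
        find_missing_dihedrals({res.name: res}, {res.name: geom}, src.params)


def test_permuted_improper_replicated_once(conversion):
    perms = conversion.fixreport.permuted_impropertypes
    assert len(perms) == 1
    p = perms[0]
    assert p.residue == "IMX"
    src_param = conversion.source.params.impropers[p.matched_key]
    assert (p.param.kpsi, p.param.psi0) == (src_param.kpsi, src_param.psi0)
    assert p.declared_types != p.matched_key


def test_equivalent_permutations_deduplicated(conversion):
    """IMX's two same-type neighbors make two permutations hit the same
    parameter key; only one replicated entry results."""
    (p,) = conversion.fixreport.permuted_impropertypes
    assert len(p.all_matches) == len(set(p.all_matches)) == 1


def test_matching_improper_needs_no_action(conversion):
    src = conversion.source
    out = resolve_improper_permutations(
        {"ALX": src.residues["ALX"]},
        {"ALX": conversion.geometries["ALX"]},
        src.params,
    )
    assert out == []


def test_unmatchable_improper_is_hard_error(conversion):
    src = conversion.source
    res = src.residues["IMX"].copy()
    res.impropers = [("N1", "C1", "C2", "H1")]
    geom = perceive_residue(res, src)
    # remove the permuted entry the fixture relies on
    import copy

    params = copy.deepcopy(src.params)
    params.impropers = {
        k: v for k, v in params.impropers.items() if "NG" not in k
    }
    geom2 = perceive_residue(res, src)
    with pytest.raises(FFError, match="no parameter under any permutation"):
        resolve_improper_permutations({res.name: res}, {res.name: geom2}, params)


def test_completeness_after_fixups(conversion):
    problems = check_completeness(
        conversion.source.retained_residues(),
        conversion.geometries,
        conversion.source.params,
        conversion.fixreport,
    )
    assert problems == []


def test_completeness_fails_without_fixups(conversion):
    empty = MissingTermReport()
    problems = check_completeness(
        conversion.source.retained_residues(),
        conversion.geometries,
        conversion.source.params,
        empty,
    )
    assert any("BTY" in p for p in problems)
    assert any("IMX" in p for p in problems)
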
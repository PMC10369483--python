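"""Dual-form single-point energies and the equivalence theorem."""

import numpy as np
import pytest

from ffport.energy import (
    Configuration,
    build_configuration,
    build_coordinates,
    compare,
    energy_charmm_form,
    energy_gmx_form,
)
from ffport.model import (
    AtomRecord,
    BondParam,
    LJParam,
    MassEntry,
    ParameterTables,
    ResidueTopology,
)
from ffport.param_convert import convert_parameters
from ffport.validation import validate_equivalence


def _two_atom_setup(k=100.0, b0=1.5, displacement=0.1):
    params = ParameterTables()
    params.masses = {"A": MassEntry(12.0, "C")}
    params.lj = {"A": LJParam(0.0, 1.0)}
    params.bonds[("A", "A")] = BondParam(k, b0)
    res = ResidueTopology(name="DI", total_charge=0.0)
    res.atoms = [AtomRecord("X1", "A", 0.0, 0), AtomRecord("X2", "A", 0.0, 0)]
    res.bonds = [("X1", "X2")]
    crd = np.array([[0.0, 0.0, 0.0], [b0 + displacement, 0.0, 0.0]])
    return params, build_configuration([res], [crd])


def test_bond_at_equilibrium_is_zero():
    params, cfg = _two_atom_setup(displacement=0.0)
    assert energy_charmm_form(cfg, params)["bond"] == 0.0


def test_bond_hand_value_and_half_k_convention():
    """K=100 kcal/(mol A^2), 0.1 A stretch: 1.0 kcal/mol on the source side,
    4.184 kJ/mol from the converted half-k form."""
    params, cfg = _two_atom_setup()
    e_src = energy_charmm_form(cfg, params)["bond"]
    assert e_src == pytest.approx(1.0, rel=1e-12)
    gmx = convert_parameters(params)
    e_conv = energy_gmx_form(cfg, gmx)["bond"]
    assert e_conv == pytest.approx(4.184, rel=1e-12)


def test_lj_minimum_depth_identity_both_forms():
    params = ParameterTables()
    params.masses = {"A": MassEntry(12.0, "C")}
    params.lj = {"A": LJParam(-0.2, 1.8)}
    res = ResidueTopology(name="PAIR", total_charge=0.0)
    res.atoms = [AtomRecord("X1", "A", 0.0, 0), AtomRecord("X2", "A", 0.0, 0)]
    rmin = 2 * 1.8
    crd = np.array([[0.0, 0.0, 0.0], [rmin, 0.0, 0.0]])
    cfg = build_configuration([res], [crd])
    e_src = energy_charmm_form(cfg, params)
    assert e_src["lj"] == pytest.approx(-0.2, rel=1e-12)
    gmx = convert_parameters(params)
    e_conv = energy_gmx_form(cfg, gmx)
    assert e_conv["lj"] == pytest.approx(-0.2 * 4.184, rel=1e-12)


def test_empty_configuration_all_terms_zero():
    params = ParameterTables()
    cfg = build_configuration([], [])
    for form, table in (
        (energy_charmm_form, params),
        (energy_gmx_form, convert_parameters(params)),
    ):
        assert all(v == 0.0 for v in form(cfg, table).values())


def test_nonbonded_only_configuration_has_zero_bonded_terms(conversion):
    src = conversion.source
    res = src.residues["SOD"]
    crd1 = np.zeros((1, 3))
    crd2 = np.array([[3.5, 0.0, 0.0]])
    cfg = build_configuration([res, res], [crd1, crd2])
    e = energy_charmm_form(cfg, src.params)
    for term in ("bond", "angle", "urey_bradley", "proper", "improper", "cmap"):
        assert e[term] == 0.0
    assert e["coulomb"] != 0.0


def test_exclusion_bookkeeping():
    """1-2 and 1-3 are excluded; 1-4 is a pair; 1-5 is plain nonbonded."""
    params = ParameterTables()
    params.masses = {"A": MassEntry(12.0, "C")}
    params.lj = {"A": LJParam(-0.1, 2.0)}
    for i in range(4):
        params.bonds[("A", "A")] = BondParam(0.0, 1.5)
    res = ResidueTopology(name="CHAIN", total_charge=0.0)
    res.atoms = [AtomRecord(f"X{i}", "A", 0.0, 0) for i in range(5)]
    res.bonds = [(f"X{i}", f"X{i+1}") for i in range(4)]
    crd = np.array([[i * 1.5, 0.1 * i * i, 0.0] for i in range(5)])
    cfg = build_configuration([res], [crd])
    assert frozenset((0, 1)) in cfg.exclusions
    assert frozenset((0, 2)) in cfg.exclusions
    assert (0, 3) in cfg.pairs14
    assert frozenset((0, 4)) not in cfg.exclusions
    assert (0, 4) not in cfg.pairs14


def test_equivalence_on_full_fixture(conversion):
    outcome = validate_equivalence(
        conversion.source, conversion.gmx, conversion.fixreport, seed=5
    )
    assert len(outcome.reports) >= 20
    assert outcome.passed
    terms_seen = set()
    for rep in outcome.reports:
        terms_seen.update(k for k, v in rep.e_charmm.items() if v != 0.0)
    # the battery covers every interaction-term class
    assert terms_seen >= {
        "bond", "angle", "urey_bradley", "proper", "improper",
        "lj", "lj14", "coulomb", "cmap",
    }


def test_corrupted_force_constant_flags_exactly_that_term(conversion):
    import copy

    src = conversion.source
    gmx = copy.deepcopy(conversion.gmx)
    key = next(iter(gmx.bondtypes))
    b0, kb = gmx.bondtypes[key]
    gmx.bondtypes[key] = (b0, kb * 1.01)
    res = src.residues["ALX"]
    rng = np.random.default_rng(3)
    cfg = build_configuration([res], [build_coordinates(res, src.params, rng)])
    dummies = {d.types for d in conversion.fixreport.dummy_dihedraltypes}
    report = compare(cfg, src.params, gmx, dummy_dihedrals=dummies)
    assert report.failing_terms() == ["bond"]


def test_numerical_gradient_consistency(conversion):
    """Central-difference gradient of the converted-form energy matches a
    finite-difference estimate of itself under coordinate perturbation --
    i.e. the evaluator is a smooth, consistent function of the geometry."""
    src = conversion.source
    res = src.residues["ETX"]
    rng = np.random.default_rng(12)
    crd = build_coordinates(res, src.params, rng)
    cfg = build_configuration([res], [crd])

    def total(c):
        cfg.coords_a = c
        return sum(energy_charmm_form(cfg, src.params).values())

    h = 1e-5
    base = crd.copy()
    g = np.zeros(3)
    for k in range(3):
        dp = base.copy()
        dp[0, k] += h
        dm = base.copy()
        dm[0, k] -= h
        g[k] = (total(dp) - total(dm)) / (2 * h)
    gh = np.zeros(3)
    h2 = 5e-6
    for k in range(3):
        dp = base.copy()
        dp[0, k] += h2
        dm = base.copy()
        dm[0, k] -= h2
        gh[k] = (total(dp) - total(dm)) / (2 * h2)
    assert np.allclose(g, gh, rtol=1e-4, atol=1e-6)


def test_fixture_generation_deterministic():
    from ffport.fixtures import generate_fixture_ff

    a = generate_fixture_ff(seed=4, size=10)
    b = generate_fixture_ff(seed=4, size=10)
    assert a.files == b.files
    c = generate_fixture_ff(seed=5, size=10)
    assert c.files != a.files


def test_fixture_size_bounds():
    from ffport.fixtures import generate_fixture_ff

    with pytest.raises(ValueError):
        generate_fixture_ff(seed=1, size=1)
    small = generate_fixture_ff(seed=1, size=2)
    assert len(small.residue_names) == 2
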
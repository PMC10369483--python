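"""Patch application, cross-link splitting and termini-entry generation."""

import pytest

from ffport.model import AtomRecord, FFError, PatchTopology, ResidueTopology
from ffport.patching import (
    Add,
    Delete,
    ImproperAdd,
    Replace,
    apply_patch,
    apply_terminus_entry,
    build_terminus_entry,
    split_crosslink_patch,
)


def _base():
    res = ResidueTopology(name="BASE", total_charge=0.0)
    res.atoms = [
        AtomRecord("N", "N", -0.4, 0),
        AtomRecord("CA", "CT", 0.1, 0),
        AtomRecord("C", "C", 0.5, 1),
        AtomRecord("O", "O", -0.2, 1),
    ]
    res.bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    res.impropers = [("C", "CA", "O", "N")]
    return res


def test_carboxylate_style_patch():
    patch = PatchTopology(name="CT2", total_charge=-1.0)
    patch.deleted_atoms = ["O"]
    patch.atoms = [
        AtomRecord("OT1", "OC", -0.67, 0),
        AtomRecord("OT2", "OC", -0.67, 0),
    ]
    patch.bonds = [("C", "OT1"), ("C", "OT2")]
    out = apply_patch(_base(), patch, "PTCH")
    assert out.atom_names == ["N", "CA", "C", "OT1", "OT2"]
    assert not any("O" in b for b in out.bonds if "OT" not in b[0] + b[1])
    assert ("C", "OT1") in out.bonds and ("C", "OT2") in out.bonds
    # deletions cascade to impropers touching the atom
    assert out.impropers == []


def test_empty_patch_is_identity_up_to_name():
    patch = PatchTopology(name="NOP", total_charge=0.0)
    out = apply_patch(_base(), patch, "SAME")
    base = _base()
    assert out.name == "SAME"
    assert out.atoms == base.atoms
    assert out.bonds == base.bonds
    assert out.impropers == base.impropers


def test_charge_only_replacement_keeps_order():
    patch = PatchTopology(name="Q", total_charge=0.1)
    patch.atoms = [AtomRecord("CA", "CT", 0.2, 0)]
    out = apply_patch(_base(), patch, "X")
    assert out.atom_names == _base().atom_names
    diffs = [
        (a.name, a.charge, b.charge)
        for a, b in zip(out.atoms, _base().atoms)
        if a.charge != b.charge
    ]
    assert diffs == [("CA", 0.2, 0.1)]


def test_pure_replacement_patch_is_idempotent():
    patch = PatchTopology(name="Q", total_charge=0.0)
    patch.atoms = [AtomRecord("CA", "CT2", 0.33, 0)]
    once = apply_patch(_base(), patch, "X")
    twice = apply_patch(once, patch, "X")
    assert once.atoms == twice.atoms
    assert once.bonds == twice.bonds


def test_charge_bookkeeping():
    patch = PatchTopology(name="Q", total_charge=0.0)
    patch.deleted_atoms = ["O"]
    patch.atoms = [AtomRecord("OX", "OC", -0.5, 0)]
    patch.bonds = [("C", "OX")]
    base = _base()
    out = apply_patch(base, patch, "X")
    net_edit = -(-0.2) + (-0.5)  # remove O, add OX
    assert out.total_charge == pytest.approx(base.charge_sum() + net_edit, abs=1e-6)


def test_deleting_nonexistent_atom_is_hard_error():
    patch = PatchTopology(name="BAD", total_charge=0.0)
    patch.deleted_atoms = ["NOPE"]
    with pytest.raises(FFError, match="NOPE"):
        apply_patch(_base(), patch, "X")


def test_dangling_bond_is_hard_error():
    patch = PatchTopology(name="BAD", total_charge=0.0)
    patch.bonds = [("C", "GHOST")]
    with pytest.raises(FFError, match="GHOST"):
        apply_patch(_base(), patch, "X")


# ---------------------------------------------------------------------------
# cross-link splitting
# ---------------------------------------------------------------------------


def _disulfide_patch():
    p = PatchTopology(name="DIS", total_charge=0.0, two_residue=True)
    p.atoms = [
        AtomRecord("1SG", "SM", -0.08, 0),
        AtomRecord("2SG", "SM", -0.08, 0),
    ]
    p.deleted_atoms = ["1HG", "2HG"]
    p.bonds = [("1SG", "2SG")]
    return p


def test_split_keeps_only_matching_side():
    half = split_crosslink_patch(_disulfide_patch(), side=1)
    assert [a.name for a in half.atoms] == ["SG"]
    assert half.deleted_atoms == ["HG"]
    assert not half.two_residue


def test_split_empty_side():
    p = PatchTopology(name="ONE", total_charge=0.0, two_residue=True)
    p.atoms = [AtomRecord("1SG", "SM", 0.0, 0)]
    half = split_crosslink_patch(p, side=2)
    assert half.atoms == [] and half.deleted_atoms == []


def test_linking_bond_dropped_from_both_halves():
    for side in (1, 2):
        half = split_crosslink_patch(_disulfide_patch(), side)
        assert half.bonds == []  # special-bond table handles the link


# ---------------------------------------------------------------------------
# termini entries (on the full fixture)
# ---------------------------------------------------------------------------


def _entries(conversion, side):
    return conversion.termini["prot"][side]


def test_rename_becomes_delete_plus_add(conversion):
    (entry,) = _entries(conversion, "N")
    deletes = {d.atom for d in entry.directives if isinstance(d, Delete)}
    adds = [d for d in entry.directives if isinstance(d, Add)]
    assert "HN" in deletes
    assert any(a.name_stem == "HT" and a.count == 3 for a in adds)


def test_type_charge_change_becomes_replace(conversion):
    (entry,) = _entries(conversion, "N")
    replaces = {d.atom: d for d in entry.directives if isinstance(d, Replace)}
    assert replaces["N"].new_type == "NH3T"
    assert replaces["N"].new_charge == pytest.approx(-0.30)


def test_extra_terminal_deletes_appended_everywhere(conversion):
    for side in ("N", "C"):
        for entry in _entries(conversion, side):
            deletes = {d.atom for d in entry.directives if isinstance(d, Delete)}
            assert "OXT" in deletes


def test_directive_order_and_no_double_coverage(conversion):
    order = {Delete: 0, Replace: 1, Add: 2, ImproperAdd: 3}
    for side in ("N", "C"):
        for entry in _entries(conversion, side):
            ranks = [order[type(d)] for d in entry.directives]
            assert ranks == sorted(ranks)
            seen = []
            for d in entry.directives:
                if isinstance(d, (Delete, Replace)):
                    seen.append(d.atom)
                elif isinstance(d, Add):
                    seen.extend(
                        [d.name_stem]
                        if d.count == 1
                        else [f"{d.name_stem}{i}" for i in range(1, d.count + 1)]
                    )
            assert len(seen) == len(set(seen))


def test_terminus_roundtrip_reproduces_patched_residue(conversion):
    """Applying the generated directives to each base reproduces the
    CHARMM-patched residue's atoms, types and charges exactly."""
    src = conversion.source
    for pname, side in (("NTE", "N"), ("CTE", "C")):
        (entry,) = _entries(conversion, side)
        patch = src.patches[pname]
        for base_name in ("ALX", "CYX"):
            base = src.residues[base_name]
            patched = apply_patch(base, patch, "ref")
            redone = apply_terminus_entry(entry, base, src.params)
            ref = {(a.name, a.type, round(a.charge, 9)) for a in patched.atoms}
            got = {(a.name, a.type, round(a.charge, 9)) for a in redone.atoms}
            assert got == ref


def test_directives_cover_symmetric_difference(conversion):
    """Delete/replace/add sets are mutually exclusive and exhaustive over
    the differences between base and patched atom sets."""
    src = conversion.source
    for pname, side in (("NTE", "N"), ("CTE", "C")):
        (entry,) = _entries(conversion, side)
        patch = src.patches[pname]
        base = src.residues["ALX"]
        patched = apply_patch(base, patch, "ref")
        base_names = set(base.atom_names)
        patched_names = set(patched.atom_names)
        deletes = {d.atom for d in entry.directives if isinstance(d, Delete)}
        adds = set()
        for d in entry.directives:
            if isinstance(d, Add):
                adds.update(
                    [d.name_stem]
                    if d.count == 1
                    else {f"{d.name_stem}{i}" for i in range(1, d.count + 1)}
                )
        assert base_names - patched_names <= deletes
        assert patched_names - base_names == adds


def test_uniform_patch_gives_single_entry(conversion):
    # NTE/CTE edit ALX and CYX identically -> one entry each, no variants
    assert len(_entries(conversion, "N")) == 1
    assert len(_entries(conversion, "C")) == 1
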
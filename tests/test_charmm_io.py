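"""Parsing of CHARMM-format topology/parameter/stream files."""

import numpy as np
import pytest

from ffport.charmm_io import (
    merge_sources,
    parse_charmm_text,
    parse_config,
    to_charmm_text,
)
from ffport.model import ConversionConfig, FFError

TOY_RTF = """\
* toy topology
*
36 1
MASS -1 NH1 14.007 N
MASS -1 H 1.008 H
MASS -1 CT1 12.011 C
MASS -1 CC 12.011 C
MASS -1 OO 15.999 O

RESI ALAX 0.00
GROUP
ATOM N NH1 -0.47
ATOM HN H 0.31
ATOM CA CT1 0.16
GROUP
ATOM C CC 0.51
ATOM O OO -0.51
BOND N HN  N CA  CA C
DOUBLE C O
IMPR N CA C HN
DONOR HN N
ACCEPTOR O C
IC -C CA *N HN 1.3551 126.49 180.0 115.42 0.9996
END
"""


def test_parse_residue_echo():
    src = parse_charmm_text(TOY_RTF, "toy.rtf", "rtf")
    assert list(src.residues) == ["ALAX"]
    res = src.residues["ALAX"]
    assert res.total_charge == 0.0
    assert [a.name for a in res.atoms] == ["N", "HN", "CA", "C", "O"]
    assert res.atoms[0].charge == -0.47
    assert res.atoms[0].group_index == 0
    assert res.atoms[3].group_index == 1
    assert abs(res.charge_sum()) < 1e-12


def test_double_bond_folded_to_plain_bond():
    src = parse_charmm_text(TOY_RTF, "toy.rtf", "rtf")
    res = src.residues["ALAX"]
    assert ("C", "O") in res.bonds
    # bond order annotation recorded as discarded, not kept as a distinction
    assert any("bond order" in d for d in src.discarded)


def test_donor_acceptor_ic_discarded_but_noted():
    src = parse_charmm_text(TOY_RTF, "toy.rtf", "rtf")
    kinds = " ".join(src.discarded)
    for tag in ("DONOR", "ACCEPTOR", "IC"):
        assert tag in kinds


def test_continuation_and_comment_handling():
    text = "* t\n*\nMASS -1 CT1 12.011 C\nRESI R 0.0\nGROUP\nATOM C1 CT1 -0.1 ! a comment\nATOM C2 CT1 0.1\nBOND C1 -\nC2\nEND\n"
    src = parse_charmm_text(text, "x.rtf", "rtf")
    assert src.residues["R"].bonds == [("C1", "C2")]


def test_keyword_abbreviations_accepted():
    text = (
        "* t\n*\nMASS -1 CT1 12.011 C\n"
        "PRES P 0.0\nGROU\nATOM C1 CT1 0.0\nDELE ATOM C9\nEND\n"
    )
    src = parse_charmm_text(text, "x.rtf", "rtf")
    assert src.patches["P"].deleted_atoms == ["C9"]


def test_malformed_record_is_hard_error_with_location():
    text = "* t\n*\nRESI R 0.0\nATOM ONLYTWO\nEND\n"
    with pytest.raises(FFError, match="x.rtf:4"):
        parse_charmm_text(text, "x.rtf", "rtf")


def test_str_mixes_topology_and_parameters(fixture_ff):
    fx, _cfg = fixture_ff
    src = parse_charmm_text(fx.files["toy_extra.str"], "toy_extra.str", "str")
    assert "ETX" in src.residues
    assert len(src.params.nbfix) == 1


def test_fixture_rtf_reparse_matches_serialization(fixture_ff):
    """Round trip: model -> CHARMM-like text -> model is field-identical."""
    fx, _cfg = fixture_ff
    src = parse_charmm_text(fx.files["toy_prot.rtf"], "p.rtf", "rtf")
    prm = parse_charmm_text(fx.files["toy_par.prm"], "p.prm", "prm")
    src.params = prm.params
    text = to_charmm_text(src)
    again = parse_charmm_text(text["rtf"], "p2.rtf", "rtf")
    again_prm = parse_charmm_text(text["prm"], "p2.prm", "prm")
    assert list(again.residues) == list(src.residues)
    for name, res in src.residues.items():
        other = again.residues[name]
        assert other.atoms == res.atoms
        assert other.bonds == res.bonds
        assert other.impropers == res.impropers
        assert other.cmaps == res.cmaps
        assert other.has_lone_pairs == res.has_lone_pairs
    for name, patch in src.patches.items():
        other = again.patches[name]
        assert other.atoms == patch.atoms
        assert other.deleted_atoms == patch.deleted_atoms
        assert other.two_residue == patch.two_residue
    p, q = src.params, again_prm.params
    assert p.bonds == q.bonds
    assert p.angles == q.angles
    assert p.dihedrals == q.dihedrals
    assert p.impropers == q.impropers
    assert p.lj == q.lj
    assert p.nbfix == q.nbfix
    assert p.masses == q.masses
    assert p.cmaps == q.cmaps


def test_cmap_grid_parsed_square(fixture_ff):
    fx, _cfg = fixture_ff
    prm = parse_charmm_text(fx.files["toy_par.prm"], "p.prm", "prm")
    for grid in prm.params.cmaps.values():
        assert grid.grid.shape == (grid.resolution, grid.resolution)
        assert 360 % grid.resolution == 0


# ---------------------------------------------------------------------------
# conversion-control file
# ---------------------------------------------------------------------------


def test_parse_config_full(fixture_ff, tmp_path):
    _fx, config_path = fixture_ff
    cfg = parse_config(config_path)
    assert len(cfg.input_files) == 3
    assert [d for _p, d, _c in cfg.input_files] == ["rtf", "prm", "str"]
    assert ("ETX", "OME", "ETXM") in cfg.patched_residues
    assert ("NTE", "N") in cfg.termini_patches
    assert ("SOD", "NA") in cfg.copyresidues
    assert cfg.extra_terminal_deletes == ["OXT"]
    assert cfg.citation_db and cfg.citation_db.endswith("toy_refs.bib")


def test_unknown_config_keyword_is_hard_error(tmp_path):
    p = tmp_path / "bad.in"
    p.write_text("name x\nfrobnicate yes\n")
    with pytest.raises(FFError, match="frobnicate"):
        parse_config(str(p))


def test_missing_input_file_is_hard_error(tmp_path):
    p = tmp_path / "bad.in"
    p.write_text("input rtf prot nosuch.rtf\n")
    with pytest.raises(FFError, match="not found"):
        parse_config(str(p))


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

_DUP = """\
* t
*
MASS -1 CT1 12.011 C
RESI ETOH {charge}
GROUP
ATOM C1 CT1 {q}
END
"""


def _mini_sources():
    a = parse_charmm_text(_DUP.format(charge="0.0", q="0.0"), "a.rtf", "rtf")
    b = parse_charmm_text(_DUP.format(charge="0.0", q="0.0"), "b.rtf", "rtf")
    b.residues["ETOH"].atoms[0].charge = 0.0
    b.residues["ETOH"].atoms[0].type = "CT1"
    return a, b


def test_duplicate_residue_without_ruling_fails():
    a, b = _mini_sources()
    cfg = ConversionConfig()
    with pytest.raises(FFError, match="ETOH"):
        merge_sources([a, b], cfg)


def test_duplicate_residue_resolved_by_config():
    a, b = _mini_sources()
    b.residues["ETOH"].total_charge = 0.0
    b.residues["ETOH"].atoms[0].name = "C1"
    # give the two versions distinguishable content
    a.residues["ETOH"].atoms[0].charge = 0.0
    lj_stub(a)
    lj_stub(b)
    cfg = ConversionConfig(residue_conflicts={"ETOH": "b.rtf"})
    merged = merge_sources([a, b], cfg)
    assert merged.residues["ETOH"].source.startswith("b.rtf")
    assert any("duplicate" in w for w in merged.warnings)


def lj_stub(src):
    from ffport.model import LJParam

    src.params.lj["CT1"] = LJParam(-0.1, 2.0)


def test_empty_conflict_set_is_concatenation():
    a = parse_charmm_text(_DUP.format(charge="0.0", q="0.0"), "a.rtf", "rtf")
    b = parse_charmm_text(
        _DUP.format(charge="0.0", q="0.0").replace("ETOH", "MEOH"), "b.rtf", "rtf"
    )
    lj_stub(a)
    lj_stub(b)
    merged = merge_sources([a, b], ConversionConfig())
    assert list(merged.residues) == ["ETOH", "MEOH"]


def test_lone_pair_residue_excluded_with_warning(merged):
    assert "LPX" in merged.residues
    assert merged.residues["LPX"].has_lone_pairs
    assert "LPX" not in merged.retained_residues()
    assert any("LPX" in w and "lone pair" in w for w in merged.warnings)


def test_missing_mass_or_lj_fails_loudly():
    text = "* t\n*\nMASS -1 CT1 12.011 C\nRESI R 0.0\nGROUP\nATOM C1 ZZ 0.0\nEND\n"
    src = parse_charmm_text(text, "x.rtf", "rtf")
    with pytest.raises(FFError, match="ZZ"):
        merge_sources([src], ConversionConfig())


def test_charge_group_integrality_reported_not_fixed():
    text = (
        "* t\n*\nMASS -1 CT1 12.011 C\n"
        "RESI R 0.30\nGROUP\nATOM C1 CT1 0.30\nEND\n"
    )
    src = parse_charmm_text(text, "x.rtf", "rtf")
    lj_stub(src)
    merged = merge_sources([src], ConversionConfig())
    assert any("not integral" in w for w in merged.warnings)
    assert merged.residues["R"].atoms[0].charge == 0.30  # untouched
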
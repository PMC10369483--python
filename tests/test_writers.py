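"""GROMACS directory writing: determinism, round trip, integrity."""

import os

import pytest

from ffport.model import FFError
from ffport.pipeline import run_conversion_from_file
from ffport.writers import (
    WATER_MODELS,
    read_gmx_parameters,
    validate_port,
    write_water_models,
)


def test_two_runs_byte_identical(fixture_ff, tmp_path):
    _fx, config_path = fixture_ff
    d1, d2 = tmp_path / "a", tmp_path / "b"
    r1 = run_conversion_from_file(config_path, outdir=str(d1))
    r2 = run_conversion_from_file(config_path, outdir=str(d2))
    assert sorted(r1.layout.files) == sorted(r2.layout.files)
    for name in r1.layout.files:
        with open(r1.layout.path(name), "rb") as fa, open(
            r2.layout.path(name), "rb"
        ) as fb:
            assert fa.read() == fb.read(), name


def test_parameter_write_read_roundtrip_exact(conversion):
    again = read_gmx_parameters(conversion.layout.directory)
    gmx = conversion.gmx
    assert again.bondtypes == gmx.bondtypes
    assert again.angletypes == gmx.angletypes
    assert again.impropertypes == gmx.impropertypes
    assert again.atomtypes == gmx.atomtypes
    assert again.pairtypes == gmx.pairtypes
    assert again.nonbond_params == gmx.nonbond_params
    assert again.cmaptypes == gmx.cmaptypes
    for key, terms in gmx.dihedraltypes.items():
        assert again.dihedraltypes[key] == terms


def test_layout_contains_expected_files(conversion):
    files = set(conversion.layout.files)
    for required in (
        "forcefield.itp", "forcefield.doc", "atomtypes.atp",
        "ffnonbonded.itp", "ffbonded.itp", "nbfix.itp",
        "ffmissingdihedrals.itp", "prot.rtp", "cgenff.rtp",
        "prot.n.tdb", "prot.c.tdb", "prot.hdb", "residuetypes.dat",
    ):
        assert required in files


def test_include_targets_exist(conversion):
    layout = conversion.layout
    for name in ("forcefield.itp", "ffnonbonded.itp"):
        with open(layout.path(name)) as fh:
            for line in fh:
                if line.strip().startswith("#include"):
                    target = line.split('"')[1]
                    assert os.path.exists(layout.path(target)), target


def test_copyresidues_duplicated_under_both_names(conversion):
    with open(conversion.layout.path("cgenff.rtp")) as fh:
        text = fh.read()
    assert "[ SOD ]" in text and "[ NA ]" in text
    body = lambda n: text.split(f"[ {n} ]")[1].split("[ ")[1]
    assert body("SOD") == body("NA")
    with open(conversion.layout.path("residuetypes.dat")) as fh:
        rt = fh.read()
    assert "SOD" in rt and "NA" in rt


def test_discarded_records_absent_from_output(conversion):
    """DONOR/ACCEPTOR/IC content never reaches the port."""
    for name in conversion.layout.files:
        with open(conversion.layout.path(name)) as fh:
            text = fh.read()
        assert "DONOR" not in text and "ACCEPTOR" not in text


def test_lone_pair_residue_absent_from_rtp(conversion):
    for name in ("prot.rtp", "cgenff.rtp"):
        with open(conversion.layout.path(name)) as fh:
            assert "[ LPX ]" not in fh.read()


def test_wildcard_token_in_dihedraltypes(conversion):
    with open(conversion.layout.path("ffbonded.itp")) as fh:
        text = fh.read()
    assert "X       " in text  # wildcard rows written with the engine token


def test_validate_port_catches_unknown_type(conversion):
    import copy

    gmx = copy.deepcopy(conversion.gmx)
    del gmx.atomtypes["CT"]
    problems = validate_port(conversion.source, gmx)
    assert problems and all("CT" in p for p in problems)


# ---------------------------------------------------------------------------
# water models
# ---------------------------------------------------------------------------


def test_default_water_model_present(conversion):
    assert "tip3p_charmm.itp" in conversion.layout.files


def test_all_seven_water_models(tmp_path):
    names = write_water_models(sorted(WATER_MODELS), str(tmp_path))
    assert len(names) == 7
    for n in names:
        assert (tmp_path / n).exists()


def test_empty_water_selection_is_error(tmp_path):
    with pytest.raises(FFError):
        write_water_models([], str(tmp_path))


def test_unknown_water_model_is_error(tmp_path):
    with pytest.raises(FFError, match="unknown water model"):
        write_water_models(["tip42"], str(tmp_path))


# ---------------------------------------------------------------------------
# documentation
# ---------------------------------------------------------------------------


def test_doc_contains_formatted_references(conversion):
    with open(conversion.layout.path("forcefield.doc")) as fh:
        text = fh.read()
    assert "Synthetic toy port" in text.splitlines()[0]
    assert "[ALX]" in text and "Doe" in text


def test_unresolved_citation_key_warns(fixture_ff, tmp_path):
    fx, _cfg = fixture_ff
    d = tmp_path / "mod"
    d.mkdir()
    for name, text in fx.files.items():
        if name == "ffport.in":
            text = text.replace("cite ALX toyff2024", "cite ALX ghostkey")
        (d / name).write_text(text)
    result = run_conversion_from_file(str(d / "ffport.in"), outdir=str(d))
    with open(result.layout.path("forcefield.doc")) as fh:
        assert "ghostkey unavailable" in fh.read()


def test_small_fixture_rtp_entry_count(tmp_path):
    """Two residues plus one patch-derived residue give three rtp entries,
    in deterministic order."""
    from ffport.fixtures import generate_fixture_ff

    fx = generate_fixture_ff(seed=3, size=2)
    config_path = fx.write(str(tmp_path))
    result = run_conversion_from_file(config_path, outdir=str(tmp_path))
    with open(result.layout.path("prot.rtp")) as fh:
        text = fh.read()
    headers = [
        line.strip() for line in text.splitlines()
        if line.startswith("[ ") and "bondedtypes" not in line
    ]
    assert headers == ["[ ALX ]", "[ CYX ]", "[ CYX2 ]"]
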
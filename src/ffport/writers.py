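"""Serialization of the converted model into a GROMACS force-field directory.

Output is deterministic: two runs on identical inputs produce byte-identical
directories (stable ordering everywhere, fixed numeric formatting).
Parameters are printed with shortest-round-trip formatting so that re-parsing
the written files recovers the converted parameter set exactly; charges use a
fixed three-decimal format.

Layout of ``<name>.ff/``::

    forcefield.itp          defaults block + includes
    forcefield.doc          one-line description + formatted references
    atomtypes.atp           atom type -> mass
    ffnonbonded.itp         [atomtypes], [pairtypes], include of nbfix.itp
    nbfix.itp               [nonbond_params] pair overrides
    ffbonded.itp            bond/angle/dihedral/improper/cmap types
    ffmissingdihedrals.itp  zero-force dummies + replicated impropers
    <class>.rtp             residue topologies per residue class
    <class>.n.tdb/.c.tdb    termini databases
    <class>.hdb             hydrogen addition database
    <model>.itp             water topologies
    watermodels.dat         available water models
    residuetypes.dat        residue -> chain-class mapping
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

from .bibtex import parse_bibtex_file
from .fixups import MissingTermReport
from .hdb import HAddRule
from .model import (
    CmapGrid,
    ConversionConfig,
    FFError,
    ForceFieldSource,
    WILDCARD,
    canonical_pair,
    canonical_quad,
    canonical_triplet,
)
from .param_convert import GmxAtomType, GmxParameterSet
from .patching import Add, Delete, ImproperAdd, Replace, TerminusEntry
from .units import TWO_POW_SIXTH

#: the downstream engine's wildcard token in dihedral/improper type lines
GMX_WILDCARD = "X"


def _fmt(x: float) -> str:
    """Shortest representation that round-trips through float()."""
    return repr(float(x))


def _wc(t: str) -> str:
    return GMX_WILDCARD if t == WILDCARD else t


@dataclass
class FFPortLayout:
    directory: str
    files: list[str] = field(default_factory=list)

    def path(self, name: str) -> str:
        return os.path.join(self.directory, name)


# ---------------------------------------------------------------------------
# water models: literature constants kept in the porting code itself
# ---------------------------------------------------------------------------


def _sig_eps(rmin2_a: float, eps_kcal: float) -> tuple[float, float]:
    return (2.0 * rmin2_a / TWO_POW_SIXTH * 0.1, eps_kcal * 4.184)


#: name -> dict of geometry (nm, degrees), charges (e) and LJ (nm, kJ/mol)
WATER_MODELS: dict[str, dict] = {
    "tip3p": dict(
        doh=0.09572, hoh=104.52, qo=-0.834, qh=0.417,
        o_lj=(0.315058, 0.636386), h_lj=(0.0, 0.0), sites=3,
    ),
    "tip3p_charmm": dict(
        doh=0.09572, hoh=104.52, qo=-0.834, qh=0.417,
        o_lj=_sig_eps(1.7682, 0.1521), h_lj=_sig_eps(0.2245, 0.046), sites=3,
    ),
    "spc": dict(
        doh=0.1, hoh=109.47, qo=-0.82, qh=0.41,
        o_lj=(0.316557, 0.650194), h_lj=(0.0, 0.0), sites=3,
    ),
    "spce": dict(
        doh=0.1, hoh=109.47, qo=-0.8476, qh=0.4238,
        o_lj=(0.316557, 0.650194), h_lj=(0.0, 0.0), sites=3,
    ),
    "tip4p": dict(
        doh=0.09572, hoh=104.52, qo=0.0, qh=0.52, qm=-1.04, dom=0.015,
        o_lj=(0.315365, 0.648520), h_lj=(0.0, 0.0), sites=4,
    ),
    "tip4pew": dict(
        doh=0.09572, hoh=104.52, qo=0.0, qh=0.52422, qm=-1.04844, dom=0.0125,
        o_lj=(0.316435, 0.680946), h_lj=(0.0, 0.0), sites=4,
    ),
    "tip5p": dict(
        doh=0.09572, hoh=104.52, qo=0.0, qh=0.241, ql=-0.241, dol=0.07,
        lol=109.47, o_lj=(0.312, 0.66944), h_lj=(0.0, 0.0), sites=5,
    ),
}


def _water_type_names(model: str) -> dict[str, str]:
    tag = model.upper().replace("_", "")[:6]
    return {"O": f"OW{tag}", "H": f"HW{tag}", "M": f"MW{tag}", "L": f"LW{tag}"}


def write_water_models(selection: list[str], outdir: str) -> list[str]:
    """Write one rigid topology per selected model; returns file names."""
    if not selection:
        raise FFError("empty water-model selection")
    written: list[str] = []
    for model in selection:
        if model not in WATER_MODELS:
            raise FFError(
                f"unknown water model {model!r}; available: "
                f"{sorted(WATER_MODELS)}"
            )
        w = WATER_MODELS[model]
        t = _water_type_names(model)
        dhh = 2.0 * w["doh"] * math.sin(math.radians(w["hoh"]) / 2.0)
        lines = [f"; {model} water, rigid {w['sites']}-site model", ""]
        lines += ["[ atomtypes ]",
                  "; name  at.num  mass     charge  ptype  sigma  epsilon"]
        lines.append(
            f"{t['O']:<8s} 8 15.99940 0.000 A {_fmt(w['o_lj'][0])} "
            f"{_fmt(w['o_lj'][1])}"
        )
        lines.append(
            f"{t['H']:<8s} 1  1.00800 0.000 A {_fmt(w['h_lj'][0])} "
            f"{_fmt(w['h_lj'][1])}"
        )
        if w["sites"] == 4:
            lines.append(f"{t['M']:<8s} 0  0.00000 0.000 D 0.0 0.0")
        if w["sites"] == 5:
            lines.append(f"{t['L']:<8s} 0  0.00000 0.000 D 0.0 0.0")
        lines += ["", "[ moleculetype ]", "SOL  2", "", "[ atoms ]"]
        lines.append(f"1  {t['O']}  1  SOL  OW  1  {_fmt(w['qo'])}")
        lines.append(f"2  {t['H']}  1  SOL  HW1 1  {_fmt(w['qh'])}")
        lines.append(f"3  {t['H']}  1  SOL  HW2 1  {_fmt(w['qh'])}")
        if w["sites"] == 4:
            lines.append(f"4  {t['M']}  1  SOL  MW  1  {_fmt(w['qm'])}")
        if w["sites"] == 5:
            lines.append(f"4  {t['L']}  1  SOL  LP1 1  {_fmt(w['ql'])}")
            lines.append(f"5  {t['L']}  1  SOL  LP2 1  {_fmt(w['ql'])}")
        lines += ["", "[ settles ]",
                  f"1  1  {_fmt(w['doh'])}  {_fmt(dhh)}", ""]
        if w["sites"] == 4:
            # virtual site on the HOH bisector
            a = w["dom"] / (2.0 * w["doh"] * math.cos(math.radians(w["hoh"]) / 2.0))
            lines += ["[ virtual_sites3 ]",
                      f"4  1  2  3  1  {_fmt(a)}  {_fmt(a)}", ""]
        if w["sites"] == 5:
            # out-of-plane lone pairs
            a = w["dol"] * math.cos(math.radians(w["lol"]) / 2.0)
            c = w["dol"] * math.sin(math.radians(w["lol"]) / 2.0)
            lines += ["[ virtual_sites3 ]",
                      f"4  1  2  3  4  {_fmt(-a)}  {_fmt(-a)}  {_fmt(c)}",
                      f"5  1  2  3  4  {_fmt(-a)}  {_fmt(-a)}  {_fmt(-c)}", ""]
        lines += ["[ exclusions ]"]
        n = w["sites"]
        for i in range(1, n + 1):
            lines.append(
                f"{i}  " + " ".join(str(j) for j in range(1, n + 1) if j != i)
            )
        lines.append("")
        name = f"{model}.itp"
        with open(os.path.join(outdir, name), "w") as fh:
            fh.write("\n".join(lines))
        written.append(name)
    return written


# ---------------------------------------------------------------------------
# documentation
# ---------------------------------------------------------------------------


def write_doc(
    config: ConversionConfig, outdir: str, warnings: list[str]
) -> str:
    """forcefield.doc: description line plus formatted references."""
    lines = [config.description]
    if config.citation_db:
        db = parse_bibtex_file(config.citation_db)
        for residue, key in config.citations:
            entry = db.get(key)
            if entry is None:
                warnings.append(
                    f"citation key {key!r} (residue {residue}) not in database"
                )
                lines.append(f"[{residue}] (reference {key} unavailable)")
            else:
                lines.append(f"[{residue}] {entry.format_reference()}")
    with open(os.path.join(outdir, "forcefield.doc"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return "forcefield.doc"


# ---------------------------------------------------------------------------
# main writer
# ---------------------------------------------------------------------------

_RTP_CHAIN_CLASS = {"prot": "Protein", "na": "DNA", "carb": "Other",
                   "lipid": "Other", "cgenff": "Other"}

#: functional-form codes of the residue-topology header: harmonic bonds,
#: Urey-Bradley angles, multiplicity-style propers, harmonic impropers,
#: automatic dihedral generation, 3-bond exclusions, 1-4 pairs generated,
#: declared dihedrals kept
_BONDEDTYPES_LINE = "     1     5     9     2     1     3     1     0"


def validate_port(
    source: ForceFieldSource, gmx: GmxParameterSet
) -> list[str]:
    """Cross-file referential integrity: every atom type used by a retained
    residue must be declared; returns the problems found (empty = OK)."""
    problems = []
    for res in source.retained_residues().values():
        for a in res.atoms:
            if a.type not in gmx.atomtypes:
                problems.append(
                    f"residue {res.name}: atom {a.name} type {a.type} not in "
                    "atomtypes"
                )
    return problems


def write_port(
    source: ForceFieldSource,
    gmx: GmxParameterSet,
    termini: dict[str, dict[str, list[TerminusEntry]]],
    hdb_rules: dict[str, list[HAddRule]],
    fixreport: MissingTermReport,
    config: ConversionConfig,
    outdir: str,
) -> FFPortLayout:
    """Assemble the complete force-field directory (all-or-nothing: the
    referential-integrity check runs before any file is written).

    ``termini`` maps residue class -> side ("N"/"C") -> entries;
    ``hdb_rules`` maps residue class -> per-residue rules.
    """
    problems = validate_port(source, gmx)
    if problems:
        raise FFError("cannot write port:\n  " + "\n  ".join(problems))
    ffdir = os.path.join(outdir, f"{config.ff_name}.ff")
    os.makedirs(ffdir, exist_ok=True)
    layout = FFPortLayout(directory=ffdir)
    warnings: list[str] = []

    # --- ffnonbonded.itp -------------------------------------------------
    lines = ["; nonbonded parameters (converted)", "", "[ atomtypes ]",
             "; name  at.num  mass  charge  ptype  sigma  epsilon  (1-4 overrides in comments)"]
    for t in sorted(gmx.atomtypes):
        a = gmx.atomtypes[t]
        tail = ""
        if a.sigma14 is not None:
            tail = f" ; sigma14= {_fmt(a.sigma14)} epsilon14= {_fmt(a.epsilon14)}"
        lines.append(
            f"{t:<8s} {a.atomic_number:3d} {_fmt(a.mass):>10s} 0.000 A "
            f"{_fmt(a.sigma)} {_fmt(a.epsilon)}{tail}"
        )
    lines += ["", "[ pairtypes ]", "; 1-4 Lennard-Jones parameters"]
    for (ta, tb) in sorted(gmx.pairtypes):
        s14, e14 = gmx.pairtypes[(ta, tb)]
        lines.append(f"{ta:<8s} {tb:<8s} 1 {_fmt(s14)} {_fmt(e14)}")
    lines += ["", '#include "nbfix.itp"', ""]
    _write(layout, "ffnonbonded.itp", lines)

    # --- nbfix.itp -------------------------------------------------------
    lines = ["; pair-specific Lennard-Jones overrides", "",
             "[ nonbond_params ]"]
    for (ta, tb) in sorted(gmx.nonbond_params):
        s, e = gmx.nonbond_params[(ta, tb)]
        lines.append(f"{ta:<8s} {tb:<8s} 1 {_fmt(s)} {_fmt(e)}")
    lines.append("")
    _write(layout, "nbfix.itp", lines)

    # --- ffbonded.itp ----------------------------------------------------
    lines = ["; bonded parameters (converted)", "", "[ bondtypes ]"]
    for key in sorted(gmx.bondtypes):
        b0, kb = gmx.bondtypes[key]
        lines.append(f"{key[0]:<8s} {key[1]:<8s} 1 {_fmt(b0)} {_fmt(kb)}")
    lines += ["", "[ angletypes ]"]
    for key in sorted(gmx.angletypes):
        th0, kth, ub0, kub = gmx.angletypes[key]
        lines.append(
            f"{key[0]:<8s} {key[1]:<8s} {key[2]:<8s} 5 "
            f"{_fmt(th0)} {_fmt(kth)} {_fmt(ub0)} {_fmt(kub)}"
        )
    lines += ["", "[ dihedraltypes ]", "; proper dihedrals"]
    for key in sorted(gmx.dihedraltypes):
        for delta, kchi, n in gmx.dihedraltypes[key]:
            lines.append(
                " ".join(f"{_wc(t):<8s}" for t in key)
                + f" 9 {_fmt(delta)} {_fmt(kchi)} {n}"
            )
    lines += ["", "[ dihedraltypes ]", "; improper dihedrals"]
    for key in sorted(gmx.impropertypes):
        psi0, kpsi = gmx.impropertypes[key]
        lines.append(
            " ".join(f"{_wc(t):<8s}" for t in key)
            + f" 2 {_fmt(psi0)} {_fmt(kpsi)}"
        )
    if gmx.cmaptypes:
        lines += ["", "[ cmaptypes ]"]
        for key in sorted(gmx.cmaptypes):
            grid = gmx.cmaptypes[key]
            head = " ".join(f"{t}" for t in key)
            vals = grid.grid.ravel()
            body = "\\\n".join(
                " ".join(_fmt(v) for v in vals[i : i + 4])
                for i in range(0, vals.size, 4)
            )
            lines.append(f"{head} 1 {grid.resolution} {grid.resolution}\\\n{body}")
    lines.append("")
    _write(layout, "ffbonded.itp", lines)

    # --- ffmissingdihedrals.itp -----------------------------------------
    lines = ["; repairs for engine differences: zero-force dummies for",
             "; collinear dihedrals, replicated impropers for permuted atom",
             "; orders", ""]
    lines += ["[ dihedraltypes ]", "; dummy (zero-force) proper dihedrals"]
    for d in sorted(fixreport.dummy_dihedraltypes, key=lambda d: d.types):
        lines.append(
            " ".join(f"{_wc(t):<8s}" for t in d.types)
            + f" 9 {_fmt(d.delta)} {_fmt(d.kchi)} {d.n}"
        )
    lines += ["", "[ dihedraltypes ]", "; replicated impropers"]
    for p in sorted(fixreport.permuted_impropertypes, key=lambda p: p.declared_types):
        psi0, kpsi = p.param.psi0, p.param.kpsi * 2.0 * 4.184
        lines.append(
            " ".join(f"{_wc(t):<8s}" for t in p.declared_types)
            + f" 2 {_fmt(psi0)} {_fmt(kpsi)}"
            + f" ; from {'-'.join(p.matched_key)} ({p.residue})"
        )
    lines.append("")
    _write(layout, "ffmissingdihedrals.itp", lines)

    # --- atomtypes.atp ---------------------------------------------------
    lines = [f"{t:<8s} {_fmt(gmx.atomtypes[t].mass):>10s}"
             for t in sorted(gmx.atomtypes)]
    lines.append("")
    _write(layout, "atomtypes.atp", lines)

    # --- per-class rtp / tdb / hdb --------------------------------------
    classes: dict[str, list] = {}
    alias_of = dict()
    for src_name, alias in config.copyresidues:
        alias_of.setdefault(src_name, []).append(alias)
    for res in source.retained_residues().values():
        classes.setdefault(res.group or "misc", []).append(res)
    for cls, residues in sorted(classes.items()):
        lines = [f"; residue topologies, class {cls}", "", "[ bondedtypes ]",
                 "; bonds angles dihedrals impropers all_dih nrexcl HH14 RemoveDih",
                 _BONDEDTYPES_LINE, ""]
        for res in residues:
            names = [res.name] + alias_of.get(res.name, [])
            for name in names:
                lines += [f"[ {name} ]", " [ atoms ]"]
                for a in res.atoms:
                    lines.append(
                        f"  {a.name:<6s} {a.type:<8s} {a.charge:8.3f} "
                        f"{a.group_index:3d}"
                    )
                if res.bonds:
                    lines.append(" [ bonds ]")
                    for b1, b2 in res.bonds:
                        lines.append(f"  {b1:<6s} {b2:<6s}")
                if res.impropers:
                    lines.append(" [ impropers ]")
                    for quad in res.impropers:
                        lines.append("  " + " ".join(f"{q:<6s}" for q in quad))
                if res.cmaps:
                    lines.append(" [ cmap ]")
                    for octet in res.cmaps:
                        lines.append("  " + " ".join(f"{q:<6s}" for q in octet))
                lines.append("")
        _write(layout, f"{cls}.rtp", lines)

    for cls, by_side in sorted(termini.items()):
        for side, entries in sorted(by_side.items()):
            suffix = "n.tdb" if side == "N" else "c.tdb"
            lines = [f"; termini database, class {cls}, {side}-side", ""]
            for entry in entries:
                lines.append(f"[ {entry.name} ]")
                deletes = [d for d in entry.directives if isinstance(d, Delete)]
                replaces = [d for d in entry.directives if isinstance(d, Replace)]
                adds = [d for d in entry.directives if isinstance(d, Add)]
                imps = [d for d in entry.directives if isinstance(d, ImproperAdd)]
                if replaces:
                    lines.append("[ replace ]")
                    for r in replaces:
                        lines.append(
                            f"{r.atom:<6s} {r.new_type:<8s} "
                            f"{_fmt(r.new_mass):>10s} {r.new_charge:8.3f}"
                        )
                if adds:
                    lines.append("[ add ]")
                    for a in adds:
                        lines.append(
                            f"{a.count} {a.rule_code} {a.name_stem:<6s} "
                            + " ".join(a.control_atoms)
                        )
                        lines.append(
                            f"\t{a.new_type:<8s} {_fmt(a.new_mass):>10s} "
                            f"{a.new_charge:8.3f}"
                        )
                if deletes:
                    lines.append("[ delete ]")
                    for d in deletes:
                        lines.append(d.atom)
                if imps:
                    lines.append("[ impropers ]")
                    for im in imps:
                        lines.append(" ".join(im.quad))
                lines.append("")
            _write(layout, f"{cls}.{suffix}", lines)

    for cls, rules in sorted(hdb_rules.items()):
        lines = [f"; hydrogen addition database, class {cls}", ""]
        for rule in rules:
            if not rule.blocks:
                continue
            lines.append(f"{rule.residue:<8s} {len(rule.blocks)}")
            for b in rule.blocks:
                lines.append(
                    f"\t{b.h_count}\t{b.rule_code}\t{b.name_stem:<6s}\t"
                    + "\t".join(b.control_atoms)
                )
        lines.append("")
        _write(layout, f"{cls}.hdb", lines)

    # --- water models ----------------------------------------------------
    water_files = write_water_models(config.water_models, ffdir)
    layout.files.extend(water_files)
    _write(layout, "watermodels.dat",
           [f"{m}  {m} water model" for m in config.water_models] + [""])

    # --- residuetypes ----------------------------------------------------
    lines = []
    for res in source.retained_residues().values():
        cc = _RTP_CHAIN_CLASS.get(res.group, "Other")
        for name in [res.name] + alias_of.get(res.name, []):
            lines.append(f"{name:<8s} {cc}")
    lines.append("SOL      Water")
    lines.append("")
    _write(layout, "residuetypes.dat", lines)

    # --- doc and master include ------------------------------------------
    layout.files.append(write_doc(config, ffdir, warnings))
    lines = [
        f"; {config.ff_name}: force field ported from CHARMM format",
        "",
        "[ defaults ]",
        "; nbfunc  comb-rule  gen-pairs  fudgeLJ  fudgeQQ",
        "  1       2          yes        1.0      1.0",
        "",
        '#include "ffnonbonded.itp"',
        '#include "ffbonded.itp"',
        '#include "ffmissingdihedrals.itp"',
        "",
    ]
    _write(layout, "forcefield.itp", lines)
    return layout


def _write(layout: FFPortLayout, name: str, lines: list[str]) -> None:
    with open(layout.path(name), "w") as fh:
        fh.write("\n".join(lines))
    layout.files.append(name)


# ---------------------------------------------------------------------------
# round-trip reader for the parameter files
# ---------------------------------------------------------------------------


def _strip_comment(line: str) -> tuple[str, str]:
    if ";" in line:
        body, comment = line.split(";", 1)
        return body.strip(), comment.strip()
    return line.strip(), ""


def read_gmx_parameters(ffdir: str) -> GmxParameterSet:
    """Re-parse ffnonbonded.itp, ffbonded.itp and nbfix.itp into a
    :class:`GmxParameterSet` (the write -> read round trip)."""
    gmx = GmxParameterSet()
    _read_nonbonded(os.path.join(ffdir, "ffnonbonded.itp"), gmx)
    _read_nonbonded(os.path.join(ffdir, "nbfix.itp"), gmx)
    _read_bonded(os.path.join(ffdir, "ffbonded.itp"), gmx)
    return gmx


def _read_nonbonded(path: str, gmx: GmxParameterSet) -> None:
    section = None
    with open(path, "r") as fh:
        for raw in fh:
            body, comment = _strip_comment(raw)
            if not body or body.startswith("#"):
                continue
            if body.startswith("["):
                section = body.strip("[] ").lower()
                continue
            toks = body.split()
            if section == "atomtypes":
                t = toks[0]
                at = GmxAtomType(
                    mass=float(toks[2]), atomic_number=int(toks[1]),
                    sigma=float(toks[5]), epsilon=float(toks[6]),
                )
                ctoks = comment.split()
                if "sigma14=" in ctoks:
                    at.sigma14 = float(ctoks[ctoks.index("sigma14=") + 1])
                    at.epsilon14 = float(ctoks[ctoks.index("epsilon14=") + 1])
                gmx.atomtypes[t] = at
            elif section == "pairtypes":
                gmx.pairtypes[canonical_pair((toks[0], toks[1]))] = (
                    float(toks[3]), float(toks[4])
                )
            elif section == "nonbond_params":
                gmx.nonbond_params[canonical_pair((toks[0], toks[1]))] = (
                    float(toks[3]), float(toks[4])
                )


def _read_bonded(path: str, gmx: GmxParameterSet) -> None:
    import numpy as np

    section = None
    with open(path, "r") as fh:
        text = fh.read().replace("\\\n", " ")
    for raw in text.splitlines():
        body, _comment = _strip_comment(raw)
        if not body or body.startswith("#"):
            continue
        if body.startswith("["):
            section = body.strip("[] ").lower()
            continue
        toks = body.split()
        if section == "bondtypes":
            gmx.bondtypes[canonical_pair((toks[0], toks[1]))] = (
                float(toks[3]), float(toks[4])
            )
        elif section == "angletypes":
            gmx.angletypes[canonical_triplet((toks[0], toks[1], toks[2]))] = (
                float(toks[4]), float(toks[5]), float(toks[6]), float(toks[7])
            )
        elif section == "dihedraltypes":
            types = tuple(WILDCARD if t == GMX_WILDCARD else t for t in toks[0:4])
            funct = toks[4]
            if funct == "9":
                key = canonical_quad(types)
                gmx.dihedraltypes.setdefault(key, []).append(
                    (float(toks[5]), float(toks[6]), int(toks[7]))
                )
            elif funct == "2":
                gmx.impropertypes[canonical_quad(types)] = (
                    float(toks[5]), float(toks[6])
                )
        elif section == "cmaptypes":
            types = tuple(toks[0:8])
            res = int(toks[9])
            vals = np.array([float(x) for x in toks[11:]], dtype=float)
            gmx.cmaptypes[types] = CmapGrid(res, vals.reshape(res, res))
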
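"""Reading CHARMM-format force-field files and the conversion-control file.

The rtf/prm/str dialects are line oriented: ``!`` starts a comment, a trailing
``-`` continues a record on the next line, keywords are case insensitive and
may be abbreviated to four characters (``DELE`` for ``DELETE``), identifiers
are case preserving.  Stream (``.str``) files interleave ``read rtf`` and
``read para`` sections.

Everything is parsed into :class:`~ffport.model.ForceFieldSource`; records the
downstream engine has no use for (DONOR/ACCEPTOR/IC, bond orders) are parsed,
noted, and discarded rather than silently skipped.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .model import (
    AtomRecord,
    BondParam,
    AngleParam,
    CmapGrid,
    ConversionConfig,
    DihedralParam,
    FFError,
    ForceFieldSource,
    ImproperParam,
    LJParam,
    MassEntry,
    NBFixParam,
    ParameterTables,
    PatchTopology,
    ResidueTopology,
    canonical_pair,
    canonical_quad,
    canonical_triplet,
    is_chain_prefixed,
    strip_chain_prefix,
    validate_merged,
)

log = logging.getLogger(__name__)

_MIN_ABBREV = 4


def _kw(token: str, *full: str) -> bool:
    """CHARMM keyword match: case-insensitive, >=4-char abbreviation."""
    t = token.upper()
    for f in full:
        f = f.upper()
        if t == f:
            return True
        if len(t) >= min(_MIN_ABBREV, len(f)) and f.startswith(t):
            return True
    return False


@dataclass
class _Line:
    text: str
    path: str
    lineno: int
    comment: str = ""

    @property
    def where(self) -> str:
        return f"{self.path}:{self.lineno}"

    def tokens(self) -> list[str]:
        return self.text.split()


def _logical_lines(text: str, path: str) -> Iterator[_Line]:
    """Strip comments, join continuation lines, keep provenance of the first
    physical line of each record."""
    pending: Optional[_Line] = None
    for i, raw in enumerate(text.splitlines(), start=1):
        comment = ""
        if "!" in raw:
            raw, comment = raw.split("!", 1)
            comment = comment.strip()
        body = raw.strip()
        if pending is not None:
            pending.text += " " + body
            pending.comment = (pending.comment + " " + comment).strip()
        elif body or comment:
            pending = _Line(body, path, i, comment)
        else:
            continue
        if pending.text.rstrip().endswith("-"):
            pending.text = pending.text.rstrip()[:-1]
        else:
            if pending.text or pending.comment:
                yield pending
            pending = None
    if pending is not None and (pending.text or pending.comment):
        yield pending


def _as_float(tok: str, line: _Line) -> float:
    try:
        return float(tok)
    except ValueError:
        raise FFError(f"{line.where}: expected a number, got {tok!r}") from None


# ---------------------------------------------------------------------------
# topology (rtf) records
# ---------------------------------------------------------------------------


def _pairs(tokens: list[str], line: _Line) -> list[tuple[str, str]]:
    if len(tokens) % 2:
        raise FFError(f"{line.where}: odd number of atoms in bond record")
    return [(tokens[i], tokens[i + 1]) for i in range(0, len(tokens), 2)]


def _quads(tokens: list[str], line: _Line) -> list[tuple[str, str, str, str]]:
    if len(tokens) % 4:
        raise FFError(f"{line.where}: improper record length not a multiple of 4")
    return [tuple(tokens[i : i + 4]) for i in range(0, len(tokens), 4)]  # type: ignore[misc]


class _RtfState:
    """Accumulates RESI/PRES blocks while scanning topology lines."""

    def __init__(self, source: ForceFieldSource, path: str) -> None:
        self.source = source
        self.path = path
        self.current: ResidueTopology | PatchTopology | None = None
        self.group_counter = -1

    def close(self) -> None:
        if self.current is None:
            return
        entry = self.current
        self.current = None
        self.group_counter = -1
        if isinstance(entry, PatchTopology):
            entry.two_residue = any(
                a.name[:1] in "12" for a in entry.atoms
            ) or any(a[:1] in "12" for a in entry.deleted_atoms)
            entry.validate()
            if entry.name in self.source.patches:
                raise FFError(
                    f"{self.path}: duplicate patch {entry.name!r} within one file"
                )
            self.source.patches[entry.name] = entry
        else:
            if entry.name in self.source.residues:
                raise FFError(
                    f"{self.path}: duplicate residue {entry.name!r} within one file"
                )
            self.source.residues[entry.name] = entry

    def feed(self, line: _Line) -> None:
        toks = line.tokens()
        if not toks:
            return
        head, rest = toks[0], toks[1:]
        if _kw(head, "RESI", "PRES"):
            self.close()
            if len(rest) < 1:
                raise FFError(f"{line.where}: RESI/PRES needs a name")
            charge = _as_float(rest[1], line) if len(rest) > 1 else 0.0
            cls = PatchTopology if _kw(head, "PRES") else ResidueTopology
            self.current = cls(name=rest[0], total_charge=charge, source=line.where)
            self.group_counter = -1
            return
        if _kw(head, "MASS"):
            # MASS <legacy index, ignored> TYPE mass [element]
            if len(rest) < 3:
                raise FFError(f"{line.where}: malformed MASS record")
            t = rest[1]
            entry = MassEntry(mass=_as_float(rest[2], line),
                              element=rest[3] if len(rest) > 3 else "")
            old = self.source.params.masses.get(t)
            if old is not None and old != entry:
                raise FFError(f"{line.where}: conflicting MASS for type {t!r}")
            self.source.params.masses[t] = entry
            return
        if _kw(head, "DECL", "DEFA", "AUTO", "PATC", "FIRS", "LAST"):
            return  # interpreter bookkeeping, nothing to convert
        if self.current is None:
            if _kw(head, "END"):
                return
            if head.replace(".", "").isdigit():
                return  # version line
            raise FFError(f"{line.where}: record {head!r} outside any RESI/PRES")
        cur = self.current
        if _kw(head, "GROUP"):
            self.group_counter += 1
            return
        if _kw(head, "ATOM"):
            if len(rest) < 3:
                raise FFError(f"{line.where}: malformed ATOM record")
            if self.group_counter < 0:
                self.group_counter = 0
            cur.atoms.append(
                AtomRecord(rest[0], rest[1], _as_float(rest[2], line),
                           self.group_counter)
            )
            return
        if _kw(head, "BOND"):
            cur.bonds.extend(_pairs(rest, line))
            return
        if _kw(head, "DOUBLE", "TRIPLE"):
            # bond-order specification is discarded; the bond itself is kept
            cur.bonds.extend(_pairs(rest, line))
            self.source.discarded.append(
                f"{line.where}: bond order ({head.upper()}) dropped"
            )
            return
        if _kw(head, "IMPR", "IMPROPER"):
            cur.impropers.extend(_quads(rest, line))
            return
        if _kw(head, "CMAP"):
            if len(rest) != 8:
                raise FFError(f"{line.where}: CMAP record needs 8 atoms")
            cur.cmaps.append(tuple(rest))
            return
        if _kw(head, "DELETE"):
            if not isinstance(cur, PatchTopology):
                raise FFError(f"{line.where}: DELETE outside a PRES block")
            if not rest:
                raise FFError(f"{line.where}: empty DELETE record")
            what, args = rest[0], rest[1:]
            if _kw(what, "ATOM"):
                cur.deleted_atoms.extend(args)
            elif _kw(what, "IMPR", "IMPROPER"):
                cur.deleted_impropers.extend(_quads(args, line))
            else:
                raise FFError(f"{line.where}: cannot DELETE {what!r}")
            return
        if _kw(head, "LONEPAIR"):
            if isinstance(cur, ResidueTopology):
                cur.has_lone_pairs = True
            self.source.discarded.append(f"{line.where}: LONEPAIR directive")
            return
        if _kw(head, "DONOR", "ACCEPTOR") or head.upper() in ("IC", "BILD"):
            self.source.discarded.append(
                f"{line.where}: {head.upper()} record (no downstream equivalent)"
            )
            cur.annotations.append(f"discarded {head.upper()}: {line.text}")
            return
        if _kw(head, "ANGL", "THET", "DIHE") or _kw(head, "END"):
            # explicit angle/dihedral declarations are regenerated downstream
            self.source.discarded.append(f"{line.where}: {head.upper()} record")
            return
        raise FFError(f"{line.where}: unrecognized topology record {head!r}")


# ---------------------------------------------------------------------------
# parameter (prm) records
# ---------------------------------------------------------------------------

_PRM_SECTIONS = (
    "BONDS", "ANGLES", "THETAS", "DIHEDRALS", "PHI", "IMPROPER", "IMPHI",
    "CMAP", "NONBONDED", "NBFIX", "HBOND", "ATOMS", "END",
)


def _section_of(token: str) -> Optional[str]:
    for name in _PRM_SECTIONS:
        if _kw(token, name):
            if name in ("THETAS",):
                return "ANGLES"
            if name in ("PHI",):
                return "DIHEDRALS"
            if name in ("IMPHI",):
                return "IMPROPER"
            return name
    return None


class _PrmState:
    def __init__(self, source: ForceFieldSource, path: str) -> None:
        self.source = source
        self.path = path
        self.section: Optional[str] = None
        # CMAP accumulation
        self._cmap_key: Optional[tuple[str, ...]] = None
        self._cmap_res = 0
        self._cmap_values: list[float] = []
        self._mass_helper = _RtfState(source, path)

    def close(self) -> None:
        self._flush_cmap(None)

    def _flush_cmap(self, line: Optional[_Line]) -> None:
        if self._cmap_key is None:
            return
        need = self._cmap_res * self._cmap_res
        if len(self._cmap_values) != need:
            where = line.where if line else self.path
            raise FFError(
                f"{where}: CMAP {self._cmap_key} has {len(self._cmap_values)} "
                f"values, expected {need}"
            )
        grid = np.array(self._cmap_values, dtype=float).reshape(
            self._cmap_res, self._cmap_res
        )
        self._insert_cmap(self._cmap_key, CmapGrid(self._cmap_res, grid))
        self._cmap_key = None
        self._cmap_values = []

    def _insert_cmap(self, key: tuple[str, ...], val: CmapGrid) -> None:
        old = self.source.params.cmaps.get(key)
        if old is not None and not (
            old.resolution == val.resolution and np.array_equal(old.grid, val.grid)
        ):
            raise FFError(f"{self.path}: conflicting CMAP for {key}")
        self.source.params.cmaps[key] = val

    def feed(self, line: _Line) -> None:
        toks = line.tokens()
        if not toks:
            return
        sec = _section_of(toks[0])
        if sec is not None:
            if self.section == "CMAP":
                self._flush_cmap(line)
            self.section = None if sec == "END" else sec
            return
        if self.section is None:
            if toks[0].replace(".", "").isdigit() and self._cmap_key is None:
                return  # version line
            raise FFError(f"{line.where}: parameter record outside any section")
        getattr(self, f"_feed_{self.section.lower()}")(toks, line)

    # -- per-section handlers --------------------------------------------
    def _feed_atoms(self, toks: list[str], line: _Line) -> None:
        if _kw(toks[0], "MASS"):
            self._mass_helper.feed(line)
        else:
            raise FFError(f"{line.where}: unexpected record in ATOMS section")

    def _feed_bonds(self, toks: list[str], line: _Line) -> None:
        if len(toks) < 4:
            raise FFError(f"{line.where}: malformed bond parameter")
        key = canonical_pair((toks[0], toks[1]))
        val = BondParam(_as_float(toks[2], line), _as_float(toks[3], line))
        self._insert(self.source.params.bonds, key, val, line)

    def _feed_angles(self, toks: list[str], line: _Line) -> None:
        if len(toks) < 5:
            raise FFError(f"{line.where}: malformed angle parameter")
        key = canonical_triplet((toks[0], toks[1], toks[2]))
        kub = s0 = None
        if len(toks) >= 7:
            kub, s0 = _as_float(toks[5], line), _as_float(toks[6], line)
        val = AngleParam(_as_float(toks[3], line), _as_float(toks[4], line), kub, s0)
        self._insert(self.source.params.angles, key, val, line)

    def _feed_dihedrals(self, toks: list[str], line: _Line) -> None:
        if len(toks) < 7:
            raise FFError(f"{line.where}: malformed dihedral parameter")
        key = canonical_quad(toks[0:4])
        val = DihedralParam(
            _as_float(toks[4], line), int(_as_float(toks[5], line)),
            _as_float(toks[6], line)
        )
        if val.n < 1:
            raise FFError(f"{line.where}: dihedral multiplicity must be >= 1")
        terms = self.source.params.dihedrals.setdefault(key, [])
        for t in terms:
            if t.n == val.n:
                if t == val:
                    return  # identical duplicate
                raise FFError(
                    f"{line.where}: conflicting dihedral for {key} n={val.n}"
                )
        terms.append(val)

    def _feed_improper(self, toks: list[str], line: _Line) -> None:
        if len(toks) < 7:
            raise FFError(f"{line.where}: malformed improper parameter")
        key = canonical_quad(toks[0:4])
        # middle column is the (unused) multiplicity placeholder, typically 0
        val = ImproperParam(_as_float(toks[4], line), _as_float(toks[6], line))
        self._insert(self.source.params.impropers, key, val, line)

    def _feed_cmap(self, toks: list[str], line: _Line) -> None:
        if not _is_number(toks[0]):
            # header line: 8 atom types + grid size
            self._flush_cmap(line)
            if len(toks) != 9:
                raise FFError(f"{line.where}: CMAP header needs 8 types + size")
            self._cmap_key = tuple(toks[0:8])
            self._cmap_res = int(_as_float(toks[8], line))
            self._cmap_values = []
            return
        if self._cmap_key is None:
            raise FFError(f"{line.where}: CMAP values before any header")
        for t in toks:
            self._cmap_values.append(_as_float(t, line))

    def _feed_nonbonded(self, toks: list[str], line: _Line) -> None:
        if _kw(toks[0], "CUTNB", "NBXMOD") or toks[0].upper().startswith("CUT"):
            return  # option continuation of the section header
        if len(toks) < 4:
            raise FFError(f"{line.where}: malformed NONBONDED record")
        eps = _as_float(toks[2], line)
        rmin2 = _as_float(toks[3], line)
        eps14 = rmin2_14 = None
        if len(toks) >= 7:
            eps14, rmin2_14 = _as_float(toks[5], line), _as_float(toks[6], line)
        if eps > 0:
            self.source.warnings.append(
                f"{line.where}: positive epsilon for {toks[0]} (expected negative)"
            )
        val = LJParam(eps, rmin2, eps14, rmin2_14)
        self._insert(self.source.params.lj, toks[0], val, line)

    def _feed_nbfix(self, toks: list[str], line: _Line) -> None:
        if len(toks) < 4:
            raise FFError(f"{line.where}: malformed NBFIX record")
        key = canonical_pair((toks[0], toks[1]))
        val = NBFixParam(_as_float(toks[2], line), _as_float(toks[3], line))
        self._insert(self.source.params.nbfix, key, val, line)

    def _feed_hbond(self, toks: list[str], line: _Line) -> None:
        self.source.discarded.append(f"{line.where}: HBOND record")

    def _insert(self, table: dict, key, val, line: _Line) -> None:
        old = table.get(key)
        if old is not None and old != val:
            raise FFError(f"{line.where}: conflicting parameter for {key}")
        table[key] = val


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# entry points
# ---------------------------------------------------------------------------


def parse_charmm_text(text: str, path: str, dialect: str) -> ForceFieldSource:
    """Parse rtf/prm/str content into a fresh :class:`ForceFieldSource`."""
    if dialect not in ("rtf", "prm", "str"):
        raise FFError(f"unknown dialect {dialect!r}")
    source = ForceFieldSource(files=[path])
    rtf = _RtfState(source, path)
    prm = _PrmState(source, path)
    mode = dialect if dialect != "str" else None
    for line in _logical_lines(text, path):
        toks = line.tokens()
        if not toks or line.text.startswith("*"):
            continue  # comment-only or title line
        if dialect == "str" and _kw(toks[0], "READ"):
            rtf.close()
            prm.close()
            if len(toks) < 2:
                raise FFError(f"{line.where}: malformed read directive")
            if _kw(toks[1], "RTF", "TOPOLOGY"):
                mode = "rtf"
            elif _kw(toks[1], "PARA", "PARAMETER"):
                mode = "prm"
            else:
                raise FFError(f"{line.where}: cannot read section {toks[1]!r}")
            continue
        if dialect == "str" and mode is None:
            if toks and _kw(toks[0], "END"):
                continue
            raise FFError(f"{line.where}: content outside read sections in stream file")
        if mode == "rtf":
            if _kw(toks[0], "END"):
                rtf.close()
                if dialect == "str":
                    mode = None
                continue
            rtf.feed(line)
        else:
            prm.feed(line)
    rtf.close()
    prm.close()
    return source


def parse_charmm_file(path: str, dialect: Optional[str] = None) -> ForceFieldSource:
    """Parse one CHARMM file; dialect inferred from the extension if omitted."""
    if dialect is None:
        dialect = os.path.splitext(path)[1].lstrip(".").lower()
    with open(path, "r") as fh:
        return parse_charmm_text(fh.read(), path, dialect)


# ---------------------------------------------------------------------------
# serialization back to CHARMM-like text (round-trip support)
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def _topology_block(entry: ResidueTopology | PatchTopology) -> list[str]:
    kind = "PRES" if isinstance(entry, PatchTopology) else "RESI"
    out = [f"{kind} {entry.name} {_fmt(entry.total_charge)}"]
    group = None
    for a in entry.atoms:
        if a.group_index != group:
            out.append("GROUP")
            group = a.group_index
        out.append(f"ATOM {a.name} {a.type} {_fmt(a.charge)}")
    for a, b in entry.bonds:
        out.append(f"BOND {a} {b}")
    for q in entry.impropers:
        out.append("IMPR " + " ".join(q))
    for c in entry.cmaps:
        out.append("CMAP " + " ".join(c))
    if isinstance(entry, PatchTopology):
        for name in entry.deleted_atoms:
            out.append(f"DELETE ATOM {name}")
        for q in entry.deleted_impropers:
            out.append("DELETE IMPR " + " ".join(q))
    if isinstance(entry, ResidueTopology) and entry.has_lone_pairs:
        out.append("LONEPAIR")
    return out


def to_charmm_text(source: ForceFieldSource) -> dict[str, str]:
    """Serialize the model back to CHARMM-like rtf and prm text.

    Re-parsing the output reproduces the model's semantic fields exactly
    (full float precision via repr); comments and discarded records are not
    regenerated.
    """
    p = source.params
    rtf: list[str] = ["* generated by ffport", "*", "36  1"]
    for t, m in p.masses.items():
        rtf.append(f"MASS -1 {t} {_fmt(m.mass)} {m.element}".rstrip())
    for res in source.residues.values():
        rtf.extend(_topology_block(res))
    for patch in source.patches.values():
        rtf.extend(_topology_block(patch))
    rtf.append("END")

    prm: list[str] = ["* generated by ffport", "*"]
    prm.append("BONDS")
    for (a, b), v in p.bonds.items():
        prm.append(f"{a} {b} {_fmt(v.kb)} {_fmt(v.b0)}")
    prm.append("ANGLES")
    for (a, b, c), v in p.angles.items():
        extra = f" {_fmt(v.kub)} {_fmt(v.s0)}" if v.kub is not None else ""
        prm.append(f"{a} {b} {c} {_fmt(v.ktheta)} {_fmt(v.theta0)}{extra}")
    prm.append("DIHEDRALS")
    for key, terms in p.dihedrals.items():
        for t in terms:
            prm.append(f"{' '.join(key)} {_fmt(t.kchi)} {t.n} {_fmt(t.delta)}")
    prm.append("IMPROPER")
    for key, v in p.impropers.items():
        prm.append(f"{' '.join(key)} {_fmt(v.kpsi)} 0 {_fmt(v.psi0)}")
    if p.cmaps:
        prm.append("CMAP")
        for key, grid in p.cmaps.items():
            prm.append(f"{' '.join(key)} {grid.resolution}")
            flat = grid.grid.ravel()
            for i in range(0, flat.size, 5):
                prm.append(" ".join(_fmt(x) for x in flat[i : i + 5]))
    prm.append("NONBONDED nbxmod 5")
    for t, v in p.lj.items():
        extra = (
            f" 0.0 {_fmt(v.epsilon14)} {_fmt(v.rmin2_14)}"
            if v.epsilon14 is not None
            else ""
        )
        prm.append(f"{t} 0.0 {_fmt(v.epsilon)} {_fmt(v.rmin2)}{extra}")
    if p.nbfix:
        prm.append("NBFIX")
        for (a, b), v in p.nbfix.items():
            prm.append(f"{a} {b} {_fmt(v.epsilon)} {_fmt(v.rmin)}")
    prm.append("END")
    return {"rtf": "\n".join(rtf) + "\n", "prm": "\n".join(prm) + "\n"}


# ---------------------------------------------------------------------------
# conversion-control file
# ---------------------------------------------------------------------------

_CONFIG_KEYWORDS = (
    "input", "name", "description", "patch", "terminus", "copyresidues",
    "terminaldelete", "citations", "cite", "conflict", "watermodels",
    "pairtypes", "collinearity", "planaritytol",
)


def parse_config(path: str) -> ConversionConfig:
    """Parse the conversion-control file (keyword-value text, ``#`` comments,
    one directive per line).  Unknown keywords are hard errors."""
    cfg = ConversionConfig(water_models=[])
    basedir = os.path.dirname(os.path.abspath(path))

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(basedir, p)

    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            body = raw.split("#", 1)[0].strip()
            if not body:
                continue
            toks = body.split()
            key = toks[0].lower()
            args = toks[1:]
            where = f"{path}:{lineno}"
            if key not in _CONFIG_KEYWORDS:
                raise FFError(f"{where}: unknown config keyword {toks[0]!r}")
            if key == "input":
                if len(args) != 3 or args[0] not in ("rtf", "prm", "str"):
                    raise FFError(
                        f"{where}: usage: input <rtf|prm|str> <class> <path>"
                    )
                p = _resolve(args[2])
                if not os.path.exists(p):
                    raise FFError(f"{where}: input file not found: {p}")
                cfg.input_files.append((p, args[0], args[1]))
            elif key == "name":
                cfg.ff_name = args[0]
            elif key == "description":
                cfg.description = " ".join(args)
            elif key == "patch":
                if len(args) != 3:
                    raise FFError(f"{where}: usage: patch <base> <patch> <newname>")
                triple = (args[0], args[1], args[2])
                if any(t[2] == args[2] for t in cfg.patched_residues):
                    raise FFError(f"{where}: duplicate patched-residue target {args[2]!r}")
                cfg.patched_residues.append(triple)
            elif key == "terminus":
                if len(args) != 2 or args[1].upper() not in ("N", "C"):
                    raise FFError(f"{where}: usage: terminus <patch> <N|C>")
                cfg.termini_patches.append((args[0], args[1].upper()))
            elif key == "copyresidues":
                if len(args) != 2:
                    raise FFError(f"{where}: usage: copyresidues <source> <alias>")
                cfg.copyresidues.append((args[0], args[1]))
            elif key == "terminaldelete":
                cfg.extra_terminal_deletes.extend(args)
            elif key == "citations":
                cfg.citation_db = _resolve(args[0])
            elif key == "cite":
                if len(args) != 2:
                    raise FFError(f"{where}: usage: cite <residue> <bibkey>")
                cfg.citations.append((args[0], args[1]))
            elif key == "conflict":
                if len(args) != 2:
                    raise FFError(f"{where}: usage: conflict <residue> <winning file>")
                cfg.residue_conflicts[args[0]] = args[1]
            elif key == "watermodels":
                cfg.water_models.extend(a.lower() for a in args)
            elif key == "pairtypes":
                if args[0] not in ("overrides", "full"):
                    raise FFError(f"{where}: pairtypes must be 'overrides' or 'full'")
                cfg.pairtypes_mode = args[0]
            elif key == "collinearity":
                cfg.collinearity_threshold = float(args[0])
            elif key == "planaritytol":
                cfg.planarity_tolerance = float(args[0])
    if not cfg.water_models:
        cfg.water_models = ["tip3p_charmm"]
    return cfg


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _residue_is_chainable(res: ResidueTopology) -> bool:
    """Homopolymer closure is possible iff every chain-prefixed bond partner
    also exists (unprefixed) inside the residue itself."""
    prefixed = res.prefixed_bonds()
    if not prefixed:
        return False
    for a, b in prefixed:
        for x in (a, b):
            if is_chain_prefixed(x) and not res.has_atom(strip_chain_prefix(x)):
                return False
    return True


def merge_sources(
    sources: list[ForceFieldSource], config: ConversionConfig
) -> ForceFieldSource:
    """Merge parsed files into one monolithic model, resolving name conflicts
    via the config and flagging lone-pair residues."""
    merged = ForceFieldSource()
    class_of_file = {path: label for path, _d, label in config.input_files}
    for src in sources:
        merged.files.extend(src.files)
        merged.discarded.extend(src.discarded)
        merged.warnings.extend(src.warnings)
        srcfile = src.files[0] if src.files else ""
        label = class_of_file.get(srcfile, "")
        for name, res in src.residues.items():
            res = res.copy()
            res.group = label
            res.chainable = _residue_is_chainable(res)
            if name in merged.residues:
                winner = config.residue_conflicts.get(name)
                if winner is None:
                    raise FFError(
                        f"residue {name!r} defined in both "
                        f"{merged.residues[name].source} and {res.source}; "
                        "add a 'conflict' ruling to the config"
                    )
                old = merged.residues[name]
                keep_new = os.path.basename(srcfile) == os.path.basename(winner) or srcfile == winner
                merged.warnings.append(
                    f"residue {name}: duplicate definitions "
                    f"({old.source} vs {res.source}); keeping "
                    f"{'second' if keep_new else 'first'} per config"
                )
                if not keep_new:
                    continue
            merged.residues[name] = res
        for name, patch in src.patches.items():
            if name in merged.patches:
                raise FFError(f"patch {name!r} defined in more than one file")
            merged.patches[name] = patch
        _merge_params(merged, src)
    for res in merged.residues.values():
        if res.has_lone_pairs:
            msg = (
                f"residue {res.name} uses lone pairs / virtual sites and is "
                "excluded from the port"
            )
            merged.warnings.append(msg)
            log.warning(msg)
    merged.warnings.extend(validate_merged(merged))
    config.validate_against(merged)
    return merged


def _merge_params(merged: ForceFieldSource, src: ForceFieldSource) -> None:
    mp, sp = merged.params, src.params
    srcfile = src.files[0] if src.files else "?"
    for table_name in ("bonds", "angles", "impropers", "lj", "nbfix", "masses"):
        mtab = getattr(mp, table_name)
        stab = getattr(sp, table_name)
        for key, val in stab.items():
            old = mtab.get(key)
            if old is not None and old != val:
                merged.warnings.append(
                    f"{table_name} entry {key}: later file {srcfile} overrides "
                    "an earlier value"
                )
            mtab[key] = val
    for key, terms in sp.dihedrals.items():
        mterms = mp.dihedrals.setdefault(key, [])
        for t in terms:
            existing = next((m for m in mterms if m.n == t.n), None)
            if existing is None:
                mterms.append(t)
            elif existing != t:
                merged.warnings.append(
                    f"dihedral {key} n={t.n}: later file {srcfile} overrides "
                    "an earlier value"
                )
                mterms[mterms.index(existing)] = t
    for key, grid in sp.cmaps.items():
        old = mp.cmaps.get(key)
        if old is not None and not np.array_equal(old.grid, grid.grid):
            merged.warnings.append(
                f"CMAP {key}: later file {srcfile} overrides an earlier grid"
            )
        mp.cmaps[key] = grid
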
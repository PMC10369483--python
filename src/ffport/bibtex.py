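"""Minimal BibTeX reader for citation handling.

Supports the subset needed for force-field documentation files: ``@type{key,
field = {value} | "value" | bare, ...}`` entries, ``%`` comment lines and
nested braces inside values.  Malformed input is a hard error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import FFError


@dataclass
class BibEntry:
    key: str
    entry_type: str
    fields: dict[str, str] = field(default_factory=dict)

    def format_reference(self) -> str:
        authors = self.fields.get("author", "Anonymous").replace(" and ", "; ")
        title = self.fields.get("title", "").strip()
        journal = self.fields.get("journal", self.fields.get("booktitle", ""))
        year = self.fields.get("year", "")
        volume = self.fields.get("volume", "")
        pages = self.fields.get("pages", "").replace("--", "-")
        bits = [authors + "."]
        if title:
            bits.append(title + ".")
        if journal:
            ref = journal
            if volume:
                ref += f" {volume}"
            if pages:
                ref += f", {pages}"
            if year:
                ref += f" ({year})"
            bits.append(ref + ".")
        elif year:
            bits.append(f"({year}).")
        return " ".join(bits)


def _read_braced(text: str, pos: int) -> tuple[str, int]:
    """Read a {...} group starting at pos (text[pos] == '{'); returns
    (content, position after the closing brace)."""
    depth = 0
    start = pos
    for i in range(pos, len(text)):
        if text[i] == "{":
            depth += 1
        elif text[i] == "}":
            depth -= 1
            if depth == 0:
                return text[start + 1 : i], i + 1
    raise FFError("BibTeX: unbalanced braces")


def parse_bibtex(text: str) -> dict[str, BibEntry]:
    entries: dict[str, BibEntry] = {}
    text = "\n".join(
        line for line in text.splitlines() if not line.lstrip().startswith("%")
    )
    pos = 0
    while True:
        at = text.find("@", pos)
        if at < 0:
            break
        m = re.match(r"@(\w+)\s*\{", text[at:])
        if not m:
            raise FFError(f"BibTeX: malformed entry near position {at}")
        entry_type = m.group(1).lower()
        body, pos = _read_braced(text, at + m.end() - 1)
        if entry_type == "comment":
            continue
        head, _, rest = body.partition(",")
        key = head.strip()
        if not key:
            raise FFError("BibTeX: entry without a key")
        entry = BibEntry(key=key, entry_type=entry_type)
        i = 0
        while i < len(rest):
            m = re.match(r"\s*(\w+)\s*=\s*", rest[i:])
            if not m:
                if rest[i:].strip(", \n\t"):
                    raise FFError(f"BibTeX: malformed field in entry {key}")
                break
            name = m.group(1).lower()
            i += m.end()
            if rest[i] == "{":
                value, j = _read_braced(rest, i)
                i = j
            elif rest[i] == '"':
                j = rest.find('"', i + 1)
                if j < 0:
                    raise FFError(f"BibTeX: unterminated string in entry {key}")
                value = rest[i + 1 : j]
                i = j + 1
            else:
                m2 = re.match(r"[^,]+", rest[i:])
                value = m2.group(0).strip()
                i += m2.end()
            entry.fields[name] = " ".join(value.split())
            m3 = re.match(r"\s*,", rest[i:])
            if m3:
                i += m3.end()
        if key in entries:
            raise FFError(f"BibTeX: duplicate key {key}")
        entries[key] = entry
    return entries


def parse_bibtex_file(path: str) -> dict[str, BibEntry]:
    with open(path, "r") as fh:
        return parse_bibtex(fh.read())
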
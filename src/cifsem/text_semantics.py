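"""Implied-semantics annotation of free article text.

Two independent scanners:

* **Glossary annotation** — a variable-length word window (4, then 3, 2,
  1) slides left-to-right over the text and compares normalised phrases
  against a glossary index; the longest match wins, the scan resumes
  after it, and stop-listed single words are never linked on their own.
  So with "space group" indexed and "group" stop-listed, the phrase
  "space group" is annotated as a whole and a bare "group" is not.

* **Geometry mentions** — a regular-expression scan for chains of 2-4
  atom labels (``C2---C21---C22---C221``) joined by dash separators
  (dots denote non-bonded contacts), optionally followed by a printed
  value with su and unit.  Mentions are then *resolved* against the
  geometry tables of a data block: a typographic match that corresponds
  to no tabulated row is dropped; a unique match binds; several matches
  are returned as ambiguous candidates for the reader to choose.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cif_syntax import DataBlock

__all__ = [
    "GlossaryIndex",
    "Annotation",
    "GeometryMention",
    "annotate",
    "scan_geometry",
    "resolve_mentions",
]

_MAX_WINDOW = 4
_STRIP_CHARS = string.punctuation + "‘’“”′"


def _normalise(phrase: str) -> str:
    return " ".join(phrase.casefold().split())


@dataclass
class GlossaryIndex:
    """Normalised phrase → target URL, plus single-word stop list."""

    entries: dict[str, str] = field(default_factory=dict)
    stop_words: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        normalised = {}
        for phrase, target in self.entries.items():
            norm = _normalise(phrase)
            if not 1 <= len(norm.split()) <= _MAX_WINDOW:
                raise ValueError(f"glossary phrase must be 1-{_MAX_WINDOW} words: {phrase!r}")
            normalised[norm] = target
        self.entries = normalised
        self.stop_words = {_normalise(w) for w in self.stop_words}

    @classmethod
    def from_tsv(cls, text: str, stop_words: Sequence[str] = ()) -> "GlossaryIndex":
        """Load a two-column (phrase TAB url) index; '#' lines are comments."""
        entries = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            phrase, _, url = line.partition("\t")
            entries[phrase] = url.strip()
        return cls(entries, set(stop_words))


@dataclass(frozen=True)
class Annotation:
    """A half-open character span linked to a glossary target."""

    span: tuple[int, int]
    phrase: str
    target: str


@dataclass(frozen=True)
class GeometryMention:
    """A typographic geometry reference found in text."""

    kind: str  # distance | angle | torsion | contact
    labels: tuple[str, ...]
    span: tuple[int, int]
    value: Optional[float] = None
    su: Optional[float] = None

    def __post_init__(self) -> None:
        expected = {"distance": 2, "contact": 2, "angle": 3, "torsion": 4}[self.kind]
        if len(self.labels) != expected:
            raise ValueError(f"{self.kind} mention needs {expected} labels")


_WORD_RE = re.compile(r"\S+")


def _core_span(text: str, start: int, end: int) -> tuple[int, int]:
    """Trim edge punctuation from a token, preserving original offsets."""
    while start < end and text[start] in _STRIP_CHARS:
        start += 1
    while end > start and text[end - 1] in _STRIP_CHARS:
        end -= 1
    return start, end


def annotate(text: str, index: GlossaryIndex) -> list[Annotation]:
    """Annotate every glossary occurrence with longest-match semantics.

    A pure function of (text, index): annotations are non-overlapping,
    ordered, and re-running it cannot produce overlapping spans.
    """
    tokens = []
    for m in _WORD_RE.finditer(text):
        s, e = _core_span(text, m.start(), m.end())
        if s < e:
            tokens.append((s, e, _normalise(text[s:e])))
    out: list[Annotation] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for w in range(min(_MAX_WINDOW, n - i), 0, -1):
            words = [tokens[i + k][2] for k in range(w)]
            phrase = " ".join(words)
            target = index.entries.get(phrase)
            if target is None:
                continue
            if w == 1 and phrase in index.stop_words:
                continue
            span = (tokens[i][0], tokens[i + w - 1][1])
            out.append(Annotation(span, text[span[0] : span[1]], target))
            i += w
            matched = True
            break
        if not matched:
            i += 1
    return out


# label grammar generalising observed usage: element symbol, digits, an
# optional disorder suffix letter and optional primes (C4', C221, O1B)
_LABEL = r"[A-Z][a-z]?\d+[A-Z]?[′']*"
_DASH_SEP = r"(?:---|—|–|-)"
_DOT_SEP = r"(?:\.\.\.|…)"
_CHAIN_RE = re.compile(
    rf"(?P<chain>{_LABEL}(?:(?:{_DASH_SEP}|{_DOT_SEP}){_LABEL}){{1,3}})"
    rf"(?P<value>\s*=?\s*\d+\.?\d*\s*\(\d+\))?"
    rf"(?P<unit>\s*(?:Å|°|deg))?"
)
_SPLIT_RE = re.compile(rf"{_DASH_SEP}|{_DOT_SEP}")
_VALUE_RE = re.compile(r"(\d+\.?\d*)\s*\((\d+)\)")


def scan_geometry(text: str) -> list[GeometryMention]:
    """Find typographic geometry references: label chains with separators.

    The kind follows the label count (2 distance, 3 angle, 4 torsion),
    except that a two-label chain joined by the dots convention is a
    non-bonded contact.
    """
    out: list[GeometryMention] = []
    for m in _CHAIN_RE.finditer(text):
        chain = m.group("chain")
        labels = tuple(_SPLIT_RE.split(chain))
        is_contact = bool(re.search(_DOT_SEP, chain))
        if len(labels) == 2:
            kind = "contact" if is_contact else "distance"
        elif len(labels) == 3:
            kind = "angle"
        elif len(labels) == 4:
            kind = "torsion"
        else:
            continue
        value = su = None
        end = m.start() + len(chain)
        if m.group("value"):
            vm = _VALUE_RE.search(m.group("value"))
            if vm:
                mantissa, su_digits = vm.group(1), vm.group(2)
                value = float(mantissa)
                ndec = len(mantissa.split(".", 1)[1]) if "." in mantissa else 0
                su = int(su_digits) * 10.0 ** (-ndec)
                end = m.end("value")
                if m.group("unit"):
                    end = m.end("unit")
        out.append(GeometryMention(kind, labels, (m.start(), end), value, su))
    return out


_TABLE_SPECS = {
    "distance": ("_geom_bond_atom_site_label_", 2, "_geom_bond_distance"),
    "contact": ("_geom_contact_atom_site_label_", 2, "_geom_contact_distance"),
    "angle": ("_geom_angle_atom_site_label_", 3, "_geom_angle"),
    "torsion": ("_geom_torsion_atom_site_label_", 4, "_geom_torsion"),
}


def _table_rows(block: DataBlock, kind: str) -> list[tuple[tuple[str, ...], Optional[float]]]:
    prefix, nlab, value_tag = _TABLE_SPECS[kind]
    loop = block.find_loop(prefix + "1")
    if loop is None:
        return []
    cols = [loop.column(f"{prefix}{i}") for i in range(1, nlab + 1)]
    values = loop.column(value_tag) if loop.has_tag(value_tag) else None
    rows = []
    for r in range(len(loop.rows)):
        labels = tuple(c[r].raw for c in cols)
        rows.append((labels, values[r].value if values else None))
    return rows


def resolve_mentions(
    mentions: Sequence[GeometryMention], block: DataBlock
) -> list[tuple[GeometryMention, list[tuple[tuple[str, ...], Optional[float]]]]]:
    """Bind scanned mentions to tabulated geometry rows of ``block``.

    A row matches when the kinds agree and the label sequences agree
    forwards or reversed.  Mentions with no tabulated counterpart are
    dropped from the actionable output; multiple matches are all returned
    so the reader can select the feature of interest.
    """
    out = []
    tables = {kind: _table_rows(block, kind) for kind in _TABLE_SPECS}
    for mention in mentions:
        matches = [
            (labels, value)
            for labels, value in tables[mention.kind]
            if labels == mention.labels or labels == mention.labels[::-1]
        ]
        if matches:
            out.append((mention, matches))
    return out
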
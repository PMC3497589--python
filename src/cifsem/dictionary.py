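"""Machine-readable CIF dictionaries and dictionary-driven validation.

A CIF dictionary is itself a CIF file: each data block defines one tag,
using a small bootstrap set of attribute tags (a reduction of DDL1):

========================  ====================================================
``_name``                 the tag being defined (begins with ``_``)
``_category``             grouping identifier
``_type``                 ``numb`` or ``char``
``_units``                declared preferred unit (assertion only)
``_enumeration``          allowed value(s); looped when there are several
``_enumeration_range``    closed numeric range as a ``min:max`` string
``_list``                 ``yes`` (must be looped) / ``no`` / ``both``
``_definition``           human-readable prose definition
========================  ====================================================

The bootstrap set is itself defined, in the same syntax, by the shipped
``ddl_bootstrap.dic`` — the dictionary formalism is self-defining.
Validation of a data block against a dictionary yields a deterministic,
document-ordered list of :class:`Violation` findings; the special values
``?`` (unknown) and ``.`` (inapplicable) always satisfy type, enumeration
and range constraints.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .cif_syntax import CifDocument, CifValue, DataBlock, parse_cif

__all__ = [
    "Definition",
    "Dictionary",
    "Violation",
    "parse_dictionary",
    "validate_block",
    "load_bootstrap_dictionary",
    "load_core_dictionary",
]

BOOTSTRAP_ATTRIBUTES = frozenset(
    {
        "_name",
        "_category",
        "_type",
        "_units",
        "_enumeration",
        "_enumeration_range",
        "_list",
        "_definition",
    }
)

_LIST_CONTEXT = {"yes": "required-in-loop", "no": "forbidden-in-loop", "both": "either"}


@dataclass
class Definition:
    """Machine-readable semantics for a single tag."""

    name: str
    category: str = ""
    type_code: str = "char"  # numb | char
    units: Optional[str] = None
    enumeration: Optional[frozenset[str]] = None
    range: Optional[tuple[Optional[float], Optional[float]]] = None
    list_context: str = "either"  # required-in-loop | forbidden-in-loop | either
    definition_text: str = ""

    def __post_init__(self) -> None:
        if not self.name.startswith("_"):
            raise ValueError(f"definition name {self.name!r} must begin with '_'")
        if self.enumeration is not None and self.range is not None:
            raise ValueError(f"{self.name}: enumeration and range are mutually exclusive")
        if self.range is not None and self.type_code != "numb":
            raise ValueError(f"{self.name}: a range requires type 'numb'")
        if self.type_code not in ("numb", "char"):
            raise ValueError(f"{self.name}: unknown type code {self.type_code!r}")


class Dictionary:
    """A set of tag definitions with case-insensitive lookup."""

    def __init__(self, title: str = ""):
        self.title = title
        self._defs: dict[str, Definition] = {}
        self.namespace_prefixes: set[str] = set()

    def add(self, definition: Definition) -> None:
        key = definition.name.lower()
        if key in self._defs:
            raise ValueError(f"duplicate definition for {definition.name!r}")
        self._defs[key] = definition

    def get(self, tag: str) -> Optional[Definition]:
        return self._defs.get(tag.lower())

    def __contains__(self, tag: str) -> bool:
        return tag.lower() in self._defs

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs.values())

    def merge(self, other: "Dictionary") -> None:
        """Add all definitions of ``other``; duplicates are an error."""
        for d in other:
            self.add(d)
        self.namespace_prefixes |= other.namespace_prefixes


@dataclass(frozen=True)
class Violation:
    """A single validation finding (data, not an exception)."""

    tag: str
    block: str
    code: str  # unknown-tag | type-mismatch | enum-violation | range-violation | loop-context
    message: str

    def __str__(self) -> str:
        return f"[{self.code}] {self.block}:{self.tag} — {self.message}"


def _parse_range(text: str) -> tuple[Optional[float], Optional[float]]:
    lo_s, _, hi_s = text.partition(":")
    lo = float(lo_s) if lo_s.strip() else None
    hi = float(hi_s) if hi_s.strip() else None
    return lo, hi


def parse_dictionary(doc: CifDocument) -> Dictionary:
    """Build a :class:`Dictionary` from a parsed dictionary file.

    A block named ``on_this_dictionary`` supplies the title and any
    registered namespace prefixes (``_namespace_prefix`` loop or item);
    every other block must carry a ``_name`` attribute.  Attribute tags
    outside the bootstrap set are preserved in the source but ignored here.
    """
    dictionary = Dictionary()
    for block in doc:
        if block.name.lower() == "on_this_dictionary":
            title = block.get("_dictionary_name")
            if title is not None:
                dictionary.title = title.raw
            ploop = block.find_loop("_namespace_prefix")
            if ploop is not None:
                dictionary.namespace_prefixes |= {
                    v.raw for v in ploop.column("_namespace_prefix")
                }
            elif "_namespace_prefix" in block:
                dictionary.namespace_prefixes.add(block["_namespace_prefix"].raw)
            continue
        name_v = block.get("_name")
        if name_v is None:
            raise ValueError(f"definition block {block.name!r} has no _name attribute")
        enum: Optional[frozenset[str]] = None
        eloop = block.find_loop("_enumeration")
        if eloop is not None:
            enum = frozenset(v.raw for v in eloop.column("_enumeration"))
        elif "_enumeration" in block:
            enum = frozenset({block["_enumeration"].raw})
        rng = None
        if "_enumeration_range" in block:
            rng = _parse_range(block["_enumeration_range"].raw)
        list_raw = block["_list"].raw.lower() if "_list" in block else "both"
        definition = Definition(
            name=name_v.raw,
            category=block["_category"].raw if "_category" in block else "",
            type_code=block["_type"].raw.lower() if "_type" in block else "char",
            units=block["_units"].raw if "_units" in block else None,
            enumeration=enum,
            range=rng,
            list_context=_LIST_CONTEXT.get(list_raw, "either"),
            definition_text=block["_definition"].raw.strip() if "_definition" in block else "",
        )
        dictionary.add(definition)
    return dictionary


def _check_value(
    tag: str, value: CifValue, definition: Definition, block_name: str, in_loop: bool
) -> list[Violation]:
    out: list[Violation] = []
    if value.is_missing:
        return out  # '?' and '.' satisfy all content constraints
    if definition.type_code == "numb" and value.numeric is None:
        out.append(
            Violation(tag, block_name, "type-mismatch",
                      f"value {value.raw!r} is not numeric (type numb)")
        )
        return out
    if definition.enumeration is not None and value.raw not in definition.enumeration:
        allowed = ", ".join(sorted(definition.enumeration))
        out.append(
            Violation(tag, block_name, "enum-violation",
                      f"value {value.raw!r} not in enumeration {{{allowed}}}")
        )
    if definition.range is not None and value.numeric is not None:
        lo, hi = definition.range
        v = value.numeric[0]
        if (lo is not None and v < lo) or (hi is not None and v > hi):
            out.append(
                Violation(tag, block_name, "range-violation",
                          f"value {v} outside closed range {lo}:{hi}")
            )
    return out


def validate_block(
    block: DataBlock, dictionary: Dictionary, strict_unknown: bool = False
) -> list[Violation]:
    """Validate one data block against a dictionary.

    Findings are returned in document order: single items first, then loop
    columns, each checked for unknown tags (only when ``strict_unknown``),
    type, enumeration, range and loop context.  Validation is pure and
    order-stable.
    """
    out: list[Violation] = []
    for tag, value in block.items():
        definition = dictionary.get(tag)
        if definition is None:
            if strict_unknown:
                out.append(Violation(tag, block.name, "unknown-tag",
                                     "tag not defined in dictionary"))
            continue
        if definition.list_context == "required-in-loop":
            out.append(Violation(tag, block.name, "loop-context",
                                 "tag must appear in a loop"))
        out.extend(_check_value(tag, value, definition, block.name, in_loop=False))
    for loop in block.loops:
        for tag in loop.tags:
            definition = dictionary.get(tag)
            if definition is None:
                if strict_unknown:
                    out.append(Violation(tag, block.name, "unknown-tag",
                                         "tag not defined in dictionary"))
                continue
            if definition.list_context == "forbidden-in-loop":
                out.append(Violation(tag, block.name, "loop-context",
                                     "tag may not appear in a loop"))
            for value in loop.column(tag):
                out.extend(_check_value(tag, value, definition, block.name, in_loop=True))
    return out


def _load_packaged(name: str) -> CifDocument:
    text = resources.files("cifsem.data").joinpath(name).read_text()
    return parse_cif(text)


def load_bootstrap_dictionary() -> Dictionary:
    """The self-defining dictionary of the bootstrap attribute tags."""
    return parse_dictionary(_load_packaged("ddl_bootstrap.dic"))


def load_core_dictionary() -> Dictionary:
    """Core crystallographic tag definitions (cell, symmetry, sites, geometry)."""
    return parse_dictionary(_load_packaged("cifsem_core.dic"))
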
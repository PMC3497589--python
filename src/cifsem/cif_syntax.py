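"""Reading and writing the CIF tag-value/loop interchange format.

The Crystallographic Information File is a free-form, ASCII-only format in
which a *tag* (a token beginning with an underscore) is separated from its
*value* by white space, and tabular data are expressed as a ``loop_`` header
of tags followed by the interleaved values.  Values are character strings,
but a string that lexes as a number is interpreted numerically, and a
trailing parenthesised integer encodes the standard uncertainty (su) in
units of the place value of the last mantissa digit: ``5.12(3)`` means
5.12 with su 0.03.

This module implements the classic CIF 1.1 lexical conventions: single- and
double-quoted strings, semicolon-delimited multi-line text blocks, ``#``
comments, and the special values ``?`` (unknown) and ``.`` (inapplicable).
Layout is not significant outside quoted regions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "CifValue",
    "Loop",
    "DataBlock",
    "CifDocument",
    "CifParseError",
    "CifWriteError",
    "lex_number",
    "make_value",
    "parse_cif",
    "write_cif",
]


class CifParseError(ValueError):
    """Raised for malformed CIF input; carries a 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CifWriteError(ValueError):
    """Raised when a document cannot be serialised as ASCII CIF."""


# Number grammar: integer / decimal / exponential mantissa, with an optional
# parenthesised trailing integer su.  Combining an exponent with an su
# (e.g. "1.2e3(4)") is accepted as an extension of common practice.
_NUMBER_RE = re.compile(
    r"""^
    (?P<sign>[+-]?)
    (?P<mantissa>\d+\.?\d*|\.\d+)
    (?:[eE](?P<exp>[+-]?\d+))?
    (?:\((?P<su>\d+)\))?
    $""",
    re.VERBOSE,
)


def lex_number(token: str) -> Optional[tuple[float, Optional[float]]]:
    """Lex a bare token as a number, returning ``(value, su)`` or ``None``.

    The su of ``1.234(5)`` is ``5`` times the place value of the last
    mantissa digit, i.e. 0.005.  Non-numeric tokens return ``None``;
    the function never raises.
    """
    m = _NUMBER_RE.match(token)
    if m is None:
        return None
    mantissa = m.group("mantissa")
    exp = int(m.group("exp")) if m.group("exp") else 0
    try:
        value = float(m.group("sign") + mantissa) * 10.0 ** exp
    except OverflowError:
        return None
    su: Optional[float] = None
    if m.group("su") is not None:
        ndec = len(mantissa.split(".", 1)[1]) if "." in mantissa else 0
        su = int(m.group("su")) * 10.0 ** (exp - ndec)
    return value, su


@dataclass(frozen=True)
class CifValue:
    """A single CIF value with its lexical interpretation.

    ``kind`` is one of ``string``, ``text-block``, ``unknown`` (``?``) or
    ``inapplicable`` (``.``); ``numeric`` is ``(value, su)`` when the raw
    token lexes as a number, else ``None``.  Quoted strings and text blocks
    are never numeric.
    """

    raw: str
    kind: str = "string"
    numeric: Optional[tuple[float, Optional[float]]] = None

    @property
    def value(self) -> Optional[float]:
        return self.numeric[0] if self.numeric else None

    @property
    def su(self) -> Optional[float]:
        return self.numeric[1] if self.numeric else None

    @property
    def is_missing(self) -> bool:
        return self.kind in ("unknown", "inapplicable")

    def __repr__(self) -> str:  # compact for test diffs
        return f"CifValue({self.raw!r}, {self.kind})"


def make_value(raw: str, quoted: bool = False) -> CifValue:
    """Build a :class:`CifValue`, applying the lexical typing rules."""
    if not raw.isascii():
        raise CifWriteError(f"non-ASCII value: {raw!r}")
    if "\n" in raw:
        return CifValue(raw, "text-block")
    if not quoted:
        if raw == "?":
            return CifValue(raw, "unknown")
        if raw == ".":
            return CifValue(raw, "inapplicable")
        num = lex_number(raw)
        if num is not None:
            return CifValue(raw, "string", num)
    return CifValue(raw, "string")


@dataclass
class Loop:
    """A looped table: a tag header plus rows of values."""

    tags: list[str]
    rows: list[tuple[CifValue, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lowered = [t.lower() for t in self.tags]
        if len(set(lowered)) != len(lowered):
            raise ValueError("duplicate tag within a loop header")
        for t in self.tags:
            if not t.startswith("_"):
                raise ValueError(f"loop tag {t!r} must begin with '_'")
        for row in self.rows:
            if len(row) != len(self.tags):
                raise ValueError("loop row length does not match header")

    def column(self, tag: str) -> list[CifValue]:
        idx = [t.lower() for t in self.tags].index(tag.lower())
        return [row[idx] for row in self.rows]

    def has_tag(self, tag: str) -> bool:
        return tag.lower() in (t.lower() for t in self.tags)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Loop):
            return NotImplemented
        return (
            [t.lower() for t in self.tags] == [t.lower() for t in other.tags]
            and self.rows == other.rows
        )


class DataBlock:
    """An ordered container of single items and loops under one block name.

    Tags are compared case-insensitively but stored as given; a tag may
    appear at most once across the single items and all loop headers.
    """

    def __init__(self, name: str):
        self.name = name
        self._items: dict[str, tuple[str, CifValue]] = {}  # lower -> (as-given, value)
        self.loops: list[Loop] = []

    # -- single items ------------------------------------------------------
    def set_item(self, tag: str, value: CifValue) -> None:
        if not tag.startswith("_"):
            raise ValueError(f"tag {tag!r} must begin with '_'")
        key = tag.lower()
        if key in self._items or any(l.has_tag(tag) for l in self.loops):
            raise ValueError(f"duplicate tag {tag!r} in block {self.name!r}")
        self._items[key] = (tag, value)

    def __contains__(self, tag: str) -> bool:
        return tag.lower() in self._items

    def __getitem__(self, tag: str) -> CifValue:
        return self._items[tag.lower()][1]

    def get(self, tag: str, default: Optional[CifValue] = None) -> Optional[CifValue]:
        entry = self._items.get(tag.lower())
        return entry[1] if entry else default

    def remove_item(self, tag: str) -> None:
        del self._items[tag.lower()]

    def replace_item(self, tag: str, value: CifValue) -> None:
        key = tag.lower()
        as_given = self._items[key][0] if key in self._items else tag
        self._items[key] = (as_given, value)

    def items(self) -> Iterator[tuple[str, CifValue]]:
        for as_given, value in self._items.values():
            yield as_given, value

    # -- loops -------------------------------------------------------------
    def add_loop(self, loop: Loop) -> None:
        for t in loop.tags:
            if t.lower() in self._items or any(l.has_tag(t) for l in self.loops):
                raise ValueError(f"duplicate tag {t!r} in block {self.name!r}")
        self.loops.append(loop)

    def find_loop(self, tag: str) -> Optional[Loop]:
        for loop in self.loops:
            if loop.has_tag(tag):
                return loop
        return None

    def remove_loop(self, loop: Loop) -> None:
        self.loops.remove(loop)

    def tags(self) -> list[str]:
        out = [t for t, _ in self.items()]
        for loop in self.loops:
            out.extend(loop.tags)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataBlock):
            return NotImplemented
        mine = {k: v for k, (_, v) in self._items.items()}
        theirs = {k: v for k, (_, v) in other._items.items()}
        return self.name == other.name and mine == theirs and self.loops == other.loops

    def __repr__(self) -> str:
        return f"DataBlock({self.name!r}, {len(self._items)} items, {len(self.loops)} loops)"


class CifDocument:
    """An ordered collection of uniquely named data blocks."""

    def __init__(self, blocks: Optional[Iterable[DataBlock]] = None):
        self.blocks: list[DataBlock] = []
        for b in blocks or []:
            self.add_block(b)

    def add_block(self, block: DataBlock) -> None:
        if any(b.name == block.name for b in self.blocks):
            raise ValueError(f"duplicate block name {block.name!r}")
        self.blocks.append(block)

    def __getitem__(self, name: str) -> DataBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def __iter__(self) -> Iterator[DataBlock]:
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CifDocument):
            return NotImplemented
        return self.blocks == other.blocks


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

@dataclass
class _Token:
    kind: str  # DATA, LOOP, TAG, VALUE
    text: str
    quoted: bool
    line: int


def _tokenize(text: str) -> Iterator[_Token]:
    if not text.isascii():
        raise CifParseError("CIF input must be ASCII")
    lines = text.split("\n")
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        lineno = i + 1
        if line.startswith(";"):
            # semicolon text block: runs to the next line starting with ';'
            body = [line[1:]]
            j = i + 1
            while j < n and not lines[j].startswith(";"):
                body.append(lines[j])
                j += 1
            if j >= n:
                raise CifParseError("unterminated text block", lineno)
            # the value is everything between the opening ';' and the
            # closing line's ';' — an exact convention that round-trips
            content = "\n".join(body)
            yield _Token("VALUE", content, True, lineno)
            # anything after the closing ';' on the same line is ignored per CIF 1.1
            i = j + 1
            continue
        pos = 0
        length = len(line)
        while pos < length:
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break  # comment to end of line
            if ch in "'\"":
                quote = ch
                end = pos + 1
                while True:
                    end = line.find(quote, end)
                    if end == -1:
                        raise CifParseError("unterminated quoted string", lineno)
                    # a quote terminates only when followed by white space or EOL
                    if end + 1 >= length or line[end + 1] in " \t":
                        break
                    end += 1
                yield _Token("VALUE", line[pos + 1 : end], True, lineno)
                pos = end + 1
                continue
            end = pos
            while end < length and line[end] not in " \t":
                end += 1
            token = line[pos:end]
            lower = token.lower()
            if lower.startswith("data_"):
                yield _Token("DATA", token[5:], False, lineno)
            elif lower == "loop_":
                yield _Token("LOOP", token, False, lineno)
            elif token.startswith("_"):
                yield _Token("TAG", token, False, lineno)
            else:
                yield _Token("VALUE", token, False, lineno)
            pos = end
        i += 1


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

def parse_cif(text: str) -> CifDocument:
    """Parse CIF text into a :class:`CifDocument`.

    Layout and white space outside quoted regions carry no meaning;
    comments are discarded.  Duplicate tags within a block, unterminated
    strings and ragged loops raise :class:`CifParseError` with a line
    number.
    """
    doc = CifDocument()
    block: Optional[DataBlock] = None
    tokens = list(_tokenize(text))
    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if tok.kind == "DATA":
            if tok.text == "":
                raise CifParseError("empty data block name", tok.line)
            block = DataBlock(tok.text)
            try:
                doc.add_block(block)
            except ValueError as exc:
                raise CifParseError(str(exc), tok.line) from None
            i += 1
        elif tok.kind == "TAG":
            if block is None:
                raise CifParseError(f"tag {tok.text!r} outside any data block", tok.line)
            if i + 1 >= n or tokens[i + 1].kind != "VALUE":
                raise CifParseError(f"tag {tok.text!r} has no value", tok.line)
            val = tokens[i + 1]
            try:
                block.set_item(tok.text, make_value(val.text, val.quoted))
            except ValueError as exc:
                raise CifParseError(str(exc), tok.line) from None
            i += 2
        elif tok.kind == "LOOP":
            if block is None:
                raise CifParseError("loop_ outside any data block", tok.line)
            i += 1
            tags: list[str] = []
            while i < n and tokens[i].kind == "TAG":
                tags.append(tokens[i].text)
                i += 1
            if not tags:
                raise CifParseError("loop_ with no tags", tok.line)
            values: list[CifValue] = []
            while i < n and tokens[i].kind == "VALUE":
                values.append(make_value(tokens[i].text, tokens[i].quoted))
                i += 1
            if len(values) % len(tags) != 0:
                raise CifParseError(
                    f"loop body of {len(values)} values is not a multiple of "
                    f"{len(tags)} tags",
                    tok.line,
                )
            rows = [
                tuple(values[j : j + len(tags)])
                for j in range(0, len(values), len(tags))
            ]
            try:
                block.add_loop(Loop(tags, rows))
            except ValueError as exc:
                raise CifParseError(str(exc), tok.line) from None
        else:
            raise CifParseError(f"unexpected value {tok.text!r}", tok.line)
    return doc


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------

_NEEDS_QUOTE_RE = re.compile(r"[\s'\"]")


def _needs_quoting(value: CifValue) -> bool:
    raw = value.raw
    if raw == "":
        return True
    if value.kind in ("unknown", "inapplicable"):
        return False
    if _NEEDS_QUOTE_RE.search(raw):
        return True
    if raw[0] in "_#$[];":
        return True
    lower = raw.lower()
    if lower.startswith("data_") or lower in ("loop_", "stop_", "global_", "save_"):
        return True
    # a string that would lex as a number, or as ?/., must be quoted to
    # survive a round trip as a plain string
    if value.numeric is None and (lex_number(raw) is not None or raw in "?."):
        return True
    return False


def _format_value(value: CifValue) -> str:
    raw = value.raw
    if not raw.isascii():
        raise CifWriteError(f"non-ASCII value: {raw!r}")
    if value.kind == "text-block" or "\n" in raw:
        for ln in raw.split("\n"):
            if ln.startswith(";"):
                raise CifWriteError(
                    "text-block line may not begin with ';' (would terminate the block)"
                )
        return f"\n;{raw}\n;\n" if not raw.startswith("\n") else f"\n;{raw}\n;\n"
    if _needs_quoting(value):
        if "'" not in raw:
            return f"'{raw}'"
        if '"' not in raw:
            return f'"{raw}"'
        raise CifWriteError(f"value contains both quote characters: {raw!r}")
    return raw


def write_cif(doc: CifDocument) -> str:
    """Serialise a document to CIF text; ``parse_cif`` inverts it exactly.

    Values containing white space are quoted, multi-line values become
    semicolon text blocks, and lines are wrapped at 80 columns where the
    token structure allows.
    """
    out: list[str] = []
    for block in doc.blocks:
        out.append(f"data_{block.name}")
        width = max((len(t) for t, _ in block.items()), default=0)
        for tag, value in block.items():
            formatted = _format_value(value)
            if formatted.startswith("\n"):
                out.append(f"{tag}{formatted.rstrip()}")
            else:
                line = f"{tag:<{width}} {formatted}"
                if len(line) > 80:
                    line = f"{tag}\n  {formatted}"
                out.append(line)
        for loop in block.loops:
            out.append("loop_")
            out.extend(f"  {t}" for t in loop.tags)
            for row in loop.rows:
                parts = [_format_value(v) for v in row]
                if any(p.startswith("\n") for p in parts):
                    # text blocks interrupt the packed row layout
                    buf = ""
                    for p in parts:
                        if p.startswith("\n"):
                            if buf:
                                out.append("  " + buf.rstrip())
                                buf = ""
                            out.append(p.strip("\n"))  # ";...\n;"
                        else:
                            buf += p + " "
                    if buf:
                        out.append("  " + buf.rstrip())
                else:
                    line = "  " + " ".join(parts)
                    if len(line) > 80:
                        # wrap between tokens
                        wrapped: list[str] = []
                        cur = " "
                        for p in parts:
                            if len(cur) + 1 + len(p) > 80 and cur.strip():
                                wrapped.append(cur)
                                cur = " "
                            cur += " " + p
                        wrapped.append(cur)
                        out.extend(wrapped)
                    else:
                        out.append(line)
        out.append("")
    text = "\n".join(out)
    if not text.isascii():
        raise CifWriteError("document contains non-ASCII content")
    return text + ("\n" if text and not text.endswith("\n") else "")
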
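"""Shared fixtures and random generators for the test suite."""

from __future__ import annotations

import string

import numpy as np
import pytest

from cifsem.cif_syntax import CifDocument, DataBlock, Loop, make_value
from cifsem.dictionary import load_bootstrap_dictionary, load_core_dictionary
from cifsem.fixtures import FixtureSpec, generate_structure

_WORD_CHARS = string.ascii_letters + string.digits + "._-+()[]{}:;,/\\%*"


def random_value(rng: np.random.RandomState):
    """A random CIF value spanning the lexical space of the format."""
    kind = rng.randint(8)
    if kind == 0:
        return make_value("?")
    if kind == 1:
        return make_value(".")
    if kind == 2:  # number, possibly with su / exponent
        mant = f"{rng.uniform(-1e3, 1e3):.{rng.randint(0, 6)}f}"
        if rng.rand() < 0.3:
            mant += f"({rng.randint(1, 99)})"
        return make_value(mant)
    if kind == 3:  # bare word
        n = rng.randint(1, 12)
        return make_value("".join(rng.choice(list(_WORD_CHARS.replace(";", ""))) for _ in range(n)))
    if kind == 4:  # quoted string with internal spaces
        words = [
            "".join(rng.choice(list(_WORD_CHARS))) for _ in range(rng.randint(1, 4))
        ]
        quote = "'" if rng.rand() < 0.5 else '"'
        other = '"' if quote == "'" else "'"
        text = " ".join(w.replace(quote, other) for w in words)
        return make_value(text, quoted=True)
    if kind == 5:  # string that would lex as a number: must stay a string
        return make_value(f"{rng.randint(0, 999)}", quoted=True)
    if kind == 6:  # multi-line text block
        lines = [
            " ".join(
                "".join(rng.choice(list(_WORD_CHARS.replace(";", ""))) for _ in range(rng.randint(1, 8)))
                for _ in range(rng.randint(1, 4))
            )
            for _ in range(rng.randint(2, 5))
        ]
        return make_value("\n".join(lines))
    return make_value("sym_" + "".join(rng.choice(list(string.ascii_lowercase)) for _ in range(5)))


def random_tag(rng: np.random.RandomState, used: set[str]) -> str:
    while True:
        tag = "_" + "".join(
            rng.choice(list(string.ascii_lowercase + string.digits + "_."))
            for _ in range(rng.randint(3, 15))
        )
        if tag.lower() not in used:
            used.add(tag.lower())
            return tag


def random_document(rng: np.random.RandomState) -> CifDocument:
    doc = CifDocument()
    for bi in range(rng.randint(1, 4)):
        block = DataBlock(f"block_{bi}_{rng.randint(10**6)}")
        used: set[str] = set()
        for _ in range(rng.randint(0, 8)):
            block.set_item(random_tag(rng, used), random_value(rng))
        for _ in range(rng.randint(0, 3)):
            tags = [random_tag(rng, used) for _ in range(rng.randint(1, 5))]
            rows = [
                tuple(random_value(rng) for _ in tags)
                for _ in range(rng.randint(1, 6))
            ]
            block.add_loop(Loop(tags, rows))
        doc.add_block(block)
    return doc


@pytest.fixture(scope="session")
def core_dict():
    return load_core_dictionary()


@pytest.fixture(scope="session")
def bootstrap_dict():
    return load_bootstrap_dictionary()


@pytest.fixture(scope="session")
def clean_block():
    return generate_structure(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def disorder_block():
    return generate_structure(FixtureSpec(seed=11, disorder=True))
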
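"""Deriving missing data items from related items in the same block.

A :class:`Method` is a registered executable rule: given resolved values
for its input tags it computes the value of one output tag.  The registry
(:class:`DerivationGraph`) resolves dependencies recursively with a
*stored-first* policy — a value present in the file always wins, and
derivation only fills gaps.  A separate consistency pass compares stored
values with what the methods would derive, to surface discrepancies
between the file and its own internal relationships.

The shipped default registry knows the cell volume, the reciprocal cell
lengths, the diffraction density from formula weight / Z / volume, and
F(000) from the formula sum — each expressed purely over tag values.

Standard uncertainties are not propagated through derivations.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

from .cif_syntax import CifValue, DataBlock, make_value
from .geometry import UnitCell, cell_volume

__all__ = [
    "Method",
    "DerivationGraph",
    "DerivationError",
    "derive_item",
    "check_consistency",
    "default_graph",
    "ATOMIC_NUMBERS",
    "ATOMIC_WEIGHTS",
]


class DerivationError(KeyError):
    """An item is absent and cannot be derived; lists the missing leaves."""

    def __init__(self, tag: str, missing: list[str]):
        self.tag = tag
        self.missing = missing
        super().__init__(
            f"{tag} is underivable; missing leaf items: {', '.join(missing)}"
        )


@dataclass(frozen=True)
class Method:
    """A pure derivation rule: ``output = compute(**{tag: value})``."""

    output: str
    inputs: tuple[str, ...]
    compute: Callable[[Mapping[str, float]], float]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.inputs:
            raise ValueError(f"method for {self.output} must have inputs")
        if self.output.lower() in (t.lower() for t in self.inputs):
            raise ValueError(f"method output {self.output} appears among its inputs")


class DerivationGraph:
    """Registry of methods keyed by output tag; the dependency DAG is acyclic."""

    def __init__(self) -> None:
        self.methods: dict[str, Method] = {}

    def register(self, method: Method) -> None:
        key = method.output.lower()
        if key in self.methods:
            raise ValueError(f"a method for {method.output} is already registered")
        self.methods[key] = method
        if self._has_cycle():
            del self.methods[key]
            raise ValueError(f"registering a method for {method.output} creates a cycle")

    def get(self, tag: str) -> Optional[Method]:
        return self.methods.get(tag.lower())

    def _has_cycle(self) -> bool:
        WHITE, GREY, BLACK = 0, 1, 2
        colour: dict[str, int] = {}

        def visit(tag: str) -> bool:
            state = colour.get(tag, 0)
            if state == GREY:
                return True
            if state == BLACK:
                return False
            colour[tag] = GREY
            m = self.methods.get(tag)
            if m is not None:
                for inp in m.inputs:
                    if visit(inp.lower()):
                        return True
            colour[tag] = BLACK
            return False

        return any(visit(t) for t in list(self.methods))


@dataclass
class Derived:
    """A derivation result with provenance."""

    tag: str
    value: CifValue
    provenance: str  # "stored" | "derived"
    inputs: tuple[str, ...] = ()
    trail: dict[str, str] = field(default_factory=dict)  # tag -> stored/derived


def _resolve(
    block: DataBlock,
    tag: str,
    graph: DerivationGraph,
    memo: dict[str, Derived],
    stack: tuple[str, ...] = (),
) -> Derived:
    key = tag.lower()
    if key in memo:
        return memo[key]
    stored = block.get(tag)
    if stored is not None and not stored.is_missing:
        result = Derived(tag, stored, "stored")
        memo[key] = result
        return result
    method = graph.get(tag)
    if method is None:
        raise DerivationError(tag, [tag])
    missing: list[str] = []
    values: dict[str, float] = {}
    trail: dict[str, str] = {}
    for inp in method.inputs:
        try:
            sub = _resolve(block, inp, graph, memo, stack + (key,))
        except DerivationError as exc:
            missing.extend(exc.missing)
            continue
        trail[inp] = sub.provenance
        trail.update(sub.trail)
        # numeric tags resolve to floats, character tags to their raw string
        values[inp] = sub.value.value if sub.value.value is not None else sub.value.raw
    if missing:
        raise DerivationError(tag, missing)
    computed = method.compute(values)
    result = Derived(
        tag,
        make_value(repr(float(computed))),
        "derived",
        inputs=method.inputs,
        trail=trail,
    )
    memo[key] = result
    return result


def derive_item(block: DataBlock, tag: str, graph: DerivationGraph) -> Derived:
    """Return the stored value of ``tag``, or derive it from related items.

    Resolution is recursive and stored-first: a value present in the block
    is never overridden.  Results are memoised within the call.  When the
    tag is absent and no chain of methods can supply it, a
    :class:`DerivationError` names the missing leaf tags.
    """
    return _resolve(block, tag, graph, memo={})


def check_consistency(
    block: DataBlock, graph: DerivationGraph, rel_tol: float = 1e-6
) -> list[tuple[str, float, float, float]]:
    """Compare stored values against their derived counterparts.

    For every registered output tag that is both stored in the block and
    derivable from the *other* stored items, report
    ``(tag, stored, derived, relative_discrepancy)`` whenever the relative
    discrepancy exceeds ``rel_tol``.  Purely diagnostic: stored values are
    never replaced.
    """
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    reports: list[tuple[str, float, float, float]] = []
    for key, method in sorted(graph.methods.items()):
        stored = block.get(method.output)
        if stored is None or stored.value is None:
            continue
        memo: dict[str, Derived] = {}
        try:
            values = {}
            for inp in method.inputs:
                sub = _resolve(block, inp, graph, memo)
                values[inp] = (
                    sub.value.value if sub.value.value is not None else sub.value.raw
                )
            derived = method.compute(values)
        except DerivationError:
            continue
        denom = max(abs(derived), 1e-30)
        rel = abs(stored.value - derived) / denom
        if rel > rel_tol:
            reports.append((method.output, stored.value, float(derived), rel))
    return reports


# ---------------------------------------------------------------------------
# Shipped methods
# ---------------------------------------------------------------------------

ATOMIC_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "Cl": 17}
ATOMIC_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "Cl": 35.45}

_FORMULA_TERM = re.compile(r"([A-Z][a-z]?)(\d*)")

_CELL_INPUTS = (
    "_cell_length_a",
    "_cell_length_b",
    "_cell_length_c",
    "_cell_angle_alpha",
    "_cell_angle_beta",
    "_cell_angle_gamma",
)


def parse_formula_sum(formula: str) -> dict[str, int]:
    """Parse a Hill-order formula sum such as ``'C2 H6 Cl O'`` into counts."""
    counts: dict[str, int] = {}
    for token in formula.split():
        m = _FORMULA_TERM.fullmatch(token)
        if m is None:
            raise ValueError(f"malformed formula term {token!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    return counts


def _cell_from_values(v: Mapping[str, float]) -> UnitCell:
    return UnitCell(*(v[t] for t in _CELL_INPUTS))


def _volume(v: Mapping[str, float]) -> float:
    return cell_volume(_cell_from_values(v))


def _reciprocal(which: str) -> Callable[[Mapping[str, float]], float]:
    # a* = bc sin(alpha) / V and cyclic permutations
    perm = {
        "a": ("_cell_length_b", "_cell_length_c", "_cell_angle_alpha"),
        "b": ("_cell_length_c", "_cell_length_a", "_cell_angle_beta"),
        "c": ("_cell_length_a", "_cell_length_b", "_cell_angle_gamma"),
    }[which]

    def compute(v: Mapping[str, float]) -> float:
        vol = cell_volume(_cell_from_values(v))
        return v[perm[0]] * v[perm[1]] * math.sin(math.radians(v[perm[2]])) / vol

    return compute


_AMU_PER_A3_TO_G_PER_CM3 = 1.66053906660  # 1 u/Å³ in g/cm³


def default_graph() -> DerivationGraph:
    """The shipped derivation registry."""
    g = DerivationGraph()
    g.register(
        Method(
            "_cell_volume",
            _CELL_INPUTS,
            _volume,
            "cell volume from the six cell parameters",
        )
    )
    for axis in "abc":
        g.register(
            Method(
                f"_cell_reciprocal_length_{axis}",
                _CELL_INPUTS,
                _reciprocal(axis),
                f"reciprocal {axis}* length from the cell parameters",
            )
        )
    g.register(
        Method(
            "_exptl_crystal_density_diffrn",
            ("_chemical_formula_weight", "_cell_formula_units_Z", "_cell_volume"),
            lambda v: _AMU_PER_A3_TO_G_PER_CM3
            * v["_chemical_formula_weight"]
            * v["_cell_formula_units_Z"]
            / v["_cell_volume"],
            "calculated density from formula weight, Z and cell volume",
        )
    )
    g.register(
        Method(
            "_chemical_formula_weight",
            ("_chemical_formula_sum",),
            lambda v: sum(
                ATOMIC_WEIGHTS[el] * n
                for el, n in parse_formula_sum(v["_chemical_formula_sum"]).items()
            ),
            "formula weight in daltons from the Hill formula sum",
        )
    )
    g.register(
        Method(
            "_exptl_crystal_F_000",
            ("_chemical_formula_sum", "_cell_formula_units_Z"),
            lambda v: v["_cell_formula_units_Z"]
            * sum(
                ATOMIC_NUMBERS[el] * n
                for el, n in parse_formula_sum(v["_chemical_formula_sum"]).items()
            ),
            "F(000): electrons per cell from the formula sum and Z",
        )
    )
    return g
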
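"""Chemical connectivity inferred from the crystallographic model.

Two sites are bonded when their minimum-image distance does not exceed
the sum of their covalent radii plus a tolerance (default 0.40 Å over
the Cordero radii shipped as package data).  Bonds between different
disorder groups of the same assembly are suppressed — such sites are
mutually exclusive alternative locations, not simultaneous neighbours.
Bond orders are left unassigned by inference: assigning them is an
explicit editing step for the author, and automatic order perception for
complex metal-organic or polymeric cases is out of scope.

The graph supports moiety (connected-component) extraction, Hill-order
molecular formulas, and round-trip serialisation to the chemical
connectivity loops of the CIF.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .cif_syntax import DataBlock, Loop, make_value
from .geometry import AtomSite, SymOp, UnitCell, orthogonalization

__all__ = [
    "Bond",
    "ConnectivityGraph",
    "DEFAULT_RADII",
    "infer_bonds",
    "moieties",
    "molecular_formula",
    "write_connection_table",
    "read_connection_table",
]


def _load_radii() -> dict[str, float]:
    text = resources.files("cifsem.data").joinpath("covalent_radii.json").read_text()
    return json.loads(text)


DEFAULT_RADII: dict[str, float] = _load_radii()

_BOND_TYPE_CODES = {"single": "sing", "double": "doub", "triple": "trip", "unassigned": "."}
_BOND_TYPE_NAMES = {v: k for k, v in _BOND_TYPE_CODES.items()}


@dataclass(frozen=True)
class Bond:
    """An unordered bond between two labelled sites."""

    atom1: str
    atom2: str
    length: float
    order: str = "unassigned"  # single | double | triple | unassigned

    def __post_init__(self) -> None:
        if self.atom1 == self.atom2:
            raise ValueError("a bond cannot join an atom to itself")
        if self.order not in _BOND_TYPE_CODES:
            raise ValueError(f"unknown bond order {self.order!r}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.atom1, self.atom2))


@dataclass
class ConnectivityGraph:
    atoms: list[AtomSite]
    bonds: list[Bond] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = {a.label for a in self.atoms}
        pairs = set()
        for b in self.bonds:
            if b.atom1 not in labels or b.atom2 not in labels:
                raise ValueError(f"bond {b.atom1}-{b.atom2} cites an unknown label")
            if b.pair in pairs:
                raise ValueError(f"duplicate bond {b.atom1}-{b.atom2}")
            pairs.add(b.pair)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.label, site=a)
        for b in self.bonds:
            g.add_edge(b.atom1, b.atom2, length=b.length, order=b.order)
        return g


def _suppressed(a: AtomSite, b: AtomSite) -> bool:
    return (
        a.disorder_assembly is not None
        and a.disorder_assembly == b.disorder_assembly
        and a.disorder_group is not None
        and b.disorder_group is not None
        and a.disorder_group != b.disorder_group
    )


def infer_bonds(
    cell: UnitCell,
    sites: Sequence[AtomSite],
    radii: Optional[Mapping[str, float]] = None,
    tol: float = 0.40,
    expand_symmetry: bool = False,
    ops: Sequence[SymOp] = (),
) -> ConnectivityGraph:
    """Perceive bonds from coordinates and covalent radii.

    A pair is bonded when its minimum-image distance (and, with
    ``expand_symmetry``, the distance to any symmetry image within one
    shell of neighbouring cells) is at most ``r1 + r2 + tol``.  Pairs in
    different disorder groups of one assembly are never bonded.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    radii = radii if radii is not None else DEFAULT_RADII
    for s in sites:
        if s.element not in radii:
            raise KeyError(f"no covalent radius for element {s.element!r}")
    m = orthogonalization(cell)
    frac = np.array([s.frac for s in sites], dtype=float)

    def min_image_dist(df: np.ndarray) -> float:
        df = df - np.round(df)
        best = np.inf
        # the rounded image is not always the nearest in oblique cells;
        # scan the surrounding shell
        for shift in product((-1.0, 0.0, 1.0), repeat=3):
            d = m @ (df + np.array(shift))
            best = min(best, float(np.linalg.norm(d)))
        return best

    bonds: list[Bond] = []
    n = len(sites)
    for i in range(n):
        for j in range(i + 1, n):
            if _suppressed(sites[i], sites[j]):
                continue
            cutoff = radii[sites[i].element] + radii[sites[j].element] + tol
            dist = min_image_dist(frac[j] - frac[i])
            if expand_symmetry and ops:
                for op in ops:
                    dist = min(dist, min_image_dist(op.apply(frac[j]) - frac[i]))
            if 1e-6 < dist <= cutoff:
                bonds.append(Bond(sites[i].label, sites[j].label, dist))
    return ConnectivityGraph(list(sites), bonds)


def moieties(graph: ConnectivityGraph) -> list[list[AtomSite]]:
    """Split the graph into discrete chemical units (connected components).

    Components are ordered largest first, ties broken by the lexically
    smallest label, and atoms within a component are label-sorted.
    """
    if not graph.atoms:
        return []
    g = graph.to_networkx()
    by_label = {a.label: a for a in graph.atoms}
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return [[by_label[l] for l in comp] for comp in comps]


def molecular_formula(component: Sequence[AtomSite]) -> str:
    """Hill-order formula with occupancy-weighted, integer-rounded counts.

    Carbon first, hydrogen second, remaining elements alphabetical;
    elements whose weighted count rounds below 1 are dropped.
    """
    weighted: dict[str, float] = {}
    for a in component:
        weighted[a.element] = weighted.get(a.element, 0.0) + a.occupancy
    counts = {el: round(w) for el, w in weighted.items() if round(w) >= 1}
    if not counts:
        return ""

    def hill_key(el: str) -> tuple[int, str]:
        return {"C": (0, ""), "H": (1, "")}.get(el, (2, el))

    parts = []
    for el in sorted(counts, key=hill_key):
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return " ".join(parts)


_ATOM_TAGS = (
    "_chemical_conn_atom_number",
    "_chemical_conn_atom_label",
    "_chemical_conn_atom_type_symbol",
)
_BOND_TAGS = (
    "_chemical_conn_bond_atom_1",
    "_chemical_conn_bond_atom_2",
    "_chemical_conn_bond_type",
)


def write_connection_table(block: DataBlock, graph: ConnectivityGraph) -> DataBlock:
    """Serialise the graph into the chemical connectivity loops of ``block``.

    Atoms are numbered in list order; bonds reference those numbers and
    carry the core bond-type codes (``.`` for unassigned order).  An
    existing connection table is replaced with a warning.  The empty graph
    emits no loops.  Modifies and returns ``block``.
    """
    for tag in ("_chemical_conn_atom_number", "_chemical_conn_bond_atom_1"):
        existing = block.find_loop(tag)
        if existing is not None:
            warnings.warn(
                f"replacing existing connection table in block {block.name!r}",
                stacklevel=2,
            )
            block.remove_loop(existing)
    if not graph.atoms:
        return block
    number = {a.label: i + 1 for i, a in enumerate(graph.atoms)}
    atom_rows = [
        (
            make_value(str(number[a.label])),
            make_value(a.label),
            make_value(a.element),
        )
        for a in graph.atoms
    ]
    block.add_loop(Loop(list(_ATOM_TAGS), atom_rows))
    if graph.bonds:
        bond_rows = [
            (
                make_value(str(number[b.atom1])),
                make_value(str(number[b.atom2])),
                make_value(_BOND_TYPE_CODES[b.order]),
            )
            for b in graph.bonds
        ]
        block.add_loop(Loop(list(_BOND_TAGS), bond_rows))
    return block


def read_connection_table(block: DataBlock) -> ConnectivityGraph:
    """Rebuild a :class:`ConnectivityGraph` from the connectivity loops.

    Inverse of :func:`write_connection_table` on (labels, bonds, orders);
    bond lengths are recomputed as 0.0 placeholders unless sites are
    available, since the table does not store them.
    """
    aloop = block.find_loop("_chemical_conn_atom_number")
    if aloop is None:
        return ConnectivityGraph([], [])
    numbers = [int(v.value) for v in aloop.column("_chemical_conn_atom_number")]
    labels = [v.raw for v in aloop.column("_chemical_conn_atom_label")]
    elements = [v.raw for v in aloop.column("_chemical_conn_atom_type_symbol")]
    by_number = dict(zip(numbers, labels))
    atoms = [
        AtomSite(label=lab, element=el, frac=(0.0, 0.0, 0.0))
        for lab, el in zip(labels, elements)
    ]
    bonds: list[Bond] = []
    bloop = block.find_loop("_chemical_conn_bond_atom_1")
    if bloop is not None:
        a1 = [int(v.value) for v in bloop.column("_chemical_conn_bond_atom_1")]
        a2 = [int(v.value) for v in bloop.column("_chemical_conn_bond_atom_2")]
        types = [v.raw for v in bloop.column("_chemical_conn_bond_type")]
        for n1, n2, t in zip(a1, a2, types):
            if n1 not in by_number or n2 not in by_number:
                raise ValueError(f"bond cites unknown atom number {n1} or {n2}")
            bonds.append(
                Bond(by_number[n1], by_number[n2], 0.0, _BOND_TYPE_NAMES.get(t, "unassigned"))
            )
    return ConnectivityGraph(atoms, bonds)
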
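"""Deterministic toy structures, dictionaries, articles and defects.

Everything the test battery needs is generated here, seeded and
reproducible: a small ethanol-like molecule (C2H6O) with a chloride
counter-ion in a triclinic cell, in space group P1 or P-1, optionally
with a two-group disorder assembly on the hydroxyl arm.  Blocks are
built so that every shipped check passes on a clean fixture — cell
volume, formula weight and geometry tables are internally consistent to
well below the consistency tolerance — and :func:`inject_defect` applies
exactly one localised corruption together with a descriptor of the
finding the downstream module must raise.

The toy chemistry is limited to H, C, N, O and Cl, which keeps the
covalent-radius table small while covering organic and ionic cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cif_syntax import CifDocument, DataBlock, Loop, make_value, parse_cif, write_cif
from .geometry import (
    AtomSite,
    UnitCell,
    angle,
    cell_from_block,
    cell_volume,
    distance,
    orthogonalization,
    sites_from_block,
    torsion,
)
from .text_semantics import GlossaryIndex

__all__ = [
    "FixtureSpec",
    "ExpectedFinding",
    "DEFECT_CODES",
    "generate_structure",
    "generate_document",
    "inject_defect",
    "generate_article",
    "default_glossary",
]

DEFECT_CODES = (
    "elongated-adp",
    "bad-enum",
    "wrong-type",
    "missing-required",
    "inconsistent-volume",
    "short-contact",
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_atoms: Optional[int] = None  # cap on molecule atoms; None = all
    symmetry: str = "P1"  # P1 | P-1
    disorder: bool = False
    defects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_atoms is not None and self.n_atoms < 1:
            raise ValueError("n_atoms must be >= 1")
        if self.symmetry not in ("P1", "P-1"):
            raise ValueError("symmetry must be 'P1' or 'P-1'")
        for code in self.defects:
            if code not in DEFECT_CODES:
                raise ValueError(f"unknown defect code {code!r}")


@dataclass(frozen=True)
class ExpectedFinding:
    """What a downstream module must report for an injected defect."""

    module: str  # dictionary | derivation | validation_alerts
    code: str  # violation code, alert code, or tag under test
    subject: str


# tetrahedral unit vectors
_T = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / math.sqrt(3.0)

_WEIGHTS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "Cl": 35.45}


def _molecule(disorder: bool) -> list[tuple[str, str, np.ndarray, float, Optional[int]]]:
    """(label, element, cartesian, occupancy, disorder_group) for the toy molecule."""
    t1, t2, t3, t4 = _T
    c1 = np.zeros(3)
    c2 = c1 + 1.53 * t1
    atoms = [
        ("C1", "C", c1, 1.0, None),
        ("C2", "C", c2, 1.0, None),
        ("H11", "H", c1 + 1.09 * t2, 1.0, None),
        ("H12", "H", c1 + 1.09 * t3, 1.0, None),
        ("H13", "H", c1 + 1.09 * t4, 1.0, None),
        ("H21", "H", c2 - 1.09 * t3, 1.0, None),
        ("H22", "H", c2 - 1.09 * t4, 1.0, None),
    ]
    o1a = c2 - 1.43 * t2
    if not disorder:
        atoms.insert(2, ("O1", "O", o1a, 1.0, None))
        atoms.append(("H1", "H", o1a + 0.97 * t3, 1.0, None))
    else:
        dir_b = 2.0 * t2 + t3
        dir_b = dir_b / np.linalg.norm(dir_b)
        o1b = c2 - 1.43 * dir_b
        atoms.insert(2, ("O1A", "O", o1a, 0.6, 1))
        atoms.insert(3, ("O1B", "O", o1b, 0.4, 2))
        atoms.append(("H1A", "H", o1a + 0.97 * t3, 0.6, 1))
        atoms.append(("H1B", "H", o1b + 0.97 * t3, 0.4, 2))
    return atoms


def _u_cartesian_to_cif(cell: UnitCell, u_cart: np.ndarray) -> np.ndarray:
    a = orthogonalization(cell)
    g_star = np.linalg.inv(a.T @ a)
    n_inv = np.diag(1.0 / np.sqrt(np.diag(g_star)))
    a_inv = np.linalg.inv(a)
    u = n_inv @ a_inv @ u_cart @ a_inv.T @ n_inv
    return (u + u.T) / 2.0


def _fmt(x: float, prec: int) -> str:
    return f"{x:.{prec}f}"


def generate_structure(spec: FixtureSpec) -> DataBlock:
    """Build one internally consistent data block from a fixture spec.

    The same seed yields a byte-identical block (and written CIF).  The
    block carries the cell, symmetry loop, atom sites (anisotropic U on
    the heavy atoms), geometry tables recomputed from the rounded stored
    coordinates, and a stored ``_cell_volume`` consistent with the stored
    cell parameters to better than 1e-9 relative.
    """
    rng = np.random.RandomState(spec.seed % 2**31)
    cell_vals = [
        round(10.0 + rng.uniform(-0.2, 0.2), 4),
        round(11.0 + rng.uniform(-0.2, 0.2), 4),
        round(12.0 + rng.uniform(-0.2, 0.2), 4),
        round(92.0 + rng.uniform(-1.0, 1.0), 4),
        round(101.0 + rng.uniform(-1.0, 1.0), 4),
        round(94.0 + rng.uniform(-1.0, 1.0), 4),
    ]
    cell = UnitCell(*cell_vals)
    m_inv = np.linalg.inv(orthogonalization(cell))

    atoms = _molecule(spec.disorder)
    if spec.n_atoms is not None:
        atoms = atoms[: spec.n_atoms]
    offset = np.array([1.3, 1.4, 1.5])
    placed: list[AtomSite] = []
    for label, elem, cart, occ, group in atoms:
        cart = cart + offset + rng.uniform(-0.01, 0.01, size=3)
        frac = np.round(m_inv @ cart, 5)
        placed.append(
            AtomSite(
                label,
                elem,
                tuple(frac),
                occupancy=occ,
                disorder_group=group,
                disorder_assembly="A" if group is not None else None,
            )
        )
    # counter-ion: general position in P1, the inversion centre in P-1
    if spec.n_atoms is None:
        cl_frac = (0.62, 0.55, 0.5) if spec.symmetry == "P1" else (0.5, 0.5, 0.5)
        placed.append(AtomSite("Cl1", "Cl", cl_frac))

    block = DataBlock(f"fixture_{spec.seed}")
    su_digits = ["(2)", "(3)", "(2)", "(8)", "(9)", "(8)"]
    for tag, val, su in zip(
        (
            "_cell_length_a",
            "_cell_length_b",
            "_cell_length_c",
            "_cell_angle_alpha",
            "_cell_angle_beta",
            "_cell_angle_gamma",
        ),
        cell_vals,
        su_digits,
    ):
        block.set_item(tag, make_value(_fmt(val, 4) + su))
    block.set_item("_cell_volume", make_value(_fmt(cell_volume(cell), 6)))
    block.set_item("_symmetry_cell_setting", make_value("triclinic"))
    block.set_item(
        "_symmetry_space_group_name_H-M",
        make_value("P 1" if spec.symmetry == "P1" else "P -1", quoted=True),
    )
    ops = ["x,y,z"] if spec.symmetry == "P1" else ["x,y,z", "-x,-y,-z"]
    block.add_loop(
        Loop(["_symmetry_equiv_pos_as_xyz"], [(make_value(op, quoted=True),) for op in ops])
    )

    counts: dict[str, float] = {}
    mult = 1 if spec.symmetry == "P1" else 2
    for site in placed:
        site_mult = 1 if site.label == "Cl1" and spec.symmetry == "P-1" else mult
        counts[site.element] = counts.get(site.element, 0.0) + site.occupancy * site_mult
    hill = sorted(counts, key=lambda e: {"C": (0, ""), "H": (1, "")}.get(e, (2, e)))
    formula = " ".join(
        e if round(counts[e]) == 1 else f"{e}{round(counts[e])}" for e in hill
    )
    block.set_item("_chemical_formula_sum", make_value(formula, quoted=True))
    weight = sum(_WEIGHTS[e] * counts[e] for e in counts)
    block.set_item("_chemical_formula_weight", make_value(_fmt(weight, 6)))
    block.set_item("_cell_formula_units_Z", make_value("1"))

    # atom site loop (coordinates already rounded to 5 decimals)
    aniso_labels = [s.label for s in placed if s.element in ("C", "O")]
    site_rows = []
    for s in placed:
        site_rows.append(
            tuple(
                make_value(v)
                for v in (
                    s.label,
                    s.element,
                    _fmt(s.frac[0], 5),
                    _fmt(s.frac[1], 5),
                    _fmt(s.frac[2], 5),
                    _fmt(s.occupancy, 3),
                    "0.030" if s.element != "H" else "0.045",
                    "Uani" if s.label in aniso_labels else "Uiso",
                    s.disorder_assembly or ".",
                    str(s.disorder_group) if s.disorder_group is not None else ".",
                )
            )
        )
    block.add_loop(
        Loop(
            [
                "_atom_site_label",
                "_atom_site_type_symbol",
                "_atom_site_fract_x",
                "_atom_site_fract_y",
                "_atom_site_fract_z",
                "_atom_site_occupancy",
                "_atom_site_U_iso_or_equiv",
                "_atom_site_adp_type",
                "_atom_site_disorder_assembly",
                "_atom_site_disorder_group",
            ],
            site_rows,
        )
    )

    # mildly anisotropic Cartesian U, expressed in the CIF convention
    aniso_rows = []
    for i, lab in enumerate(aniso_labels):
        u_cart = np.diag([0.028 + 0.004 * (i % 3), 0.034, 0.040])
        u_cif = _u_cartesian_to_cif(cell, u_cart)
        aniso_rows.append(
            (
                make_value(lab),
                make_value(_fmt(u_cif[0, 0], 5)),
                make_value(_fmt(u_cif[1, 1], 5)),
                make_value(_fmt(u_cif[2, 2], 5)),
                make_value(_fmt(u_cif[0, 1], 5)),
                make_value(_fmt(u_cif[0, 2], 5)),
                make_value(_fmt(u_cif[1, 2], 5)),
            )
        )
    if aniso_rows:
        block.add_loop(
            Loop(
                [
                    "_atom_site_aniso_label",
                    "_atom_site_aniso_U_11",
                    "_atom_site_aniso_U_22",
                    "_atom_site_aniso_U_33",
                    "_atom_site_aniso_U_12",
                    "_atom_site_aniso_U_13",
                    "_atom_site_aniso_U_23",
                ],
                aniso_rows,
            )
        )

    _append_geometry_tables(block)

    for code in spec.defects:
        block, _ = inject_defect(block, code)
    return block


def _append_geometry_tables(block: DataBlock) -> None:
    """Recompute bond/angle/torsion tables from the stored coordinates."""
    from .connectivity import infer_bonds  # deferred: module-level cycle

    cell = cell_from_block(block)
    sites = sites_from_block(block)
    by_label = {s.label: s for s in sites}
    graph = infer_bonds(cell, sites)
    neighbours: dict[str, list[str]] = {s.label: [] for s in sites}
    for b in graph.bonds:
        neighbours[b.atom1].append(b.atom2)
        neighbours[b.atom2].append(b.atom1)
    for lst in neighbours.values():
        lst.sort()

    bond_rows = [
        (
            make_value(b.atom1),
            make_value(b.atom2),
            make_value(_fmt(b.length, 3)),
        )
        for b in sorted(graph.bonds, key=lambda b: (b.atom1, b.atom2))
    ]
    if bond_rows:
        block.add_loop(
            Loop(
                [
                    "_geom_bond_atom_site_label_1",
                    "_geom_bond_atom_site_label_2",
                    "_geom_bond_distance",
                ],
                bond_rows,
            )
        )

    angle_rows = []
    for centre in sorted(neighbours):
        nb = neighbours[centre]
        for i in range(len(nb)):
            for j in range(i + 1, len(nb)):
                val = angle(cell, by_label[nb[i]].frac, by_label[centre].frac, by_label[nb[j]].frac)
                angle_rows.append(
                    (
                        make_value(nb[i]),
                        make_value(centre),
                        make_value(nb[j]),
                        make_value(_fmt(val, 1)),
                    )
                )
    if angle_rows:
        block.add_loop(
            Loop(
                [
                    "_geom_angle_atom_site_label_1",
                    "_geom_angle_atom_site_label_2",
                    "_geom_angle_atom_site_label_3",
                    "_geom_angle",
                ],
                angle_rows,
            )
        )

    torsion_rows = []
    for b in sorted(graph.bonds, key=lambda b: (b.atom1, b.atom2)):
        for a in neighbours[b.atom1]:
            if a == b.atom2:
                continue
            for d in neighbours[b.atom2]:
                if d == b.atom1 or d == a:
                    continue
                try:
                    val = torsion(
                        cell,
                        by_label[a].frac,
                        by_label[b.atom1].frac,
                        by_label[b.atom2].frac,
                        by_label[d].frac,
                    )
                except ValueError:
                    continue
                torsion_rows.append(
                    tuple(make_value(x) for x in (a, b.atom1, b.atom2, d))
                    + (make_value(_fmt(val, 1)),)
                )
    if torsion_rows:
        block.add_loop(
            Loop(
                [
                    "_geom_torsion_atom_site_label_1",
                    "_geom_torsion_atom_site_label_2",
                    "_geom_torsion_atom_site_label_3",
                    "_geom_torsion_atom_site_label_4",
                    "_geom_torsion",
                ],
                torsion_rows,
            )
        )


def generate_document(spec: FixtureSpec) -> CifDocument:
    return CifDocument([generate_structure(spec)])


def _clone(block: DataBlock) -> DataBlock:
    return parse_cif(write_cif(CifDocument([block])))[block.name]


def inject_defect(block: DataBlock, code: str) -> tuple[DataBlock, ExpectedFinding]:
    """Apply one localised corruption; return (corrupted copy, descriptor)."""
    if code not in DEFECT_CODES:
        raise ValueError(f"unknown defect code {code!r}")
    out = _clone(block)
    if code == "elongated-adp":
        cell = cell_from_block(out)
        u_cif = _u_cartesian_to_cif(cell, np.diag([0.090, 0.009, 0.009]))
        loop = out.find_loop("_atom_site_aniso_label")
        target = loop.rows[0][0].raw
        new_row = (loop.rows[0][0],) + tuple(
            make_value(_fmt(u_cif[i, j], 5))
            for i, j in ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
        )
        loop.rows[0] = new_row
        return out, ExpectedFinding("validation_alerts", "PLAT213_ALERT_2_A", target)
    if code == "bad-enum":
        out.replace_item("_symmetry_cell_setting", make_value("quintoclinic"))
        return out, ExpectedFinding("dictionary", "enum-violation", "_symmetry_cell_setting")
    if code == "wrong-type":
        out.replace_item("_chemical_formula_weight", make_value("heavy"))
        return out, ExpectedFinding("dictionary", "type-mismatch", "_chemical_formula_weight")
    if code == "missing-required":
        out.remove_item("_chemical_formula_sum")
        return out, ExpectedFinding(
            "validation_alerts", "COMP01_ALERT_1_A", "_chemical_formula_sum"
        )
    if code == "inconsistent-volume":
        stored = out["_cell_volume"].value
        out.replace_item("_cell_volume", make_value(_fmt(stored * 1.1, 6)))
        return out, ExpectedFinding("derivation", "_cell_volume", "_cell_volume")
    if code == "short-contact":
        cell = cell_from_block(out)
        sites = {s.label: s for s in sites_from_block(out)}
        h = "H1" if "H1" in sites else "H1A"
        o = "O1" if "O1" in sites else "O1A"
        d = distance(cell, sites[o].frac, sites[h].frac)
        scale = 0.50 / d
        new_frac = np.round(
            np.array(sites[o].frac) + scale * (np.array(sites[h].frac) - np.array(sites[o].frac)),
            5,
        )
        loop = out.find_loop("_atom_site_label")
        for r, row in enumerate(loop.rows):
            if row[0].raw == h:
                row = list(row)
                row[2] = make_value(_fmt(new_frac[0], 5))
                row[3] = make_value(_fmt(new_frac[1], 5))
                row[4] = make_value(_fmt(new_frac[2], 5))
                loop.rows[r] = tuple(row)
        pair = "-".join(sorted((o, h)))
        return out, ExpectedFinding("validation_alerts", "BOND01_ALERT_2_B", pair)
    raise AssertionError("unreachable")


def default_glossary() -> GlossaryIndex:
    """A small crystallographic glossary with context-constrained targets."""
    odc = "https://reference.iucr.org/dictionary"
    return GlossaryIndex(
        entries={
            "space group": f"{odc}/Space_group",
            "plane group": f"{odc}/Plane_group",
            "group theory": f"{odc}/Group",
            "inverse element": f"{odc}/Group",
            "unit cell": f"{odc}/Unit_cell",
            "asymmetric unit": f"{odc}/Asymmetric_unit",
            "structure factor": f"{odc}/Structure_factor",
            "torsion angle": f"{odc}/Torsion_angle",
        },
        stop_words={"group", "cell", "unit", "angle"},
    )


def generate_article(
    block: DataBlock, seed: int = 0
) -> tuple[str, list[tuple[str, tuple[str, ...]]]]:
    """Compose a synthetic article fragment from a block's geometry tables.

    Returns the text and the ground-truth list of resolvable geometry
    mentions as (kind, labels) pairs.  Decoy label chains use atoms absent
    from every table, so a resolver must drop them; glossary phrases are
    woven into the prose for the annotation scanner.
    """
    rng = np.random.RandomState(seed % 2**31)
    sentences = [
        "The title compound crystallizes in the space group P1 with one "
        "formula unit in the asymmetric unit.",
        "All geometric parameters were derived from the refined unit cell.",
    ]
    truth: list[tuple[str, tuple[str, ...]]] = []

    def pick(rows: list, k: int) -> list:
        idx = rng.permutation(len(rows))[:k]
        return [rows[i] for i in sorted(idx)]

    bond_loop = block.find_loop("_geom_bond_atom_site_label_1")
    if bond_loop is not None:
        for row in pick(bond_loop.rows, 2):
            l1, l2, dist = row[0].raw, row[1].raw, row[2].raw
            sentences.append(
                f"The {l1}---{l2} bond length of {dist} (2) Å is unexceptional."
            )
            truth.append(("distance", (l1, l2)))
    angle_loop = block.find_loop("_geom_angle_atom_site_label_1")
    if angle_loop is not None:
        for row in pick(angle_loop.rows, 2):
            l1, l2, l3, val = (row[i].raw for i in range(4))
            sentences.append(
                f"The {l1}---{l2}---{l3} angle of {val} (3)° shows no strain."
            )
            truth.append(("angle", (l1, l2, l3)))
    torsion_loop = block.find_loop("_geom_torsion_atom_site_label_1")
    if torsion_loop is not None:
        for row in pick(torsion_loop.rows, 1):
            l1, l2, l3, l4 = (row[i].raw for i in range(4))
            sentences.append(
                f"The conformation is defined by the {l1}---{l2}---{l3}---{l4} "
                "torsion angle."
            )
            truth.append(("torsion", (l1, l2, l3, l4)))
    if truth:
        # decoys: valid typography, labels foreign to every table
        sentences.append("A putative N8---N9 interaction could not be confirmed.")
        sentences.append("The N7---N8---N9 angle of the solvent model was discarded.")
    return " ".join(sentences), truth
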
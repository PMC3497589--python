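"""Crystallographic metric geometry and symmetry.

Provides the unit-cell metric (volume, orthogonalization), molecular
geometry (distance / angle / torsion) on fractional coordinates, exact
rational symmetry-operator algebra parsed from ``x,y,z``-style coordinate
triplets, site orbits and multiplicities, and a plain structure-factor
summation over the symmetry-expanded cell contents.

Orthogonalization follows the common crystallographic convention: the
``a`` axis lies along Cartesian *x* and ``b`` lies in the *xy* plane.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np

from .cif_syntax import DataBlock

__all__ = [
    "UnitCell",
    "SymOp",
    "AtomSite",
    "cell_volume",
    "orthogonalization",
    "metric_tensor",
    "distance",
    "angle",
    "torsion",
    "parse_symop",
    "format_symop",
    "site_orbit",
    "structure_factor",
    "cell_from_block",
    "symops_from_block",
    "sites_from_block",
]


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell dimensions: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        if 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg <= 0.0:
            raise ValueError("cell metric is not positive definite")


def cell_volume(cell: UnitCell) -> float:
    """Cell volume in Å³: ``abc·sqrt(1−cos²α−cos²β−cos²γ+2cosαcosβcosγ)``."""
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0.0:
        raise ValueError("cell metric is not positive definite")
    return cell.a * cell.b * cell.c * math.sqrt(arg)


def orthogonalization(cell: UnitCell) -> np.ndarray:
    """3×3 matrix mapping fractional to Cartesian coordinates (Å).

    Convention: **a** along *x*, **b** in the *xy* plane.  The determinant
    equals :func:`cell_volume`.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    v = cell_volume(cell)
    return np.array(
        [
            [cell.a, cell.b * cg, cell.c * cb],
            [0.0, cell.b * sg, cell.c * (ca - cb * cg) / sg],
            [0.0, 0.0, v / (cell.a * cell.b * sg)],
        ]
    )


def metric_tensor(cell: UnitCell) -> np.ndarray:
    """Real-space metric tensor G with G_ij = a_i · a_j."""
    m = orthogonalization(cell)
    return m.T @ m


def _cart(cell: UnitCell, frac: Sequence[float]) -> np.ndarray:
    return orthogonalization(cell) @ np.asarray(frac, dtype=float)


def distance(cell: UnitCell, x1: Sequence[float], x2: Sequence[float]) -> float:
    """Distance in Å between two fractional positions (no symmetry applied)."""
    return float(np.linalg.norm(_cart(cell, x1) - _cart(cell, x2)))


def angle(
    cell: UnitCell, x1: Sequence[float], x2: Sequence[float], x3: Sequence[float]
) -> float:
    """Angle x1–x2–x3 in degrees, vertex at x2."""
    v1 = _cart(cell, x1) - _cart(cell, x2)
    v2 = _cart(cell, x3) - _cart(cell, x2)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise ValueError("coincident points: angle undefined")
    cosang = float(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def torsion(
    cell: UnitCell,
    x1: Sequence[float],
    x2: Sequence[float],
    x3: Sequence[float],
    x4: Sequence[float],
) -> float:
    """Signed torsion x1–x2–x3–x4 in degrees, in (−180, 180].

    The sign follows the right-hand IUPAC convention: looking from x2
    towards x3, a clockwise rotation of the far bond is positive.
    """
    p = [_cart(cell, x) for x in (x1, x2, x3, x4)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if nb2 < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate (collinear or coincident) points: torsion undefined")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b2 / nb2)
    ang = math.degrees(math.atan2(y, x))
    # atan2 can yield exactly -180 via signed zero; fold onto +180
    return 180.0 if ang <= -180.0 + 1e-12 else ang


# ---------------------------------------------------------------------------
# Symmetry operators
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(
    r"(?P<sign>[+-]?)\s*(?:(?P<var>[xyz])|(?P<num>\d+(?:\.\d+)?)(?:\s*/\s*(?P<den>\d+))?)"
)


@dataclass(frozen=True)
class SymOp:
    """A symmetry operation: exact rational rotation matrix and translation.

    ``rotation`` rows/columns follow the ``x,y,z`` component order; the
    translation is reduced modulo 1 into [0, 1).
    """

    rotation: tuple[tuple[Fraction, ...], ...]
    translation: tuple[Fraction, ...]

    def __post_init__(self) -> None:
        det = _det3(self.rotation)
        if det not in (1, -1):
            raise ValueError(f"rotation determinant must be ±1, got {det}")
        for t in self.translation:
            if not 0 <= t < 1:
                raise ValueError("translation components must lie in [0, 1)")

    @staticmethod
    def identity() -> "SymOp":
        one, zero = Fraction(1), Fraction(0)
        return SymOp(
            ((one, zero, zero), (zero, one, zero), (zero, zero, one)),
            (zero, zero, zero),
        )

    def apply(self, frac: Sequence[float]) -> np.ndarray:
        r = np.array([[float(v) for v in row] for row in self.rotation])
        t = np.array([float(v) for v in self.translation])
        return r @ np.asarray(frac, dtype=float) + t

    def __mul__(self, other: "SymOp") -> "SymOp":
        r1, r2 = self.rotation, other.rotation
        rot = tuple(
            tuple(sum(r1[i][k] * r2[k][j] for k in range(3)) for j in range(3))
            for i in range(3)
        )
        tr = tuple(
            (sum(r1[i][k] * other.translation[k] for k in range(3)) + self.translation[i]) % 1
            for i in range(3)
        )
        return SymOp(rot, tr)


def _det3(m: Sequence[Sequence[Fraction]]) -> Fraction:
    return (
        m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
        - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
        + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0])
    )


def parse_symop(text: str) -> SymOp:
    """Parse a coordinate triplet such as ``-x,y+1/2,-z+1/2`` exactly.

    Terms may be ±x/±y/±z, fractions ``n/m`` or decimals; the translation
    is reduced mod 1.
    """
    parts = text.split(",")
    if len(parts) != 3:
        raise ValueError(f"coordinate triplet must have 3 components: {text!r}")
    rot: list[tuple[Fraction, ...]] = []
    trans: list[Fraction] = []
    axes = {"x": 0, "y": 1, "z": 2}
    for part in parts:
        row = [Fraction(0)] * 3
        t = Fraction(0)
        pos = 0
        stripped = part.strip()
        if not stripped:
            raise ValueError(f"empty component in triplet {text!r}")
        while pos < len(stripped):
            m = _TERM_RE.match(stripped, pos)
            if m is None or (pos > 0 and not m.group("sign") and stripped[pos] not in "+-"):
                raise ValueError(f"malformed triplet component {part!r}")
            if m is None:
                raise ValueError(f"malformed triplet component {part!r}")
            sign = -1 if m.group("sign") == "-" else 1
            if m.group("var"):
                row[axes[m.group("var")]] += sign
            else:
                num = m.group("num")
                if m.group("den"):
                    frac = Fraction(int(num), int(m.group("den")))
                else:
                    frac = Fraction(num).limit_denominator(48)
                t += sign * frac
            pos = m.end()
            while pos < len(stripped) and stripped[pos] == " ":
                pos += 1
        rot.append(tuple(row))
        trans.append(t % 1)
    return SymOp(tuple(rot), tuple(trans))


def format_symop(op: SymOp) -> str:
    """Format a :class:`SymOp` back to a canonical coordinate triplet."""
    names = "xyz"
    comps: list[str] = []
    for i in range(3):
        terms: list[str] = []
        for j in range(3):
            coef = op.rotation[i][j]
            if coef == 0:
                continue
            if abs(coef) == 1:
                term = names[j]
            else:
                term = f"{abs(coef)}{names[j]}"
            terms.append(("-" if coef < 0 else "+") + term)
        t = op.translation[i]
        if t != 0:
            terms.append(f"+{t.numerator}/{t.denominator}")
        comp = "".join(terms) or "0"
        comps.append(comp.lstrip("+"))
    return ",".join(comps)


def _min_image_sep(d: np.ndarray) -> float:
    """Fractional minimum-image norm of a fractional difference vector."""
    d = d - np.round(d)
    return float(np.linalg.norm(d))


def site_orbit(
    ops: Sequence[SymOp], x: Sequence[float], tol: float = 1e-4
) -> list[np.ndarray]:
    """Distinct positions (mod 1) generated from ``x`` by ``ops``.

    Positions closer than ``tol`` under the fractional minimum-image metric
    are merged, so a site on a special position has a reduced orbit; the
    orbit size is the site multiplicity and divides ``len(ops)``.
    """
    if not ops:
        raise ValueError("operator list must be non-empty")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if not any(
        all(op.rotation[i][j] == (1 if i == j else 0) for i in range(3) for j in range(3))
        and all(t == 0 for t in op.translation)
        for op in ops
    ):
        raise ValueError("operator list must contain the identity")
    orbit: list[np.ndarray] = []
    for op in ops:
        pos = op.apply(x) % 1.0
        if not any(_min_image_sep(pos - q) <= tol for q in orbit):
            orbit.append(pos)
    return orbit


@dataclass
class AtomSite:
    """A fractional atom site with occupancy, displacement and disorder labels."""

    label: str
    element: str
    frac: tuple[float, float, float]
    occupancy: float = 1.0
    u_iso: Optional[float] = None
    u_aniso: Optional[np.ndarray] = None  # CIF-convention tensor, Å²
    disorder_group: Optional[int] = None
    disorder_assembly: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy of {self.label} must be in (0, 1]")
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, dtype=float)


def structure_factor(
    hkl: Sequence[int],
    sites: Sequence[AtomSite],
    ops: Sequence[SymOp],
    f: Mapping[str, float],
) -> complex:
    """Structure factor F(hkl) by direct summation over the expanded cell.

    Every site is expanded by every operator; contributions are weighted by
    occupancy and the constant per-element scattering factor ``f``.  No
    displacement-parameter damping is applied, so F(000) equals the sum of
    occupancy-weighted scattering factors over the expanded atom list.
    """
    h = np.asarray(hkl, dtype=float)
    total = 0j
    for site in sites:
        if site.element not in f:
            raise KeyError(f"no scattering factor for element {site.element!r}")
        fe = f[site.element]
        for op in ops or [SymOp.identity()]:
            x = op.apply(site.frac)
            total += site.occupancy * fe * np.exp(2j * np.pi * float(h @ x))
    return complex(total)


# ---------------------------------------------------------------------------
# Extraction from data blocks (core CIF tag spellings)
# ---------------------------------------------------------------------------

CELL_TAGS = (
    "_cell_length_a",
    "_cell_length_b",
    "_cell_length_c",
    "_cell_angle_alpha",
    "_cell_angle_beta",
    "_cell_angle_gamma",
)


def cell_from_block(block: DataBlock) -> UnitCell:
    """Read the six ``_cell_*`` items into a :class:`UnitCell`."""
    vals = []
    for tag in CELL_TAGS:
        v = block.get(tag)
        if v is None or v.value is None:
            raise ValueError(f"block {block.name!r} lacks a numeric {tag}")
        vals.append(v.value)
    return UnitCell(*vals)


def symops_from_block(block: DataBlock) -> list[SymOp]:
    """Read the ``_symmetry_equiv_pos_as_xyz`` loop; identity if absent."""
    loop = block.find_loop("_symmetry_equiv_pos_as_xyz")
    if loop is None:
        return [SymOp.identity()]
    return [parse_symop(v.raw) for v in loop.column("_symmetry_equiv_pos_as_xyz")]


def sites_from_block(block: DataBlock) -> list[AtomSite]:
    """Read ``_atom_site_*`` (and aniso) loops into :class:`AtomSite` objects."""
    loop = block.find_loop("_atom_site_label")
    if loop is None:
        raise ValueError(f"block {block.name!r} has no _atom_site_ loop")

    def col(tag: str) -> Optional[list]:
        return loop.column(tag) if loop.has_tag(tag) else None

    labels = [v.raw for v in loop.column("_atom_site_label")]
    elems_col = col("_atom_site_type_symbol")
    elems = [v.raw for v in elems_col] if elems_col else [re.match(r"[A-Z][a-z]?", l).group() for l in labels]
    fx = [v.value for v in loop.column("_atom_site_fract_x")]
    fy = [v.value for v in loop.column("_atom_site_fract_y")]
    fz = [v.value for v in loop.column("_atom_site_fract_z")]
    occ_col = col("_atom_site_occupancy")
    uiso_col = col("_atom_site_U_iso_or_equiv")
    grp_col = col("_atom_site_disorder_group")
    asm_col = col("_atom_site_disorder_assembly")

    aniso: dict[str, np.ndarray] = {}
    aloop = block.find_loop("_atom_site_aniso_label")
    if aloop is not None:
        alabels = [v.raw for v in aloop.column("_atom_site_aniso_label")]
        comps = {
            sfx: [v.value for v in aloop.column(f"_atom_site_aniso_U_{sfx}")]
            for sfx in ("11", "22", "33", "12", "13", "23")
        }
        for i, lab in enumerate(alabels):
            u11, u22, u33 = comps["11"][i], comps["22"][i], comps["33"][i]
            u12, u13, u23 = comps["12"][i], comps["13"][i], comps["23"][i]
            aniso[lab] = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])

    sites = []
    for i, lab in enumerate(labels):
        occ = occ_col[i].value if occ_col and occ_col[i].value is not None else 1.0
        grp_v = grp_col[i] if grp_col else None
        asm_v = asm_col[i] if asm_col else None
        sites.append(
            AtomSite(
                label=lab,
                element=elems[i],
                frac=(fx[i], fy[i], fz[i]),
                occupancy=occ,
                u_iso=uiso_col[i].value if uiso_col else None,
                u_aniso=aniso.get(lab),
                disorder_group=int(grp_v.value) if grp_v is not None and grp_v.value is not None else None,
                disorder_assembly=asm_v.raw if asm_v is not None and not asm_v.is_missing else None,
            )
        )
    if len({s.label for s in sites}) != len(sites):
        raise ValueError("atom site labels are not unique")
    return sites
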
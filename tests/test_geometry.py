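"""Metric geometry, symmetry algebra, orbits, structure factors.

The independent oracle throughout is the metric tensor assembled
directly from the cell parameters (G_ij = |a_i||a_j|cos(angle_ij)):
volumes come from sqrt(det G) and Cartesian coordinates from a Cholesky
factor of G, with geometry then computed by plain vector arithmetic.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from cifsem.geometry import (
    AtomSite,
    SymOp,
    UnitCell,
    angle,
    cell_volume,
    distance,
    format_symop,
    orthogonalization,
    parse_symop,
    site_orbit,
    structure_factor,
    torsion,
)


def oracle_metric(cell: UnitCell) -> np.ndarray:
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    return np.array(
        [
            [cell.a**2, cell.a * cell.b * cg, cell.a * cell.c * cb],
            [cell.a * cell.b * cg, cell.b**2, cell.b * cell.c * ca],
            [cell.a * cell.c * cb, cell.b * cell.c * ca, cell.c**2],
        ]
    )


def oracle_cart(cell: UnitCell, frac) -> np.ndarray:
    # any matrix A with AᵀA = G is a valid Cartesian frame
    L = np.linalg.cholesky(oracle_metric(cell))
    return L.T @ np.asarray(frac, dtype=float)


def random_cells(n, seed=0):
    rng = np.random.RandomState(seed)
    out = []
    while len(out) < n:
        try:
            out.append(
                UnitCell(
                    rng.uniform(3, 30),
                    rng.uniform(3, 30),
                    rng.uniform(3, 30),
                    rng.uniform(60, 120),
                    rng.uniform(60, 120),
                    rng.uniform(60, 120),
                )
            )
        except ValueError:
            continue
    return out


class TestCellVolume:
    def test_cubic_and_orthorhombic(self):
        assert cell_volume(UnitCell(10, 10, 10)) == pytest.approx(1000.0)
        assert cell_volume(UnitCell(5, 6, 7)) == pytest.approx(210.0)

    def test_triclinic_matches_triple_product_oracle(self):
        cell = UnitCell(6.1, 7.3, 8.9, 91.2, 103.5, 95.0)
        oracle = math.sqrt(np.linalg.det(oracle_metric(cell)))
        assert cell_volume(cell) == pytest.approx(oracle, rel=1e-12)

    def test_determinant_of_orthogonalization_equals_volume(self):
        for cell in random_cells(200, seed=5):
            v = cell_volume(cell)
            assert abs(np.linalg.det(orthogonalization(cell)) - v) <= 1e-9 * v

    def test_invalid_metric_rejected(self):
        with pytest.raises(ValueError):
            UnitCell(5, 5, 5, 170, 170, 170)


class TestOrthogonalization:
    def test_cubic_is_scaled_identity(self):
        assert np.allclose(orthogonalization(UnitCell(2, 2, 2)), 2 * np.eye(3))

    def test_a_along_x_b_in_xy(self):
        m = orthogonalization(UnitCell(7, 8, 9, 95, 100, 105))
        assert np.linalg.norm(m @ [1, 0, 0]) == pytest.approx(7.0)
        assert m[2, 1] == pytest.approx(0.0)
        # the b column reproduces b·cos γ on the x axis
        assert m[0, 1] == pytest.approx(8 * math.cos(math.radians(105)))

    def test_gram_matrix_matches_oracle_metric(self):
        for cell in random_cells(50, seed=1):
            m = orthogonalization(cell)
            assert np.allclose(m.T @ m, oracle_metric(cell), rtol=1e-9, atol=1e-9)


class TestMolecularGeometry:
    def test_axis_distance(self):
        cell = UnitCell(4, 5, 6)
        assert distance(cell, (0, 0, 0), (0.5, 0, 0)) == pytest.approx(2.0)

    def test_trans_and_cis_torsions(self):
        cell = UnitCell(10, 10, 10)
        zig = [(0.1, 0.1, 0), (0.2, 0.2, 0), (0.3, 0.1, 0)]
        assert torsion(cell, *zig, (0.4, 0.2, 0)) == pytest.approx(180.0)
        assert torsion(cell, *zig, (0.2, 0.0, 0.0)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_cartesian_oracle_on_random_triclinic(self):
        rng = np.random.RandomState(3)
        for cell in random_cells(50, seed=17):
            pts = rng.uniform(-0.5, 1.5, size=(4, 3))
            c = [oracle_cart(cell, p) for p in pts]
            assert distance(cell, pts[0], pts[1]) == pytest.approx(
                np.linalg.norm(c[0] - c[1]), rel=1e-9
            )
            v1, v2 = c[0] - c[1], c[2] - c[1]
            oracle_angle = math.degrees(
                math.acos(np.clip(v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
            )
            assert angle(cell, pts[0], pts[1], pts[2]) == pytest.approx(oracle_angle, abs=1e-7)
            b1, b2, b3 = c[1] - c[0], c[2] - c[1], c[3] - c[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            oracle_torsion = math.degrees(
                math.atan2(np.cross(n1, n2) @ b2 / np.linalg.norm(b2), n1 @ n2)
            )
            assert torsion(cell, *pts) == pytest.approx(oracle_torsion, abs=1e-7)

    def test_symmetry_properties(self):
        cell = UnitCell(8, 9, 10, 85, 95, 100)
        p = [(0.1, 0.2, 0.3), (0.3, 0.3, 0.3), (0.5, 0.2, 0.4), (0.6, 0.5, 0.5)]
        assert distance(cell, p[0], p[1]) == distance(cell, p[1], p[0])
        assert angle(cell, p[0], p[1], p[2]) == pytest.approx(angle(cell, p[2], p[1], p[0]))
        # reversing the atom order preserves the torsion; inverting the
        # structure (the mirror image) flips its sign
        assert torsion(cell, *p) == pytest.approx(torsion(cell, *p[::-1]))
        mirrored = [tuple(-c for c in x) for x in p]
        assert torsion(cell, *mirrored) == pytest.approx(-torsion(cell, *p))

    def test_coincident_points_rejected(self):
        cell = UnitCell(5, 5, 5)
        with pytest.raises(ValueError):
            angle(cell, (0.1, 0, 0), (0.1, 0, 0), (0.2, 0, 0))


class TestSymOps:
    def test_identity(self):
        op = parse_symop("x,y,z")
        assert op == SymOp.identity()

    def test_screw_like_triplet(self):
        op = parse_symop("-x,y+1/2,-z+1/2")
        assert op.rotation == (
            (Fraction(-1), Fraction(0), Fraction(0)),
            (Fraction(0), Fraction(1), Fraction(0)),
            (Fraction(0), Fraction(0), Fraction(-1)),
        )
        assert op.translation == (Fraction(0), Fraction(1, 2), Fraction(1, 2))

    @pytest.mark.parametrize("bad", ["x,y", "x,y,z,w", "a,b,c", "x,,z", "x+y,y,"])
    def test_malformed_triplets_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_symop(bad)

    @pytest.mark.parametrize(
        "text",
        ["x,y,z", "-x,-y,-z", "-x,y+1/2,-z+1/2", "y,x,z", "x-y,x,z+1/3", "1/2+x,1/2-y,z"],
    )
    def test_format_round_trips(self, text):
        op = parse_symop(text)
        assert parse_symop(format_symop(op)) == op

    def test_composition_stays_in_group(self):
        a = parse_symop("-x,y+1/2,-z+1/2")
        assert a * a == SymOp.identity()


class TestOrbits:
    P1BAR = [parse_symop("x,y,z"), parse_symop("-x,-y,-z")]

    def test_identity_only_orbit(self):
        assert len(site_orbit([SymOp.identity()], (0.3, 0.7, 0.9))) == 1

    def test_general_vs_special_position(self):
        assert len(site_orbit(self.P1BAR, (0.1, 0.2, 0.3))) == 2
        assert len(site_orbit(self.P1BAR, (0.0, 0.0, 0.0))) == 1  # inversion centre
        assert len(site_orbit(self.P1BAR, (0.5, 0.5, 0.5))) == 1

    def test_mod1_invariance(self):
        a = site_orbit(self.P1BAR, (0.1, 0.2, 0.3))
        b = site_orbit(self.P1BAR, (1.1, 0.2, -0.7))
        assert all(np.allclose(x, y) for x, y in zip(a, b))

    def test_orbit_size_divides_group_order_and_matches_brute_force(self):
        ops = [
            parse_symop(t)
            for t in ("x,y,z", "-x,-y,z", "-x,y+1/2,-z+1/2", "x,-y+1/2,-z+1/2")
        ]
        rng = np.random.RandomState(2)
        for _ in range(50):
            x = rng.uniform(0, 1, 3)
            orbit = site_orbit(ops, x)
            # brute force: all images, deduplicated pairwise by minimum image
            images = [op.apply(x) % 1.0 for op in ops]
            distinct = []
            for img in images:
                d = [np.linalg.norm((img - q) - np.round(img - q)) for q in distinct]
                if not d or min(d) > 1e-4:
                    distinct.append(img)
            assert len(orbit) == len(distinct)
            assert len(ops) % len(orbit) == 0

    def test_ops_without_identity_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            site_orbit([parse_symop("-x,-y,-z")], (0.1, 0.1, 0.1))


class TestStructureFactor:
    def site(self, label, elem, frac, occ=1.0):
        return AtomSite(label, elem, frac, occupancy=occ)

    def test_f000_counts_occupancy_weighted_atoms(self):
        sites = [
            self.site("C1", "C", (0.1, 0.2, 0.3)),
            self.site("C2", "C", (0.4, 0.1, 0.9), occ=0.5),
        ]
        ops = [parse_symop("x,y,z"), parse_symop("-x,-y,-z")]
        f = structure_factor((0, 0, 0), sites, ops, {"C": 1.0})
        assert f == pytest.approx(complex(2 * 1.5, 0.0))

    def test_single_atom_at_origin(self):
        f = structure_factor((3, 1, 2), [self.site("X1", "C", (0, 0, 0))], [], {"C": 1.0})
        assert f == pytest.approx(1 + 0j)

    def test_half_cell_pair_extinction(self):
        sites = [self.site("A", "C", (0, 0, 0)), self.site("B", "C", (0.5, 0, 0))]
        f = structure_factor((1, 0, 0), sites, [SymOp.identity()], {"C": 1.0})
        assert abs(f) < 1e-12

    def test_friedel_pairs_and_centrosymmetric_reality(self):
        rng = np.random.RandomState(4)
        sites = [
            self.site(f"C{i}", "C", tuple(rng.uniform(0, 1, 3))) for i in range(6)
        ]
        ops = [parse_symop("x,y,z"), parse_symop("-x,-y,-z")]
        for hkl in [(1, 2, 3), (2, 0, 1), (5, -3, 2)]:
            f_plus = structure_factor(hkl, sites, ops, {"C": 6.0})
            f_minus = structure_factor(tuple(-h for h in hkl), sites, ops, {"C": 6.0})
            assert abs(f_plus) == pytest.approx(abs(f_minus), rel=1e-10)
            assert abs(f_plus.imag) < 1e-10  # centrosymmetric: F is real

    def test_missing_scattering_factor_is_an_error(self):
        with pytest.raises(KeyError):
            structure_factor((1, 0, 0), [self.site("N1", "N", (0, 0, 0))], [], {"C": 6.0})
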
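"""Bond perception, moieties, formulas, connection-table round trips."""

from itertools import product

import numpy as np
import pytest

from cifsem.cif_syntax import CifDocument, DataBlock, parse_cif, write_cif
from cifsem.connectivity import (
    DEFAULT_RADII,
    Bond,
    ConnectivityGraph,
    infer_bonds,
    moieties,
    molecular_formula,
    read_connection_table,
    write_connection_table,
)
from cifsem.geometry import AtomSite, UnitCell, cell_from_block, orthogonalization, parse_symop, sites_from_block


def site(label, elem, frac, occ=1.0, group=None, assembly=None):
    return AtomSite(label, elem, frac, occupancy=occ, disorder_group=group,
                    disorder_assembly=assembly)


class TestInferBonds:
    CELL = UnitCell(10, 10, 10)

    def test_threshold_arithmetic(self):
        radii = {"C": 0.77}
        near = [site("C1", "C", (0, 0, 0)), site("C2", "C", (0.15, 0, 0))]  # 1.50 Å
        g = infer_bonds(self.CELL, near, radii, tol=0.40)
        assert [(b.atom1, b.atom2) for b in g.bonds] == [("C1", "C2")]
        assert g.bonds[0].length == pytest.approx(1.5)
        assert g.bonds[0].order == "unassigned"
        far = [site("C1", "C", (0, 0, 0)), site("C2", "C", (0.3, 0, 0))]  # 3.0 Å
        assert infer_bonds(self.CELL, far, radii, tol=0.40).bonds == []

    def test_minimum_image_bonds_across_the_cell_edge(self):
        sites = [site("C1", "C", (0.02, 0, 0)), site("C2", "C", (0.90, 0, 0))]
        g = infer_bonds(self.CELL, sites, {"C": 0.77}, tol=0.40)
        assert len(g.bonds) == 1 and g.bonds[0].length == pytest.approx(1.2)

    def test_disorder_groups_suppress_cross_bonds(self):
        sites = [
            site("O1A", "O", (0, 0, 0), 0.6, group=1, assembly="A"),
            site("O1B", "O", (0.08, 0, 0), 0.4, group=2, assembly="A"),
            site("C1", "C", (0.12, 0.1, 0)),
        ]
        g = infer_bonds(self.CELL, sites, DEFAULT_RADII, tol=0.40)
        pairs = {frozenset((b.atom1, b.atom2)) for b in g.bonds}
        assert frozenset(("O1A", "O1B")) not in pairs  # 0.8 Å yet suppressed
        # different assemblies bond normally
        sites[1] = site("O1B", "O", (0.08, 0, 0), 0.4, group=2, assembly="B")
        g2 = infer_bonds(self.CELL, sites, DEFAULT_RADII, tol=0.40)
        assert frozenset(("O1A", "O1B")) in {frozenset((b.atom1, b.atom2)) for b in g2.bonds}

    def test_symmetry_expansion_finds_image_contacts(self):
        ops = [parse_symop("x,y,z"), parse_symop("-x,-y,-z")]
        # direct separation 3.0 Å (no bond), but the inversion image of C2
        # at (0.1, 0.5, 0.5) sits 1.0 Å from C1
        sites = [site("C1", "C", (0.2, 0.5, 0.5)), site("C2", "C", (0.9, 0.5, 0.5))]
        plain = infer_bonds(self.CELL, sites, {"C": 0.77}, tol=0.40)
        assert plain.bonds == []
        expanded = infer_bonds(self.CELL, sites, {"C": 0.77}, tol=0.40,
                               expand_symmetry=True, ops=ops)
        assert len(expanded.bonds) == 1

    def test_missing_radius_is_an_error(self):
        with pytest.raises(KeyError, match="covalent radius"):
            infer_bonds(self.CELL, [site("U1", "U", (0, 0, 0))], {"C": 0.77})

    def test_matches_brute_force_oracle_on_fixture(self, clean_block, disorder_block):
        for block in (clean_block, disorder_block):
            cell = cell_from_block(block)
            sites = sites_from_block(block)
            g = infer_bonds(cell, sites, DEFAULT_RADII, tol=0.40)
            got = {frozenset((b.atom1, b.atom2)) for b in g.bonds}
            # oracle: exhaustive scan over all 27 neighbouring images
            m = orthogonalization(cell)
            expected = set()
            for i, a in enumerate(sites):
                for j in range(i + 1, len(sites)):
                    b = sites[j]
                    if (
                        a.disorder_assembly is not None
                        and a.disorder_assembly == b.disorder_assembly
                        and a.disorder_group is not None
                        and b.disorder_group is not None
                        and a.disorder_group != b.disorder_group
                    ):
                        continue
                    cutoff = DEFAULT_RADII[a.element] + DEFAULT_RADII[b.element] + 0.40
                    best = min(
                        np.linalg.norm(
                            m @ (np.array(b.frac) - np.array(a.frac) + np.array(s))
                        )
                        for s in product((-1, 0, 1), repeat=3)
                    )
                    if best <= cutoff:
                        expected.add(frozenset((a.label, b.label)))
            assert got == expected

    def test_permutation_invariance(self, clean_block):
        cell = cell_from_block(clean_block)
        sites = sites_from_block(clean_block)
        g1 = infer_bonds(cell, sites, DEFAULT_RADII)
        g2 = infer_bonds(cell, list(reversed(sites)), DEFAULT_RADII)
        pairs = lambda g: {frozenset((b.atom1, b.atom2)) for b in g.bonds}
        assert pairs(g1) == pairs(g2)


class TestMoieties:
    def test_molecule_plus_counter_ion(self, clean_block):
        cell = cell_from_block(clean_block)
        sites = sites_from_block(clean_block)
        comps = moieties(infer_bonds(cell, sites, DEFAULT_RADII))
        assert len(comps) == 2
        assert [a.label for a in comps[1]] == ["Cl1"]  # smallest last

    def test_partition_property(self, disorder_block):
        cell = cell_from_block(disorder_block)
        sites = sites_from_block(disorder_block)
        comps = moieties(infer_bonds(cell, sites, DEFAULT_RADII))
        labels = [a.label for comp in comps for a in comp]
        assert sorted(labels) == sorted(s.label for s in sites)
        assert len(labels) == len(set(labels))

    def test_empty_graph(self):
        assert moieties(ConnectivityGraph([], [])) == []

    def test_fully_connected_toy(self):
        atoms = [site("C1", "C", (0, 0, 0)), site("C2", "C", (0.1, 0, 0))]
        g = ConnectivityGraph(atoms, [Bond("C1", "C2", 1.0)])
        assert len(moieties(g)) == 1


class TestFormula:
    def test_methane(self):
        comp = [site("C1", "C", (0, 0, 0))] + [
            site(f"H{i}", "H", (0.1 * i, 0, 0)) for i in range(1, 5)
        ]
        assert molecular_formula(comp) == "C H4"

    def test_perchlorate(self):
        comp = [site("Cl1", "Cl", (0, 0, 0))] + [
            site(f"O{i}", "O", (0.1 * i, 0, 0)) for i in range(1, 5)
        ]
        assert molecular_formula(comp) == "Cl O4"

    def test_occupancy_weighting_rounds_to_integers(self):
        comp = [
            site("O1A", "O", (0, 0, 0), occ=0.6),
            site("O1B", "O", (0.1, 0, 0), occ=0.4),
            site("C1", "C", (0.2, 0, 0)),
        ]
        assert molecular_formula(comp) == "C O"

    def test_empty_component(self):
        assert molecular_formula([]) == ""


class TestConnectionTable:
    @staticmethod
    def fresh_block(disorder=False):
        from cifsem.fixtures import FixtureSpec, generate_structure

        return generate_structure(FixtureSpec(seed=23, disorder=disorder))

    def build_graph(self, block):
        return infer_bonds(cell_from_block(block), sites_from_block(block), DEFAULT_RADII)

    def test_round_trip_identity(self):
        for block in (self.fresh_block(), self.fresh_block(disorder=True)):
            graph = self.build_graph(block)
            write_connection_table(block, graph)
            back = read_connection_table(block)
            assert [a.label for a in back.atoms] == [a.label for a in graph.atoms]
            assert [(b.pair, b.order) for b in back.bonds] == [
                (b.pair, b.order) for b in graph.bonds
            ]

    def test_round_trip_survives_file_serialisation(self):
        block = self.fresh_block()
        graph = self.build_graph(block)
        write_connection_table(block, graph)
        reread = parse_cif(write_cif(CifDocument([block])))[block.name]
        back = read_connection_table(reread)
        assert {b.pair for b in back.bonds} == {b.pair for b in graph.bonds}

    def test_empty_graph_emits_no_loops(self):
        block = DataBlock("empty")
        write_connection_table(block, ConnectivityGraph([], []))
        assert block.loops == []
        assert read_connection_table(block).atoms == []

    def test_existing_table_replaced_with_warning(self):
        block = self.fresh_block()
        graph = self.build_graph(block)
        write_connection_table(block, graph)
        with pytest.warns(UserWarning, match="replacing"):
            write_connection_table(block, graph)
        assert len([l for l in block.loops if l.has_tag("_chemical_conn_atom_number")]) == 1

    def test_bond_citing_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            ConnectivityGraph([site("C1", "C", (0, 0, 0))], [Bond("C1", "X9", 1.0)])
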
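import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dasi.chemgraph import (EMPTY_GRAPH, AROMATIC, Atom, ChemGraphError,
                            Formula, FormatError, MolGraph, canonical_key,
                            formula_of, is_substructure, mcs, parse_structure,
                            tanimoto, to_molblock, to_smiles)
from oracles import (ORACLE_MASSES, brute_force_isomorphic,
                     monomorphism_exists, permute_graph)


class TestParse:
    def test_ethanol(self):
        g = parse_structure("CCO")
        assert g.num_atoms == 3
        assert str(formula_of(g)) == "C2H6O"

    def test_atom_order_invariance(self):
        assert canonical_key(parse_structure("OCC")) == canonical_key(parse_structure("CCO"))

    def test_malformed(self):
        with pytest.raises(FormatError):
            parse_structure("C(")

    def test_kekule_vs_aromatic(self):
        assert (canonical_key(parse_structure("C1=CC=CC=C1"))
                == canonical_key(parse_structure("c1ccccc1")))

    def test_sdf_roundtrip(self, mols):
        for name in ("ethanol", "benzene", "glycine"):
            block = to_molblock(mols[name])
            back = parse_structure(block, fmt="sdf")
            assert canonical_key(back) == canonical_key(mols[name])

    def test_graph_invariants_enforced(self):
        with pytest.raises(ChemGraphError):
            MolGraph((Atom("C"),), ((0, 0, 1.0),))
        with pytest.raises(ChemGraphError):
            MolGraph((Atom("C"), Atom("C")), ((0, 1, 1.0), (0, 1, 2.0)))
        with pytest.raises(ChemGraphError):
            MolGraph((Atom("C"),), ((0, 1, 1.0),))


class TestCanonicalKey:
    def test_butane_vs_isobutane(self, mols):
        assert canonical_key(mols["butane"]) != canonical_key(mols["isobutane"])

    def test_permutation_invariance(self, mols):
        for name in ("toluene", "glycine", "ethanol"):
            g = mols[name]
            n = g.num_atoms
            for perm in itertools.islice(itertools.permutations(range(n)), 30):
                assert canonical_key(permute_graph(g, perm)) == canonical_key(g)

    def test_benzene_vs_cyclohexadiene(self, mols):
        # independent check first: the graphs are genuinely non-isomorphic
        assert not brute_force_isomorphic(mols["benzene"], mols["cyclohexadiene"])
        assert canonical_key(mols["benzene"]) != canonical_key(mols["cyclohexadiene"])

    def test_agrees_with_brute_force(self, mols):
        small = [g for g in mols.values() if g.num_atoms <= 7]
        for g1, g2 in itertools.combinations(small, 2):
            assert (canonical_key(g1) == canonical_key(g2)) == \
                brute_force_isomorphic(g1, g2)


class TestSubstructure:
    def test_benzene_in_toluene(self, mols):
        res = is_substructure(mols["benzene"], mols["toluene"])
        assert res.found
        assert len(res.mapping) == 6
        assert len(set(res.mapping.values())) == 6

    def test_toluene_not_in_benzene(self, mols):
        assert not is_substructure(mols["toluene"], mols["benzene"]).found

    def test_ethyl_in_ethanol(self, mols):
        frag = MolGraph((Atom("C", 0, 3), Atom("C", 0, 2)), ((0, 1, 1.0),))
        assert is_substructure(frag, mols["ethanol"]).found

    def test_self_substructure(self, mols):
        for g in mols.values():
            assert is_substructure(g, g).found

    def test_antisymmetric_for_different_sizes(self, mols):
        for g1, g2 in itertools.combinations(mols.values(), 2):
            if g1.num_atoms == g2.num_atoms:
                continue
            small, big = sorted((g1, g2), key=lambda g: g.num_atoms)
            if is_substructure(small, big).found:
                assert not is_substructure(big, small).found

    def test_agrees_with_independent_matcher(self, mols):
        names = list(mols)
        for n1, n2 in itertools.combinations(names, 2):
            got = is_substructure(mols[n1], mols[n2]).found
            assert got == monomorphism_exists(mols[n1], mols[n2])


class TestTanimoto:
    def test_identical(self, mols):
        for g in mols.values():
            assert tanimoto(g, g) == 1.0

    def test_symmetric(self, mols):
        pairs = list(itertools.combinations(mols.values(), 2))[:20]
        for a, b in pairs:
            assert tanimoto(a, b) == pytest.approx(tanimoto(b, a))

    def test_range(self, mols):
        for a, b in itertools.combinations(mols.values(), 2):
            assert 0.0 <= tanimoto(a, b) <= 1.0

    def test_matches_jaccard_definition(self, mols):
        from dasi.chemgraph import _fingerprint
        a, b = mols["ethanol"], mols["propanol"]
        fa = set(_fingerprint(a).GetOnBits())
        fb = set(_fingerprint(b).GetOnBits())
        expected = len(fa & fb) / len(fa | fb)
        assert tanimoto(a, b) == pytest.approx(expected)


class TestMCS:
    def test_identity(self, mols):
        out = mcs([mols["ethanol"], mols["ethanol"]])
        assert canonical_key(out) == canonical_key(mols["ethanol"])

    def test_singleton(self, mols):
        assert mcs([mols["toluene"]]) is mols["toluene"]

    def test_ethanol_propanol(self, mols):
        out = mcs([mols["ethanol"], mols["propanol"]])
        assert out.num_atoms == 3
        assert sorted(a.element for a in out.atoms) == ["C", "C", "O"]
        # linear C-C-O shape: both bonds single, connected
        assert len(out.bonds) == 2

    def test_methane_tetrafluoromethane(self, mols):
        out = mcs([mols["methane"], mols["tetrafluoromethane"]])
        assert out.num_atoms == 1
        assert out.atoms[0].element == "C"

    def test_no_common_atom(self, mols):
        water = parse_structure("O")
        assert mcs([mols["methane"], water]) is EMPTY_GRAPH

    def test_output_substructure_of_all_members(self, mols):
        members = [mols["toluene"], mols["benzene"], mols["pyridine"]]
        out = mcs(members)
        for m in members:
            assert is_substructure(out, m).found
            assert monomorphism_exists(out, m)  # independent route


class TestFormula:
    def test_ethanol_mass_derived(self, mols):
        expected = 2 * ORACLE_MASSES["C"] + 6 * ORACLE_MASSES["H"] + ORACLE_MASSES["O"]
        f = formula_of(mols["ethanol"])
        assert f.mass == pytest.approx(expected, abs=1e-4)
        assert f.mass == pytest.approx(46.0419, abs=1e-3)

    def test_benzene(self, mols):
        assert str(formula_of(mols["benzene"])) == "C6H6"

    def test_glycine(self, mols):
        assert str(formula_of(mols["glycine"])) == "C2H5NO2"

    def test_parse_roundtrip(self):
        f = Formula.from_string("C10H13N5O4")
        assert f["C"] == 10 and f["H"] == 13 and f["N"] == 5 and f["O"] == 4
        assert Formula.from_string(str(f)) == f

    def test_exact_equality(self):
        assert Formula.from_string("CH4") != Formula.from_string("CH3")

    def test_contains(self):
        big = Formula.from_string("C6H12O6")
        assert big.contains(Formula.from_string("C2H4O"))
        assert not big.contains(Formula.from_string("C7H2"))

    def test_unknown_element(self):
        with pytest.raises(Exception):
            Formula.from_string("Xx3")


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_property_permuted_key_stable(mols, data):
    name = data.draw(st.sampled_from(
        ["benzene", "butane", "ethanol", "glycine"]))
    g = mols[name]
    perm = tuple(data.draw(st.permutations(range(g.num_atoms))))
    assert canonical_key(permute_graph(g, perm)) == canonical_key(g)


def test_smiles_roundtrip(mols):
    for name, g in mols.items():
        back = parse_structure(to_smiles(g))
        assert canonical_key(back) == canonical_key(g), name
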
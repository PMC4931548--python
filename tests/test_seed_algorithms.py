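import numpy as np
import pytest

from dasi.bin_io import CIDSpectrum, UnknownFeatures
from dasi.chemgraph import (Atom, Formula, MolGraph, canonical_key,
                            is_substructure, mcs, parse_structure)
from dasi.config import FilterWindows
from dasi.fragment_match import (FragmentMatch, UniqueFragment,
                                 attach_fragments, consolidate)
from dasi.seed_algorithms import (A3_VARIANTS, SeedFailure, algorithm1,
                                  algorithm2, algorithm3, atom_match_counts,
                                  cluster_candidates, make_seed, molfind_score,
                                  seed_similarity, trim_mcs)
from conftest import make_candidate


def _unknown(spectrum=((50.0, 100.0),), formula="C4H8O2"):
    f = Formula.from_string(formula)
    return UnknownFeatures(id="u", mimw=f.mass, formula=f, ri_ref=200.0,
                           ecom50_ref=5.0, drift_ref=10.0,
                           spectrum=CIDSpectrum(tuple(spectrum)))


def _frag(smiles):
    """Build a fragment-shaped MolGraph from SMILES."""
    return parse_structure(smiles)


def _attach(cand, frag_smiles_and_intensities):
    cand.fragments = [
        FragmentMatch(_frag(smi), mz, inten, cand.id)
        for smi, mz, inten in frag_smiles_and_intensities]
    return cand


class TestMolfindScore:
    def test_perfect(self, windows):
        c = make_candidate("c", "CCOC(C)=O")
        c.metfrag_score = 1.0
        assert molfind_score(c, _unknown(), windows) == 1.0

    def test_half_window_derived(self, windows):
        # hand evaluation: (0.5 + (1-20/40) + 1 + 1)/4 = 0.75
        c = make_candidate("c", "CCOC(C)=O", ri=220.0)
        c.metfrag_score = 0.5
        assert molfind_score(c, _unknown(), windows) == pytest.approx(0.75)

    def test_zero_boundary(self, windows):
        c = make_candidate("c", "CCOC(C)=O", ri=240.0, ecom50=5.5, drift=10.35)
        c.metfrag_score = 0.0
        assert molfind_score(c, _unknown(), windows) == pytest.approx(0.0)

    def test_monotone_in_each_delta(self, windows):
        u = _unknown()
        base = make_candidate("c", "CCOC(C)=O")
        base.metfrag_score = 0.5
        prev = molfind_score(base, u, windows)
        for d_ri in (5.0, 10.0, 20.0, 40.0):
            c = make_candidate("c", "CCOC(C)=O", ri=200.0 + d_ri)
            c.metfrag_score = 0.5
            score = molfind_score(c, u, windows)
            assert score < prev
            prev = score


class TestClustering:
    def test_two_identical_plus_outlier(self, windows):
        a = make_candidate("a", "CCOC(C)=O")
        b = make_candidate("b", "O=C(C)OCC")
        c = make_candidate("c", "CCCCCCCCCC")
        clusters = cluster_candidates([a, b, c], _unknown(), windows)
        sizes = sorted(len(cl.members) for cl in clusters)
        assert sizes == [1, 2]

    def test_singleton(self, windows):
        out = cluster_candidates([make_candidate("a", "CCO")], _unknown(), windows)
        assert len(out) == 1 and len(out[0].members) == 1

    def test_ranked_by_avg_score(self, windows):
        good = make_candidate("good", "CCOC(C)=O")           # all deltas 0
        bad = make_candidate("bad", "CCCCCCCCCC", ri=235.0)  # large RI delta
        clusters = cluster_candidates([bad, good], _unknown(), windows)
        assert clusters[0].member_ids == ("good",)

    def test_min_pairwise_similarity_invariant(self, windows):
        from dasi.chemgraph import tanimoto
        cands = [make_candidate(f"c{k}", smi) for k, smi in enumerate(
            ["CCOC(C)=O", "O=C(C)OCC", "CCCCO", "CCCCCCCCCC", "c1ccccc1"])]
        clusters = cluster_candidates(cands, _unknown(), windows, threshold=0.9)
        for cl in clusters:
            for x in cl.members:
                for y in cl.members:
                    assert tanimoto(x.structure, y.structure) >= 0.9 - 1e-9


class TestAlgorithm1:
    def test_shared_fragment_wins(self):
        a = _attach(make_candidate("a", "CCOC(C)=O"),
                    [("CCO", 47.0, 10.0), ("CC=O", 45.0, 5.0)])
        b = _attach(make_candidate("b", "CC(=O)C(C)O"),
                    [("CCO", 47.0, 20.0), ("CC(C)=O", 59.0, 99.0)])
        seed = algorithm1([a, b])
        assert canonical_key(seed.graph) == canonical_key(_frag("CCO"))
        assert seed.algorithm == "A1"

    def test_single_candidate_single_fragment(self):
        a = _attach(make_candidate("a", "CCO"), [("CC", 31.0, 50.0)])
        seed = algorithm1([a])
        assert canonical_key(seed.graph) == canonical_key(_frag("CC"))

    def test_no_fragments_fails(self):
        a = make_candidate("a", "CCO")
        with pytest.raises(SeedFailure):
            algorithm1([a])


class TestAlgorithm2:
    def test_top_cluster_scope(self, windows):
        # two clusters; the global best fragment lives in the *lower* ranked
        # cluster, A2 must ignore it
        top1 = _attach(make_candidate("t1", "CCOC(C)=O"), [("CCO", 47.0, 10.0)])
        top2 = _attach(make_candidate("t2", "O=C(C)OCC"), [("CCO", 47.0, 12.0)])
        low = _attach(make_candidate("low", "CCCCCCCCCC", ri=230.0),
                      [("CCCC", 57.0, 99.0), ("CCCC", 57.0, 99.0),
                       ("CCCC", 57.0, 99.0)])
        seed = algorithm2([top1, top2, low], _unknown(), windows)
        assert canonical_key(seed.graph) == canonical_key(_frag("CCO"))

    def test_single_cluster_equals_algorithm1(self, windows):
        a = _attach(make_candidate("a", "CCOC(C)=O"), [("CCO", 47.0, 10.0)])
        b = _attach(make_candidate("b", "O=C(C)OCC"), [("CC=O", 45.0, 30.0)])
        s1 = algorithm1([a, b])
        s2 = algorithm2([a, b], _unknown(), windows)
        assert canonical_key(s1.graph) == canonical_key(s2.graph)

    def test_fragmentless_top_cluster_fails(self, windows):
        top1 = make_candidate("t1", "CCOC(C)=O")
        top2 = make_candidate("t2", "O=C(C)OCC")
        low = _attach(make_candidate("low", "CCCCCCCCCC", ri=235.0),
                      [("CCCC", 57.0, 99.0)])
        with pytest.raises(SeedFailure):
            algorithm2([top1, top2, low], _unknown(), windows)


class TestAtomMatchCounts:
    def test_benzene_fragment_on_toluene_mcs(self, mols):
        uf = UniqueFragment(mols["benzene"], occurrences=1, intensity=50.0)
        counts = atom_match_counts(mols["toluene"], [uf])
        # ring atoms covered once, methyl carbon never
        assert sorted(counts) == [0, 1, 1, 1, 1, 1, 1]

    def test_no_embedding_all_zero(self, mols):
        uf = UniqueFragment(_frag("CCCCCC"), occurrences=1, intensity=1.0)
        counts = atom_match_counts(mols["toluene"], [uf])
        assert counts == [0] * 7

    def test_multiple_fragments_accumulate(self, mols):
        ufs = [UniqueFragment(mols["benzene"], 1, 5.0),
               UniqueFragment(_frag("C"), 1, 5.0)]
        counts = atom_match_counts(mols["toluene"], ufs)
        assert max(counts) == 2  # ring carbons hit by both
        assert min(counts) == 1  # methyl carbon hit by the single-C fragment

    def test_per_fragment_increment_despite_symmetry(self, mols):
        # benzene embeds in toluene's ring 12 ways; per-fragment mode still
        # increments each covered atom exactly once
        uf = UniqueFragment(mols["benzene"], occurrences=1, intensity=1.0)
        counts = atom_match_counts(mols["toluene"], [uf], mode="per_fragment")
        assert max(counts) == 1


def _linear_abc():
    """A(3)-B(1)-C(2) linear three-carbon graph."""
    g = MolGraph((Atom("C", 0, 3), Atom("C", 0, 2), Atom("C", 0, 3)),
                 ((0, 1, 1.0), (1, 2, 1.0)))
    return g, [3, 1, 2]


class TestTrimMcs:
    def test_connectivity_retention_linear(self):
        g, counts = _linear_abc()
        seed = trim_mcs(g, counts, scheme="min2")
        # B is below threshold but bridges A and C: retained
        assert seed.graph.num_atoms == 3

    def test_ring_disintegration_blocked(self, mols):
        # benzene ring all counts 1 + exocyclic methyl count 3, scheme >=2:
        # ring kept intact, exocyclic kept
        toluene = mols["toluene"]
        methyl = next(i for i in range(7)
                      if len(toluene.neighbors(i)) == 1
                      and toluene.neighbors(i)[0][1] == 1.0)
        counts = [1] * 7
        counts[methyl] = 3
        seed = trim_mcs(toluene, counts, scheme="min2")
        assert seed.graph.num_atoms == 7

    def test_identity_when_all_above(self):
        g, _ = _linear_abc()
        seed = trim_mcs(g, [5, 5, 5], scheme="min2")
        assert canonical_key(seed.graph) == canonical_key(g)

    def test_terminal_atom_deleted(self):
        g, counts = _linear_abc()
        seed = trim_mcs(g, [3, 2, 1], scheme="min2")  # only C deletable
        assert seed.graph.num_atoms == 2

    def test_avg_scheme_derived(self):
        # counts {2,2,0}: average over matched atoms = 2 -> the 0 atom is the
        # deletion candidate
        g = MolGraph((Atom("C", 0, 3), Atom("C", 0, 2), Atom("C", 0, 3)),
                     ((0, 1, 1.0), (1, 2, 1.0)))
        seed = trim_mcs(g, [2, 2, 0], scheme="avg")
        assert seed.graph.num_atoms == 2

    def test_output_substructure_of_input(self, mols):
        g = mols["toluene"]
        seed = trim_mcs(g, [0, 1, 2, 3, 0, 1, 2], scheme="min2")
        assert is_substructure(seed.graph, g).found


class TestAlgorithm3:
    def _bin(self, windows):
        u = _unknown()
        a = _attach(make_candidate("a", "CCOC(C)=O"),
                    [("CCO", 47.0, 10.0), ("CCOC", 61.0, 20.0)])
        b = _attach(make_candidate("b", "O=C(C)OCC"),
                    [("CCO", 47.0, 15.0)])
        return u, [a, b]

    def test_variant_pipeline_runs(self, windows):
        u, cands = self._bin(windows)
        for variant in range(1, 7):
            seed = algorithm3(cands, u, windows, variant)
            assert seed.algorithm == f"A3-{variant}"
            assert seed.graph.is_connected()
            for c in cands[:1]:
                # seed must embed in every top-cluster member
                assert is_substructure(seed.graph, c.structure).found

    def test_singleton_top_cluster_mcs_is_member(self, windows):
        u = _unknown()
        lone = _attach(make_candidate("a", "CCOC(C)=O"), [("CCO", 47.0, 9.0)])
        seed = algorithm3([lone], u, windows, variant=1)
        assert is_substructure(seed.graph, lone.structure).found

    def test_threshold_ordering_property(self, windows):
        # deletion-candidate set for >=2 is a superset of that for >=1,
        # checked over 50 random count vectors (pre-retention)
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 4, size=7).tolist()
            del1 = {i for i, c in enumerate(counts) if c < 1}
            del2 = {i for i, c in enumerate(counts) if c < 2}
            assert del1 <= del2

    def test_make_seed_dispatch(self, windows):
        u, cands = self._bin(windows)
        for alg in ("A1", "A2", "A3-3", "A3-6"):
            seed = make_seed(cands, u, windows, alg)
            assert seed.algorithm == alg
        with pytest.raises(ValueError):
            make_seed(cands, u, windows, "A9")


class TestSeedSimilarity:
    def test_identical(self, mols):
        assert seed_similarity(mols["toluene"], mols["toluene"]) == 100.0

    def test_benzene_in_toluene_derived(self, mols):
        # 100 * 6/7
        assert seed_similarity(mols["benzene"], mols["toluene"]) == \
            pytest.approx(100 * 6 / 7)

    def test_not_embeddable(self, mols):
        assert seed_similarity(mols["glycine"], mols["benzene"]) == 0.0


def test_seed_is_substructure_of_top_cluster_members(windows, mols):
    """Chained invariant: trim_mcs output ⊆ MCS ⊆ every top-cluster member."""
    u = _unknown()
    a = _attach(make_candidate("a", "CCOC(C)=O"), [("CCO", 47.0, 10.0)])
    b = _attach(make_candidate("b", "O=C(C)OCC"), [("CCO", 47.0, 11.0)])
    seed = algorithm3([a, b], u, windows, variant=1)
    for c in seed.source_cluster.members:
        assert is_substructure(seed.graph, c.structure).found
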
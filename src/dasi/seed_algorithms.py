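"""Consensus-seed construction from a filtered candidate bin.

Three families of seed generators are provided:

* A1 — most frequent / most intense unique fragment over all filtered
  candidates.
* A2 — the same selection restricted to the top-ranked candidate
  cluster (complete-linkage Tanimoto clustering, clusters ranked by
  cluster-averaged composite score).
* A3-1..A3-6 — maximum common substructure of the top cluster, trimmed
  by per-atom fragment-match counts under six variant schemes (fragment
  pool: top cluster or all candidates; retention threshold: >=1, >=2, or
  >= the average count over matched atoms).

Trimming never disconnects the seed and never partially removes a ring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import chemgraph
from .chemgraph import MolGraph
from .bin_io import Candidate, UnknownFeatures
from .config import CLUSTER_THRESHOLD, ATOM_MATCH_MODE, FilterWindows
from .fragment_match import UniqueFragment, consolidate

ALGORITHM_IDS = ("A1", "A2", "A3-1", "A3-2", "A3-3", "A3-4", "A3-5", "A3-6")

#: Algorithm-3 variants: (fragment pool, retention scheme).
A3_VARIANTS = {
    1: ("top", "min1"),
    2: ("all", "min1"),
    3: ("top", "min2"),
    4: ("all", "min2"),
    5: ("top", "avg"),
    6: ("all", "avg"),
}


class SeedFailure(RuntimeError):
    """No seed can be derived from this bin with this algorithm."""


@dataclass(frozen=True)
class CandidateCluster:
    members: tuple[Candidate, ...]
    avg_molfind_score: float

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.members)


@dataclass(frozen=True)
class SeedStructure:
    graph: MolGraph
    algorithm: str
    source_cluster: Optional[CandidateCluster] = None

    def __post_init__(self):
        if self.graph.is_empty():
            raise SeedFailure(f"{self.algorithm}: empty seed graph")
        if not self.graph.is_connected():
            raise SeedFailure(f"{self.algorithm}: seed graph is disconnected")


def molfind_score(c: Candidate, unknown: UnknownFeatures, w: FilterWindows) -> float:
    """Composite of spectral match and window-normalized property deltas:

    (metfrag + (1-|dRI|/W_RI) + (1-|dEcom50|/W_E) + (1-|dDrift|/W_D)) / 4
    """
    d_ri = abs(unknown.ri_ref - c.ri_pred) / w.ri_window
    d_ec = abs(unknown.ecom50_ref - c.ecom50_pred) / w.ecom50_window
    d_dr = abs(unknown.drift_ref - c.drift_pred) / w.drift_window
    return (c.metfrag_score + (1 - d_ri) + (1 - d_ec) + (1 - d_dr)) / 4.0


def cluster_candidates(candidates: Sequence[Candidate], unknown: UnknownFeatures,
                       w: FilterWindows,
                       threshold: float = CLUSTER_THRESHOLD) -> list[CandidateCluster]:
    """Complete-linkage agglomerative clustering on Tanimoto similarity.

    Clusters are cut so that every merged cluster has minimum pairwise
    similarity >= threshold, then ranked by average composite score
    (ties: larger cluster, then sorted member ids).
    """
    if not candidates:
        raise SeedFailure("cannot cluster an empty candidate list")
    n = len(candidates)
    if n == 1:
        labels = [1]
    else:
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = 1.0 - chemgraph.tanimoto(candidates[i].structure,
                                             candidates[j].structure)
                dist[i, j] = dist[j, i] = d
        z = linkage(squareform(dist, checks=False), method="complete")
        labels = fcluster(z, t=(1.0 - threshold) + 1e-9, criterion="distance")
    groups: dict[int, list[Candidate]] = {}
    for lab, cand in zip(labels, candidates):
        groups.setdefault(int(lab), []).append(cand)
    clusters = [
        CandidateCluster(
            members=tuple(mem),
            avg_molfind_score=float(np.mean([molfind_score(c, unknown, w) for c in mem])),
        )
        for mem in groups.values()
    ]
    clusters.sort(key=lambda cl: (-cl.avg_molfind_score, -len(cl.members),
                                  tuple(sorted(cl.member_ids))))
    return clusters


def _unique_fragments(candidates: Sequence[Candidate]) -> list[UniqueFragment]:
    matches = [fm for c in candidates for fm in c.fragments]
    return consolidate(matches)


def algorithm1(candidates: Sequence[Candidate]) -> SeedStructure:
    """Seed = top unique fragment over all filtered candidates."""
    uniques = _unique_fragments(candidates)
    if not uniques:
        raise SeedFailure("A1: no fragment matches in the filtered bin")
    return SeedStructure(graph=uniques[0].fragment, algorithm="A1")


def algorithm2(candidates: Sequence[Candidate], unknown: UnknownFeatures,
               w: FilterWindows,
               threshold: float = CLUSTER_THRESHOLD) -> SeedStructure:
    """Seed = top unique fragment over the top-ranked cluster's members."""
    clusters = cluster_candidates(candidates, unknown, w, threshold=threshold)
    top = clusters[0]
    uniques = _unique_fragments(top.members)
    if not uniques:
        raise SeedFailure("A2: top cluster has no fragment matches")
    return SeedStructure(graph=uniques[0].fragment, algorithm="A2",
                         source_cluster=top)


def atom_match_counts(mcs_graph: MolGraph,
                      frags: Sequence[UniqueFragment],
                      mode: str = ATOM_MATCH_MODE) -> list[int]:
    """Per-MCS-atom count of unique fragments covering the atom.

    In ``per_fragment`` mode (default) each unique fragment increments an
    atom at most once, on the union of its embeddings; ``per_embedding``
    counts every embedding separately.
    """
    if mcs_graph.is_empty():
        raise SeedFailure("empty MCS")
    counts = [0] * mcs_graph.num_atoms
    for uf in frags:
        embeddings = chemgraph.all_embeddings(uf.fragment, mcs_graph)
        if not embeddings:
            continue
        if mode == "per_fragment":
            covered = {t for emb in embeddings for t in emb.values()}
            for t in covered:
                counts[t] += 1
        elif mode == "per_embedding":
            for emb in embeddings:
                for t in emb.values():
                    counts[t] += 1
        else:
            raise ValueError(f"unknown atom-match mode {mode!r}")
    return counts


def _resolve_threshold(scheme: str, counts: Sequence[int]) -> float:
    if scheme == "min1":
        return 1.0
    if scheme == "min2":
        return 2.0
    if scheme == "avg":
        matched = [c for c in counts if c >= 1]
        if not matched:
            return 1.0  # nothing matched; everything is below threshold
        return float(np.mean(matched))
    raise ValueError(f"unknown scheme {scheme!r}")


def trim_mcs(mcs_graph: MolGraph, counts: Sequence[int], scheme: str,
             algorithm: str = "A3") -> SeedStructure:
    """Delete under-matched MCS atoms, lowest count first, skipping any
    deletion that would disconnect the graph or break a ring.

    An atom that lies on any cycle of the current graph is never deleted
    (a single-atom removal from a ring is a ring disintegration); a
    deletion that splits the remainder into two or more pieces is
    skipped and the atom retained.
    """
    if mcs_graph.is_empty():
        raise SeedFailure(f"{algorithm}: empty MCS")
    if len(counts) != mcs_graph.num_atoms:
        raise ValueError("counts length must equal MCS atom count")
    threshold = _resolve_threshold(scheme, counts)

    g = mcs_graph.to_networkx()
    colors = chemgraph._refine_colors(mcs_graph, [0] * mcs_graph.num_atoms)
    deletable = sorted((a for a in range(mcs_graph.num_atoms) if counts[a] < threshold),
                       key=lambda a: (counts[a], colors[a], a))
    for atom in deletable:
        if g.number_of_nodes() <= 1:
            break
        ring_atoms = {a for cycle in nx.cycle_basis(g) for a in cycle}
        if atom in ring_atoms:
            continue  # ring disintegration not allowed
        trial = g.copy()
        trial.remove_node(atom)
        if trial.number_of_nodes() == 0 or not nx.is_connected(trial):
            continue  # disconnection not allowed
        g = trial

    kept = sorted(g.nodes)
    if not kept:
        raise SeedFailure(f"{algorithm}: trimming removed every atom")
    seed_graph = mcs_graph.subgraph(kept)
    return SeedStructure(graph=seed_graph, algorithm=algorithm)


def algorithm3(candidates: Sequence[Candidate], unknown: UnknownFeatures,
               w: FilterWindows, variant: int,
               threshold: float = CLUSTER_THRESHOLD) -> SeedStructure:
    """MCS of the top cluster, trimmed by fragment-match counts."""
    if variant not in A3_VARIANTS:
        raise ValueError(f"variant must be 1..6, got {variant}")
    pool_kind, scheme = A3_VARIANTS[variant]
    name = f"A3-{variant}"
    clusters = cluster_candidates(candidates, unknown, w, threshold=threshold)
    top = clusters[0]
    core = chemgraph.mcs([c.structure for c in top.members])
    if core.is_empty():
        raise SeedFailure(f"{name}: top cluster has no common substructure")
    pool = top.members if pool_kind == "top" else candidates
    uniques = _unique_fragments(pool)
    counts = atom_match_counts(core, uniques)
    seed = trim_mcs(core, counts, scheme, algorithm=name)
    return SeedStructure(graph=seed.graph, algorithm=name, source_cluster=top)


def make_seed(candidates: Sequence[Candidate], unknown: UnknownFeatures,
              w: FilterWindows, algorithm: str,
              threshold: float = CLUSTER_THRESHOLD) -> SeedStructure:
    """Dispatch on an algorithm identifier from ``ALGORITHM_IDS``."""
    if algorithm == "A1":
        return algorithm1(candidates)
    if algorithm == "A2":
        return algorithm2(candidates, unknown, w, threshold=threshold)
    if algorithm.startswith("A3-"):
        return algorithm3(candidates, unknown, w, int(algorithm.split("-")[1]),
                          threshold=threshold)
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHM_IDS}")


def seed_similarity(seed: MolGraph, target: MolGraph) -> float:
    """Percent of target heavy atoms covered by an exact embedding of the
    seed; 0 when the seed does not embed."""
    if seed.is_empty() or target.is_empty():
        raise ValueError("seed and target must be non-empty")
    if not chemgraph.is_substructure(seed, target).found:
        return 0.0
    return 100.0 * seed.num_atoms / target.num_atoms
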
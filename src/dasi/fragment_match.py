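"""Surrogate in-silico fragmentation and CID peak matching.

Fragments are produced by systematic disconnection of up to ``max_depth``
bonds; every connected product is a subgraph of the parent whose atoms
keep the parent's hydrogen counts (no hydrogen rearrangement is
modelled).  Matching is positive-ion mode: a fragment matches a peak
when the peak m/z is within a ppm tolerance of the fragment's protonated
monoisotopic mass.  The surrogate spectral score is the matched fraction
of total peak intensity; it is deliberately pluggable so a full
bond-energy-weighted scorer can replace it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from . import chemgraph
from .chemgraph import PROTON_MASS, MolGraph
from .bin_io import Candidate, CIDSpectrum
from .config import FRAGMENT_DEPTH, MATCH_TOL_PPM


@dataclass(frozen=True)
class FragmentMatch:
    fragment: MolGraph
    matched_mz: float
    matched_intensity: float
    parent_candidate_id: str


@dataclass(frozen=True)
class UniqueFragment:
    """A deduplicated fragment with occurrence count and the maximum
    matched-peak intensity over its occurrences."""

    fragment: MolGraph
    occurrences: int
    intensity: float

    @property
    def key(self) -> str:
        return chemgraph.canonical_key(self.fragment)


def fragment_molecule(m: MolGraph, max_depth: int = FRAGMENT_DEPTH) -> list[MolGraph]:
    """All unique connected fragments from 1..max_depth bond removals.

    Returned in deterministic (canonical key) order; every fragment is a
    subgraph of ``m`` by construction.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    n_bonds = len(m.bonds)
    if n_bonds == 0:
        return []
    base = m.to_networkx()
    seen: dict[str, MolGraph] = {}
    parent_key = chemgraph.canonical_key(m)
    for depth in range(1, max_depth + 1):
        for cut in itertools.combinations(range(n_bonds), depth):
            g = base.copy()
            removed = {(m.bonds[k][0], m.bonds[k][1]) for k in cut}
            g.remove_edges_from(removed)
            for comp in nx.connected_components(g):
                kept = [(i, j) for i, j, _ in m.bonds
                        if i in comp and j in comp and (i, j) not in removed]
                frag = m.subgraph(comp, bond_subset=kept)
                key = chemgraph.canonical_key(frag)
                if key != parent_key and key not in seen:
                    seen[key] = frag
    return [seen[k] for k in sorted(seen)]


def protonated_mass(fragment: MolGraph) -> float:
    """[fragment + H]+ monoisotopic mass."""
    return chemgraph.monoisotopic_mass(fragment) + PROTON_MASS


def match_spectrum(frags: Sequence[MolGraph], spec: CIDSpectrum,
                   tol_ppm: float = MATCH_TOL_PPM,
                   parent_candidate_id: str = "") -> list[FragmentMatch]:
    """Assign each fragment to at most one peak (the closest within the
    ppm tolerance of its protonated mass)."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    out = []
    for frag in frags:
        mz_f = protonated_mass(frag)
        best: Optional[tuple[float, float, float]] = None
        for mz, inten in spec.peaks:
            err = abs(mz - mz_f)
            if err / mz <= tol_ppm * 1e-6:
                if best is None or err < best[0]:
                    best = (err, mz, inten)
        if best is not None:
            out.append(FragmentMatch(frag, best[1], best[2], parent_candidate_id))
    return out


def metfrag_surrogate_score(matches: Sequence[FragmentMatch], spec: CIDSpectrum) -> float:
    """Matched fraction of total peak intensity, in [0, 1].

    Each peak counts once however many fragments hit it.
    """
    total = spec.total_intensity
    if total <= 0:
        return 0.0
    matched_mzs = {m.matched_mz for m in matches}
    matched = sum(inten for mz, inten in spec.peaks if mz in matched_mzs)
    return matched / total


def consolidate(matches: Sequence[FragmentMatch]) -> list[UniqueFragment]:
    """Group matches by fragment canonical key into UniqueFragments,
    sorted by occurrences desc, intensity desc, canonical key asc."""
    groups: dict[str, list[FragmentMatch]] = {}
    rep: dict[str, MolGraph] = {}
    for fm in matches:
        key = chemgraph.canonical_key(fm.fragment)
        groups.setdefault(key, []).append(fm)
        rep.setdefault(key, fm.fragment)
    uniques = [
        UniqueFragment(fragment=rep[key],
                       occurrences=len(group),
                       intensity=max(fm.matched_intensity for fm in group))
        for key, group in groups.items()
    ]
    uniques.sort(key=lambda u: (-u.occurrences, -u.intensity, u.key))
    return uniques


def attach_fragments(candidates: Sequence[Candidate], spec: CIDSpectrum,
                     max_depth: int = FRAGMENT_DEPTH,
                     tol_ppm: float = MATCH_TOL_PPM) -> None:
    """Fragment every candidate, match against the unknown's spectrum and
    fill each candidate's ``fragments`` and ``metfrag_score`` in place."""
    for c in candidates:
        frags = fragment_molecule(c.structure, max_depth=max_depth)
        c.fragments = match_spectrum(frags, spec, tol_ppm=tol_ppm,
                                     parent_candidate_id=c.id)
        c.metfrag_score = metfrag_surrogate_score(c.fragments, spec)
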
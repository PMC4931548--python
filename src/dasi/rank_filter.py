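"""Refiltering and ranking of generated structures.

Generated structures are pushed back through the property windows with
live predictor contracts, fragmented and scored against the unknown's
CID spectrum, ranked by spectral score, and optionally filtered by a
molecular-mechanics energy window (mean +/- k*sd of a reference cluster's
conformer energies).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import chemgraph
from .chemgraph import MolGraph
from .bin_io import UnknownFeatures
from .config import (ENERGY_K, FRAGMENT_DEPTH, MATCH_TOL_PPM, AcceptAll,
                     BiologicalClassifier, FilterWindows, ForceFieldProvider,
                     PredictorSet)
from .fragment_match import fragment_molecule, match_spectrum, metfrag_surrogate_score
from .structgen import GenerationResult

log = logging.getLogger(__name__)


class RefilterRefused(RuntimeError):
    """Bin hit the generation cap; refiltering is not attempted."""


@dataclass(frozen=True)
class EnergyWindow:
    mean: float
    sd: float
    k: float = ENERGY_K

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.mean - self.k * self.sd, self.mean + self.k * self.sd)

    def contains(self, energy: float) -> bool:
        lo, hi = self.bounds
        return lo <= energy <= hi


@dataclass(frozen=True)
class RankedCandidate:
    structure: MolGraph
    fragment_score: float
    metfrag_rank: int  # 1-based, dense, ties share a rank
    molfind_score: float
    ri_pred: float
    ecom50_pred: float
    drift_pred: float
    energy: Optional[float] = None

    @property
    def key(self) -> str:
        return chemgraph.canonical_key(self.structure)


def _dense_ranks(scores: Sequence[float]) -> list[int]:
    """Dense 1-based ranks for descending scores (ties share a rank)."""
    distinct = sorted(set(scores), reverse=True)
    rank_of = {s: r + 1 for r, s in enumerate(distinct)}
    return [rank_of[s] for s in scores]


def refilter(gen: GenerationResult, unknown: UnknownFeatures, w: FilterWindows,
             predictors: PredictorSet,
             bio: Optional[BiologicalClassifier] = None,
             max_depth: int = FRAGMENT_DEPTH,
             tol_ppm: float = MATCH_TOL_PPM) -> list[RankedCandidate]:
    """Window-filter, score and rank generated structures.

    Refuses bins that hit the structure cap (refiltering such bins is
    impractical by contract).  Output is sorted by fragment score
    descending, canonical key ascending, with dense tie-aware ranks.
    """
    if gen.truncated_by == "cap":
        raise RefilterRefused(
            f"generation was capped at {gen.count} structures; refusing to refilter")
    bio = bio or AcceptAll()

    scored = []
    for g in gen.structures:
        ri = predictors.ri.predict(g)
        ec = predictors.ecom50.predict(g)
        dr = predictors.drift.predict(g)
        if abs(ri - unknown.ri_ref) > w.ri_window:
            continue
        if abs(ec - unknown.ecom50_ref) > w.ecom50_window:
            continue
        if abs(dr - unknown.drift_ref) > w.drift_window:
            continue
        if not bio.accepts(g):
            continue
        frags = fragment_molecule(g, max_depth=max_depth)
        matches = match_spectrum(frags, unknown.spectrum, tol_ppm=tol_ppm)
        fscore = metfrag_surrogate_score(matches, unknown.spectrum)
        mfscore = (fscore
                   + (1 - abs(unknown.ri_ref - ri) / w.ri_window)
                   + (1 - abs(unknown.ecom50_ref - ec) / w.ecom50_window)
                   + (1 - abs(unknown.drift_ref - dr) / w.drift_window)) / 4.0
        scored.append((fscore, chemgraph.canonical_key(g), g, mfscore, ri, ec, dr))

    scored.sort(key=lambda t: (-t[0], t[1]))
    ranks = _dense_ranks([t[0] for t in scored])
    return [
        RankedCandidate(structure=g, fragment_score=fscore, metfrag_rank=rank,
                        molfind_score=mfscore, ri_pred=ri, ecom50_pred=ec,
                        drift_pred=dr)
        for (fscore, _, g, mfscore, ri, ec, dr), rank in zip(scored, ranks)
    ]


def energy_window_from_cluster(energies: Sequence[float],
                               others: Sequence[tuple[float, float]] = (),
                               k: float = ENERGY_K) -> EnergyWindow:
    """Energy window from a cluster's conformer energies.

    With two or more energies: mean and sample (n-1) standard deviation.
    A singleton cluster borrows the average relative sd of the other
    clusters, scaled by the magnitude of its single energy.
    """
    if not energies:
        raise ValueError("energies must be non-empty")
    if len(energies) >= 2:
        mean = float(np.mean(energies))
        sd = float(np.std(energies, ddof=1))
        return EnergyWindow(mean=mean, sd=sd, k=k)
    if not others:
        raise ValueError("singleton cluster needs other clusters' summaries "
                         "to derive a window")
    rel = [abs(sd_i / mean_i) for mean_i, sd_i in others if mean_i != 0]
    if not rel:
        raise ValueError("other clusters have zero means; no relative sd derivable")
    single = float(energies[0])
    return EnergyWindow(mean=single, sd=float(np.mean(rel)) * abs(single), k=k)


def apply_energy_filter(cands: Sequence[RankedCandidate], window: EnergyWindow,
                        ff: ForceFieldProvider) -> list[RankedCandidate]:
    """Keep candidates whose lowest-conformer energy is inside the closed
    window; provider failures retain the candidate (fail-open).  Relative
    order is preserved and ranks recomputed densely."""
    survivors = []
    for c in cands:
        try:
            energy = ff.lowest_energy(c.structure)
            if not math.isfinite(energy):
                raise RuntimeError(f"non-finite energy {energy}")
        except Exception as exc:
            log.warning("force-field failure on %s: %s; candidate retained",
                        c.key[:40], exc)
            survivors.append(replace(c, energy=None))
            continue
        if window.contains(energy):
            survivors.append(replace(c, energy=energy))
    ranks = _dense_ranks([c.fragment_score for c in survivors])
    return [replace(c, metfrag_rank=r) for c, r in zip(survivors, ranks)]


def write_ranked_csv(cands: Sequence[RankedCandidate], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "smiles", "fragment_score", "molfind_score",
                         "ri_pred", "ecom50_pred", "drift_pred", "energy"])
        for c in cands:
            try:
                smiles = chemgraph.to_smiles(c.structure)
            except Exception:
                smiles = ""
            writer.writerow([c.metfrag_rank, smiles, f"{c.fragment_score:.6f}",
                             f"{c.molfind_score:.6f}", c.ri_pred, c.ecom50_pred,
                             c.drift_pred,
                             "" if c.energy is None else f"{c.energy:.4f}"])
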
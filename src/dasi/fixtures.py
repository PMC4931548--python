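"""Self-contained toy bins and badlists for testing every stage offline.

A toy bin hides a known target: candidates are structural analogs of the
target produced by formula-preserving edits (element transpositions and
single-bond rewires), each assigned predicted properties equal to the
target's references plus Normal noise; the unknown's CID spectrum is
synthesized from the target's own fragments.  The target itself is
excluded from the candidate list, so recovering it exercises the whole
seed -> generate -> refilter path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from . import chemgraph
from .chemgraph import Atom, MolGraph
from .config import VALENCES
from .fragment_match import fragment_molecule, protonated_mass

#: Reference property values every fixture unknown is pinned to.
REFERENCE_RI = 200.0
REFERENCE_ECOM50 = 5.0
REFERENCE_DRIFT = 10.0


class FixtureError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    target: Union[str, MolGraph]
    n_analogs: int = 8
    property_noise: tuple[float, float, float] = (5.0, 0.05, 0.05)
    fragment_depth: int = 2
    rng_seed: int = 0
    max_peaks: int = 30

    @property
    def target_graph(self) -> MolGraph:
        if isinstance(self.target, MolGraph):
            return self.target
        return chemgraph.parse_structure(self.target, fmt="smiles")


def _degree(g: MolGraph, i: int) -> float:
    return sum(order for _, order in g.neighbors(i))


def _rebuild(atoms, bonds) -> MolGraph:
    return MolGraph(tuple(atoms), tuple(sorted(bonds)))


def _valid(g: MolGraph) -> bool:
    if not g.is_connected():
        return False
    try:
        chemgraph.to_rdkit(g, sanitize=True)
        return True
    except Exception:
        return False


def _element_transpositions(g: MolGraph) -> list[MolGraph]:
    """Exchange the elements of two unlike atoms (formula-preserving)."""
    out = []
    for i, j in itertools.combinations(range(g.num_atoms), 2):
        ai, aj = g.atoms[i], g.atoms[j]
        if ai.element == aj.element or ai.charge or aj.charge:
            continue
        di, dj = _degree(g, i), _degree(g, j)
        vi, vj = VALENCES.get(aj.element), VALENCES.get(ai.element)
        if vi is None or vj is None:
            continue
        hi, hj = vi - di, vj - dj
        if hi < 0 or hj < 0 or hi != int(hi) or hj != int(hj):
            continue
        atoms = list(g.atoms)
        atoms[i] = Atom(aj.element, 0, int(hi))
        atoms[j] = Atom(ai.element, 0, int(hj))
        cand = _rebuild(atoms, g.bonds)
        if _valid(cand):
            out.append(cand)
    return out


def _bond_rewires(g: MolGraph) -> list[MolGraph]:
    """Move one non-aromatic bond to a currently unbonded atom pair."""
    out = []
    bonded = {(i, j) for i, j, _ in g.bonds}
    for b_idx, (i, j, order) in enumerate(g.bonds):
        if order == chemgraph.AROMATIC:
            continue
        rest = [g.bonds[k] for k in range(len(g.bonds)) if k != b_idx]
        for k, l in itertools.combinations(range(g.num_atoms), 2):
            if (k, l) in bonded or (k, l) == (i, j):
                continue
            atoms = list(g.atoms)
            ok = True
            # hydrogen bookkeeping: i and j gain order H, k and l lose order H
            deltas: dict[int, float] = {}
            for idx, dh in ((i, order), (j, order), (k, -order), (l, -order)):
                deltas[idx] = deltas.get(idx, 0) + dh
            for idx, dh in deltas.items():
                a = atoms[idx]
                nh = a.n_h + dh
                if nh < 0 or nh != int(nh):
                    ok = False
                    break
                atoms[idx] = Atom(a.element, a.charge, int(nh))
            if not ok:
                continue
            cand = _rebuild(atoms, rest + [(k, l, order)])
            if _valid(cand):
                out.append(cand)
    return out


def analog_pool(target: MolGraph) -> list[MolGraph]:
    """All distinct valid formula-preserving analogs of the target,
    excluding the target itself, in deterministic canonical-key order."""
    target_key = chemgraph.canonical_key(target)
    pool: dict[str, MolGraph] = {}
    for cand in _element_transpositions(target) + _bond_rewires(target):
        key = chemgraph.canonical_key(cand)
        if key != target_key and key not in pool:
            pool[key] = cand
    return [pool[k] for k in sorted(pool)]


def synth_spectrum(target: MolGraph, depth: int, rng: np.random.Generator,
                   max_peaks: int = 30) -> list[list[float]]:
    """Peak list from the target's own fragments: protonated masses with
    synthetic decaying intensities."""
    masses = sorted({round(protonated_mass(f), 4)
                     for f in fragment_molecule(target, max_depth=depth)})
    if len(masses) > max_peaks:
        idx = rng.choice(len(masses), size=max_peaks, replace=False)
        masses = sorted(masses[i] for i in idx)
    peaks = []
    for rank, mz in enumerate(sorted(masses, reverse=True)):
        inten = 100.0 * (0.85 ** rank) * float(rng.uniform(0.9, 1.1))
        peaks.append([mz, round(inten, 3)])
    peaks.sort(key=lambda p: p[0])
    return peaks


def make_toy_bin(spec: FixtureSpec) -> dict:
    """Build a ``dasi-bin/1`` document around a hidden target."""
    target = spec.target_graph
    if target.num_atoms > 12:
        raise FixtureError("fixture targets are capped at 12 heavy atoms")
    rng = np.random.default_rng(spec.rng_seed)
    pool = analog_pool(target)
    if not pool:
        raise FixtureError("no valid analogs constructible from this target")
    if len(pool) < spec.n_analogs:
        raise FixtureError(
            f"only {len(pool)} analogs constructible, {spec.n_analogs} requested")
    chosen_idx = rng.choice(len(pool), size=spec.n_analogs, replace=False)
    analogs = [pool[i] for i in sorted(chosen_idx)]

    ri_sd, ec_sd, dr_sd = spec.property_noise
    formula = chemgraph.formula_of(target)
    doc = {
        "version": "dasi-bin/1",
        "fixture": {"rng_seed": spec.rng_seed, "n_analogs": spec.n_analogs,
                    "fragment_depth": spec.fragment_depth,
                    "property_noise": [ri_sd, ec_sd, dr_sd]},
        "unknown": {
            "id": "unknown-0",
            "formula": str(formula),
            "mimw": formula.mass,
            "ri": REFERENCE_RI,
            "ecom50": REFERENCE_ECOM50,
            "drift": REFERENCE_DRIFT,
            "spectrum": synth_spectrum(target, spec.fragment_depth, rng,
                                       max_peaks=spec.max_peaks),
        },
        "candidates": [],
    }
    for k, analog in enumerate(analogs):
        doc["candidates"].append({
            "id": f"analog-{k:03d}",
            "smiles": chemgraph.to_smiles(analog),
            "ri_pred": REFERENCE_RI + float(rng.normal(0, ri_sd)) if ri_sd else REFERENCE_RI,
            "ecom50_pred": REFERENCE_ECOM50 + float(rng.normal(0, ec_sd)) if ec_sd else REFERENCE_ECOM50,
            "drift_pred": REFERENCE_DRIFT + float(rng.normal(0, dr_sd)) if dr_sd else REFERENCE_DRIFT,
            "bio_score": 1.0,
        })
    return doc


BADLIST_FIXTURE = """\
# Strained-ring and non-endogenous bonding patterns (illustrative starter set).
C1=CC1            # cyclopropene
O1C=C1            # oxirene
C1=CC=C1          # cyclobutadiene
C=C=C             # cumulated diene
[OX2][OX2]        # peroxide linkage
[NX3][NX3][NX3]   # triamine chain
"""


def make_badlist_fixture() -> str:
    """Starter badlist text (SMARTS, one per line, '#' comments)."""
    return BADLIST_FIXTURE
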
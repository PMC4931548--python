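"""Desk-scale constrained combinatorial structure generation.

Enumerates every connected constitutional isomer of a molecular formula
over a fixed valence model (nitrogen valence 3), optionally constrained
to contain a seed substructure and to contain no forbidden (badlist)
SMARTS pattern.

The enumerator fills the upper triangle of the bond-order matrix pair by
pair over a fixed, element-sorted atom ordering, with exact bond-order
budget, per-atom valence caps, a sound partial-symmetry prune (adjacent
same-element columns must be non-increasing while their prefixes agree),
and a final canonical-key deduplication after aromatic perception, so a
Kekulé-degenerate aromatic system counts once.  Seed and badlist
constraints are verified per emitted structure with the independent
matchers in :mod:`dasi.chemgraph`.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from rdkit import Chem

from . import chemgraph
from .chemgraph import Atom, Formula, MolGraph
from .config import (GENERATION_TIMEOUT_S, HEAVY_ATOM_GUARD, MAX_STRUCTURES,
                     VALENCES)
from .seed_algorithms import SeedStructure


class GenerationError(RuntimeError):
    pass


class GenerationTimeout(GenerationError):
    """Timed out before emitting a single structure."""


class BadlistError(ValueError):
    """A badlist SMARTS pattern failed to parse."""


#: Deterministic atom ordering for enumeration: valence desc, then symbol.
_ELEMENT_ORDER = sorted(VALENCES, key=lambda el: (-VALENCES[el], el))


@dataclass(frozen=True)
class GenerationJob:
    formula: Formula
    seed: Optional[Union[SeedStructure, MolGraph]] = None
    badlist: tuple[str, ...] = ()
    max_structures: int = MAX_STRUCTURES
    timeout: float = GENERATION_TIMEOUT_S
    heavy_atom_guard: int = HEAVY_ATOM_GUARD
    force: bool = False

    def __post_init__(self):
        if self.max_structures < 1:
            raise ValueError("max_structures must be >= 1")
        seed_graph = self.seed_graph
        if seed_graph is not None:
            if not self.formula.contains(chemgraph.formula_of(seed_graph)):
                # hydrogen counts of a fragment seed may legitimately exceed
                # the H budget locally; heavy atoms must fit element-wise
                heavy = {el: n for el, n in
                         chemgraph.formula_of(seed_graph).counts if el != "H"}
                if not all(self.formula[el] >= n for el, n in heavy.items()):
                    raise ValueError("seed formula exceeds job formula")

    @property
    def seed_graph(self) -> Optional[MolGraph]:
        if self.seed is None:
            return None
        return self.seed.graph if isinstance(self.seed, SeedStructure) else self.seed


@dataclass
class GenerationResult:
    structures: list[MolGraph]
    truncated_by: str  # "none" | "cap" | "timeout"

    @property
    def count(self) -> int:
        return len(self.structures)


# ---------------------------------------------------------------------------
# badlist
# ---------------------------------------------------------------------------

_SMARTS_CACHE: dict[str, Chem.Mol] = {}


def compile_badlist(patterns: Sequence[str]) -> list[Chem.Mol]:
    out = []
    for p in patterns:
        if p not in _SMARTS_CACHE:
            q = Chem.MolFromSmarts(p)
            if q is None:
                raise BadlistError(f"invalid SMARTS pattern {p!r}")
            _SMARTS_CACHE[p] = q
        out.append(_SMARTS_CACHE[p])
    return out


def load_badlist(path) -> list[str]:
    """Read a SMARTS badlist file: one pattern per line, '#' comments."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                patterns.append(line)
    compile_badlist(patterns)  # validate at load time
    return patterns


def contains_badlist(g: MolGraph, badlist: Sequence[str]) -> bool:
    """True iff any badlist pattern has at least one embedding in g."""
    if not badlist:
        return False
    queries = compile_badlist(list(badlist))
    try:
        mol = chemgraph.to_rdkit(g, sanitize=True)
    except Exception:
        try:
            mol = chemgraph.to_rdkit(g, sanitize=False)
        except Exception:
            return False  # fail-open: unmatchable graph is not rejected
    return any(mol.HasSubstructMatch(q) for q in queries)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

class _CapReached(Exception):
    pass


class _TimedOut(Exception):
    pass


def _atom_list(formula: Formula) -> tuple[list[str], int]:
    counts = formula.as_dict()
    n_h = counts.pop("H", 0)
    for el in counts:
        if el not in VALENCES:
            raise GenerationError(
                f"unsupported element {el!r}; supported: {sorted(VALENCES)}")
    elements = []
    for el in _ELEMENT_ORDER:
        elements.extend([el] * counts.get(el, 0))
    return elements, n_h


def _perceive(g: MolGraph) -> MolGraph:
    """Aromatic perception on a Kekulé graph; raw graph on failure."""
    try:
        return chemgraph.from_rdkit(chemgraph.to_rdkit(g, sanitize=True))
    except Exception:
        return g


def generate(job: GenerationJob) -> GenerationResult:
    """Enumerate all structures satisfying the job constraints.

    Exhaustive when ``truncated_by == "none"``; stops early at the
    structure cap or the cooperative timeout.
    """
    elements, h_target = _atom_list(job.formula)
    n = len(elements)
    if n == 0:
        raise GenerationError("formula has no heavy atoms")
    if n > job.heavy_atom_guard and not job.force:
        raise GenerationError(
            f"{n} heavy atoms exceeds the desk-scale guard "
            f"({job.heavy_atom_guard}); pass force=True to override")

    valences = [VALENCES[el] for el in elements]
    total_val = sum(valences)
    seed_graph = job.seed_graph
    badlist = list(job.badlist)
    deadline = time.monotonic() + job.timeout

    # exact total bond order; infeasible budgets yield empty results
    if (total_val - h_target) % 2 != 0 or total_val - h_target < 0:
        return GenerationResult([], "none")
    budget = (total_val - h_target) // 2
    if n == 1:
        out = []
        if budget == 0:
            g = _perceive(MolGraph((Atom(elements[0], 0, h_target),), ()))
            if _accept(g, seed_graph, badlist):
                out.append(g)
        return GenerationResult(out, "none")
    if budget < n - 1:
        return GenerationResult([], "none")

    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    a = [[0] * n for _ in range(n)]
    deg = [0] * n
    seen: set[str] = set()
    accepted: list[MolGraph] = []
    state = {"leaves": 0, "pending_cap": False}

    def finish_leaf() -> None:
        state["leaves"] += 1
        if state["leaves"] % 64 == 0 and time.monotonic() > deadline:
            raise _TimedOut()
        # connectivity
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        comps = n
        for i in range(n):
            for j in range(i + 1, n):
                if a[i][j]:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
                        comps -= 1
        if comps != 1:
            return
        atoms = tuple(Atom(elements[i], 0, valences[i] - deg[i]) for i in range(n))
        bonds = tuple((i, j, float(a[i][j]))
                      for i in range(n) for j in range(i + 1, n) if a[i][j])
        g = _perceive(MolGraph(atoms, bonds))
        key = chemgraph.canonical_key(g)
        if key in seen:
            return
        seen.add(key)
        if not _accept(g, seed_graph, badlist):
            return
        if state["pending_cap"]:
            raise _CapReached()  # at least one more structure exists
        accepted.append(g)
        if len(accepted) == job.max_structures:
            state["pending_cap"] = True

    def assign(p: int, used: int) -> None:
        if p == len(pairs):
            if used == budget:
                finish_leaf()
            return
        i, j = pairs[p]
        remaining_after = len(pairs) - p - 1
        cap_ij = min(3, valences[i] - deg[i], valences[j] - deg[j], budget - used)
        # symmetry prune: columns j-1 and j swap-comparable while equal above
        limit = cap_ij
        if j - 1 > i and elements[j - 1] == elements[j]:
            if all(a[k][j - 1] == a[k][j] for k in range(i)):
                limit = min(limit, a[i][j - 1])
        for order in range(limit, -1, -1):
            a[i][j] = a[j][i] = order
            deg[i] += order
            deg[j] += order
            ok = True
            if j == n - 1 and deg[i] == 0:
                ok = False  # atom i's pairs are complete and it is isolated
            if ok and p == len(pairs) - 1 and deg[n - 1] == 0:
                ok = False
            if ok and budget - used - order > 3 * remaining_after:
                ok = False  # cannot spend the remaining budget
            if ok:
                assign(p + 1, used + order)
            deg[i] -= order
            deg[j] -= order
            a[i][j] = a[j][i] = 0

    truncated = "none"
    try:
        assign(0, 0)
    except _CapReached:
        truncated = "cap"
    except _TimedOut:
        if not accepted:
            raise GenerationTimeout(
                f"no structures generated within {job.timeout:.0f} s")
        truncated = "timeout"
    return GenerationResult(accepted, truncated)


def _accept(g: MolGraph, seed_graph: Optional[MolGraph],
            badlist: Sequence[str]) -> bool:
    if seed_graph is not None and not chemgraph.is_substructure(seed_graph, g).found:
        return False
    if badlist and contains_badlist(g, badlist):
        return False
    return True
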
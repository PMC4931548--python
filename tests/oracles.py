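"""Independent oracles used by the test suite.

Deliberately separate code paths from the package: brute-force
permutation isomorphism, a hand-written monomorphism backtracker, and a
symmetry-blind structure enumerator deduplicated with networkx VF2.
These must stay independent of dasi.chemgraph / dasi.structgen internals
so that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools

import networkx as nx

from dasi.chemgraph import Atom, MolGraph

#: Independent copy of the standard monoisotopic masses (NIST values).
ORACLE_MASSES = {"H": 1.007825032, "C": 12.0, "N": 14.003074005,
                 "O": 15.994914620, "S": 31.972071174, "P": 30.973761998}


def brute_force_isomorphic(g1: MolGraph, g2: MolGraph) -> bool:
    """All-permutations isomorphism test (element, charge, n_h, order)."""
    if g1.num_atoms != g2.num_atoms or len(g1.bonds) != len(g2.bonds):
        return False
    lab1 = sorted(a.label() for a in g1.atoms)
    lab2 = sorted(a.label() for a in g2.atoms)
    if lab1 != lab2:
        return False
    b2 = {(i, j): o for i, j, o in g2.bonds}
    for perm in itertools.permutations(range(g1.num_atoms)):
        if any(g1.atoms[i].label() != g2.atoms[perm[i]].label()
               for i in range(g1.num_atoms)):
            continue
        ok = True
        for i, j, o in g1.bonds:
            pi, pj = sorted((perm[i], perm[j]))
            if b2.get((pi, pj)) != o:
                ok = False
                break
        if ok and len(b2) == len(g1.bonds):
            return True
    return False


def monomorphism_exists(query: MolGraph, target: MolGraph) -> bool:
    """Hand-written backtracking subgraph-monomorphism check (elements,
    charges and bond orders exact; hydrogen counts ignored)."""
    nq, nt = query.num_atoms, target.num_atoms
    if nq == 0 or nq > nt:
        return nq == 0
    q_adj = [dict() for _ in range(nq)]
    for i, j, o in query.bonds:
        q_adj[i][j] = o
        q_adj[j][i] = o
    t_adj = [dict() for _ in range(nt)]
    for i, j, o in target.bonds:
        t_adj[i][j] = o
        t_adj[j][i] = o

    assignment: dict[int, int] = {}
    used: set[int] = set()

    def compatible(q: int, t: int) -> bool:
        aq, at = query.atoms[q], target.atoms[t]
        if aq.element != at.element or aq.charge != at.charge:
            return False
        for qn, o in q_adj[q].items():
            if qn in assignment and t_adj[t].get(assignment[qn]) != o:
                return False
        return True

    order = sorted(range(nq), key=lambda q: -len(q_adj[q]))

    def backtrack(pos: int) -> bool:
        if pos == nq:
            return True
        q = order[pos]
        for t in range(nt):
            if t in used or not compatible(q, t):
                continue
            assignment[q] = t
            used.add(t)
            if backtrack(pos + 1):
                return True
            del assignment[q]
            used.remove(t)
        return False

    return backtrack(0)


def permute_graph(g: MolGraph, perm: tuple[int, ...]) -> MolGraph:
    """Relabel atoms of g by perm (atom i goes to position perm[i])."""
    atoms = [None] * g.num_atoms
    for i, a in enumerate(g.atoms):
        atoms[perm[i]] = a
    bonds = tuple(sorted((min(perm[i], perm[j]), max(perm[i], perm[j]), o)
                         for i, j, o in g.bonds))
    return MolGraph(tuple(atoms), bonds)


# ---------------------------------------------------------------------------
# independent structure enumerator
# ---------------------------------------------------------------------------

ORACLE_VALENCES = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}


def _parse_formula(s: str) -> dict[str, int]:
    import re
    counts: dict[str, int] = {}
    for el, num in re.findall(r"([A-Z][a-z]?)(\d*)", s):
        if el:
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    return counts


def count_structures_oracle(formula: str) -> int:
    """Count connected constitutional isomers by symmetry-blind
    enumeration of all bond-order matrices + VF2 isomorphism dedup."""
    counts = _parse_formula(formula)
    h = counts.pop("H", 0)
    elements: list[str] = []
    for el in sorted(counts):
        elements.extend([el] * counts[el])
    n = len(elements)
    val = [ORACLE_VALENCES[el] for el in elements]
    total = sum(val) - h
    if total < 0 or total % 2:
        return 0
    budget = total // 2
    if n == 1:
        return 1 if budget == 0 else 0
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    deg = [0] * n
    reps: list[nx.Graph] = []

    def nm(a, b):
        return a["element"] == b["element"]

    def em(a, b):
        return a["order"] == b["order"]

    def leaf(orders):
        g = nx.Graph()
        for i, el in enumerate(elements):
            g.add_node(i, element=el)
        for (i, j), o in zip(pairs, orders):
            if o:
                g.add_edge(i, j, order=o)
        if g.number_of_edges() == 0 or not nx.is_connected(g):
            return
        for r in reps:
            if nx.is_isomorphic(r, g, node_match=nm, edge_match=em):
                return
        reps.append(g)

    orders = [0] * len(pairs)

    def rec(p, used):
        if p == len(pairs):
            if used == budget:
                leaf(orders)
            return
        if budget - used > 3 * (len(pairs) - p):
            return
        i, j = pairs[p]
        cap = min(3, val[i] - deg[i], val[j] - deg[j], budget - used)
        for o in range(cap + 1):
            orders[p] = o
            deg[i] += o
            deg[j] += o
            rec(p + 1, used + o)
            deg[i] -= o
            deg[j] -= o
        orders[p] = 0

    rec(0, 0)
    return len(reps)
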
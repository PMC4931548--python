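"""Chemical-graph core.

Hydrogen-suppressed molecular graphs with explicit per-atom hydrogen
counts, canonical keying, subgraph (monomorphism) search, maximum common
substructure, fingerprint similarity and formula handling.

The in-memory currency is :class:`MolGraph`, a plain immutable graph that
does not require RDKit sanitization.  This matters because fragments
produced by ring-opening an aromatic system keep their aromatic bond
orders and parent hydrogen counts, which RDKit will not sanitize; such
graphs must still be keyed, compared and embedded.  RDKit is used at the
edges: parsing and writing SMILES/SDF, SMARTS matching, fingerprints and
force fields.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit import DataStructs

RDLogger.DisableLog("rdApp.*")

#: Monoisotopic masses (Da) of the supported elements.
MONOISOTOPIC = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "F": 18.99840322,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "I": 126.904473,
}

#: Mass of a proton (Da), used for [M+H]+ style matching.
PROTON_MASS = 1.00727646688

AROMATIC = 1.5  # bond-order token for aromatic bonds


class FormatError(ValueError):
    """Raised when a structure record cannot be parsed."""


class ChemGraphError(ValueError):
    """Raised on invalid graph operations."""


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0
    n_h: int = 0

    def label(self) -> tuple:
        return (self.element, self.charge, self.n_h)


@dataclass(frozen=True)
class MolGraph:
    """Immutable hydrogen-suppressed molecular graph.

    ``atoms`` holds heavy atoms with explicit hydrogen counts; ``bonds``
    are ``(i, j, order)`` with ``i < j`` and order in {1, 2, 3, 1.5}
    (1.5 denotes aromatic).
    """

    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, float], ...]
    _key_cache: list = field(default_factory=list, compare=False, repr=False, hash=False)

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ChemGraphError(f"bond ({i},{j}) references missing atom")
            if i == j:
                raise ChemGraphError(f"self-bond on atom {i}")
            if i > j:
                raise ChemGraphError("bonds must be stored with i < j")
            if (i, j) in seen:
                raise ChemGraphError(f"duplicate bond ({i},{j})")
            if order not in (1.0, 2.0, 3.0, AROMATIC):
                raise ChemGraphError(f"unsupported bond order {order}")
            seen.add((i, j))

    # -- basic accessors ----------------------------------------------------

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def is_empty(self) -> bool:
        return not self.atoms

    def is_connected(self) -> bool:
        if self.num_atoms <= 1:
            return True
        g = self.to_networkx()
        return nx.is_connected(g)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for idx, a in enumerate(self.atoms):
            g.add_node(idx, element=a.element, charge=a.charge, n_h=a.n_h)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def subgraph(self, atom_indices: Iterable[int],
                 bond_subset: Optional[Iterable[tuple[int, int]]] = None) -> "MolGraph":
        """Extract a subgraph; hydrogen counts are inherited from parent atoms."""
        keep = sorted(set(atom_indices))
        remap = {old: new for new, old in enumerate(keep)}
        allowed = None if bond_subset is None else {tuple(sorted(b)) for b in bond_subset}
        atoms = tuple(self.atoms[i] for i in keep)
        bonds = []
        for i, j, order in self.bonds:
            if i in remap and j in remap:
                if allowed is not None and (i, j) not in allowed:
                    continue
                bonds.append((remap[i], remap[j], order))
        return MolGraph(atoms, tuple(sorted(bonds)))


EMPTY_GRAPH = MolGraph((), ())


# ---------------------------------------------------------------------------
# canonical labeling
# ---------------------------------------------------------------------------

def _refine_colors(g: MolGraph, colors: list[int]) -> list[int]:
    """Iterative neighbourhood color refinement (1-WL with edge orders)."""
    adj = [g.neighbors(i) for i in range(g.num_atoms)]
    while True:
        sigs = []
        for i in range(g.num_atoms):
            nb = tuple(sorted((order, colors[j]) for j, order in adj[i]))
            sigs.append((colors[i], nb))
        order_map = {s: c for c, s in enumerate(sorted(set(sigs)))}
        new = [order_map[s] for s in sigs]
        if new == colors:
            return new
        colors = new


def _key_from_order(g: MolGraph, order: list[int]) -> tuple:
    pos = {atom: rank for rank, atom in enumerate(order)}
    atoms = tuple(g.atoms[a].label() for a in order)
    bonds = tuple(sorted(
        (min(pos[i], pos[j]), max(pos[i], pos[j]), o) for i, j, o in g.bonds))
    return (atoms, bonds)


def _canonical_form(g: MolGraph) -> tuple:
    """Minimum key over a refinement-guided individualization search.

    Exponential only for pathologically symmetric graphs; molecular
    graphs at desk scale resolve in a handful of branches.
    """
    n = g.num_atoms
    if n == 0:
        return ((), ())
    init = {lab: c for c, lab in enumerate(sorted({a.label() for a in g.atoms}))}
    best: list[Optional[tuple]] = [None]

    def search(colors: list[int]) -> None:
        colors = _refine_colors(g, colors)
        cells: dict[int, list[int]] = {}
        for i, c in enumerate(colors):
            cells.setdefault(c, []).append(i)
        ambiguous = [(c, mem) for c, mem in sorted(cells.items()) if len(mem) > 1]
        if not ambiguous:
            order = sorted(range(n), key=lambda i: colors[i])
            key = _key_from_order(g, order)
            if best[0] is None or key < best[0]:
                best[0] = key
            return
        _, members = ambiguous[0]
        for pick in members:
            branched = list(colors)
            branched[pick] = -1  # individualize: strictly smallest color
            search(branched)

    search([init[a.label()] for a in g.atoms])
    return best[0]


def canonical_key(g: MolGraph) -> str:
    """A string equal for two MolGraphs iff they are isomorphic.

    Isomorphism respects element, formal charge, hydrogen count and bond
    order (aromatic distinct from single/double).
    """
    if g._key_cache:
        return g._key_cache[0]
    key = repr(_canonical_form(g))
    g._key_cache.append(key)
    return key


# ---------------------------------------------------------------------------
# RDKit bridge
# ---------------------------------------------------------------------------

def from_rdkit(mol: Chem.Mol) -> MolGraph:
    """Convert an RDKit mol (sanitized or not) to a MolGraph.

    Explicit hydrogen atoms are folded into the heavy-atom hydrogen
    counts.
    """
    heavy = {}
    atoms = []
    extra_h = {}
    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "H":
            continue
        heavy[atom.GetIdx()] = len(atoms)
        atoms.append(atom)
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetSymbol() == "H" and b.GetSymbol() != "H":
            extra_h[b.GetIdx()] = extra_h.get(b.GetIdx(), 0) + 1
        elif b.GetSymbol() == "H" and a.GetSymbol() != "H":
            extra_h[a.GetIdx()] = extra_h.get(a.GetIdx(), 0) + 1

    out_atoms = []
    for atom in atoms:
        if atom.GetSymbol() not in MONOISOTOPIC:
            raise ChemGraphError(f"unsupported element {atom.GetSymbol()!r}")
        n_h = atom.GetTotalNumHs() + extra_h.get(atom.GetIdx(), 0)
        out_atoms.append(Atom(atom.GetSymbol(), atom.GetFormalCharge(), n_h))

    order_map = {
        Chem.BondType.SINGLE: 1.0,
        Chem.BondType.DOUBLE: 2.0,
        Chem.BondType.TRIPLE: 3.0,
        Chem.BondType.AROMATIC: AROMATIC,
    }
    bonds = []
    for bond in mol.GetBonds():
        bi, bj = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if bi not in heavy or bj not in heavy:
            continue
        i, j = sorted((heavy[bi], heavy[bj]))
        bt = bond.GetBondType()
        if bt not in order_map:
            raise ChemGraphError(f"unsupported bond type {bt}")
        bonds.append((i, j, order_map[bt]))
    return MolGraph(tuple(out_atoms), tuple(sorted(bonds)))


_BOND_TYPES = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
               3.0: Chem.BondType.TRIPLE, AROMATIC: Chem.BondType.AROMATIC}


def to_rdkit(g: MolGraph, sanitize: bool = True) -> Chem.Mol:
    """Build an RDKit mol; with ``sanitize=False`` no perception is run.

    Raises on sanitization failure (e.g. aromatic bonds outside rings);
    callers that can tolerate raw graphs should pass ``sanitize=False``.
    """
    rw = Chem.RWMol()
    for a in g.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.charge)
        atom.SetNumExplicitHs(a.n_h)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in g.bonds:
        rw.AddBond(i, j, _BOND_TYPES[order])
        if order == AROMATIC:
            rw.GetAtomWithIdx(i).SetIsAromatic(True)
            rw.GetAtomWithIdx(j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    mol = rw.GetMol()
    if sanitize:
        Chem.SanitizeMol(mol)
    else:
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    return mol


def _best_effort_rdkit(g: MolGraph) -> Chem.Mol:
    try:
        return to_rdkit(g, sanitize=True)
    except Exception:
        return to_rdkit(g, sanitize=False)


def parse_structure(text: str, fmt: Optional[str] = None) -> MolGraph:
    """Parse a SMILES string or a single SDF (V2000) record.

    Format is auto-detected unless ``fmt`` ("smiles" | "sdf") is given.
    Aromaticity is perceived on parse so Kekulé and aromatic inputs of
    the same molecule yield identical graphs.
    """
    if fmt is None:
        fmt = "sdf" if ("V2000" in text or "M  END" in text) else "smiles"
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(text.strip())
        if mol is None:
            raise FormatError(f"invalid SMILES: {text.strip()!r}")
        return from_rdkit(mol)
    if fmt == "sdf":
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
        if mol is None:
            mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
            if mol is None:
                raise FormatError("invalid SDF record")
            mol.UpdatePropertyCache(strict=False)
        return from_rdkit(mol)
    raise FormatError(f"unknown format {fmt!r}")


def to_smiles(g: MolGraph) -> str:
    return Chem.MolToSmiles(to_rdkit(g, sanitize=True))


def to_molblock(g: MolGraph, name: str = "") -> str:
    """Write a V2000 mol block with hydrogens as explicit atoms.

    Explicit hydrogens make the record self-describing for graphs that
    RDKit would refuse to sanitize (broken aromatic systems keep their
    type-4 bonds).
    """
    rw = Chem.RWMol()
    for a in g.atoms:
        atom = Chem.Atom(a.element)
        atom.SetFormalCharge(a.charge)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j, order in g.bonds:
        rw.AddBond(i, j, _BOND_TYPES[order])
        if order == AROMATIC:
            rw.GetAtomWithIdx(i).SetIsAromatic(True)
            rw.GetAtomWithIdx(j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    for idx, a in enumerate(g.atoms):
        for _ in range(a.n_h):
            h = rw.AddAtom(Chem.Atom("H"))
            rw.AddBond(idx, h, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    mol.SetProp("_Name", name)
    return Chem.MolToMolBlock(mol, kekulize=False)


def write_sdf(graphs: Sequence[MolGraph], path, names: Optional[Sequence[str]] = None) -> None:
    with open(path, "w") as fh:
        for k, g in enumerate(graphs):
            name = names[k] if names else f"record_{k}"
            fh.write(to_molblock(g, name=name))
            fh.write("$$$$\n")


def read_sdf(path) -> list[MolGraph]:
    with open(path) as fh:
        text = fh.read()
    records = [r for r in text.split("$$$$") if r.strip()]
    return [parse_structure(r.lstrip("\n"), fmt="sdf") for r in records]


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _node_match(t_attrs, q_attrs) -> bool:
    # hydrogen counts intentionally ignored: a fragment CH embeds on a
    # substituted ring carbon
    return (t_attrs["element"] == q_attrs["element"]
            and t_attrs["charge"] == q_attrs["charge"])


def _edge_match(t_attrs, q_attrs) -> bool:
    return t_attrs["order"] == q_attrs["order"]


@dataclass(frozen=True)
class MatchResult:
    found: bool
    mapping: Optional[dict] = None  # query atom index -> target atom index


def _monomorphisms(query: MolGraph, target: MolGraph) -> Iterator[dict]:
    if query.is_empty() or query.num_atoms > target.num_atoms:
        return iter(())
    gm = nx.algorithms.isomorphism.GraphMatcher(
        target.to_networkx(), query.to_networkx(),
        node_match=_node_match, edge_match=_edge_match)
    return ({q: t for t, q in m.items()} for m in gm.subgraph_monomorphisms_iter())


def is_substructure(query: MolGraph, target: MolGraph) -> MatchResult:
    """Subgraph-monomorphism test: elements, charges and bond orders must
    match exactly; aromatic bonds match only aromatic bonds."""
    for mapping in _monomorphisms(query, target):
        return MatchResult(True, mapping)
    return MatchResult(False, None)


def all_embeddings(query: MolGraph, target: MolGraph) -> list[dict]:
    """All distinct query->target atom mappings (may be empty)."""
    return list(_monomorphisms(query, target))


# ---------------------------------------------------------------------------
# fingerprints / similarity
# ---------------------------------------------------------------------------

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _fingerprint(g: MolGraph):
    try:
        mol = _best_effort_rdkit(g)
        return _MORGAN.GetFingerprint(mol)
    except Exception:
        return None


def tanimoto(a: MolGraph, b: MolGraph) -> float:
    """Morgan (radius 2, 2048 bit) Tanimoto similarity in [0, 1].

    Identical canonical keys short-circuit to 1.0; an empty/empty
    fingerprint pair is defined as 0.0.
    """
    if canonical_key(a) == canonical_key(b):
        return 1.0
    fa, fb = _fingerprint(a), _fingerprint(b)
    if fa is None or fb is None:
        return 0.0
    if fa.GetNumOnBits() == 0 and fb.GetNumOnBits() == 0:
        return 0.0
    return DataStructs.TanimotoSimilarity(fa, fb)


# ---------------------------------------------------------------------------
# maximum common substructure
# ---------------------------------------------------------------------------

_MCS_EDGE_LIMIT = 18


def _connected_subgraphs(g: MolGraph) -> Iterator[MolGraph]:
    """All connected subgraphs (atom subset + bond subset), largest first.

    Enumerated as connected edge subsets plus single atoms; practical for
    graphs with at most ``_MCS_EDGE_LIMIT`` bonds.
    """
    m = len(g.bonds)
    if m > _MCS_EDGE_LIMIT:
        raise ChemGraphError(
            f"reference graph has {m} bonds; MCS enumeration capped at {_MCS_EDGE_LIMIT}")
    subs: list[tuple[int, MolGraph]] = []
    for r in range(1, m + 1):
        for combo in itertools.combinations(range(m), r):
            edges = [g.bonds[k] for k in combo]
            atom_set = {i for i, j, _ in edges} | {j for i, j, _ in edges}
            gg = nx.Graph()
            gg.add_nodes_from(atom_set)
            gg.add_edges_from((i, j) for i, j, _ in edges)
            if not nx.is_connected(gg):
                continue
            sub = g.subgraph(atom_set, bond_subset=[(i, j) for i, j, _ in edges])
            subs.append((len(atom_set), sub))
    for idx in range(g.num_atoms):
        subs.append((1, g.subgraph([idx])))
    subs.sort(key=lambda t: -t[0])
    for _, sub in subs:
        yield sub


def mcs(members: Sequence[MolGraph]) -> MolGraph:
    """Maximum common connected substructure of all members.

    Maximal in heavy-atom count; ties broken by lexicographically
    smallest canonical key.  A singleton input returns that member; no
    common atom at all returns the empty-graph sentinel.
    """
    if not members:
        raise ChemGraphError("mcs requires at least one member")
    if len(members) == 1:
        return members[0]
    ref = min(members, key=lambda g: (g.num_atoms, len(g.bonds)))
    others = [g for g in members if g is not ref]
    best_size = 0
    best: list[tuple[str, MolGraph]] = []
    seen: set[str] = set()
    for sub in _connected_subgraphs(ref):
        if best_size and sub.num_atoms < best_size:
            break
        key = canonical_key(sub)
        if key in seen:
            continue
        seen.add(key)
        if all(is_substructure(sub, g).found for g in others):
            best_size = sub.num_atoms
            best.append((key, sub))
    if not best:
        return EMPTY_GRAPH
    best.sort(key=lambda t: t[0])
    return best[0][1]


# ---------------------------------------------------------------------------
# formulas
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """Element -> count map with monoisotopic mass."""

    counts: tuple[tuple[str, int], ...]

    @staticmethod
    def from_counts(counts: dict[str, int]) -> "Formula":
        clean = {el: int(n) for el, n in counts.items() if n}
        for el, n in clean.items():
            if el not in MONOISOTOPIC:
                raise ChemGraphError(f"unknown element {el!r}")
            if n < 0:
                raise ChemGraphError(f"negative count for {el}")
        return Formula(tuple(sorted(clean.items())))

    @staticmethod
    def from_string(s: str) -> "Formula":
        counts: dict[str, int] = {}
        pos = 0
        s = s.strip()
        while pos < len(s):
            m = _FORMULA_RE.match(s, pos)
            if not m or not m.group(1):
                raise FormatError(f"cannot parse formula {s!r} at position {pos}")
            el = m.group(1)
            n = int(m.group(2)) if m.group(2) else 1
            counts[el] = counts.get(el, 0) + n
            pos = m.end()
        if not counts:
            raise FormatError(f"empty formula {s!r}")
        return Formula.from_counts(counts)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def mass(self) -> float:
        return sum(MONOISOTOPIC[el] * n for el, n in self.counts)

    def __getitem__(self, el: str) -> int:
        return self.as_dict().get(el, 0)

    def contains(self, other: "Formula") -> bool:
        mine = self.as_dict()
        return all(mine.get(el, 0) >= n for el, n in other.counts)

    def __str__(self) -> str:
        d = self.as_dict()
        parts = []
        for el in ("C", "H"):
            if el in d:
                parts.append(f"{el}{d[el] if d[el] > 1 else ''}")
        for el in sorted(d):
            if el in ("C", "H"):
                continue
            parts.append(f"{el}{d[el] if d[el] > 1 else ''}")
        return "".join(parts)


def formula_of(g: MolGraph) -> Formula:
    """Molecular formula including implicit hydrogens."""
    counts: dict[str, int] = {}
    n_h = 0
    for a in g.atoms:
        if a.element not in MONOISOTOPIC:
            raise ChemGraphError(f"unknown element {a.element!r}")
        counts[a.element] = counts.get(a.element, 0) + 1
        n_h += a.n_h
    if n_h:
        counts["H"] = counts.get("H", 0) + n_h
    return Formula.from_counts(counts)


def monoisotopic_mass(g: MolGraph) -> float:
    return formula_of(g).mass
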
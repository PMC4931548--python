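"""Pinned defaults and pluggable provider contracts.

Everything threshold-like that the pipeline's reproducibility depends on
lives here: filter windows, fingerprint family, fragmentation depth,
match tolerances, generator limits and valence model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, runtime_checkable

from . import chemgraph
from .chemgraph import MolGraph


@dataclass(frozen=True)
class FilterWindows:
    """Closed acceptance windows around the unknown's reference values."""

    ri_window: float = 40.0        # RI units
    ecom50_window: float = 0.5     # eV
    drift_window: float = 0.35     # ms
    mass_ppm: float = 10.0         # ppm

    def __post_init__(self):
        for name in ("ri_window", "ecom50_window", "drift_window", "mass_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Fingerprint family pinned for Tanimoto thresholds (see chemgraph).
FINGERPRINT = {"family": "morgan", "radius": 2, "n_bits": 2048}

#: Default fragmentation depth (simultaneous bond disconnections).
FRAGMENT_DEPTH = 2

#: Default m/z match tolerance (ppm) for fragment-to-peak assignment.
MATCH_TOL_PPM = 10.0

#: Tanimoto threshold for candidate clustering.
CLUSTER_THRESHOLD = 0.90

#: Atom-match counting mode for MCS trimming: one increment per unique
#: fragment ("per_fragment") or per embedding ("per_embedding").
ATOM_MATCH_MODE = "per_fragment"

#: Fragment intensity aggregation on duplicate fragments.
INTENSITY_AGGREGATION = "max"

#: Structure-generation limits.
MAX_STRUCTURES = 100_000
GENERATION_TIMEOUT_S = 3600.0
HEAVY_ATOM_GUARD = 14

#: Valence model for generation.  Nitrogen is fixed at 3.
VALENCES = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3}

#: Energy-window multiplier.
ENERGY_K = 3.0


# ---------------------------------------------------------------------------
# provider contracts
# ---------------------------------------------------------------------------

@runtime_checkable
class PropertyPredictor(Protocol):
    """QSPR predictor contract: one physicochemical value per structure."""

    def predict(self, structure: MolGraph) -> float: ...


@dataclass(frozen=True)
class ConstantPredictor:
    """Returns a fixed value for every structure (identity-style testing:
    set it to the unknown's reference so every delta is zero)."""

    value: float

    def predict(self, structure: MolGraph) -> float:
        return self.value


@dataclass(frozen=True)
class TablePredictor:
    """Canonical-key lookup with a default; stands in for a trained model."""

    table: dict
    default: float = 0.0

    def predict(self, structure: MolGraph) -> float:
        return self.table.get(chemgraph.canonical_key(structure), self.default)


@dataclass(frozen=True)
class PredictorSet:
    ri: PropertyPredictor
    ecom50: PropertyPredictor
    drift: PropertyPredictor

    @staticmethod
    def constant(ri: float, ecom50: float, drift: float) -> "PredictorSet":
        return PredictorSet(ConstantPredictor(ri), ConstantPredictor(ecom50),
                            ConstantPredictor(drift))


@runtime_checkable
class BiologicalClassifier(Protocol):
    """Endogenous-metabolite gate.  ``accepts`` may inspect the structure
    and/or a precomputed score carried by the record."""

    def accepts(self, structure: MolGraph, score: Optional[float] = None) -> bool: ...


class AcceptAll:
    def accepts(self, structure: MolGraph, score: Optional[float] = None) -> bool:
        return True


@dataclass(frozen=True)
class ScoreGate:
    """Accepts when the record's precomputed biological score exceeds a
    threshold (the default reading of a binary keep/drop gate)."""

    threshold: float = 0.0

    def accepts(self, structure: MolGraph, score: Optional[float] = None) -> bool:
        if score is None:
            return True
        return score > self.threshold


@dataclass(frozen=True)
class SmartsGate:
    """Accepts structures containing none of the given SMARTS patterns."""

    patterns: tuple[str, ...]

    def accepts(self, structure: MolGraph, score: Optional[float] = None) -> bool:
        from .structgen import contains_badlist
        return not contains_badlist(structure, list(self.patterns))


@runtime_checkable
class ForceFieldProvider(Protocol):
    """Lowest-conformer molecular-mechanics energy, kcal/mol."""

    def lowest_energy(self, structure: MolGraph) -> float: ...


@dataclass(frozen=True)
class StubForceField:
    """Deterministic test provider: optional table lookup, else a simple
    size-based surrogate energy."""

    table: dict = field(default_factory=dict)
    per_atom: float = 5.0

    def lowest_energy(self, structure: MolGraph) -> float:
        key = chemgraph.canonical_key(structure)
        if key in self.table:
            return self.table[key]
        return self.per_atom * structure.num_atoms + len(structure.bonds)


class MMFF94ForceField:
    """MMFF94 lowest-energy-of-k-conformers via RDKit, seeded ETKDG."""

    def __init__(self, n_confs: int = 5, seed: int = 20160217):
        self.n_confs = n_confs
        self.seed = seed

    def lowest_energy(self, structure: MolGraph) -> float:
        from rdkit import Chem
        from rdkit.Chem import AllChem

        mol = Chem.AddHs(chemgraph.to_rdkit(structure, sanitize=True))
        params = AllChem.ETKDGv3()
        params.randomSeed = self.seed
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=self.n_confs, params=params)
        if not ids:
            raise RuntimeError("conformer embedding failed")
        results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
        energies = [e for converged, e in results if e is not None]
        if not energies:
            raise RuntimeError("MMFF94 optimization failed")
        return min(energies)
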
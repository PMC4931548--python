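"""Candidate-bin I/O and initial filtering.

A "bin" couples one unknown's observed features (monoisotopic weight,
formula, reference RI/Ecom50/drift, CID peak list) with database
candidate structures carrying predicted properties.  This module loads
and validates the versioned JSON document, applies the QSPR window +
biological filters, and performs formula/redundancy cleanup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from . import chemgraph
from .chemgraph import Formula, MolGraph
from .config import AcceptAll, BiologicalClassifier, FilterWindows

SCHEMA_VERSION = "dasi-bin/1"


class BinValidationError(ValueError):
    """Schema violation in a bin document; message names field and record."""


@dataclass(frozen=True)
class CIDSpectrum:
    """Peak list of (m/z, relative intensity), sorted by m/z."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self):
        prev = 0.0
        for mz, inten in self.peaks:
            if mz <= 0:
                raise BinValidationError(f"non-positive m/z {mz}")
            if inten <= 0:
                raise BinValidationError(f"non-positive intensity {inten} at m/z {mz}")
            if mz < prev:
                raise BinValidationError("peaks must be sorted by m/z")
            prev = mz

    @property
    def total_intensity(self) -> float:
        return sum(i for _, i in self.peaks)


@dataclass(frozen=True)
class UnknownFeatures:
    id: str
    mimw: float
    formula: Formula
    ri_ref: float
    ecom50_ref: float
    drift_ref: float
    spectrum: CIDSpectrum

    def validate(self, mass_ppm: float = 10.0) -> None:
        if self.mimw <= 0:
            raise BinValidationError(f"unknown {self.id!r}: mimw must be positive")
        err = abs(self.mimw - self.formula.mass) / self.mimw * 1e6
        if err > mass_ppm:
            raise BinValidationError(
                f"unknown {self.id!r}: mimw {self.mimw} is {err:.1f} ppm from "
                f"formula mass {self.formula.mass:.4f} (limit {mass_ppm})")


@dataclass
class Candidate:
    id: str
    structure: MolGraph
    ri_pred: float
    ecom50_pred: float
    drift_pred: float
    bio_score: float = 1.0
    metfrag_score: float = 0.0
    fragments: list = field(default_factory=list)

    def __post_init__(self):
        import math
        for name in ("ri_pred", "ecom50_pred", "drift_pred", "bio_score"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise BinValidationError(f"candidate {self.id!r}: {name} not finite")

    @property
    def key(self) -> str:
        return chemgraph.canonical_key(self.structure)


def _require(record: dict, fields: Sequence[str], where: str) -> None:
    for f in fields:
        if f not in record:
            raise BinValidationError(f"{where}: missing field {f!r}")


def load_bin(source: Union[str, dict], mass_ppm: float = 10.0
             ) -> tuple[UnknownFeatures, list[Candidate]]:
    """Load a ``dasi-bin/1`` JSON document (path or already-parsed dict)."""
    if isinstance(source, dict):
        doc = source
    else:
        with open(source) as fh:
            doc = json.load(fh)
    if doc.get("version") != SCHEMA_VERSION:
        raise BinValidationError(
            f"document version {doc.get('version')!r} != {SCHEMA_VERSION!r}")
    _require(doc, ["unknown", "candidates"], "bin document")
    u = doc["unknown"]
    _require(u, ["id", "formula", "mimw", "ri", "ecom50", "drift", "spectrum"],
             "unknown record")
    peaks = tuple(sorted((float(mz), float(inten)) for mz, inten in u["spectrum"]))
    unknown = UnknownFeatures(
        id=str(u["id"]),
        mimw=float(u["mimw"]),
        formula=Formula.from_string(u["formula"]),
        ri_ref=float(u["ri"]),
        ecom50_ref=float(u["ecom50"]),
        drift_ref=float(u["drift"]),
        spectrum=CIDSpectrum(peaks),
    )
    unknown.validate(mass_ppm=mass_ppm)

    candidates: list[Candidate] = []
    seen_ids: set[str] = set()
    for k, rec in enumerate(doc["candidates"]):
        where = f"candidate #{k} (id={rec.get('id', '?')!r})"
        _require(rec, ["id", "smiles", "ri_pred", "ecom50_pred", "drift_pred"], where)
        cid = str(rec["id"])
        if cid in seen_ids:
            raise BinValidationError(f"{where}: duplicate candidate id")
        seen_ids.add(cid)
        try:
            structure = chemgraph.parse_structure(rec["smiles"], fmt="smiles")
        except chemgraph.FormatError as exc:
            raise BinValidationError(f"{where}: {exc}") from exc
        candidates.append(Candidate(
            id=cid,
            structure=structure,
            ri_pred=float(rec["ri_pred"]),
            ecom50_pred=float(rec["ecom50_pred"]),
            drift_pred=float(rec["drift_pred"]),
            bio_score=float(rec.get("bio_score", 1.0)),
        ))
    return unknown, candidates


def save_bin(unknown: UnknownFeatures, candidates: Sequence[Candidate], path) -> None:
    doc = {
        "version": SCHEMA_VERSION,
        "unknown": {
            "id": unknown.id,
            "formula": str(unknown.formula),
            "mimw": unknown.mimw,
            "ri": unknown.ri_ref,
            "ecom50": unknown.ecom50_ref,
            "drift": unknown.drift_ref,
            "spectrum": [[mz, inten] for mz, inten in unknown.spectrum.peaks],
        },
        "candidates": [
            {
                "id": c.id,
                "smiles": chemgraph.to_smiles(c.structure),
                "ri_pred": c.ri_pred,
                "ecom50_pred": c.ecom50_pred,
                "drift_pred": c.drift_pred,
                "bio_score": c.bio_score,
            }
            for c in candidates
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def qspr_filter(candidates: Sequence[Candidate], unknown: UnknownFeatures,
                windows: FilterWindows,
                bio: Optional[BiologicalClassifier] = None) -> list[Candidate]:
    """Keep candidates inside all closed property windows and accepted by
    the biological classifier.  Order is preserved."""
    bio = bio or AcceptAll()
    out = []
    for c in candidates:
        if abs(c.ri_pred - unknown.ri_ref) > windows.ri_window:
            continue
        if abs(c.ecom50_pred - unknown.ecom50_ref) > windows.ecom50_window:
            continue
        if abs(c.drift_pred - unknown.drift_ref) > windows.drift_window:
            continue
        if not bio.accepts(c.structure, score=c.bio_score):
            continue
        out.append(c)
    return out


def cleanup_bin(candidates: Sequence[Candidate], unknown: UnknownFeatures,
                target: Optional[Union[str, MolGraph]] = None) -> list[Candidate]:
    """Formula check, canonical-key deduplication, and removal of the
    hidden target (by candidate id or structure) plus anything sharing
    its canonical key."""
    target_key: Optional[str] = None
    if isinstance(target, MolGraph):
        target_key = chemgraph.canonical_key(target)
    elif isinstance(target, str):
        for c in candidates:
            if c.id == target:
                target_key = c.key
                break

    out: list[Candidate] = []
    seen: set[str] = set()
    for c in candidates:
        if chemgraph.formula_of(c.structure) != unknown.formula:
            continue
        key = c.key
        if key in seen:
            continue
        if target_key is not None and (key == target_key or
                                       (isinstance(target, str) and c.id == target)):
            continue
        seen.add(key)
        out.append(c)
    return out
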
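"""Atomic-structure data model.

A :class:`Structure` is an ordered collection of residues with provenance
metadata (experimental X-ray entry vs predicted model).  For predicted
models the B-factor column carries per-residue confidence (pLDDT, 0-100)
rather than displacement parameters; the model stores it unchanged.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .errors import EmptyStructureError

# Three-letter codes of the 20 standard amino acids.
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
WATER_NAMES = frozenset({"HOH", "WAT"})

EXPERIMENTAL = "experimental"
PREDICTED = "predicted"


@dataclass
class Atom:
    """One heavy atom.

    ``bfactor`` is an isotropic displacement parameter (A^2) for
    experimental entries and a pLDDT confidence in [0, 100] for
    predicted models.
    """

    serial: int
    name: str
    element: str
    altloc: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        self.element = self.element.strip().capitalize()


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        """(chain_id, seq_number, icode) — unique within a Structure."""
        return (self.chain_id, self.seq_number, self.icode)

    def get_atom(self, name: str) -> Optional[Atom]:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_standard_aa(self) -> bool:
        return self.res_name in STANDARD_AA

    def mean_bfactor(self) -> float:
        return float(np.mean([a.bfactor for a in self.atoms]))


@dataclass
class DBRef:
    """PDB DBREF record: links a chain to a sequence-database accession."""

    chain_id: str
    db_name: str
    accession: str
    seq_begin: int
    seq_end: int
    db_begin: int
    db_end: int


@dataclass
class SSBondRecord:
    """Declared disulphide between two residues (PDB SSBOND record)."""

    chain_1: str
    seq_1: int
    icode_1: str
    chain_2: str
    seq_2: int
    icode_2: str


@dataclass
class StructureMetadata:
    entry_id: str = ""
    source: str = EXPERIMENTAL
    method: Optional[str] = None
    resolution: Optional[float] = None  # Angstrom
    temperature: Optional[float] = None  # Kelvin
    n_models: int = 1
    dbrefs: list[DBRef] = field(default_factory=list)
    ssbond_records: list[SSBondRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")
        if self.temperature is not None and self.temperature <= 0:
            raise ValueError("temperature must be positive when present")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.source not in (EXPERIMENTAL, PREDICTED):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class Structure:
    """An atomic model: metadata plus an ordered collection of residues."""

    metadata: StructureMetadata
    residues: list[Residue] = field(default_factory=list)

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(res.atoms) for res in self.residues)

    def residue_index(self) -> dict[tuple[str, int, str], Residue]:
        return {res.key: res for res in self.residues}

    def get_residue(self, chain_id: str, seq_number: int, icode: str = "") -> Optional[Residue]:
        for res in self.residues:
            if res.chain_id == chain_id and res.seq_number == seq_number and res.icode == icode:
                return res
        return None

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for res in self.residues:
            seen.setdefault(res.chain_id, None)
        return list(seen)

    def copy(self) -> "Structure":
        return _copy.deepcopy(self)


def nonprotein_fraction(structure: Structure) -> float:
    """Fraction of atoms that belong neither to a standard amino acid nor to water.

    Waters (residue name HOH/WAT) count in the denominator but never in the
    numerator: the selection filter targets ligands/cofactors, not solvent.
    """
    total = 0
    nonprotein = 0
    for res in structure.residues:
        n = len(res.atoms)
        total += n
        if not (res.is_standard_aa or res.is_water):
            nonprotein += n
    if total == 0:
        raise EmptyStructureError("structure has no atoms")
    return nonprotein / total
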
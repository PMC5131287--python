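"""In-memory coordinate model: atoms, residues, models, complexes.

A water molecule is represented by its oxygen position throughout; hydrogens
are retained when present but never enter heavy-atom distance rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyInputError, SelectionError

#: residue names recognised as water by default
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "WAT", "SOL", "TIP", "SPC", "TIP3", "TIP4"})


@dataclass(frozen=True)
class ResidueID:
    """Identity of a residue: chain, sequence number, insertion code, name.

    Hashable; equality compares all four fields.
    """

    chain: str
    resseq: int
    icode: str
    resname: str

    def __str__(self) -> str:  # e.g. "ASP A62" or "SER B74a"
        return f"{self.resname} {self.chain}{self.resseq}{self.icode.strip()}"

    def key(self) -> tuple:
        """Positional key (chain, resseq, icode) used for contact identity."""
        return (self.chain, self.resseq, self.icode)


@dataclass
class AtomRecord:
    """One atom with optional PQR charge/radius annotation."""

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    element: str
    charge: float | None = None  # e, PQR only
    radius: float | None = None  # Å, PQR only

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.z)):
            raise ValueError(f"non-finite coordinates for atom serial {self.serial}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_id(self) -> ResidueID:
        return ResidueID(self.chain, self.resseq, self.icode, self.resname)


@dataclass
class Model:
    """One coordinate model: protein atoms plus water oxygens (+ H if present)."""

    protein: list[AtomRecord] = field(default_factory=list)
    waters: list[AtomRecord] = field(default_factory=list)  # oxygen atoms
    water_hydrogens: list[AtomRecord] = field(default_factory=list)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.protein:
            seen.setdefault(a.chain, None)
        return list(seen)

    def protein_atoms(self, chains=None, heavy_only: bool = True) -> list[AtomRecord]:
        chains = None if chains is None else set(chains)
        out = []
        for a in self.protein:
            if chains is not None and a.chain not in chains:
                continue
            if heavy_only and not a.is_heavy:
                continue
            out.append(a)
        return out

    def protein_coords(self, chains=None, heavy_only: bool = True) -> np.ndarray:
        atoms = self.protein_atoms(chains, heavy_only)
        if not atoms:
            return np.empty((0, 3), dtype=float)
        return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)

    def water_coords(self) -> np.ndarray:
        if not self.waters:
            return np.empty((0, 3), dtype=float)
        return np.array([[a.x, a.y, a.z] for a in self.waters], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.protein) + len(self.waters) + len(self.water_hydrogens)


@dataclass
class ComplexStructure:
    """An ordered list of models with a protein/water partition per model."""

    models: list[Model] = field(default_factory=list)
    source: str = ""
    water_resnames: frozenset = DEFAULT_WATER_RESNAMES

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def first(self) -> Model:
        if not self.models:
            raise EmptyInputError(f"structure {self.source!r} has no models")
        return self.models[0]

    @property
    def chains(self) -> list[str]:
        return self.first.chains


def select_component(structure: ComplexStructure, chains) -> ComplexStructure:
    """Restrict protein atoms to the given chains, keeping all waters.

    The input structure is left untouched.  Unknown chain ids raise a
    :class:`SelectionError` listing the chains that are available.
    """
    chains = set(chains)
    available = set()
    for m in structure.models:
        available.update(m.chains)
    missing = chains - available
    if missing:
        raise SelectionError(
            f"unknown chain(s) {sorted(missing)}; available: {sorted(available)}"
        )
    out_models = []
    for m in structure.models:
        out_models.append(
            Model(
                protein=[replace(a) for a in m.protein if a.chain in chains],
                waters=[replace(a) for a in m.waters],
                water_hydrogens=[replace(a) for a in m.water_hydrogens],
            )
        )
    return ComplexStructure(
        models=out_models,
        source=structure.source,
        water_resnames=structure.water_resnames,
    )
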
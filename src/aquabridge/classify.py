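"""Water classification: interfacial, core, associated, bulk.

Distance rules
--------------
* first shell / contact: water oxygen within ``d_c`` (default 3.5 Å,
  inclusive ≤) of at least one protein heavy atom;
* interfacial: in contact with both binding partners simultaneously;
* core: within ``d_core`` (default 11.0 Å, strict <) of at least one heavy
  atom of *every* structural component (used for water-filled protein cores
  such as four-helix-bundle antifreeze proteins);
* associated: first-shell but not interfacial/core;
* bulk: everything else.

All functions accept and return numpy boolean masks over the water array, so
the same code path serves AtomRecord lists (via coordinate extraction) and
raw coordinate fixtures.  A cKDTree accelerates the queries; results are
bit-identical to the brute-force all-pairs rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyInputError

DEFAULT_CONTACT_CUTOFF = 3.5  # Å, inclusive
DEFAULT_CORE_CUTOFF = 11.0  # Å (1.1 nm), strict

LABELS = ("interfacial", "core", "associated", "bulk")


def _as_coords(x) -> np.ndarray:
    """Accept an (N,3) array or a sequence of AtomRecords."""
    if isinstance(x, np.ndarray):
        return x.reshape(-1, 3).astype(float)
    seq = list(x)
    if seq and hasattr(seq[0], "coords"):
        return np.array([[a.x, a.y, a.z] for a in seq], dtype=float)
    return np.asarray(seq, dtype=float).reshape(-1, 3)


def _min_dist(points: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest reference atom."""
    tree = cKDTree(ref)
    d, _ = tree.query(points, k=1)
    return np.atleast_1d(d)


def first_shell(waters, protein_heavy, d_c: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """Mask of waters within ``d_c`` (inclusive) of ≥1 protein heavy atom."""
    if d_c <= 0:
        raise ValueError(f"contact cutoff must be positive, got {d_c}")
    w = _as_coords(waters)
    p = _as_coords(protein_heavy)
    if p.shape[0] == 0:
        raise EmptyInputError("no protein atoms: first shell undefined")
    if w.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    return _min_dist(w, p) <= d_c


def interfacial_waters(
    waters, ligand_heavy, receptor_heavy, d_c: float = DEFAULT_CONTACT_CUTOFF
) -> np.ndarray:
    """Mask of waters in simultaneous contact (≤ d_c) with both partners."""
    return first_shell(waters, ligand_heavy, d_c) & first_shell(waters, receptor_heavy, d_c)


def core_waters(waters, component_heavy_sets, d_core: float = DEFAULT_CORE_CUTOFF) -> np.ndarray:
    """Mask of waters strictly within ``d_core`` of every structural component."""
    if d_core <= 0:
        raise ValueError(f"core cutoff must be positive, got {d_core}")
    components = [_as_coords(c) for c in component_heavy_sets]
    if len(components) < 2:
        raise ValueError("core definition needs at least two components")
    w = _as_coords(waters)
    if w.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    mask = np.ones(w.shape[0], dtype=bool)
    for comp in components:
        if comp.shape[0] == 0:
            raise EmptyInputError("empty component set in core-water rule")
        mask &= _min_dist(w, comp) < d_core
    return mask


@dataclass
class WaterClassification:
    """Per-water labels, exhaustive and mutually exclusive."""

    labels: np.ndarray  # array of strings from LABELS
    d_c: float = DEFAULT_CONTACT_CUTOFF
    d_core: float = DEFAULT_CORE_CUTOFF
    mode: str = "interface"
    counts: dict = field(init=False)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        unknown = set(self.labels) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels {unknown}")
        self.counts = {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def __len__(self) -> int:
        return len(self.labels)


def classify(
    waters,
    ligand_heavy,
    receptor_heavy,
    d_c: float = DEFAULT_CONTACT_CUTOFF,
    d_core: float = DEFAULT_CORE_CUTOFF,
    mode: str = "interface",
) -> WaterClassification:
    """Assign each water exactly one label.

    ``mode="interface"``: interfacial first, remaining first-shell waters
    associated, rest bulk.  ``mode="core"``: the strict-``d_core`` core rule
    (against the two partners as components) replaces the interfacial rule.
    """
    if mode not in ("interface", "core"):
        raise ValueError(f"mode must be 'interface' or 'core', got {mode!r}")
    w = _as_coords(waters)
    n = w.shape[0]
    labels = np.array(["bulk"] * n, dtype=object)
    if n == 0:
        return WaterClassification(labels, d_c, d_core, mode)

    lig = _as_coords(ligand_heavy)
    rec = _as_coords(receptor_heavy)
    shell = first_shell(w, np.vstack([lig, rec]), d_c)
    if mode == "interface":
        special = interfacial_waters(w, lig, rec, d_c)
        special_label = "interfacial"
    else:
        special = core_waters(w, [lig, rec], d_core)
        special_label = "core"
    labels[shell & ~special] = "associated"
    labels[special] = special_label
    return WaterClassification(labels, d_c, d_core, mode)
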
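"""Water-mediated inter-chain contacts, f^w(nat) recall, quality categories.

A single-bridge contact is a (ligand residue, receptor residue) pair for
which one water oxygen lies within the contact cutoff of at least one heavy
atom of each residue.  A double-bridge contact relaxes this to a chain of
two distinct waters, residue–w1–w2–residue, with a water–water oxygen cutoff
between them; it captures diffuse water networks in protein cores where few
waters touch both chains at once.

The number of contacts can exceed the number of mediating waters: one water
adjacent to several residues on both sides mediates every pairing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .classify import DEFAULT_CONTACT_CUTOFF, _as_coords
from .errors import EmptyInputError, SelectionError
from .models import ComplexStructure, Model, ResidueID

DEFAULT_WW_CUTOFF = 3.5  # Å, water-water oxygen cutoff for double bridges

CATEGORIES = ("bad", "fair", "good", "excellent", "outstanding")
#: category lower bounds on f^w(nat); upper bound of each is the next entry
CATEGORY_EDGES = {"bad": 0.0, "fair": 0.1, "good": 0.3, "excellent": 0.5, "outstanding": 0.8}

#: default residue polarity classes (configurable; histidine counted charged)
RESIDUE_CLASSES = {
    "charged": frozenset({"ASP", "GLU", "LYS", "ARG", "HIS"}),
    "polar": frozenset({"SER", "THR", "ASN", "GLN", "TYR", "CYS", "TRP"}),
    "non-polar": frozenset({"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "GLY"}),
}


@dataclass
class BridgeContactSet:
    """Set of inter-chain residue pairs plus mediating-water bookkeeping.

    ``contacts`` holds (ligand ResidueID, receptor ResidueID) pairs;
    ``mediators`` maps each contact to the set of water serials (single
    bridge) or ordered serial pairs (double bridge) that realise it.
    """

    contacts: frozenset = frozenset()
    mediators: dict = field(default_factory=dict)
    bridge_order: int = 1

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def mediating_waters(self) -> frozenset:
        """All water serials involved in any contact."""
        out = set()
        for meds in self.mediators.values():
            for m in meds:
                if isinstance(m, tuple):
                    out.update(m)
                else:
                    out.add(m)
        return frozenset(out)

    def contact_keys(self) -> frozenset:
        """Positional identity (chain, resseq, icode) pairs, resname-free."""
        return frozenset((l.key(), r.key()) for l, r in self.contacts)


@dataclass
class RecallResult:
    """Recall of native water-mediated contacts by a model."""

    fwnat: float
    n_native: int
    n_recovered: int
    n_false_positive: int
    category: str

    def __post_init__(self):
        if self.n_native > 0:
            assert abs(self.fwnat - self.n_recovered / self.n_native) < 1e-12


def _water_residue_adjacency(
    model: Model, chains: set, d_c: float
) -> dict[int, set[ResidueID]]:
    """For each water index, the set of residues (in `chains`) with a heavy
    atom within d_c of the water oxygen."""
    atoms = model.protein_atoms(chains=chains, heavy_only=True)
    w = model.water_coords()
    adj: dict[int, set[ResidueID]] = {i: set() for i in range(len(model.waters))}
    if not atoms or w.shape[0] == 0:
        return adj
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    rids = [a.residue_id for a in atoms]
    tree = cKDTree(coords)
    for wi, hits in enumerate(tree.query_ball_point(w, d_c)):
        for ai in hits:
            adj[wi].add(rids[ai])
    return adj


def _get_model(structure) -> Model:
    if isinstance(structure, Model):
        return structure
    if isinstance(structure, ComplexStructure):
        return structure.first
    raise TypeError(f"expected ComplexStructure or Model, got {type(structure)!r}")


def _check_chains(model: Model, ligand_chains, receptor_chains) -> tuple[set, set]:
    lig, rec = set(ligand_chains), set(receptor_chains)
    if lig & rec:
        raise SelectionError(f"ligand and receptor chains overlap: {sorted(lig & rec)}")
    return lig, rec


def single_bridge_contacts(
    structure, ligand_chains, receptor_chains, d_c: float = DEFAULT_CONTACT_CUTOFF
) -> BridgeContactSet:
    """Contacts mediated by one water touching both partners (≤ d_c each side)."""
    if d_c <= 0:
        raise ValueError("contact cutoff must be positive")
    model = _get_model(structure)
    lig, rec = _check_chains(model, ligand_chains, receptor_chains)
    adj_l = _water_residue_adjacency(model, lig, d_c)
    adj_r = _water_residue_adjacency(model, rec, d_c)
    contacts: dict[tuple, set] = {}
    for wi, water in enumerate(model.waters):
        for rl, rr in itertools.product(adj_l[wi], adj_r[wi]):
            contacts.setdefault((rl, rr), set()).add(water.serial)
    return BridgeContactSet(
        contacts=frozenset(contacts), mediators=contacts, bridge_order=1
    )


def double_bridge_contacts(
    structure,
    ligand_chains,
    receptor_chains,
    d_c: float = DEFAULT_CONTACT_CUTOFF,
    d_ww: float = DEFAULT_WW_CUTOFF,
) -> tuple[BridgeContactSet, BridgeContactSet]:
    """Contacts mediated by a chain of two distinct waters.

    Returns ``(strict, union)``: the strict two-water set, and its union with
    the single-bridge contacts at the same ``d_c`` (whether a published
    double-bridge count includes single bridges is convention-dependent, so
    both are always available).
    """
    if d_c <= 0 or d_ww <= 0:
        raise ValueError("cutoffs must be positive")
    model = _get_model(structure)
    lig, rec = _check_chains(model, ligand_chains, receptor_chains)
    adj_l = _water_residue_adjacency(model, lig, d_c)
    adj_r = _water_residue_adjacency(model, rec, d_c)

    w = model.water_coords()
    contacts: dict[tuple, set] = {}
    if w.shape[0] >= 2:
        tree = cKDTree(w)
        pairs = tree.query_pairs(d_ww, output_type="ndarray")
        for i, j in pairs:
            for w1, w2 in ((i, j), (j, i)):  # ordered: w1 on ligand side
                if not adj_l[w1] or not adj_r[w2]:
                    continue
                med = (model.waters[w1].serial, model.waters[w2].serial)
                for rl, rr in itertools.product(adj_l[w1], adj_r[w2]):
                    contacts.setdefault((rl, rr), set()).add(med)
    strict = BridgeContactSet(
        contacts=frozenset(contacts), mediators=contacts, bridge_order=2
    )

    single = single_bridge_contacts(model, lig, rec, d_c)
    union_meds: dict[tuple, set] = {k: set(v) for k, v in single.mediators.items()}
    for k, v in strict.mediators.items():
        union_meds.setdefault(k, set()).update(v)
    union = BridgeContactSet(
        contacts=frozenset(union_meds), mediators=union_meds, bridge_order=2
    )
    return strict, union


def consensus_contacts(contact_sets, chain_mappings) -> BridgeContactSet:
    """Intersection of contact sets after mapping each copy onto a canonical one.

    ``chain_mappings``: one dict per contact set, mapping that copy's chain
    ids to canonical chain ids (the first mapping is typically the identity).
    Residues are mapped by chain while keeping resseq/icode/resname.
    """
    contact_sets = list(contact_sets)
    if not contact_sets:
        raise EmptyInputError("consensus of zero contact sets")
    if len(chain_mappings) != len(contact_sets):
        raise ValueError("need one chain mapping per contact set")

    def map_rid(rid: ResidueID, mapping: dict) -> ResidueID:
        if rid.chain not in mapping:
            raise SelectionError(f"residue {rid} has no chain mapping (chain {rid.chain!r})")
        return ResidueID(mapping[rid.chain], rid.resseq, rid.icode, rid.resname)

    mapped = []
    for cs, mp in zip(contact_sets, chain_mappings):
        mapped.append(frozenset((map_rid(l, mp), map_rid(r, mp)) for l, r in cs.contacts))
    common = frozenset.intersection(*mapped)

    canonical = contact_sets[0]
    mp0 = chain_mappings[0]
    meds = {}
    for (l, r), m in canonical.mediators.items():
        pair = (map_rid(l, mp0), map_rid(r, mp0))
        if pair in common:
            meds[pair] = set(m)
    return BridgeContactSet(
        contacts=common, mediators=meds, bridge_order=canonical.bridge_order
    )


def quality_category(fwnat: float) -> str:
    """CAPRI-style quality bin for an f^w(nat) value.

    bad [0,0.1) < fair [0.1,0.3) < good [0.3,0.5) < excellent [0.5,0.8)
    < outstanding [0.8,1].
    """
    if not 0.0 <= fwnat <= 1.0:
        raise ValueError(f"f^w(nat) must lie in [0,1], got {fwnat}")
    cat = "bad"
    for name, lo in CATEGORY_EDGES.items():
        if fwnat >= lo:
            cat = name
    return cat


def fwnat(native: BridgeContactSet, model: BridgeContactSet) -> RecallResult:
    """Recall of native water-mediated contacts: |native ∩ model| / |native|.

    Matching is by residue-pair positional identity (chain, resseq, icode);
    which water mediates the contact does not enter.
    """
    if len(native) == 0:
        raise EmptyInputError("empty native contact set: recall undefined")
    nat = native.contact_keys()
    mod = model.contact_keys()
    n_rec = len(nat & mod)
    value = n_rec / len(nat)
    return RecallResult(
        fwnat=value,
        n_native=len(nat),
        n_recovered=n_rec,
        n_false_positive=len(mod - nat),
        category=quality_category(value),
    )


def interface_composition(
    contacts: BridgeContactSet, residue_classes: dict = RESIDUE_CLASSES
) -> dict[str, float]:
    """Charged/polar/non-polar percentage of interface residues.

    Interface residues are the unique residues on either side of the contact
    set; percentages sum to 100 up to rounding.
    """
    residues = set()
    for l, r in contacts.contacts:
        residues.add(l)
        residues.add(r)
    if not residues:
        raise EmptyInputError("no interface residues: composition undefined")
    counts = dict.fromkeys(residue_classes, 0)
    for rid in residues:
        for cls, names in residue_classes.items():
            if rid.resname.upper() in names:
                counts[cls] += 1
                break
        else:
            raise ValueError(f"residue type {rid.resname!r} has no polarity class")
    total = sum(counts.values())
    return {cls: 100.0 * c / total for cls, c in counts.items()}
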
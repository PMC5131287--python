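"""End-to-end orchestration: crystal reference, per-frame recall, reports."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import contacts as _contacts
from . import io as _io
from .classify import classify as _classify_waters
from .classify import interfacial_waters as _interfacial_waters
from .errors import EmptyInputError, SelectionError
from .models import ComplexStructure, Model

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one analysis run (YAML-mappable)."""

    structure_path: str = ""
    ligand_chains: list = field(default_factory=lambda: ["A"])
    receptor_chains: list = field(default_factory=lambda: ["B"])
    d_c: float = 3.5  # Å, water-protein contact cutoff (inclusive)
    d_core: float = 11.0  # Å, core-region cutoff (strict)
    d_ww: float = 3.5  # Å, water-water cutoff for double bridges
    exclusion_radius: float = 3.0  # Å, placement exclusion
    mode: str = "interface"  # or "core"
    double_bridge: bool = False
    #: one chain mapping (copy chain -> canonical chain) per crystal copy;
    #: None disables consensus filtering
    consensus_copies: list | None = None
    dpbl: bool = False
    dpbl_dims: list = field(default_factory=lambda: [65, 65, 65])
    yukawa: bool = False
    seed: int = 0
    output_dir: str | None = None
    water_resnames: list = field(default_factory=lambda: sorted(_io.DEFAULT_WATER_RESNAMES))

    def __post_init__(self):
        for name in ("d_c", "d_core", "d_ww", "exclusion_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if set(self.ligand_chains) & set(self.receptor_chains):
            raise ValueError("ligand and receptor chain sets overlap")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _contact_set(model: Model, config: RunConfig):
    """Single- or double-bridge (union) contact set per the config."""
    if config.double_bridge:
        strict, union = _contacts.double_bridge_contacts(
            model, config.ligand_chains, config.receptor_chains, config.d_c, config.d_ww
        )
        return union, strict
    single = _contacts.single_bridge_contacts(
        model, config.ligand_chains, config.receptor_chains, config.d_c
    )
    return single, None


def reference_from_crystal(config: RunConfig, structure: ComplexStructure | None = None):
    """Native contact set and water classification from a crystal structure.

    With ``consensus_copies`` set, contacts are computed per crystal copy,
    mapped onto the canonical (first) copy and intersected, so only contacts
    present in every copy survive.  Returns (BridgeContactSet,
    WaterClassification).
    """
    if structure is None:
        structure = _io.read_pdb(config.structure_path, frozenset(config.water_resnames))
    model = structure.first
    if not model.waters:
        raise EmptyInputError("crystal structure contains no waters: reference undefined")

    if config.consensus_copies:
        sets = []
        for mapping in config.consensus_copies:
            inv = {}
            for copy_chain, canon in mapping.items():
                inv.setdefault(canon, []).append(copy_chain)
            lig = [c for canon in config.ligand_chains for c in inv.get(canon, [])]
            rec = [c for canon in config.receptor_chains for c in inv.get(canon, [])]
            if not lig or not rec:
                raise SelectionError(f"mapping {mapping} covers no ligand/receptor chains")
            cfg = dataclasses.replace(config, consensus_copies=None)
            cfg.ligand_chains, cfg.receptor_chains = lig, rec
            contact_set, _ = _contact_set(model, cfg)
            sets.append(contact_set)
        reference = _contacts.consensus_contacts(sets, config.consensus_copies)
    else:
        reference, _ = _contact_set(model, config)

    wc = _classify_waters(
        model.water_coords(),
        model.protein_coords(chains=config.ligand_chains),
        model.protein_coords(chains=config.receptor_chains),
        d_c=config.d_c,
        d_core=config.d_core,
        mode=config.mode,
    )
    log.info(
        "reference: %d contacts, %d interfacial/core waters (d_c=%.2f, d_core=%.2f)",
        len(reference),
        wc.counts["interfacial"] + wc.counts["core"],
        config.d_c,
        config.d_core,
    )
    return reference, wc


def evaluate_frame(frame, reference, config: RunConfig) -> dict:
    """f^w(nat) of one frame's waters against a native contact set.

    With ``config.dpbl`` the frame waters are additionally stripped, the
    DPBL density solved from the frame's PQR charges, waters re-placed from
    the density, and a second recall computed (keys ``recall`` and
    ``recall_dpbl``).
    """
    model = frame.first if isinstance(frame, ComplexStructure) else frame
    missing = (set(config.ligand_chains) | set(config.receptor_chains)) - set(model.chains)
    if missing:
        raise SelectionError(f"frame lacks chain(s) {sorted(missing)}")
    contact_set, _ = _contact_set(model, config)
    out = {"recall": _contacts.fwnat(reference, contact_set)}
    out["n_model_contacts"] = len(contact_set)
    out["n_interfacial_waters"] = int(
        _interfacial_waters(
            model.water_coords(),
            model.protein_coords(chains=config.ligand_chains),
            model.protein_coords(chains=config.receptor_chains),
            config.d_c,
        ).sum()
    )
    if config.dpbl:
        out["recall_dpbl"] = _dpbl_recall(model, reference, config)
    return out


def _dpbl_recall(model: Model, reference, config: RunConfig):
    from . import dpbl as _dpbl
    from .models import AtomRecord

    if not any(a.charge is not None for a in model.protein):
        raise ValueError("DPBL evaluation requires PQR charges/radii on the frame")
    protein_only = ComplexStructure(models=[Model(protein=list(model.protein))])
    lattice = _dpbl.build_lattice(
        protein_only, dims=tuple(config.dpbl_dims), yukawa=config.yukawa,
        yukawa_amplitude=0.5 if config.yukawa else 0.0,
    )
    solution = _dpbl.solve(lattice, mode="nonlinear")
    density = _dpbl.water_density(solution, lattice)
    placed = _dpbl.place_waters(density, exclusion_radius=config.exclusion_radius)
    waters = [
        AtomRecord(
            serial=100000 + i, name="O", resname="HOH", chain="W", resseq=i + 1,
            icode="", x=p[0], y=p[1], z=p[2], element="O",
        )
        for i, p in enumerate(placed)
    ]
    placed_model = Model(protein=list(model.protein), waters=waters)
    contact_set, _ = _contact_set(placed_model, config)
    return _contacts.fwnat(reference, contact_set)


def report(results) -> pd.DataFrame:
    """Tabulate per-frame results (one row per frame)."""
    results = list(results)
    if not results:
        raise EmptyInputError("no results to report")
    rows = []
    for i, res in enumerate(results):
        row = {"frame": i}
        for key, val in res.items():
            if hasattr(val, "fwnat"):
                prefix = "" if key == "recall" else key.replace("recall", "")
                row[f"fwnat{prefix}"] = val.fwnat
                row[f"category{prefix}"] = val.category
                row[f"n_recovered{prefix}"] = val.n_recovered
                row[f"n_native{prefix}"] = val.n_native
            else:
                row[key] = val
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, out_dir, stem: str = "report") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / f"{stem}.tsv", sep="\t", index=False)
    df.to_json(out_dir / f"{stem}.json", orient="records", indent=1)


def read_report_json(path) -> pd.DataFrame:
    with open(path) as fh:
        return pd.DataFrame(json.load(fh))
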
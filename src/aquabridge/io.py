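"""Reading and writing PDB / multi-model PDB / PQR files.

PDB parsing is delegated to gemmi; PQR parsing to MDAnalysis (the
whitespace-delimited pdb2pqr dialect with charge and radius columns).  Both
are converted into the package's uniform :class:`~aquabridge.models.ComplexStructure`.
Altloc policy: the first-listed alternate location of each atom is kept.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .errors import EmptyInputError, FormatError
from .models import (
    DEFAULT_WATER_RESNAMES,
    AtomRecord,
    ComplexStructure,
    Model,
)
from .models import select_component  # noqa: F401  (re-exported: part of the I/O surface)

log = logging.getLogger(__name__)

_TWO_LETTER_ELEMENTS = {"CL", "NA", "MG", "ZN", "FE", "BR", "CA", "MN", "CU", "SE"}


def guess_element(atom_name: str, resname: str = "") -> str:
    """Guess an element symbol from an atom name (PQR files carry none).

    Protein/water atom names start with the element letter after any leading
    digits; two-letter ions are recognised explicitly.  ``CA`` in an amino
    acid is an alpha-carbon, not calcium.
    """
    s = atom_name.strip().lstrip("0123456789")
    if not s:
        return "X"
    two = s[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and len(resname.strip()) <= 2:
        return two.capitalize()
    return s[0].upper()


def _prescan_pdb(path: Path) -> int:
    """Validate coordinate fields line by line; return the ATOM/HETATM count."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n += 1
            if len(line.rstrip("\n")) < 54:
                raise FormatError(f"{path}: line {lineno}: truncated coordinate record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: unparsable coordinates: {line.rstrip()!r}"
                ) from exc
    return n


def read_pdb(path, water_resnames=DEFAULT_WATER_RESNAMES) -> ComplexStructure:
    """Read a (multi-model) PDB file into a ComplexStructure.

    One model per MODEL block (a single implicit model if none); waters are
    separated from protein by residue name; for alternate locations the
    first-listed conformer is kept.
    """
    import gemmi

    path = Path(path)
    n_atoms = _prescan_pdb(path)
    if n_atoms == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")

    st = gemmi.read_pdb(str(path))
    st.remove_alternative_conformations()

    water_resnames = frozenset(r.upper() for r in water_resnames)
    out = ComplexStructure(source=str(path), water_resnames=water_resnames)
    for gm in st:
        model = Model()
        for chain in gm:
            for res in chain:
                resname = res.name.strip().upper()
                is_water = resname in water_resnames
                for atom in res:
                    rec = AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        resname=res.name.strip(),
                        chain=chain.name,
                        resseq=res.seqid.num,
                        icode=(res.seqid.icode or " ").strip(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        element=atom.element.name or guess_element(atom.name, res.name),
                    )
                    if is_water:
                        if rec.is_heavy:
                            model.waters.append(rec)
                        else:
                            model.water_hydrogens.append(rec)
                    else:
                        model.protein.append(rec)
        out.models.append(model)
    return out


def read_pqr(path) -> ComplexStructure:
    """Read a PQR file; atoms carry charge (e) and radius (Å).

    The net charge is logged at INFO level and available via :func:`net_charge`.
    """
    import MDAnalysis as mda

    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format="PQR")
        except (ValueError, IndexError, EOFError) as exc:
            raise FormatError(f"{path}: not parseable as PQR: {exc}") from exc
    if len(u.atoms) == 0:
        raise EmptyInputError(f"{path}: no atoms")
    try:
        charges = u.atoms.charges
        radii = u.atoms.radii
    except AttributeError as exc:
        raise FormatError(f"{path}: missing charge/radius column") from exc

    model = Model()
    water_resnames = DEFAULT_WATER_RESNAMES
    for i, a in enumerate(u.atoms):
        resname = str(a.resname).strip()
        chain = getattr(a, "chainID", "") or getattr(a, "segid", "") or "A"
        rec = AtomRecord(
            serial=int(a.id),
            name=str(a.name),
            resname=resname,
            chain=str(chain)[:1] if str(chain) else "A",
            resseq=int(a.resid),
            icode="",
            x=float(a.position[0]),
            y=float(a.position[1]),
            z=float(a.position[2]),
            element=guess_element(str(a.name), resname),
            # PQR charges/radii are fixed-decimal in the file; rounding undoes
            # the reader's float32 storage without losing information
            charge=round(float(charges[i]), 6),
            radius=round(float(radii[i]), 6),
        )
        if resname.upper() in water_resnames:
            (model.waters if rec.is_heavy else model.water_hydrogens).append(rec)
        else:
            model.protein.append(rec)
    cs = ComplexStructure(models=[model], source=str(path))
    log.info("read_pqr %s: %d atoms, net charge %+.4f e", path, len(u.atoms), net_charge(cs))
    return cs


def net_charge(structure: ComplexStructure, model_index: int = 0) -> float:
    """Sum of per-atom charges of one model (PQR input); NaN-free."""
    m = structure.models[model_index]
    total = 0.0
    for a in m.protein + m.waters + m.water_hydrogens:
        if a.charge is not None:
            total += a.charge
    return total


def _format_atom_line(record_type: str, a: AtomRecord, serial: int | None = None) -> str:
    name = a.name
    if len(name) < 4 and (len(a.element) == 1):
        name = " " + name
    serial = a.serial if serial is None else serial
    icode = a.icode if a.icode else " "
    return (
        f"{record_type:<6s}{serial:>5d} {name:<4s} {a.resname:>3s} "
        f"{a.chain:1s}{a.resseq:>4d}{icode:1s}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2s}"
    )


def write_pdb(structure: ComplexStructure, path) -> None:
    """Write a ComplexStructure as a (multi-model) PDB file."""
    path = Path(path)
    multi = structure.n_models > 1
    with open(path, "w") as fh:
        fh.write("REMARK   generated by aquabridge\n")
        for i, m in enumerate(structure.models, start=1):
            if multi:
                fh.write(f"MODEL {i:>8d}\n")
            for a in m.protein:
                fh.write(_format_atom_line("ATOM", a) + "\n")
            for a in m.waters + m.water_hydrogens:
                fh.write(_format_atom_line("HETATM", a) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_placed_waters(waters, path) -> None:
    """Write placed water oxygens as sequentially numbered HETATM/HOH records."""
    waters = np.asarray(waters, dtype=float).reshape(-1, 3)
    if waters.size and not np.all(np.isfinite(waters)):
        raise ValueError("non-finite water coordinates")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("REMARK   waters placed by aquabridge\n")
        for i, (x, y, z) in enumerate(waters, start=1):
            rec = AtomRecord(
                serial=i, name="O", resname="HOH", chain="W",
                resseq=i, icode="", x=x, y=y, z=z, element="O",
            )
            fh.write(_format_atom_line("HETATM", rec) + "\n")
        fh.write("END\n")
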
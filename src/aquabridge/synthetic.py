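"""Synthetic fixtures with exactly known ground truth.

Every generator is a deterministic function of its seed and plants a truth
that can be re-derived independently by brute force:

* two-chain pseudo-protein complexes with waters planted as interfacial,
  associated, bulk, or double-bridge mediators at guaranteed margins from
  the 3.5 Å rule;
* Brownian water trajectories with a known diffusion constant;
* two-state (on/off) contact timelines with known mean episode length;
* Gaussian-peak density grids with an analytic ranking of maxima.

Chains are built as straight Cα rods with Cβ pseudo-sidechains that point
into or away from the inter-chain gap; this gives exact control over every
planted distance (a water planted at 3.0 Å stays ≥0.4 Å clear of the 3.5 Å
rule after jitter), which a helical backbone would not provide for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dpbl import DensityGrid
from .dynamics import Trajectory
from .models import AtomRecord, ComplexStructure, Model, ResidueID
from .units import CM2_PER_S_TO_A2_PER_PS

_SPACING = 3.8  # Å between residue columns
_GAP_HALF = 4.5  # Å, chain Cα planes at z = ±_GAP_HALF
_JITTER = 0.03  # Å, uniform water-position jitter; margins account for it
_RESNAME_CYCLE = ("ASP", "SER", "ALA", "GLY", "LYS", "THR", "LEU", "GLU")
_MAX_FEATURES = 900


@dataclass
class PlantedComplex:
    """A synthetic two-chain complex with per-water ground truth."""

    structure: ComplexStructure
    labels: list  # intended label per water, structure order
    single_contacts: frozenset  # (ligand ResidueID, receptor ResidueID)
    double_contacts: frozenset  # strict two-water bridges
    seed: int
    ligand_chain: str = "A"
    receptor_chain: str = "B"

    @property
    def label_counts(self) -> dict:
        out = {"interfacial": 0, "associated": 0, "bulk": 0}
        for lab in self.labels:
            out[lab] += 1
        return out


def _atom(serial, name, resname, chain, resseq, xyz, element) -> AtomRecord:
    return AtomRecord(
        serial=serial, name=name, resname=resname, chain=chain, resseq=resseq,
        icode="", x=xyz[0], y=xyz[1], z=xyz[2], element=element,
    )


def make_planted_complex(
    n_interfacial: int,
    n_associated: int,
    n_bulk: int,
    n_double_bridge: int = 0,
    seed: int = 0,
) -> PlantedComplex:
    """Build a two-chain complex realising exactly the requested counts.

    Waters planted as double-bridge mediators are first-shell but touch only
    one chain, so their classification label is ``associated``; the
    classifier therefore recovers ``n_associated + 2*n_double_bridge``
    associated waters.
    """
    for v in (n_interfacial, n_associated, n_bulk, n_double_bridge):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n_features = n_interfacial + n_associated + n_double_bridge
    if n_features > _MAX_FEATURES:
        raise ValueError(
            f"infeasible packing: {n_features} feature columns exceed {_MAX_FEATURES}"
        )
    rng = np.random.default_rng(seed)

    # feature columns every other residue, one residue margin at each end
    n_res = max(2 * n_features + 2, 4)
    feature_cols = [1 + 2 * k for k in range(n_features)]
    kinds = (
        ["interfacial"] * n_interfacial
        + ["double"] * n_double_bridge
        + ["associated"] * n_associated
    )
    rng.shuffle(kinds)
    col_kind = dict(zip(feature_cols, kinds))

    model = Model()
    serial = 0
    for chain, z_ca, inward in (("A", +_GAP_HALF, -1.5), ("B", -_GAP_HALF, +1.5)):
        for i in range(n_res):
            x = _SPACING * i
            resname = _RESNAME_CYCLE[i % len(_RESNAME_CYCLE)]
            serial += 1
            model.protein.append(_atom(serial, "CA", resname, chain, i + 1, (x, 0.0, z_ca), "C"))
            # CB points into the gap only on interfacial columns
            if col_kind.get(i) == "interfacial":
                z_cb = z_ca + inward
            else:
                z_cb = z_ca - inward
            serial += 1
            model.protein.append(_atom(serial, "CB", resname, chain, i + 1, (x, 0.0, z_cb), "C"))

    labels: list[str] = []
    singles: set = set()
    doubles: set = set()

    def rid(chain: str, i: int) -> ResidueID:
        return ResidueID(chain, i + 1, "", _RESNAME_CYCLE[i % len(_RESNAME_CYCLE)])

    def add_water(xyz) -> None:
        nonlocal serial
        serial += 1
        jit = rng.uniform(-_JITTER, _JITTER, 3)
        model.waters.append(
            _atom(serial, "O", "HOH", "W", len(model.waters) + 1, np.asarray(xyz) + jit, "O")
        )

    for i in feature_cols:
        x = _SPACING * i
        kind = col_kind[i]
        if kind == "interfacial":
            add_water((x, 0.0, 0.0))  # 3.0 Å from each inward CB
            labels.append("interfacial")
            singles.add((rid("A", i), rid("B", i)))
        elif kind == "double":
            add_water((x, 0.0, _GAP_HALF - 2.8))  # w1: 2.8 Å below CA of A
            add_water((x, 0.0, -_GAP_HALF + 2.8))  # w2: 2.8 Å above CA of B
            labels.extend(["associated", "associated"])
            doubles.add((rid("A", i), rid("B", i)))
        else:  # associated: beside chain B, outside chain A's shell
            add_water((x, 3.0, -_GAP_HALF - 1.5))
            labels.append("associated")

    for j in range(n_bulk):
        add_water((_SPACING * j, 0.0, -40.0))
        labels.append("bulk")

    planted = PlantedComplex(
        structure=ComplexStructure(models=[model], source=f"planted(seed={seed})"),
        labels=labels,
        single_contacts=frozenset(singles),
        double_contacts=frozenset(doubles),
        seed=seed,
    )
    _verify_planted(planted)
    return planted


def _verify_planted(pc: PlantedComplex, d_c: float = 3.5, d_ww: float = 3.5) -> None:
    """Brute-force self-consistency gate on the planted truth."""
    m = pc.structure.first
    w = m.water_coords()
    lig = m.protein_coords(chains=[pc.ligand_chain])
    rec = m.protein_coords(chains=[pc.receptor_chain])
    if w.shape[0] == 0:
        return
    dl = np.sqrt(((w[:, None, :] - lig[None, :, :]) ** 2).sum(-1)).min(axis=1)
    dr = np.sqrt(((w[:, None, :] - rec[None, :, :]) ** 2).sum(-1)).min(axis=1)
    for k, lab in enumerate(pc.labels):
        near_l, near_r = dl[k] <= d_c, dr[k] <= d_c
        got = (
            "interfacial" if near_l and near_r
            else "associated" if near_l or near_r
            else "bulk"
        )
        if got != lab:
            raise AssertionError(
                f"planted water {k} violates its label: intended {lab}, realises {got}"
            )


def brownian_trajectory(
    n_waters: int, D: float, dt: float, n_frames: int, seed: int = 0, start_box: float = 50.0
) -> Trajectory:
    """Isotropic Gaussian random walk with diffusion constant D (cm²/s).

    Per-axis step variance is 2·D·dt after converting D to Å²/ps.
    """
    if D < 0:
        raise ValueError("diffusion constant must be non-negative")
    if n_frames < 2:
        raise ValueError("need at least two frames")
    rng = np.random.default_rng(seed)
    d_a2ps = D * CM2_PER_S_TO_A2_PER_PS
    sigma = np.sqrt(2.0 * d_a2ps * dt)
    start = rng.uniform(0.0, start_box, size=(1, n_waters, 3))
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_waters, 3)) if sigma > 0 else np.zeros(
        (n_frames - 1, n_waters, 3)
    )
    coords = np.concatenate([start, start + np.cumsum(steps, axis=0)], axis=0)
    return Trajectory(coords=coords, dt=dt)


def onoff_timeline(
    mean_on: float, mean_off: float, dt: float, n_frames: int, seed: int = 0
) -> np.ndarray:
    """Alternating geometric on/off runs with the given mean durations (ps)."""
    if mean_on <= 0 or mean_off <= 0:
        raise ValueError("mean durations must be positive")
    if dt <= 0 or n_frames < 1:
        raise ValueError("dt must be positive and n_frames >= 1")
    rng = np.random.default_rng(seed)
    p_on = min(1.0, dt / mean_on)
    p_off = min(1.0, dt / mean_off)
    state = bool(rng.random() < mean_on / (mean_on + mean_off))
    out = np.empty(n_frames, dtype=bool)
    pos = 0
    while pos < n_frames:
        run = rng.geometric(p_on if state else p_off)
        out[pos : pos + run] = state
        pos += run
        state = not state
    return out


@dataclass
class SyntheticDensity:
    """A Gaussian-peak density grid plus its analytic placement truth."""

    grid: DensityGrid
    peak_nodes: np.ndarray  # (K,3) node coordinates of supra-threshold peaks
    peak_values: np.ndarray  # corresponding analytic density values, descending


def gaussian_density_grid(
    peaks, dims=(33, 33, 33), spacing=1.0, bulk: float = 1.0, base: float = 0.5
) -> SyntheticDensity:
    """Sum of isotropic Gaussians on a sub-bulk floor.

    ``peaks``: list of (centre, height, width).  Values are in units of the
    bulk reference density: the floor ``base`` lies below the placement
    threshold ``bulk``, so only peaks with base+height above ``bulk`` are
    placeable.  Peak centres are snapped to the nearest grid node in the
    recorded truth.
    """
    dims = tuple(int(d) for d in dims)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float).reshape(-1), (3,)).astype(float)
    origin = -spacing * (np.array(dims) - 1) / 2.0
    ax = [origin[i] + np.arange(dims[i]) * spacing[i] for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    vals = np.full(dims, base, dtype=float)
    truth = []
    for centre, height, width in peaks:
        c = np.asarray(centre, dtype=float)
        r2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        vals += height * np.exp(-r2 / (2.0 * width**2))
        node = np.round((c - origin) / spacing).astype(int)
        node = np.clip(node, 0, np.array(dims) - 1)
        truth.append((base + height, origin + node * spacing))
    vals = np.clip(vals, 0.0, None)
    grid = DensityGrid(values=vals, origin=origin, spacing=spacing, bulk_density=0.0334)
    supra = sorted(
        [(v, tuple(n)) for v, n in truth if v > bulk], key=lambda t: -t[0]
    )
    return SyntheticDensity(
        grid=grid,
        peak_nodes=np.array([n for _, n in supra]).reshape(-1, 3),
        peak_values=np.array([v for v, _ in supra]),
    )
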
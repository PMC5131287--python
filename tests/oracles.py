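"""Independent brute-force oracles: plain double/triple/quadruple loops.

These deliberately avoid every data structure the implementation uses
(KD-trees, spatial hashes, FFTs) so that agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def dist_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, float).reshape(-1, 3)
    b = np.asarray(b, float).reshape(-1, 3)
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))


def first_shell_brute(waters, protein, d_c):
    return dist_matrix(waters, protein).min(axis=1) <= d_c


def interfacial_brute(waters, lig, rec, d_c):
    return first_shell_brute(waters, lig, d_c) & first_shell_brute(waters, rec, d_c)


def core_brute(waters, components, d_core):
    mask = np.ones(np.asarray(waters).reshape(-1, 3).shape[0], bool)
    for comp in components:
        mask &= dist_matrix(waters, comp).min(axis=1) < d_core
    return mask


def single_bridge_brute(model, lig_chains, rec_chains, d_c):
    """Triple loop over (water, ligand residue, receptor residue)."""
    lig_atoms = model.protein_atoms(chains=lig_chains, heavy_only=True)
    rec_atoms = model.protein_atoms(chains=rec_chains, heavy_only=True)
    contacts = set()
    for w in model.waters:
        wl = {a.residue_id for a in lig_atoms if _d(w, a) <= d_c}
        wr = {a.residue_id for a in rec_atoms if _d(w, a) <= d_c}
        for rl in wl:
            for rr in wr:
                contacts.add((rl, rr))
    return frozenset(contacts)


def double_bridge_brute(model, lig_chains, rec_chains, d_c, d_ww):
    """Quadruple loop over (w1, w2, ligand residue, receptor residue)."""
    lig_atoms = model.protein_atoms(chains=lig_chains, heavy_only=True)
    rec_atoms = model.protein_atoms(chains=rec_chains, heavy_only=True)
    near_l = [{a.residue_id for a in lig_atoms if _d(w, a) <= d_c} for w in model.waters]
    near_r = [{a.residue_id for a in rec_atoms if _d(w, a) <= d_c} for w in model.waters]
    contacts = set()
    n = len(model.waters)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if _d(model.waters[i], model.waters[j]) > d_ww:
                continue
            for rl in near_l[i]:
                for rr in near_r[j]:
                    contacts.add((rl, rr))
    return frozenset(contacts)


def _d(a, b) -> float:
    return float(np.sqrt((a.x - b.x) ** 2 + (a.y - b.y) ** 2 + (a.z - b.z) ** 2))


def msd_brute(coords: np.ndarray) -> np.ndarray:
    """All-origins MSD by explicit double loop; coords (F, N, 3)."""
    F = coords.shape[0]
    out = np.zeros(F)
    for m in range(F):
        acc = 0.0
        for t in range(F - m):
            acc += ((coords[t + m] - coords[t]) ** 2).sum(-1).mean()
        out[m] = acc / (F - m)
    return out


def place_waters_brute(values, coords, exclusion_radius, stop):
    """Re-scan greedy placement: full argmax pass after every placement."""
    values = values.copy().ravel().astype(float)
    coords = coords.reshape(-1, 3)
    placed = []
    alive = np.ones(values.size, bool)
    while True:
        cand = np.where(alive & (values > stop))[0]
        if cand.size == 0:
            break
        best = cand[np.argmax(values[cand])]
        # lexicographic tie-break: smallest flat index among maxima
        ties = cand[values[cand] == values[best]]
        best = ties.min()
        p = coords[best]
        placed.append(p)
        alive &= ((coords - p) ** 2).sum(1) >= exclusion_radius**2
    return np.array(placed) if placed else np.empty((0, 3))
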
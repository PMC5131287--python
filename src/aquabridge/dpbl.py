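"""Simplified lattice dipolar Poisson-Boltzmann Langevin (DPBL) solver.

Mean-field continuum electrostatics with the solvent entering as mobile
point dipoles on a lattice.  The electrostatic potential ϕ (in kT/e)
satisfies a variable-coefficient Poisson equation

    ∇·[ε(r, |∇ϕ|) ∇ϕ] − κ̄²(r) ϕ = −4π λ_B0 ρ(r)

on a regular grid, where λ_B0 is the vacuum Bjerrum length, ρ the fixed
charge density (e/Å³) spread from PQR atoms, κ̄² the (linearised) implicit
ion term, and ε the Langevin-dipole permittivity closure

    ε(u) = 1 + 4π λ_B0 c p₀² · L(u)/u ,     u = p₀ |∇ϕ| / (kT/e·Å)

with L the Langevin function, c the solvent dipole concentration and p₀ the
dipole moment.  At u→0 this reduces to a uniform solvent permittivity; with
a protein exclusion region the protein interior takes ε_p (default 3).
The water density follows the same closure, ρ_w/ρ_bulk = sinh(u)/u, zero in
the protein interior.  Hydration sites are produced by walking the density
grid in descending order, eliminating neighbours within an exclusion radius
after every placement (greedy, deterministic tie-break by grid index).

Solver modes: ``uniform`` (uniform-ε linear PB, for closed-form checks),
``linear`` (ε_p inside / bulk DPBL ε outside), ``nonlinear`` (field-dependent
ε via damped Picard iteration).  Boundary values are Dirichlet from a
screened-monopole estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, GridError
from .models import ComplexStructure
from .units import DEBYE_TO_E_ANGSTROM, MOLAR_TO_PER_A3, bjerrum_length_vacuum


def _is_pow2_plus1(n: int) -> bool:
    m = n - 1
    return m >= 2 and (m & (m - 1)) == 0


def next_grid_dim(n: int) -> int:
    """Smallest 2^k+1 ≥ n."""
    m = 2
    while m + 1 < n:
        m *= 2
    return m + 1


@dataclass
class LatticeModel:
    """Grid geometry plus the physical parameters of the solvent model."""

    dims: tuple  # (nx, ny, nz), each 2^n + 1
    spacing: np.ndarray  # (3,) Å
    origin: np.ndarray  # (3,) Å, coordinates of node (0,0,0)
    eps_protein: float = 3.0
    solvent_lattice_a: float = 2.8  # Å, size of one solvent site
    dipole_debye: float = 3.0
    conc_molar: float = 55.0
    ion_molar: float = 0.0
    temperature: float = 300.0
    yukawa: bool = False
    yukawa_amplitude: float = 0.0  # dimensionless coupling; 0 disables
    yukawa_screening: float = 2.8  # Å

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        for d in self.dims:
            if not _is_pow2_plus1(d):
                raise GridError(f"grid dims must be 2^n+1, got {self.dims}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise GridError("grid spacing must be positive")
        if self.eps_protein < 1:
            raise GridError("protein dielectric constant must be >= 1")

    # -- derived physical quantities ------------------------------------
    @property
    def bjerrum0(self) -> float:
        return bjerrum_length_vacuum(self.temperature)

    @property
    def dipole_eA(self) -> float:
        return self.dipole_debye * DEBYE_TO_E_ANGSTROM

    @property
    def conc_per_A3(self) -> float:
        return self.conc_molar * MOLAR_TO_PER_A3

    @property
    def eps_bulk(self) -> float:
        """Zero-field solvent permittivity of the Langevin closure."""
        return 1.0 + (4.0 * math.pi / 3.0) * self.bjerrum0 * self.conc_per_A3 * self.dipole_eA**2

    @property
    def kappa_bar2(self) -> float:
        """Linearised 1:1 ion coefficient κ̄² = 8π λ_B0 c_ion (Å⁻²).

        The physical Debye screening constant is κ² = κ̄²/ε_s.
        """
        return 8.0 * math.pi * self.bjerrum0 * self.ion_molar * MOLAR_TO_PER_A3

    def axes(self):
        return [self.origin[i] + np.arange(self.dims[i]) * self.spacing[i] for i in range(3)]

    def node_coords(self) -> np.ndarray:
        """(nx,ny,nz,3) array of node coordinates."""
        ax = self.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X, Y, Z], axis=-1)


def langevin(u):
    """L(u) = coth(u) − 1/u, with the u→0 limit handled."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = np.abs(u) < 1e-4
    us = u[small]
    out[small] = us / 3.0 - us**3 / 45.0
    ub = u[~small]
    out[~small] = 1.0 / np.tanh(ub) - 1.0 / ub
    return out


def _sinhc(u):
    """sinh(u)/u with the u→0 limit; clipped to avoid overflow."""
    u = np.clip(np.abs(np.asarray(u, dtype=float)), 0.0, 500.0)
    out = np.ones_like(u)
    big = u > 1e-8
    out[big] = np.sinh(u[big]) / u[big]
    return out


def relative_density(u, phi_b: float):
    """Lattice-gas Langevin solvent density in units of the bulk density.

    ρ/ρ_bulk = sinhc(u) / (1 − φ_b + φ_b·sinhc(u)) with φ_b = c·a³ the bulk
    occupancy of the solvent lattice.  Monotonically increasing in u,
    normalised to 1 at zero field, saturating at the steric limit 1/φ_b
    (one molecule per solvent lattice site).
    """
    if not 0.0 < phi_b <= 1.0:
        raise ValueError(f"bulk occupancy must lie in (0, 1], got {phi_b}")
    s = _sinhc(u)
    return s / (1.0 - phi_b + phi_b * s)


@dataclass
class Lattice:
    """A LatticeModel together with its charge and exclusion maps."""

    model: LatticeModel
    charge: np.ndarray  # e per node
    exclusion: np.ndarray  # bool, True inside protein
    total_charge: float = 0.0
    charge_center: np.ndarray = field(default_factory=lambda: np.zeros(3))


def build_lattice(
    structure: ComplexStructure | None,
    dims=(65, 65, 65),
    padding: float = 10.0,
    spacing=None,
    **model_kwargs,
) -> Lattice:
    """Spread PQR charges onto a grid and mark the protein exclusion region.

    Charges are distributed trilinearly over the eight surrounding nodes
    (exactly charge-conserving); the exclusion map flags nodes inside any
    atom's radius.  With ``spacing=None`` the spacing is chosen so the
    structure plus ``padding`` fills the grid; an explicit spacing that
    cannot accommodate the structure raises GridError naming workable dims.
    An empty/None structure yields a uniform solvent lattice centred at the
    origin.
    """
    atoms = []
    if structure is not None and structure.models:
        m = structure.first
        atoms = [a for a in m.protein + m.waters + m.water_hydrogens]
    dims = tuple(int(d) for d in dims)

    if atoms:
        pos = np.array([[a.x, a.y, a.z] for a in atoms])
        radii = np.array([0.0 if a.radius is None else a.radius for a in atoms])
        q = np.array([0.0 if a.charge is None else a.charge for a in atoms])
        lo = (pos - radii[:, None]).min(axis=0) - padding
        hi = (pos + radii[:, None]).max(axis=0) + padding
        extent = hi - lo
        if spacing is None:
            sp_vec = extent / (np.array(dims) - 1)
            origin = lo
        else:
            sp_vec = np.broadcast_to(np.asarray(spacing, dtype=float).reshape(-1), (3,)).copy()
            if sp_vec.size == 1:
                sp_vec = np.repeat(sp_vec, 3)
            box = sp_vec * (np.array(dims) - 1)
            if np.any(extent > box):
                need = [next_grid_dim(int(np.ceil(e / s)) + 1) for e, s in zip(extent, sp_vec)]
                raise GridError(
                    f"structure (extent {np.round(extent, 1)} Å + padding) does not fit "
                    f"grid {dims} at spacing {sp_vec}; need dims >= {tuple(need)}"
                )
            center = (lo + hi) / 2.0
            origin = center - box / 2.0
    else:
        pos = np.empty((0, 3))
        radii = q = np.empty(0)
        sp_vec = (
            np.full(3, 1.0)
            if spacing is None
            else np.broadcast_to(np.asarray(spacing, float).reshape(-1), (3,)).astype(float)
        )
        origin = -sp_vec * (np.array(dims) - 1) / 2.0

    model = LatticeModel(dims=dims, spacing=sp_vec, origin=origin, **model_kwargs)
    charge = np.zeros(dims)
    exclusion = np.zeros(dims, dtype=bool)

    # trilinear charge spreading
    for p, qq in zip(pos, q):
        if qq == 0.0:
            continue
        f = (p - origin) / sp_vec
        i0 = np.floor(f).astype(int)
        frac = f - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (frac[0] if dx else 1 - frac[0])
                        * (frac[1] if dy else 1 - frac[1])
                        * (frac[2] if dz else 1 - frac[2])
                    )
                    ii = (i0[0] + dx, i0[1] + dy, i0[2] + dz)
                    if all(0 <= ii[k] < dims[k] for k in range(3)):
                        charge[ii] += qq * w

    # exclusion: nodes inside any atom radius
    ax = model.axes()
    for p, r in zip(pos, radii):
        if r <= 0:
            continue
        sl = []
        ok = True
        for k in range(3):
            a0 = int(np.ceil((p[k] - r - origin[k]) / sp_vec[k]))
            a1 = int(np.floor((p[k] + r - origin[k]) / sp_vec[k]))
            a0, a1 = max(a0, 0), min(a1, dims[k] - 1)
            if a0 > a1:
                ok = False
                break
            sl.append((a0, a1))
        if not ok:
            continue
        gx, gy, gz = np.meshgrid(
            ax[0][sl[0][0] : sl[0][1] + 1],
            ax[1][sl[1][0] : sl[1][1] + 1],
            ax[2][sl[2][0] : sl[2][1] + 1],
            indexing="ij",
        )
        inside = (gx - p[0]) ** 2 + (gy - p[1]) ** 2 + (gz - p[2]) ** 2 <= r * r
        exclusion[
            sl[0][0] : sl[0][1] + 1, sl[1][0] : sl[1][1] + 1, sl[2][0] : sl[2][1] + 1
        ] |= inside

    total_q = float(q.sum())
    center = pos.T @ np.abs(q) / np.abs(q).sum() if np.abs(q).sum() > 0 else origin + sp_vec * (
        np.array(dims) - 1
    ) / 2.0
    return Lattice(
        model=model,
        charge=charge,
        exclusion=exclusion,
        total_charge=total_q,
        charge_center=np.asarray(center, dtype=float),
    )


@dataclass
class FieldSolution:
    """Electrostatic potential in kT/e plus convergence metadata."""

    phi: np.ndarray
    mode: str
    iterations: int
    residuals: list
    converged: bool


def _boundary_estimate(lattice: Lattice, eps_s: float) -> np.ndarray:
    """Screened-monopole Dirichlet estimate on the whole grid."""
    model = lattice.model
    if lattice.total_charge == 0.0:
        return np.zeros(model.dims)
    r = np.linalg.norm(model.node_coords() - lattice.charge_center, axis=-1)
    r = np.maximum(r, 1e-9)
    kappa = math.sqrt(model.kappa_bar2 / eps_s) if model.kappa_bar2 > 0 else 0.0
    return lattice.total_charge * model.bjerrum0 * np.exp(-kappa * r) / (eps_s * r)


def _face_eps(eps_node: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean permittivity on faces in +axis direction (node i, i+1)."""
    a = eps_node
    b = np.roll(eps_node, -1, axis=axis)
    return 2.0 * a * b / (a + b)


def _linear_solve(model: LatticeModel, eps_node, kappa2_node, charge, phi_b, rtol=1e-8):
    """One variable-coefficient 7-point finite-difference solve (CG).

    Uses the mean spacing h (grids are built near-isotropic); equation is
    discretised per interior node, multiplied through by h².
    """
    dims = model.dims
    h = float(np.mean(model.spacing))
    N = int(np.prod(dims))
    interior = np.ones(dims, dtype=bool)
    for axk in range(3):
        sl = [slice(None)] * 3
        sl[axk] = 0
        interior[tuple(sl)] = False
        sl[axk] = -1
        interior[tuple(sl)] = False
    ii = np.where(interior.ravel())[0]
    mapg = -np.ones(N, dtype=np.int64)
    mapg[ii] = np.arange(len(ii))

    b = 4.0 * math.pi * model.bjerrum0 * charge.ravel()[ii] / h
    diag = kappa2_node.ravel()[ii] * h * h
    eps_faces = [_face_eps(eps_node, axk).ravel() for axk in range(3)]
    strides = [dims[1] * dims[2], dims[2], 1]
    rows, cols, vals = [], [], []
    for axk, st in enumerate(strides):
        for s in (+1, -1):
            nb = ii + s * st
            fi = np.where(s > 0, ii, nb)
            e = eps_faces[axk][fi]
            diag = diag + e
            mm = mapg[nb]
            bnd = mm < 0
            rows.append(np.arange(len(ii))[~bnd])
            cols.append(mm[~bnd])
            vals.append(-e[~bnd])
            b[bnd] += e[bnd] * phi_b.ravel()[nb[bnd]]
    rows.append(np.arange(len(ii)))
    cols.append(np.arange(len(ii)))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(ii), len(ii)),
    )
    x, info = spla.cg(A, b, rtol=rtol, maxiter=5000, M=sp.diags(1.0 / A.diagonal()))
    if info != 0:
        raise ConvergenceError(f"inner CG failed to converge (info={info})")
    phi = phi_b.copy().ravel()
    phi[ii] = x
    return phi.reshape(dims)


def _grad_magnitude(phi: np.ndarray, spacing) -> np.ndarray:
    g = np.gradient(phi, *spacing)
    return np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)


def solve(
    lattice: Lattice,
    mode: str = "nonlinear",
    tol: float = 1e-3,
    max_iter: int = 50,
    mix: float = 0.6,
    eps_uniform: float | None = None,
) -> FieldSolution:
    """Solve for the electrostatic potential (kT/e).

    Modes: ``uniform`` (constant ε everywhere, ``eps_uniform`` required —
    the linear-PB limit with closed-form checks), ``linear`` (ε_p inside the
    protein, zero-field DPBL ε outside), ``nonlinear`` (Langevin-dipole
    field-dependent ε, damped Picard iteration until max|Δϕ| < tol).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    model = lattice.model
    if mode == "uniform":
        if eps_uniform is None:
            raise ValueError("mode='uniform' requires eps_uniform")
        eps_s = float(eps_uniform)
        eps_node = np.full(model.dims, eps_s)
        solvent = np.ones(model.dims, dtype=bool)
    elif mode in ("linear", "nonlinear"):
        eps_s = model.eps_bulk
        eps_node = np.where(lattice.exclusion, model.eps_protein, eps_s)
        solvent = ~lattice.exclusion
    else:
        raise ValueError(f"unknown solver mode {mode!r}")

    kappa2 = np.where(solvent, model.kappa_bar2, 0.0)
    phi_b = _boundary_estimate(lattice, eps_s)

    phi = _linear_solve(model, eps_node, kappa2, lattice.charge, phi_b)
    if mode in ("uniform", "linear"):
        return FieldSolution(phi=phi, mode=mode, iterations=1, residuals=[0.0], converged=True)

    residuals = []
    for it in range(1, max_iter + 1):
        u = model.dipole_eA * _grad_magnitude(phi, model.spacing)
        lu_over_u = np.where(u > 1e-12, langevin(u) / np.maximum(u, 1e-12), 1.0 / 3.0)
        eps_field = 1.0 + 4.0 * math.pi * model.bjerrum0 * model.conc_per_A3 * (
            model.dipole_eA**2
        ) * lu_over_u
        eps_node = np.where(lattice.exclusion, model.eps_protein, eps_field)
        phi_new = _linear_solve(model, eps_node, kappa2, lattice.charge, phi_b)
        phi_next = (1.0 - mix) * phi + mix * phi_new
        res = float(np.max(np.abs(phi_next - phi)))
        residuals.append(res)
        phi = phi_next
        if res < tol:
            return FieldSolution(
                phi=phi, mode=mode, iterations=it, residuals=residuals, converged=True
            )
    raise ConvergenceError(
        f"DPBL Picard iteration did not reach tol={tol} in {max_iter} iterations "
        f"(last residual {residuals[-1]:.3g})",
        residuals=residuals,
    )


@dataclass
class DensityGrid:
    """Relative solvent density (units of bulk density) on a regular grid."""

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    bulk_density: float  # molecules per Å³ corresponding to value 1.0
    exclusion: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.values < 0):
            raise ValueError("density must be non-negative")

    def node_coords_flat(self) -> np.ndarray:
        ax = [self.origin[i] + np.arange(self.values.shape[i]) * self.spacing[i] for i in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def to_dx(self, path) -> None:
        from gridData import Grid

        Grid(self.values, origin=self.origin, delta=self.spacing).export(str(path), typequote="")

    @classmethod
    def from_dx(cls, path, bulk_density: float = 1.0) -> "DensityGrid":
        from gridData import Grid

        g = Grid(str(path))
        delta = np.diag(g.delta) if np.ndim(g.delta) == 2 else np.asarray(g.delta)
        return cls(values=g.grid, origin=np.asarray(g.origin), spacing=delta, bulk_density=bulk_density)


def water_density(solution: FieldSolution, lattice: Lattice) -> DensityGrid:
    """Langevin solvent density from a converged field (see relative_density).

    Zero inside the protein exclusion region.  With the Yukawa variant
    enabled, a short-range dipole-dipole repulsion attenuates the density in
    proportion to the locally screened excess density (coupling amplitude 0
    reproduces the plain model exactly).
    """
    if not solution.converged:
        raise ValueError("water_density requires a converged field solution")
    model = lattice.model
    u = model.dipole_eA * _grad_magnitude(solution.phi, model.spacing)
    phi_b = model.conc_per_A3 * model.solvent_lattice_a**3
    dens = relative_density(u, phi_b)
    dens[lattice.exclusion] = 0.0
    if model.yukawa and model.yukawa_amplitude > 0.0:
        dens = _yukawa_attenuate(dens, model)
        dens[lattice.exclusion] = 0.0
    return DensityGrid(
        values=dens,
        origin=model.origin,
        spacing=model.spacing,
        bulk_density=model.conc_per_A3,
        exclusion=lattice.exclusion.copy(),
    )


def _yukawa_attenuate(dens: np.ndarray, model: LatticeModel) -> np.ndarray:
    from scipy.ndimage import convolve

    ell = model.yukawa_screening
    half = [max(1, int(np.ceil(2.0 * ell / s))) for s in model.spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, model.spacing)], indexing="ij"
    )
    r = np.sqrt(sum(g**2 for g in grids))
    r[r == 0] = model.spacing.min() / 2.0
    kernel = np.exp(-r / ell) / (r / ell)
    kernel /= kernel.sum()
    excess = convolve(dens - 1.0, kernel, mode="constant", cval=0.0)
    return dens * np.exp(-model.yukawa_amplitude * np.clip(excess, 0.0, None))


def place_waters(
    density: DensityGrid, exclusion_radius: float = 3.0, stop: float | None = None
) -> np.ndarray:
    """Greedy hydration-site placement from a density grid.

    Repeatedly take the highest-density remaining node with density strictly
    above ``stop`` (default: the bulk reference, 1.0 in relative units),
    emit a water oxygen there, and eliminate all nodes within
    ``exclusion_radius`` (default 3.0 Å).  Ties are broken by lexicographic
    grid index, making the result a pure function of the density values.
    """
    if exclusion_radius <= 0:
        raise ValueError("exclusion radius must be positive")
    stop = 1.0 if stop is None else float(stop)
    vals = density.values.ravel()
    cand = np.where(vals > stop)[0]
    if cand.size == 0:
        return np.empty((0, 3))
    # primary key: descending density; secondary: ascending flat index
    order = cand[np.lexsort((cand, -vals[cand]))]
    coords = density.node_coords_flat()[order]

    placed: list[np.ndarray] = []
    cell = exclusion_radius
    buckets: dict[tuple, list[int]] = {}
    r2 = exclusion_radius**2
    for k, p in enumerate(coords):
        key = tuple((p // cell).astype(int))
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for j in buckets.get((key[0] + dx, key[1] + dy, key[2] + dz), ()):
                        d = placed[j] - p
                        if d @ d < r2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault(key, []).append(len(placed))
            placed.append(p)
    return np.array(placed) if placed else np.empty((0, 3))
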
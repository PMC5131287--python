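# Methods

This note records the models implemented by `aquabridge`, the defaults and
their units, the numerical choices, and what the synthetic fixtures do and
do not establish about real data.

## Water classification and bridge contacts

All contact rules operate on the water **oxygen** and on protein **heavy**
atoms only (hydrogens are retained in memory when present, but never enter
a distance rule; atom types are not otherwise distinguished).  Two
comparison conventions coexist deliberately:

- the 3.5 Å first-shell/contact rule is **inclusive** (≤ 3.5 Å);
- the 11 Å (1.1 nm) core rule is **strict** (< 11 Å).

Labels are exhaustive and mutually exclusive, assigned in order:
interfacial (or core, in core mode) first, then associated (first-shell
remainder), then bulk.  Enlarging either cutoff can only grow the
corresponding set (a property the test suite checks).

Contact identity is the unordered residue pair keyed by
(chain, resseq, icode); the mediating water does not enter contact
equality, so recall compares contact topology, not water positions.  The
double-bridge detector reports **both** the strict two-water set and its
union with the single-bridge set: published double-bridge counts do not fix
which convention was used, so both are always available, and the pipeline
uses the union as the native set in double-bridge mode (a double-bridge
analysis extends, rather than replaces, the single-bridge one).  The
water–water oxygen cutoff for double bridges defaults to 3.5 Å, the same
as the water–protein cutoff; it is exposed as a parameter because no
published value fixes it.

Distance queries use `scipy.spatial.cKDTree`; results are required (and
tested) to be identical to brute-force all-pairs loops — the tree is a
performance contract, not a semantic one.

Residue polarity classes for interface composition default to
charged {ASP, GLU, LYS, ARG, HIS}, polar {SER, THR, ASN, GLN, TYR, CYS,
TRP}, non-polar {ALA, VAL, LEU, ILE, PRO, PHE, MET, GLY}.  Histidine as
charged and tryptophan as polar are conventions, not facts; the table is
configurable and composition percentages should be read qualitatively.

Consensus contacts over multiple crystal copies map each copy's residues
onto a canonical copy chain-by-chain (resseq/icode/resname preserved) and
intersect the contact sets, so only contacts present in every copy count.

## Structure I/O

PDB parsing is delegated to gemmi, PQR parsing to MDAnalysis, both behind a
uniform coordinate model with a protein/water partition per model
(water residue names default to {HOH, WAT, SOL, TIP, SPC, TIP3, TIP4}).
Alternate locations: the first-listed conformer is kept — deterministic and
common practice; occupancy-weighted selection is not attempted.  PQR
charges and radii are rounded to 6 decimals on input to restore the file's
fixed-decimal semantics after the reader's float32 storage.  Multi-model
PDB is the trajectory interchange format; frames are matched by water
serial.  Coordinates are Å everywhere; quantities stated in nm in the
literature (the 1.1 nm core shell) are converted at the API boundary.

## Diffusion and residence times

The MSD is the all-origins average, computed per water by the standard
FFT-autocorrelation decomposition (exactly equal to the double loop over
origins, which the tests verify).  With a periodic box attached,
coordinates are first unwrapped by accumulating minimum-image frame
displacements.  The Einstein fit `D = slope/6` uses an ordinary
least-squares line over a lag window defaulting to [10 %, 50 %] of the
maximum lag — below that the curve is dominated by the short-time regime,
above it by origin-starved noise.  Unit conversion: 1 Å²/ps = 10⁻⁴ cm²/s.

Residence episodes are maximal runs of consecutive in-contact frames
(contact = first-shell rule per frame); a run of k frames counts k·dt ps.
Runs touching either trajectory end are **censored** — their true length is
unknown — and excluded from the mean by default (including them biases
short trajectories downward; the censored count is reported so either
convention can be reconstructed).  No gap tolerance by default; a
`gap_frames` option merges runs separated by short excursions for users who
want the laxer convention.

On a geometric on/off process with 7 ps mean on-time, 10⁵ frames at
dt = 0.2 ps give the mean within a few percent; the Brownian generator at
D = 4 × 10⁻⁵ cm²/s with 100 waters × 10⁴ frames is recovered within ~3 %.
These sizes are what the tests and the acceptance script run.

## DPBL lattice solver

Potential ϕ is in kT/e, lengths in Å, charges in e.  The only coupling
constant is the vacuum Bjerrum length λ_B0 = e²/(4πε₀kT) (≈ 557 Å at
300 K), giving `∇·(ε_r∇ϕ) = −4πλ_B0 ρ` with ρ in e/Å³.

- **Grid**: (2ⁿ+1)³ nodes (defaults 65³ or 129³, ≈1 Å spacing); charges
  spread trilinearly to the 8 surrounding nodes (exactly
  charge-conserving, tested to 10⁻⁹ e); exclusion map = nodes inside any
  atom's PQR radius; ε_p (default 3) inside, solvent model outside.
- **Closure**: the Langevin-dipole permittivity
  ε(u) = 1 + 4πλ_B0·c·p₀²·L(u)/u with u = p₀|∇ϕ|, c = 55 mol/l,
  p₀ = 3.0 D.  Its zero-field limit gives ε_bulk ≈ 31 for these defaults —
  the known mean-field underestimate of water's 78; we keep the bare
  closure rather than rescaling p₀, and document it as a model choice.
- **Ions**: linearised 1:1 salt, κ̄² = 8πλ_B0·c_ion in the solvent region
  (physical Debye constant κ² = κ̄²/ε_s).
- **Discretisation**: 7-point finite differences with harmonic-mean face
  permittivities; Dirichlet boundary from a screened-monopole estimate
  (net charge at the charge centroid).  Inner linear solves use
  diagonally-preconditioned conjugate gradients (rtol 10⁻⁸).
- **Nonlinear mode**: damped Picard iteration (mixing 0.6) on ε(|∇ϕ|),
  converged when max|Δϕ| < tol (default 10⁻³ kT/e); non-convergence raises
  with the residual history.  Mode flags `uniform` (constant ε) and
  `linear` (ε_p/ε_bulk, no field dependence) exist so the Coulomb and
  Debye–Hückel closed forms can exercise the solver: on a 65³ grid at
  1.25 Å spacing the maximum relative error in the 5–20 Å shell is ≈2 %
  (Coulomb) and ≈3.4 % (screened), against a 5 % requirement.

**Water density.**  ρ_w/ρ_bulk = sinhc(u)/(1−φ_b+φ_b·sinhc(u)) with
φ_b = c·a³ the bulk occupancy of the solvent lattice (a = 2.8 Å →
φ_b ≈ 0.73).  This is the lattice-gas form: it reduces to the pure
sinh(u)/u Langevin factor at small u, is monotonically increasing in the
field, and saturates at one molecule per solvent site (1/a³), which keeps
densities finite next to bare charges.  Density is zero inside the
exclusion region.  The optional Yukawa variant models short-range
dipole–dipole repulsion as a density attenuation
ρ → ρ·exp(−A·[K ⊛ (ρ/ρ_b − 1)]₊) with a normalised Yukawa kernel
K ∝ e^(−r/ℓ)/(r/ℓ) (defaults ℓ = 2.8 Å, A = 0 — i.e. off; A → 0
reproduces the plain model bit-for-bit, which is tested).  Amplitude and
screening length are model-choice parameters, not published values.

**Placement.**  Greedy walk down the density values: repeatedly take the
highest-density remaining node with density strictly above the stop
threshold (default: the bulk reference), emit a water oxygen, eliminate
nodes strictly within the exclusion radius (default 3.0 Å).  Ties are
broken by lexicographic grid index, so placement is a pure function of the
density values; the spatial-hash implementation is tested identical to a
full re-scan-per-placement oracle, and placed waters are pairwise ≥ 3.0 Å
apart by construction.

## Synthetic fixtures: what they do and do not show

The planted-complex generator builds two straight Cα rods (3.8 Å residue
spacing, Cα planes 9 Å apart) with Cβ pseudo-sidechains pointing into the
inter-chain gap on interfacial columns and away from it elsewhere.  This
geometry realises each requested label with a guaranteed margin to the
3.5 Å rule (planted distances 2.8–3.0 Å or ≥ 3.8 Å, jitter ±0.03 Å), and
every generated fixture re-verifies its own truth by brute force before it
is returned.  Straight rods were chosen over helices deliberately: the
margins are exact and auditable, and a helical backbone adds no power to a
distance-rule test.  Waters planted as double-bridge mediators touch one
chain only, so they classify as associated (the classifier recovers
n_associated + 2·n_double_bridge).

What passing these tests shows: the distance rules, contact detectors,
estimators and placement rule implement their definitions exactly.  What
they do not show: agreement with crystallographic counts for real
complexes, which depends on deposited coordinates, altloc/occupancy
conventions and chain selections — the crystal-count tests cover that and
require the PDB entries on disk (`scripts/fetch_crystals.py`).

The Brownian generator has no protein, no hydrodynamics and no caging; the
on/off generator is memoryless.  They validate estimator correctness and
bias, not water physics.  The Gaussian density grids place their sub-bulk
floor at 0.5 of the reference so that sub-bulk peaks genuinely stay below
the placement threshold.

## Known limitations

- No hydrogen-bond angular criteria, occupancy or B-factor filtering in
  the water rules; no positional (distance-to-crystal-water) recall.
- The DPBL functional here is a standard Langevin-dipole/lattice-gas
  closure; it is not a reimplementation of any particular solver's
  numerics, and its bulk permittivity (≈31 at the defaults) underestimates
  water's.
- The residence-time estimator's censoring convention matters for short
  trajectories; both conventions are derivable from the reported output.
- mmCIF, symmetry mates and missing-atom reconstruction are out of scope;
  PQR inputs are expected to come from an external protonation/charge
  assignment tool.
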
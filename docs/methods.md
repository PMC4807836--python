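# Methods

This note documents the models implemented in `vibro`, the conventions
and numerical choices behind them, what the synthetic generators emulate,
and the limits of what the test suite demonstrates.

## Units and constants

Internally: Hartree atomic units for Hessians, electric fields and
multipoles; Angstrom for geometry I/O; amu for masses; cm⁻¹ for
vibrational frequencies (1 cm⁻¹ = 0.123984 meV); kcal/mol for MD energies.
Every conversion factor is derived at import time from CODATA values via
`scipy.constants` (`vibro/units.py`), so round trips are exact to machine
precision and no hand-copied constants can drift. The MD electrostatic
constant 332.0636 kcal·Å/(mol·e²) and the gas constant
R = 0.0019872 kcal/(mol·K) fall out of the same table.

## Harmonic analysis

The Cartesian Hessian (symmetrized on load; asymmetries above 1e-4 au are
logged) is mass-weighted and the six rigid-body degrees of freedom are
removed by explicit projection of the orthonormalized Eckart
translation/rotation vectors, P = I − Σ v vᵀ, before diagonalization —
not by discarding the smallest eigenvalues. Explicit projection remains
robust when the geometry is not exactly stationary (typical for embedded
structures), in which case more than six near-zero modes trigger a
warning rather than silent misassignment. Eigenvalues below
|ν̃| < 1 cm⁻¹ are treated as rigid-body remnants and dropped; negative
eigenvalues are reported as negative ("imaginary") frequencies and
excluded from the coupling and spectrum stages with a warning, since the
displaced-oscillator formalism assumes real ω.

Mode vectors follow the convention Σ_n m(n)|y_μ(n)|² = 1 (units amu^−1/2).
This is the unique normalization that makes the coupling strength
u = −√(ω/2ħ)·δΠ dimensionless with δΠ in amu^1/2·Bohr, and it fixes the
reduced mass as 1/Σ|y|². Each eigenvector's sign is chosen so its
largest-magnitude component is positive, making δΠ signs reproducible
across BLAS implementations.

IR intensities use the double-harmonic expression
A_μ ∝ |Σ_n (∂μ⃗/∂r_n)·y_μ(n)|² with the standard km/mol prefactor
(≈ 974.9 km/mol per e²/amu), validated in the tests against a
finite-difference dipole-expectation oracle.

Vacuum/embedded mode pairing is solved as a linear assignment problem on
the squared mass-weighted overlap matrix (`scipy.optimize.
linear_sum_assignment`); overlaps lie in [0, 1] by orthonormality, the
assignment is a bijection, and shifts are reported in cm⁻¹ and meV.
Spectra are sums of unit-area Lorentzians scaled by stick intensity; the
broadening FWHM is a free parameter (no canonical value exists for this
kind of plot).

## Embedding fields

Environment sites carry monopoles, point dipoles, traceless Buckingham
quadrupoles (the trace is removed on load, with a warning above 1e-8 au)
and symmetric anisotropic dipole–dipole polarizabilities. Fields are
evaluated analytically (E = −∇φ for each multipole order); the test suite
checks the implementation against a central-difference gradient of the
analytically summed potential. Induced dipoles are converged by Picard
iteration of μ_i = α_i(E_perm,i + Σ_j T_ij μ_j) to a max-component
tolerance (default 1e-8 au, 200 iterations); divergence — the
polarization catastrophe for closely spaced polarizable sites — raises an
error with the residual. No Thole-style damping is applied: the intended
inputs are LoProp-quality distributed polarizabilities at
chemically sensible separations.

Design choices that were genuinely open:

- *Field "at the center" of the odorant*: mass-weighted average of the
  per-atom field vectors (a geometric-center option exists). Mass
  weighting matches the vibrational formalism, where every projection is
  mass-weighted.
- The odorant's own multipoles never contribute to the field acting on it
  (embedding semantics).
- When polarizabilities are present the default field includes converged
  induced dipoles; a permanent-only evaluation is a flag away.

## Electron-phonon coupling

The displacement Δ(E⃗_i, n) of atom n under the state-i field admits two
routes:

1. **Linear response** (self-contained): forces F_n = q_n E⃗(n) on the
   partial charges; Δ = H⁺F via the eigendecomposition pseudo-inverse of
   the Eckart-projected mass-weighted Hessian, so rigid-body force
   components are annihilated rather than amplified, and Δ is exactly
   internal. A Hessian that is singular beyond the six rigid-body modes
   raises.
2. **Geometry difference**: two optimized geometries (e.g. vacuum vs.
   embedded, or before/after ET) are superposed by mass-weighted Kabsch
   rotation before differencing, removing spurious rigid-body
   contributions to δΠ.

δΠ_μ = Σ_n m(n) y_μ(n)·Δ(n) then follows directly; with the y
normalization above this equals the projection of the mass-weighted
displacement onto the orthonormal eigenvector, so completeness
(reconstruction of any internal Δ from its projections) holds to 1e-8 and
is tested.

u = −√(ω/2ħ)·δΠ is evaluated in atomic units (ħ = 1; ω from cm⁻¹ via
2πc; δΠ from amu^1/2 Bohr via √(amu/mₑ)). The Huang-Rhys weights are the
normalized Poisson distribution σ_n = Sⁿe^(−S)/n! with S = (u_D − u_A)²,
computed in log space for numerical stability at large S; Σσ_n = 1 holds
to 1e-12 for S ≤ 10 at n_max = 50. A divergent variant with e^(+S) is
retained behind `normalized=False` purely for comparison with legacy
typeset forms; it is never the default because Franck–Condon factors must
sum to one. Per-mode tables report σ_1 (single-phonon emission, the
quantity relevant to inelastic tunnelling); the full σ_n table is always
available.

## Marcus energetics

The energy-density fit reproduces the literal histogram protocol:
density-normalized bins of width 5 kcal/mol (default) and a least-squares
fit of p(E) = (1/(ω√(π/2))) exp(−2(E−⟨E⟩)²/ω²), initialized at the
sample mean and 2×SD; a closed-form MLE path exists behind
`method="mle"`. Note the binning bias: least squares on bin heights
inflates the recovered variance by ≈ (bin width)²/12, negligible when the
distribution is much wider than a bin (the intended receptor-scale regime,
widths ~100 kcal/mol) but significant otherwise — the λ = 5 kcal/mol
recovery demonstration therefore bins at 1 kcal/mol, since that
distribution is itself only ~5 kcal/mol wide.

G(E) = −RT ln p(E) is an exact parabola (minimum at ⟨E⟩, curvature
4RT/ω²) and is constructed analytically, not by numerical logarithm of
binned data. The reorganization report gives (a) the descriptive minima
separation |⟨E_D⟩ − ⟨E_A⟩| with an "indistinguishable" flag when it is
below one sampling bin — the order-of-magnitude argument appropriate for
total-potential-energy distributions — and (b) the width-based estimator
λ_w = ω²/(8RT) from the linear-response identity Var(E) = 2λRT, clearly
labelled an extension: for total-energy (rather than energy-gap)
distributions it is an upper-bound-flavoured heuristic, which is why the
default reporting leads with the descriptive comparison.

The Marcus rate uses the standard exponent denominator 4λk_BT. A
`literal_exponent` flag inserts an extra π (a form that appears in some
typeset sources); it is preserved for inspection, never default, and the
difference is documented by a test.

## Trajectory metrics

Alignment is least-squares rigid-body superposition (SVD Kabsch with the
proper-rotation determinant correction) of each frame onto frame 0 over a
selection of ≥ 3 atoms. RMSD is computed against a reference frame
without re-fitting, so users control whether rigid-body motion is removed
(align first) — matching the common workflow of aligning on a backbone
selection and measuring ligand RMSD.

Interaction energies are analysis-grade direct sums: Coulomb
q_iq_j·332.0636/r with a hard 12 Å cutoff (ε_r = 1; the production MD's
PME is out of scope for post-processing decomposition), and 12-6
Lennard-Jones ε[(r_min/r)¹² − 2(r_min/r)⁶] under a CHARMM-style C¹
energy-switching function between 10 and 12 Å. Pair parameters combine as
ε_ij = √(ε_iε_j), r_min,ij = (r_min,i + r_min,j)/2. Periodic minimum-image
handling is not implemented (the synthetic fixtures are non-periodic);
the running mean is centered with symmetrically shrinking edge windows,
default window 50 frames.

## Synthetic data: what it emulates, and what it does not

The generators produce every input class with attached ground truth:

- **Toy molecules** (`diatomic`, `linear_triatomic`, `bent_triatomic`,
  `chain-N`, `cluster-N`): Hessians assembled as Σ k(∂s/∂x)(∂s/∂x)ᵀ over
  bond, valence-angle and (for linear chains) transverse-bend
  coordinates — exact at equilibrium, so harmonic frequencies are exact,
  and closed forms exist for the diatomic and the symmetric linear
  triatomic stretches. `cluster-N` places N atoms at seeded random 3D
  positions with all-pair springs: a generic nonlinear molecule with full
  internal rank, used for the 17-atom (acetophenone-sized) 3N−6 = 45 mode
  count. Default force constant 0.3 Hartree/Bohr² and charges ±0.3 e are
  ordinary covalent-bond / organic-partial-charge magnitudes.
- **Two-state environments**: point charges only by default — the
  smallest structure with a closed-form field difference (two opposite
  charges appearing at the donor/acceptor sites upon ET with
  q_transfer = 1 e, i.e. the transferred electron).
- **Energy traces**: independent Gaussians per state, SD = width/2. The
  default regime has equal means and widths (the near-degenerate,
  λ → 0 situation); `make_traces_for_lambda` encodes a chosen λ through
  Var = 2λRT for recovery tests.
- **Trajectories**: scripted motions (static, drift, axial oscillation,
  seeded random walk) with closed-form expected RMSD/distance series in
  the metadata.

What passing tests therefore show: the mathematics of every stage is
correct against independent oracles, unit conversions compose exactly,
and the pipeline is internally consistent end to end. What they do not
show: anything about real receptor electrostatics — the synthetic
environments have no protein structure, no conformational sampling, no
polarization heterogeneity, and the toy Hessians have no anharmonicity.
Quantities that depend on production QM/MM data (e.g. specific mode
wavenumbers of a real odorant, or in-protein frequency shifts) are
obtained by feeding such data through `molecular_io`; the package
validates the analysis, not the electronic-structure inputs.

## Problem sizes

Default demonstration sizes were chosen so every analysis is effectively
instantaneous while estimator noise stays well inside the documented
tolerances: 10⁵ samples for density fits (Monte-Carlo error on the mean
≈ SD/√n ≈ 0.16 kcal/mol at width 100), ≤ 17-atom toys (45-mode Hessians
diagonalize in milliseconds), tens of frames for trajectory fixtures.

## Known limitations

- Linear-response displacements require per-atom point charges; fields
  varying strongly across a bond are represented only through their
  values at the nuclei.
- The induced-dipole solver has no damping and will (correctly) refuse
  to converge for sub-Ångström polarizable contacts.
- λ_w from total-potential-energy traces inherits all caveats of the
  linear-response identity; it is an order-of-magnitude tool.
- The PDB reader takes coordinates and elements only; no topology,
  occupancy filtering, or altloc handling.
- No periodic boundary conditions anywhere in the analysis layer.
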
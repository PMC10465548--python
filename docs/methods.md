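# Methods

## Interaction model

The unit of all energetics is a rigid molecule: an ordered list of atoms
with coordinates (Å), partial charges (e), Lennard-Jones parameters
(ε in kcal/mol, self-pair σᵢᵢ in Å) and residue labels.  The pair energy
between two molecules is the sum over cross atom pairs of

* a hard core: infinite when r < (σᵢᵢ + σⱼⱼ)/2, the sum of core radii;
* a Lennard-Jones attraction 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] scaled by
  s₁ (default 0.16);
* a Debye–Hückel term 332·qᵢqⱼ·e^(−κr)/(ε_r·r) kcal/mol scaled by s₂
  (default 1.6), with ε_r = 78.5 and κ = √I/3.047 Å⁻¹ × √(78.5·298/(ε_r·T))
  for ionic strength I in M (default 0.24 M).

Both r-dependent terms are truncated sharply (no shift) at 12 Å — per
atom pair, identically in the direct evaluator and in the FFT kernels,
so the two routes are interchangeable.  The combining rule is geometric
in both ε and σ: this is what factorises the double sum over atoms into
two separable correlations and is therefore a structural requirement of
the FFT engine, not merely a convention; the s₁ calibration absorbs the
(small) difference from Lorentz–Berthelot.  κ is always evaluated at the
reference temperature (298 K): the entire energy function is frozen
there and only the Boltzmann β changes when chemical potentials or
virial coefficients are requested at other temperatures.

The dielectric constant is exposed in `EnergyParams` because s₂ is, in
part, a proxy for dielectric reduction in crowded solutions; 78.5 is the
bulk-water default.

PQR input: charges and radii come from the file.  The radius column is
interpreted as an Rmin/2-type van der Waals radius by default
(σᵢᵢ = 2r/2^{1/6}); `sigma_convention="sigma"` treats it as σᵢᵢ/2
directly.  A bundled AMBER-ff99-style per-element table supplies ε (and
σ only when the file's radius is zero, as for some polar hydrogens);
unknown atoms raise rather than defaulting silently.

## FFT scan

A cubic lattice (default spacing 0.6 Å) tiles the periodic box;
n_per_dim = round(box/spacing), so a 324 Å box gives exactly 540³
points.  For one solution configuration, three Fourier-space fields are
built from per-atom weight grids (√ε·σ⁶, √ε·σ³, q deposited by trilinear
interpolation onto the 8 surrounding voxels) convolved with truncated
r⁻¹², r⁻⁶ and Debye–Hückel kernels.  One test orientation then costs a
few forward FFTs of the rotated test-molecule grids and two inverse
FFTs, yielding the raw nonpolar and electrostatic terms at every lattice
point; the scaled total is s₁·nonpolar + s₂·electrostatic.  Keeping the
two terms separate means s₁/s₂ can be rescanned from stored histograms
without re-running any FFTs.

Steric clash is resolved exactly on the lattice: test atoms are grouped
by core radius, and for each group the solution atoms are stamped as
balls of the summed contact radius (strict inequality) around their
nearest voxel; a positive cross-correlation with the test group's delta
grid means precisely that some snapped atom pair sits closer than its
contact distance.  For atoms on lattice points this reproduces the hard
core exactly; off-lattice atoms are resolved to within one voxel.

The r⁻¹² and r⁻⁶ kernels are capped at their one-voxel value.  The cap
lies inside the hard core whenever the spacing is below the smallest
contact distance, so clash-free energies are never affected.

Rasterisation error: trilinear spreading effectively blurs each source
atom over ± one voxel, and near the hard-core contact — where the
potential curvature is largest and the Boltzmann factor matters most —
this biases deep attractive wells toward zero.  The error grows with
β·ε and with spacing relative to atom size; it is negligible for the
default 0.6 Å spacing on protein-sized molecules (thousands of shallow
atom pairs) but visible for single-atom toys with deep wells, which is
why the dual-route virial consistency check uses a gently attractive
sphere at 0.5 Å spacing.

## Configuration sampling

Solution configurations come from Metropolis Monte Carlo on rigid-body
poses: single-molecule Gaussian translations plus small axis-angle
rotations, acceptance with the full pair energy at 298 K, minimum-image
convention.  Only the equilibrium ensemble matters for Widom insertion,
so no attempt is made to model dynamics.  Move sizes are auto-tuned
toward 30–50% acceptance during equilibration only; production sampling
therefore satisfies detailed balance.  Initial configurations are built
by random sequential clash-free insertion (10⁶-attempt budget).  All
randomness flows through one seeded generator, making runs
bit-reproducible.  The sampler's distributional contract is tested
through g(r): at low density the centre-of-geometry pair distribution
must follow e^(−βu(r)).

## Widom insertion and the energy histogram

Clash-free insertion energies from all (configuration, orientation)
scans are pooled into a histogram with 0.016 kcal/mol bins;
exp(−βμ_ex) = (f_CF/M_CF)·ΣH(U)e^(−βU), evaluated by log-sum-exp
(β|U_min| can exceed 700).  The clash-free fraction f_CF is pooled over
all scans and treated as a constant — its fluctuations are orders of
magnitude below those of the Boltzmann average.

Alongside each bin's count we store its energy sum (first moment), and
all Boltzmann/Mayer sums use the count-weighted mean bin energy rather
than the nominal centre.  With nominal centres the ±Δ/2 quantisation is
coherent across the enormous near-zero-energy bulk and produced a ~13%
bias in toy virial coefficients; first moments make the sums
second-order accurate in Δ while keeping the
one-histogram-for-all-temperatures design.  The CDF/tail machinery uses
nominal centres (it only needs counts).

Energies above +500 kcal/mol are clamped into the top bin; their
Boltzmann weight is zero at any temperature of interest, and the clamp
only bounds the histogram's extent.

Per-orientation sub-histograms are retained; the per-orientation average
Boltzmann factors feed a Flyvbjerg–Petersen blocking estimate of the
standard error (successive pair averaging; the reported SE is the
largest level estimate among levels with ≥ 16 blocks, a conservative
plateau rule), propagated through −ln as SE/m.  Poses with energies
below −8 kcal/mol (insertion) or −6 kcal/mol (virial scans) are archived
for clustering and residue decomposition.

## Low-energy tail correction

The unnormalised CDF of insertion energies is empirically exponential,
C(U) = A·e^(αU), over the negative-U range; equivalently x = e^(−βU)
follows a power law with upper bound b = e^(−βU_min).  ln C(U) is fitted
by tricube-weighted local linear regression (degree 1, span 0.75 — a
loess replica; exact numerical parity with R's loess is not promised,
parameter-recovery tolerances are the contract) over a window bounded
below by the count level 10⁴ and above by U = −4 kcal/mol; both bounds
are parameters because toy histograms are far smaller than the ~10¹⁴
insertion energies of a production run.  Below the window the model
extrapolates along the tangent at the window's lower edge (value and
slope continuous); α is that slope.

The endpoint U_min is estimated two ways.  The block-minimum route
divides the energies into blocks of M_ori orientations, averages each
block size's lowest energy, and fits Û(M) = U_min + E/(1 + (M/D)^δ) by
trust-region least squares with δ ∈ [0.6, 1] and D shared across
concentrations (initial values: δ = 0.8, D = median M, E from the data
range, U_min from the deepest mean).  The default route anchors the
extrapolated CDF at CDF(U_min) = B·f_CF^γ with B = 1, γ = 0.25, which
the block fits validate.  The corrected chemical potential replaces
H(U) below the window by the differenced extrapolated CDF truncated at
U_min, rescaled so the replaced mass equals the observed count below the
window (total stays at M_CF exactly).  An observed lowest energy more
than 1 kcal/mol below the CDF = 1 extrapolation is flagged as an
outlier.

## Phase diagram

βμ_ex(ρ) at each temperature (≥ 6 concentrations) is fitted by a
fifth-order polynomial with no constant term; b₁ is reported as twice
the second virial coefficient.  The full curve ln(ρ/ρ₀) + Σb_lρˡ is
scanned for interior extrema (dense sampling plus bounded refinement);
exactly one maximum followed by one minimum constitutes a van der Waals
loop, anything else returns a no-loop (supercritical) marker rather than
an error.  The bisection level μ* solves the equal-area condition
∫(βμ − μ*)dρ = 0 between the outer intersections; for the ideal +
polynomial form the integral uses the closed-form antiderivative
(ρlnρ − ρ plus polynomial terms), for generic curves adaptive
quadrature.  The outer intersections are the binodal, the extrema the
spinodal.  T_c is reported as a bracket — warmest loop-bearing and
coolest loop-free temperature — plus its midpoint; no scaling-law
extrapolation is attempted.  ρ₀ = 1 (arbitrary units) cancels in the
construction.

The Vliegenthart–Lekkerkerker estimate locates the root of
B₂(T)/V_st + 6 on the linear interpolant of a B₂(T) sweep, reporting
"below range"/"above range" when there is no crossing.

## Virial coefficients

FMAPB2 places a single central copy in a periodic box (default 200 Å;
required to be large enough that periodic images cannot interact) and
scans the test copy over the lattice for a deterministic SO(3) covering.
Clashed lattice points contribute exactly −1 to the Mayer average,
clash-free points e^(−βU) − 1; B₂ = −(V/2)·mean.  One histogram plus the
clash count serves the whole temperature grid, and the steric-only value
B₂ˢᵗ = (V/2)·(clash fraction) needs no separate scan.  V_st ≡ B₂ˢᵗ/4.
Conversion to the per-mass convention multiplies by 10⁻²⁴·N_A/M².

The orientation covering is the product of a Fibonacci lattice of frame
z-axes (4π/res² points, poles included so the identity is a member) with
a uniform ring of in-plane spins (2π/res points): at 6° this gives
1146 × 60 = 68 760 rotations, and the count scales as res⁻³.  The
covering-radius and doubling-robustness contracts, not any particular
matrix list, define correctness.

FMAPB23 averages B₂ arithmetically over all n × n ordered (central,
test) pairs from a structure library sharing one sequence.  Group
contrasts use Welch's unequal-variance t-test (degenerate zero-variance
groups are handled by the exact limit).

## Pose and sequence analyses

Ligand-RMSD between two placements of the test molecule (central copy
fixed) drives greedy clustering: the lowest-energy unassigned pose seeds
a cluster and absorbs every unassigned pose within the 10 Å cutoff, with
no later stealing; ties in energy are broken lexicographically by
position then orientation, making clustering deterministic.  Clusters of
≥ 20 members are flagged "large".  Residue profiles decompose each
pose's energy into per-residue contributions of the test molecule
against the whole central copy and (for homotypic pairs) the reverse,
averaging first over poses and then over the two directions; profile
differences between two proteins are flagged beyond mean ± 3 SD, with
gap-aligned positions contributing zero.  Site–site distance
distributions measure a named residue's sidechain-centroid separation
across poses, optionally weighted by the normalised Mayer function.

The Grantham machinery regenerates the 20 × 20 distance matrix from the
1974 composition/polarity/volume properties (α = 1.833, β = 0.1018,
γ = 0.000399, scale 50.723); a few published entries (e.g. C–W, printed
215 versus the formula's 214.36) differ by one unit from the regenerated
rounding.  The residual inter-group distance at an alignment column is
the inter-group mean minus the larger intra-group mean; pairs touching a
gap are dropped, and a column where more than half the inter-group pairs
are dropped is zeroed and marked gap-dominated (the stated rule for a
single known position, generalised as package policy).  Flags use
mean + 3 SD over columns.

## Synthetic data and what the tests show

The toy generator produces three deterministic molecules: a single
sphere (σ, ε, q free), a charged dumbbell (±q, two residues — the
smallest molecule with a dipole and a decomposable structure) and a
four-atom/two-residue tetramer.  They emulate the *mechanics* of the
pipeline — hard cores, attraction wells, screened charges, residue
structure — at sizes where brute-force enumeration, closed forms and
radial quadrature are available as independent oracles.  They do not
emulate protein-scale features: thousands of shallow heterogeneous atom
pairs, anisotropic charge patterns, or the 10¹⁴-sample statistics that
make the production tail model necessary.  Passing tests therefore
demonstrate correctness of the machinery and its internal consistency,
not the accuracy of s₁/s₂ for any particular protein.

Problem sizes in the test suite and acceptance script were chosen so
each check isolates one contract: oracle equivalence on ≤ 32³ lattices
with atoms on lattice points (where FFT and direct sums must agree to
rounding), hard-sphere excluded volume with a 16-voxel contact radius
(ball-counting error ~0.5%), two-molecule boxes with 15 000 sweeps for
g(r) (~2% counting noise at the contact peak), 512 × 400 samples for
tail recovery, and eight concentrations of an attraction-dominated
sphere for the dual-route virial comparison.

## Known limitations

* Rigid molecules only; no conformational response beyond the FMAPB23
  library average.
* Trilinear rasterisation biases deep, narrow attraction wells at coarse
  spacing (quantified above); production use should keep spacing well
  below the smallest contact distance.
* The Metropolis sampler uses the same pair energy as the insertion
  scan.  A sampler with a different (e.g. solvation-augmented) energy
  would shift μ_ex at high density; the package makes the two consistent
  by construction and does not model that difference.
* The loess replica matches R's loess in spirit (tricube, degree 1,
  span 0.75) but not bit-for-bit.
* T_c is a bracket midpoint, with resolution set by the temperature grid.
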
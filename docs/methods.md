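# Methods

## Slow feature analysis

Given a J-dimensional time series C(t), SFA seeks output signals
y_k(t) = g_k(c(t)) minimizing the slowness Δy_k = ⟨ẏ_k²⟩ subject to
⟨y_k⟩ = 0, ⟨y_k²⟩ = 1, and ⟨y_k y_k'⟩ = 0 for k ≠ k'. The implementation
is the classical closed-form solution:

1. **Normalization.** Each column is centred and scaled to unit
   *population* variance; ⟨·⟩ throughout means the temporal average over
   all frames of all segments, normalized by 1/T, not 1/(T−1). This choice
   is deliberate: it makes the training-data identities (unit variance,
   Δy_k = λ_k) hold to machine precision and keeps the direct
   generalized-eigenproblem cross-check exact.
2. **Expansion.** Order 1 is the identity (linear SFA, the mode intended
   for dihedral features); order 2 appends all degree-2 monomials
   including mixed terms, in the documented order c₁…c_J, c₁c₁, c₁c₂, …,
   c_Jc_J. No higher orders: quadratic expansion already scales as O(J²)
   columns.
3. **Whitening.** z = S(Z − ⟨Z⟩) with S = D^(−1/2)Uᵀ from the
   eigendecomposition of the covariance of the (expanded) signal.
   Principal components with eigenvalue below 1e-10 of the largest are
   discarded: near-null directions explode under D^(−1/2) and would
   contaminate the slowest features with numerical noise.
4. **Slow directions.** Forward differences of z are taken *within* each
   independent trajectory segment only; a difference across a segment
   boundary would inject a spurious fast jump between unrelated
   trajectories. The raw (uncentred) second moment of the differences is
   diagonalized and the eigenvectors of smallest eigenvalue kept,
   ascending. Differences of a stationary series are near zero-mean, so
   centring this moment would change nothing material, but the raw moment
   is what makes Δy_k = λ_k an exact identity.

There is no lag-time parameter anywhere — this is the structural
difference from tICA, and removing that hyper-parameter is precisely why
SFA is attractive for CV discovery.

### Conventions and edge cases

- **Sign.** Slow features are sign-indeterminate; each weight vector is
  flipped so its largest-magnitude pulled-back input coefficient is
  positive, making fitted models and emitted files deterministic.
- **Degenerate eigenvalues.** The eigensolver's order is kept and
  stabilized by original index; under ties the contract is the spanned
  subspace, not individual vectors.
- **Constant columns** (e.g. the sin of an angle pinned at 0) are dropped
  with a logged warning rather than failing the fit; the model records
  them so that transform() accepts inputs that still carry them.
- **Feature matching** in transform() is by name, never by position.

## Dihedral featurization

Dihedrals use the IUPAC signed convention computed from the two plane
normals with a two-argument arctangent: cis = 0, trans = π, range (−π, π]
(the branch point −π is folded onto +π). The convention is cross-checked
in the tests against an independent implementation (mdtraj). χ1 is
N–CA–CB–G and χ2 is CA–CB–G–D with the conventional heavy atom per residue
type; a residue lacking a requested angle raises an explicit error instead
of being silently skipped. Angles are expanded to interleaved
sin/cos pairs, which removes the branch cut before SFA sees the data.
Coordinates are stored in nm and times in ps, matching PLUMED.

## PLUMED export

An order-1 model over sin/cos torsion features is exactly affine in
sin/cos of the underlying torsions, so each slow feature is emitted as one
CUSTOM action over TORSION actions (1-based atom serials), with the
offset folding the feature means, scales, and expansion mean. The central
correctness property — CVSpec evaluation equals transform() on arbitrary
frames — is asserted at 1e-6. The CUSTOM combination is declared
PERIODIC=NO: a sum of sines and cosines with an offset is aperiodic by
construction. All numeric fields use a fixed 9-significant-digit format so
identical inputs yield identical bytes (golden-file testing).

The METAD action carries the default well-tempered parameterization:
height 1.50 kJ/mol, pace 500 steps, bias factor 20, 300 K, and per-CV
widths from the heuristic width_k = std(y_k over first 10 000 training
frames)/3 (with a warning when fewer frames exist).

The funnel restraint is hand-built from PLUMED primitives: the
ligand-COM displacement from the anchor COM is split into an axial
component z (funnel axis along the box z axis, which presumes the usual
orientational fitting of the protein) and a radial component ρ, and a
harmonic upper wall (κ = 50 000 kJ/mol/nm²) penalizes ρ beyond
R(z) = R_cyl + step(Z_cc − z)(Z_cc − z)tan(α), i.e. a cone of half-angle
α = 0.5 rad switching to a cylinder of radius 0.1 nm at Z_cc = 2.0 nm.

## Tiwary–Parrinello reweighting

The reweighting factor is evaluated at every hill-deposition time as

c(t) = (1/β) ln [ Σ_s exp(βγ/(γ−1) V(s,t)) / Σ_s exp(β/(γ−1) V(s,t)) ]

with V the accumulated bias tabulated incrementally on a CV grid
(default 100 bins per dimension, covering the hill centers padded by
3 max widths; a 10× finer grid changes c(t) by < 0.01 kJ/mol in the
tests). Both sums use log-sum-exp. Between depositions c(t) is
stepwise-constant (right-continuous): the bias only changes at
depositions. Frame weights are w_t ∝ exp(β(V(s_t,t) − c(t))), normalized
to one; V(s_t,t) is taken from the COLVAR bias column as recorded.

**HILLS height convention.** Heights in a HILLS file are taken as the
actual deposited (already tempered) heights — the PLUMED convention. A
`heights='scaled'` flag rescales by (γ−1)/γ for dialects that store the
un-tempered height instead. This is the single most dangerous silent
corruption point in metadynamics post-processing, hence an explicit flag
rather than a guess.

Free-energy surfaces are F(bin) = −kT ln(Σ weights in bin), min-shifted
to zero over occupied bins; empty bins carry an explicit flag rather than
+∞ or a cap. Energies are kJ/mol with kT from the molar gas constant at
the given temperature (default 300 K); passing `kt=` directly overrides
this, which the reduced-unit toy engine uses.

## Toy engine: what it emulates and what it does not

`toysim` works in reduced units (kT = 1); the unit boundary to kJ/mol sits
exactly at the PLUMED I/O and reweighting layers and is covered by tests.

- **Canonical SFA signal** x₁ = sin t + cos² 11t, x₂ = cos 11t: the slow
  driver sin t is invisible to any linear readout but equals x₁ − x₂²
  exactly, so quadratic SFA must recover it (asserted at |corr| ≥ 0.99
  with n = 5 000).
- **Two-state dihedral**: a symmetric telegraph process (default flip
  probability 0.005/frame, T = 100 000, Gaussian jitter σ = 0.1 rad)
  between wells at −π/3 and +2π/3, plus 9 fast angles of i.i.d. wrapped
  noise. Telegraph-plus-jitter was chosen over Langevin on a periodic
  double well because the flip rate is then exactly known, enabling
  binomial count tests. The defaults emulate a rare aromatic side-chain
  flip buried among fast degrees of freedom — rare enough to be clearly
  the slowest process, frequent enough (~500 flips) for stable statistics.
- **Langevin**: overdamped Euler–Maruyama, x ← x − ∇U dt/γ_f + √(2 dt/γ_f) ξ.
  Chosen over BAOAB because it is adequate for overdamped toy potentials
  and trivially auditable; its O(dt) discretization bias is why the
  equipartition test tolerates 5%.
- **Toy well-tempered metadynamics**: deposited height
  h·exp(−V(s,t)/((γ−1)kT)) every `pace` steps; bias force through the CV
  gradients; records COLVAR (time, CVs, instantaneous bias) and HILLS
  (actual deposited heights) in the exact dialect the parsers read.

What the toy engine does **not** emulate: real solvated-protein
energetics, anisotropic diffusion, CV discretization error from finite
atom counts, or multi-walker schemes. Passing the end-to-end tests shows
the *estimators* are correct, not that any particular protein system is
converged.

## Problem sizes and numerical checks

The validation suite uses desk-scale problem sizes chosen to keep every
statistical assertion comfortably powered: T = 100 000 frames for the flip
fixture and the lag-1 autocorrelation identity (λ_k ≈ 2(1 − ρ_k),
asserted at 1e-3); T = 10 000, J = 12 for the five-dataset
generalized-eigenproblem cross-check (eigenvalues at 1e-8 relative,
subspace angles below 1e-6 rad); 100 000 Langevin/metadynamics steps
(200 hills, γ = 10, height 0.5 kT, width 0.3) for the end-to-end
double-well recovery, asserted within 0.5 kT over the wells and barrier
(|x| ≤ 1.5; the steep tails are sparsely sampled and dominated by
histogram noise).

The c(t) trace of the toy run is asserted non-decreasing within 0.01 kT —
the grid estimator can wiggle by ~1e-3 kT when a hill lands at the edge
of the padded grid — and its late-time increments must fall below half
the early-time increments, the approach to the asymptotic plateau expected
of a converging well-tempered run.

## Known limitations

- PLUMED export requires an order-1 model over pure sin/cos torsion
  features; order-2 models are fit- and transform-capable but not
  exportable (an explicit error), since a quadratic monomial of
  normalized features has no compact PLUMED expression.
- The funnel block assumes the funnel axis is aligned with the box z axis
  after fitting; systems with a tumbling solute need an orientation
  restraint or an axis defined by three anchor points.
- The reweighting estimator assumes well-tempered hills and a quasi-static
  bias between depositions; it is not an estimator for transition rates.
- `read_trajectory` trusts the file's frame spacing when present and
  falls back to 1 ps otherwise; pass `dt` explicitly for formats that
  carry no time information.
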
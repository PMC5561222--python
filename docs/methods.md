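# Methods

This note records the models, conventions, and numerical choices behind
`trxss`, in the spirit of the methods documentation of packages like
msprime or statsmodels: what is computed, under which assumptions, with
which defaults, and what the synthetic benchmarks do and do not show.

## Sequential two-state kinetic decomposition

Difference scattering ΔI(q, t) is modelled as two time-independent basis
spectra mixed by sequentially populated states: an intermediate rising
with time constant τ₁ that converts into a final state with time
constant τ₂,

    C₁(t) = τ₂/(τ₁−τ₂) (e^(−t/τ₁) − e^(−t/τ₂)),
    C₂(t) = 1 + (τ₂ e^(−t/τ₂) − τ₁ e^(−t/τ₁))/(τ₁−τ₂).

Both concentrations lie in [0, 1] for τ₁ < τ₂ and satisfy the balance
C₁ + C₂ = 1 − e^(−t/τ₁) exactly; the test suite asserts both on dense
time grids.  τ₁ = τ₂ makes the shared denominator vanish; the model
constructor rejects it and instructs the caller to perturb one constant
(the analytic limit is deliberately not implemented).

Fitting is by **variable projection**.  For a trial (τ₁, τ₂) the
concentration matrix C is fixed, and the basis matrix solves the linear
least-squares problem row by row.  Because the per-q solve decouples
across rows, any positive per-row weight cancels from the basis
solution; the q weight of the model equation q·ΔI = BS·C therefore
enters only the scalar objective ‖diag(q)(ΔI − BS·C)‖ used to rank
(τ₁, τ₂).  Basis spectra are stored and returned in ΔI units, so a fit
to noise-free synthetic data reconstructs the input exactly.

(τ₁, τ₂) are searched on a log₁₀ scale — default bounds 10⁻⁷–10⁻³ s and
10⁻³–10 s, a 25 × 25 coarse grid, then Nelder–Mead refinement (xatol
10⁻⁸ on log₁₀ τ).  The procedure is deterministic.  A fit whose both
constants end on their bounds is flagged non-converged.  The
photoexcitation turnover is absorbed into the basis amplitudes: from
difference data alone it is not separately identifiable, and recovered
basis spectra equal truth × turnover.

Optional preprocessing approximates each delay's curve by a degree-40
polynomial in q (Chebyshev basis on the mapped interval [−1, 1] for
conditioning), a low-pass filter matched to the information content of
solution scattering curves.  Smoothing is applied along q, per delay;
the default fit uses raw data and exposes smoothing as a choice.

The flash-photolysis companion fit A e^(−t/τ) + B uses bounded
Levenberg–Marquardt with τ's asymptotic standard error from the
covariance; non-decaying traces (τ at a bound, or vanishing amplitude)
are flagged rather than reported.

## Coarse-grained scattering model

Theoretical curves are exact Debye double sums over one-site-per-residue
structures, I(q) = Σᵢⱼ fᵢ(q) fⱼ(q) sin(q rᵢⱼ)/(q rᵢⱼ), with the i = j and
q = 0 limits taken analytically, evaluated on 101 points over
0–1 Å⁻¹ by default.  The q = 0 endpoint is included for convenience;
I(0) = (Σ fᵢ(0))² exactly.  Form factors are effective per-class
amplitudes with an optional single-Gaussian decay; the default is a
uniform constant amplitude.  There is no hydration shell, excluded
volume, or hydrogen treatment: the pipeline needs internal consistency
between the generator and the fitter, not absolute agreement with
all-atom predictors, and the same calculator is used on both sides of
every comparison.  Flexible residues 1–10 of each chain (and, by name,
purification-tag residues) are trimmed before scattering is computed so
that disordered termini do not dominate the fit.

Polychromatic ("pink-beam") smearing uses the linearity of q in photon
energy at fixed angle: I_poly(q) = Σₖ wₖ I_mono(q Eₖ/E_nom), with linear
interpolation on the monochromatic grid, constant extrapolation at the
ends, and E_nom defaulting to the spectrum's weight maximum.  Energy and
wavelength conversions use E·λ = 12.398 keV·Å.

## Ensemble pair fitting

Each dark × light candidate pair yields ΔI_theory = turnover ×
(I_light − I_dark), restricted to the fit range 0.06–1.0 Å⁻¹, and is
scored with R = Σ|ΔI_exp − c ΔI_theory| / Σ|ΔI_exp|.  The square root of
a square is an absolute value, so the score is L1; an L2 variant exists
behind a config flag for comparison but is not the default.  R(c) is
convex piecewise linear; the constrained minimizer is computed exactly
as the lower weighted median of the breakpoints ΔI_exp/ΔI_theory with
weights |ΔI_theory|, clipped to the bounds 0.35 ≤ c ≤ 1.6.  When the
minimizing set is an interval the smallest admissible c is returned, a
deterministic tie-break the tests rely on.  The bounds encode the
~70–75% excitation turnover: c is a bounded correction around a nominal
scale established by `initial_scale` (least squares between absolute
curves).  Ranking is ascending in R with ties broken by (dark index,
light index); the 100 lowest-R pairs are accepted.  Member intensities
are computed once per ensemble (|dark| + |light| Debye sums, not
|dark| × |light|), so peak memory does not grow with the number of
pairs.

## Geometry descriptors

* **Superposition** is the proper-rotation (det +1) Kabsch solution;
  mirror images keep a positive residual by construction.
* **χ** is the angle at the hinge centroid (residues 146–156) subtended
  by the LOV (11–127) and linker/DHp (170–200) Cα centroids, pooling
  both chains per range; centres of mass are unweighted Cα centroids
  (equal masses).  Note a consequence: for an exactly C2-symmetric
  dimer all pooled centroids lie on the symmetry axis and χ = 180°, so
  only deviations from symmetry register.  A per-chain variant can be
  built by passing custom ranges.
* **ψ** is the standard signed dihedral of the four centres of mass
  LOV(A), LOV(B), CA(A), CA(B) with CA-domain range 224–377, in
  (−180°, 180°].  The sign convention — positive Δψ = left-handed
  rotation of the kinase pair viewed from the sensor side — is fixed by
  a constructed-rotation test.
* **Displacement fields** average per-pair displacement vectors (after
  LOV alignment) and report the magnitude of the mean vector, with the
  mean of magnitudes as a secondary column.
* **Double distance difference** D(state_b) − D(state_a): the dark-state
  term cancels algebraically, and the implementation asserts this by
  accepting (and ignoring the coordinates of) the dark structure, which
  still anchors the residue bookkeeping.

## Synthetic data: what it emulates, and what it does not

The generator replaces the beamline data and the restrained-MD conformer
pools with a controlled, fully reproducible stand-in:

* **Toy dimer.**  A two-chain Cα model (default 385 residues per chain,
  domain splits at 127/200/223) with globular sensor and CA-domain
  blobs, an ascending/descending coiled helix pair, and chain B equal to
  chain A rotated 180° about z — so the dimer centroid lies exactly on
  the symmetry axis.  Blob residues are uniform random points in a
  ball: realistic at scattering resolution, meaningless as a fold.  The
  CA blob is offset 60° azimuthally so the base ψ (~114°) sits far from
  the dihedral branch cut.
* **Conformer pools.**  Dark members carry supercoiling rotations
  d_psi ~ N(0, 1.5°), light members N(11°, 1.5°), plus 0.3 Å i.i.d.
  coordinate jitter on all sites — mirroring the two restrained pools of
  dark- and light-locked trajectories at 200 + 200 instead of
  45,000 + 45,000 members.  The rotation is applied about the dimer z
  axis with the angle solved (Brent bisection, xtol 10⁻¹²) so that the
  ψ descriptor changes by exactly the requested amount; the four-point
  dihedral is not numerically identical to the raw rotation angle, and
  pinning the descriptor makes cross-module recovery tests exact to
  10⁻⁶ degrees.
* **Truth construction.**  The intermediate state is an 11° rotation
  plus a 2° bend; the final state a 12° rotation, the same bend, and an
  internal reorientation of one CA domain about its own centroid (8°),
  which changes the basis-curve shape without a net domain translation —
  mirroring the observed sequence of supercoiling followed by internal
  kinase rearrangement, with comparable basis amplitudes.  Defaults:
  τ₁ = 2 μs, τ₂ = 250 ms, turnover 0.7.
* **Dataset.**  ΔI(:, t) = turnover [C₁ BS_int + C₂ BS_fin] +
  heating_amp · h(t) · h_ref + noise, with h(t) = 1 − e^(−t/τ₁) (heat
  deposited with the photochemistry) and i.i.d. Gaussian noise scaled to
  2% of the peak protein signal by default.  The heating reference is a
  smooth bump supported on 1.4–2.4 Å⁻¹ peaking at 1.9 Å⁻¹.  The
  heating amplitude is a free knob (default 5% of the protein signal in
  the full pipeline): the experimental effect was small but the
  subtraction path must be exercised.
* **Scale separation.**  When the q grid extends past ~1.3 Å⁻¹ the
  protein basis curves are windowed smoothly to zero by 1.45 Å⁻¹.  This
  encodes the empirical fact the reduction design depends on — above
  ~1.5 Å⁻¹ the measured difference signal is essentially all solvent —
  and makes heating subtraction exactly well-posed in the synthetic
  world (noise-free reduction reproduces the protein-only signal to
  10⁻¹⁰).

What passing tests therefore show: the estimators are unbiased and
stable under the stated noise model, the search recovers planted ground
truth, and all bookkeeping (grids, residue keys, seeds) is exact.  What
they do not show: robustness to correlated detector noise, imperfect
heating references, beam-damage drifts, absolute-scale calibration, or
conformer pools that do not contain the true structures — real-data
concerns that the synthetic model deliberately idealizes away.  Noise
is i.i.d. per (q, t) point; replicate-level correlations are out of
scope.

## Reduction conventions

Normalization divides by the mean intensity over 1.4–1.6 Å⁻¹, the band
around the water-scattering isosbestic point (matching a water reference
value instead is config-selectable).  Outlier rejection is a single
pass, per delay: a curve's statistic is the band mean of its absolute
(3σ rule, 1.7–2.0 Å⁻¹) or relative (5% rule, 1.7–2.2 Å⁻¹) pointwise
deviation from the across-curve median curve, with σ the population
standard deviation of that statistic across curves.  Whether the
original procedure's σ was per q-point or per band is not recorded
anywhere we could find; the band convention is order-free and is the
documented choice here.  Averaging records the per-point standard error
when a delay retains at least two replicates.  Heating subtraction fits
the scale per delay by closed-form least squares on 1.5–2.2 Å⁻¹ and is
idempotent to noise level.

## Pipeline and reproducibility

The `trxss run` driver executes simulate → reduce → fit-kinetics →
fit-ensemble → geometry from one TOML config.  A master seed derives
per-stage seeds by SHA-256 hashing of the stage name (stable across
runs and platforms, < 2³¹), so stages can be re-run in isolation and a
rerun of the same config is byte-identical.  The ensemble stage fits
both recovered basis spectra (intermediate and final) as targets,
reusing one set of member curves; which experimental curve served as
the fitting target for each state is not recorded in the source
analysis, so the driver makes the recovered basis spectra its explicit,
documented choice.  Missing optional stages are skipped with a logged
notice; any stage failure aborts with the stage name.

## Problem sizes of the shipped benchmarks

The recovery experiments run at desk scale by design: 25 delays, 101 q
points, 20 noise seeds for kinetic recovery; 200 × 200 member pools
(40,000 scored pairs, 100 accepted) with ~750-site structures for the
planted-pair search.  These sizes exercise every code path, including
chunked pair scoring, while keeping a full run in minutes on a single
core; the chunking contract means larger pools change runtime, not
memory.

## Known limitations

* The toy dimer is a scattering-level caricature; χ/ψ values on real
  structures depend on author residue numbering matching the default
  ranges (configurable).
* The τ₁ → τ₂ degenerate limit of the kinetic model is not implemented.
* The Debye calculator is exact but O(N² n_q); it is meant for
  Cα-level models, not all-atom systems.
* mmCIF input, multi-model NMR ensembles (beyond model 1), and absolute
  intensity calibration are unsupported.
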
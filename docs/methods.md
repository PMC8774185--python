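# Methods

`bundlesans` analyses one-dimensional small-angle neutron scattering (SANS)
curves of dilute protein solutions, with a focus on the solution states a
four-α-helix bundle protein passes through on its unfolding pathway: the
compactly folded (dimeric) bundle, partially dissociated mixtures, the
"open-bundle" intermediate in which the helices keep their rod shape but
lose inter-helix packing, and the fully unfolded random coil.  This note
records the models, the defaults that matter, the numerical choices, and
what the synthetic-data tests do and do not establish.

## Scattering curves and conventions

A curve is (Q, I(Q), σ(Q)) with Q in Å⁻¹ and intensity in arbitrary but
consistent units (cm⁻¹ for absolute-scale data).  All analyses are
scale-covariant, so absolute calibration is never required.  Negative
intensities are legal (background-subtracted data) and are only masked
where logarithms are taken.  A curve whose maximum Q exceeds 5 Å⁻¹
triggers a nm⁻¹-input warning but is never silently converted.

## Model-free estimators

**Guinier.** Weighted linear regression of ln I on Q² over a user window
(default 0.001–0.002 Å⁻², the narrow window conventional for folded
proteins measured to Q ≈ 0.03–0.05 Å⁻¹); Rg = √(−3·slope),
I(0) = exp(intercept), errors from the regression covariance scaled by the
residual variance.  Exceeding Q·Rg = 1.3 at the window edge sets a warning
flag rather than failing, because unfolded states are conventionally fit
beyond the guideline.  Note the Guinier approximation itself carries a
truncation bias for compact particles: for a uniform sphere the fitted Rg
is high by ≈1.1% with the window edge at Q·Rg = 1.0, ≈0.9% at 0.9 and
≈0.3% at 0.6.  Tests that assert sub-0.1 Å agreement therefore use a deep
window (edge ≤ 0.6); this is a property of the estimator, not of its
implementation.

**Debye coil fit.** I(Q) = I(0)·D(u), D = 2(e^{−u} + u − 1)/u²,
u = (Q·Rg)², by weighted nonlinear least squares with a series expansion
below u = 10⁻⁴.  Auto-initialization from a Guinier pass, with a restart
grid {5, 10, 20, 40, 80} Å on failure.

**Kratky classification.** y = Q²·I(Q).  Features (all thresholds are
function parameters):

- *strict bell*: a local maximum of the Savitzky–Golay-smoothed transform
  below Q = 0.15 Å⁻¹ exceeding the high-Q median by ≥ 25% — the signature
  of a compact fold;
- *plateau*: relative drift of the smoothed transform over Q > 0.2 Å⁻¹
  within ±20% of flat **and** a level of at least 30% of the profile
  maximum.  The significance condition is ours: the flat incoherent floor
  under a folded particle's bell is an order of magnitude below the bell
  and does not indicate chain flexibility, whereas a coil's plateau *is*
  its maximum;
- *broad bell*: an interior global maximum (≤ 90% of the way to the last
  point) followed by a > 10% decline.  A Gaussian coil rises monotonically
  onto its plateau and never turns over; a chain of finite-radius rods
  peaks (possibly above 0.15 Å⁻¹) and then decays.  This feature is what
  separates an open bundle's "weaker, broader bell" from a true coil.

Classification: strict bell without plateau → `folded`; plateau with no
bell of either kind → `random_coil`; anything in between →
`partially_flexible`.

**Molecular-weight ratio.** At fixed contrast I(0) ∝ MW·C, so
MW/MW_st = [I(0)/C]/[I(0)_st/C_st].  Reported both at full precision and
half-up-rounded to one decimal (the convention of printed tables).

**Aggregate fraction.** Fits I(Q) = i0_m·e^{−Q²r_m²/3} + i0_a·e^{−Q²r_a²/3}
over Q ≤ 3/r_a with (r_m, i0_m) anchored near a supplied monomer fit and
r_a assumed (default 100 Å).  Per particle I(0) ∝ V², so the number ratio
is (i0_a/i0_m)·(r_m/r_a)⁶.  The monomer anchor must come from a window the
aggregate does not contaminate; with a V²-weighted 0.2% number fraction of
100 Å particles the aggregate dominates I(0) even though its signature at
the usable window edge is small.  The result echoes every assumption.

## Indirect Fourier transform

P(r) is expanded on a Moore sine basis, P(r) = Σ aₙ sin(nπr/Dmax), which
vanishes at r = 0 and r = Dmax by construction (default 20 modes,
trapezoid quadrature on 301 r-points).  The coefficients minimize
‖(I_obs − 4π∫P·sinc(Qr)dr)/σ‖² + α‖P″‖², solved through the stacked
(augmented-row) least-squares system — materially stabler than the normal
equations when modes beyond the data's resolution support are
unconstrained.  α is chosen at the maximum-curvature corner of the
L-curve over a 25-point log grid unless given.  Negative P(r) is permitted
but penalized by one reweighting pass, kept only when it does not degrade
the weighted χ² by more than 5%.  Rg, I(0) and their errors come from the
moments of P(r) and the posterior coefficient covariance
(Gauss–Markov sandwich, delta method for Rg).  I(0) is an extrapolation of
the basis representation, so a fit window starting at 0.05 Å⁻¹ still
yields I(0).  Dmax is a required user input; `scan_dmax` reports χ², Rg
and an oscillation/endpoint quality score per candidate and deliberately
makes no automatic choice — on coil-like data χ² decreases monotonically
with Dmax and only the elbow is meaningful.

## Theoretical curves from coordinates

The orientationally averaged intensity of a rigid structure is the Debye
double sum I(Q) = Σᵢⱼ fᵢfⱼ·sinc(Q·rᵢⱼ) with excess amplitudes
fᵢ = bᵢ − ρ_solv·Vᵢ.  Coherent scattering lengths are the standard Sears
values; displaced volumes are CRYSOL-style atomic group volumes; the
solvent scattering length density follows from the D₂O volume fraction
(0.638 fm/Å³ for pure D₂O at 30 Å³ per water).  Hydrogens missing from
crystal structures are folded into their parent heavy atoms (united-atom
scheme) via a per-residue, per-atom table of implicit H counts; hydrogens
on N, O and S are labile and exchange to deuterium with probability
`exchange_fraction` (default 0.9) times the D₂O fraction, applied in the
mean-field sense.  Unknown residues (heme, ligands) fall back to one
implicit H per carbon — adequate for a prosthetic group that contributes a
few percent of the total scattering length.  No hydration-shell term is
included; by CRYSON experience this shifts protein Rg by ≲ 0.5 Å.

The O(N²) direct sum is exact; the default distance-histogram route bins
pair distances at 0.1 Å and uses the weight-averaged distance per bin,
which agrees with the direct sum to ≲ 10⁻⁴ relative at protein scale.

**Helix geometry.** A helix's axis is the dominant eigenvector of its
C-alpha coordinate covariance; its length is the peak-to-peak extent of
the C-alpha projections onto the axis (≥ 4 C-alphas required).  Its
diameter is twice the RMS radial distance of the backbone atoms
(N, CA, C, O) from the axis.  These conventions are validated on generated
ideal helices (1.5 Å rise, 2.3 Å C-alpha radius, 100°/residue).

## The joint-clubs model

The open bundle is modeled as `n_clubs` rigid cylinders of length L and
**diameter** R (the single most consequential convention: R is a diameter,
matching how helix diameters (~10 Å) are quoted; the cylinder radius used
internally is R/2), joined end to end.  Consecutive clubs are separated by
`loop_gap` (default 5 Å — the inter-helix loops are a few residues) along
the next club's axis.  Joint orientations are uniform on the sphere with a
fold-back rejection: consecutive axes may not bend beyond 150°.  This
uniform-with-rejection joint distribution is an explicit, documented
approximation; an angle-constrained kernel can replace it behind the same
signature.

The measured intensity is scale·⟨|Σₖ A_cyl(Q; uₖ)e^{iQ·cₖ}|²⟩/n² + bkg,
with A_cyl the standard cylinder amplitude (axial sinc × radial 2J₁(x)/x).
The ensemble average is Monte Carlo over conformations; because every
conformation is built in an isotropically random global orientation, the
orientational average comes along for free, and a fixed 16-direction
Fibonacci set per conformation only reduces variance.  Defaults: 2 000
conformations for fitting, 20 000 for final curves.  Everything is driven
by one seed, so curves are bit-reproducible; the fit draws its ensemble
once and reuses it at every objective evaluation (common random numbers),
making the optimization deterministic.  Fitting floats (L, R, scale,
background) with n_clubs and loop_gap fixed; errors come from the Jacobian
at the optimum inflated by √(reduced χ²); a 3×3 (L, R) start grid backs up
the caller's initialization.  Checks: n = 1 agrees with the classical
quadrature cylinder form factor to < 1%; a long thin club follows the
Neugebauer rod form factor to < 3%; the noiseless n = 4 curve at
L = 31.5 Å, R = 10.6 Å has Guinier Rg ≈ 26 Å — the size jump from the
~18 Å compact bundle that motivates the model.

## Synthetic data: the stated world

Generators produce exact model curves (sphere, Gaussian coil, cylinder,
joint-clubs, atomistic Debye sum, two-population Guinier mixture) on a
default grid of 0.01–0.4 Å⁻¹ (the usable measurement window plus Guinier
and Kratky coverage), then add Gaussian noise with
σ(Q) = I·(floor + k/√(I·t_eff)), floor = 1%, k = 0.0013 — chosen so σ/I
reaches ≈3% at Q = 0.25 Å⁻¹ on curves with I(0) ≈ 0.1, matching the error
bars of reduced SANS data on ~5 mg/mL protein.  Ground truth travels as a
returned record or a sidecar JSON, never in filenames.

The four-scenario suite emulates the pD series of the unfolding pathway:
a Gaussian-coil monomer (Rg 25 Å; the molecular-weight standard,
I(0) = 0.078 at 5.5 mg/mL), a compact globule dimer (Rg 18 Å, I(0)/C twice
the standard's), a 9:1 dimer:monomer forward-intensity mixture, and a
joint-clubs open bundle (n = 4, L = 31.5 Å, R = 10.6 Å).  The generators
emulate noise structure and the I(0)/C bookkeeping of real measurements;
they do **not** emulate instrument resolution smearing, inter-detector
merging artifacts, structure factor at finite concentration, or real
aggregation tails.  A green scenario test therefore establishes that the
estimators invert the stated models at realistic noise — not that every
systematic of beamline data is handled.

## State assignment

Per condition the pipeline runs Guinier, Kratky, P(r), a Debye and/or
joint-clubs fit, and the molecular-weight ratio against the designated
standard, then applies bands: ratio ≥ 1.7 with a folded Kratky class →
`folded_dimer`; ratio ≤ 1.3 with a coil class → `random_coil`; ratio ≤ 1.3
with `partially_flexible` and the joint-clubs fit beating the Debye fit →
`open_bundle_monomer`; anything else → `folded_mixed`.  The bands
discretize the observed clustering of I(0)/C ratios around 1 and 2 and are
parameters of `run_pipeline`.  Every assignment carries its evidence list;
reports are deterministic (sorted-key JSON) for a fixed config and seed.

## Known limitations

- No instrument smearing anywhere (model or data side).
- The united-atom hydrogen table covers the 20 amino acids; heme and other
  ligands use a generic per-element fallback.
- The joint-clubs joint distribution (uniform with a 150° fold-back
  cutoff) and the loop-gap placement along the incoming axis are modeling
  choices, not derived from chain statistics.
- `aggregate_fraction` assumes a single aggregate size and V²-per-particle
  forward scattering; it bounds, rather than measures, weak aggregation.
- Dmax selection is assisted, never automatic.
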
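# Methods

## Model and assumptions

The protein solution is treated as a one-component fluid of coarse-grained
protein particles; solvent, buffer and salt ions act only as modifiers of
the effective protein–protein interaction (a McMillan–Mayer picture). A
particle is a hard sphere of diameter σ with M equivalent attractive sites
on its surface (distance d = σ/2 from the centre). Two sites on different
particles interact through a square well of depth ε and range ω, and each
site may bond at most once. The model deliberately ignores charge
anisotropy, site-placement geometry, explicit electrostatics, solubility /
crystallization lines and any aggregation pathway beyond reversible
association (no amyloid formation).

The Helmholtz free energy is the TPT1 sum

    βA/N = [ln(ρΛ³) − 1] + η(4−3η)/(1−η)² + M(ln X − X/2 + 1/2),

with Carnahan–Starling for the hard-sphere excess and the Wertheim
association term. The unbonded-site fraction X solves X + MρΔX² = 1 in
closed form; the cancellation-free root X = 2/(1+√(1+4MρΔ)) is used so the
dilute branch (ρ as low as 10⁻⁶ nm⁻³) keeps full precision. The
association strength in the sticky limit is

    Δ = 4π g_hs(σ) ∫_σ^{σ+ω} f̄(r) r² dr
      = g_hs(σ) (e^{βε} − 1) π ω⁴ (15σ + 4ω) / (30σ²),

where f̄(r) = (e^{βε} − 1)(σ+ω−r)²(2ω+r−σ)/(6σ²r) is the orientation
average of the site-pair Mayer function for surface sites. This closed
form was derived independently from the two-point geometry (the
probability that two points, uniform on spheres of radius σ/2 with centres
a distance r apart, lie within ω of each other) and is verified in the
test suite against both adaptive quadrature and a brute-force Monte-Carlo
orientation average of the explicit pair potential.

Two deliberate inconsistencies of the antecedent coarse-grained model are
retained as-is: the hard-sphere free energy is Carnahan–Starling while the
contact value inside Δ is Percus–Yevick, and the thermal wavelength Λ is
fixed to 1 nm (it shifts βμ by a state-independent constant that cancels
in all coexistence conditions).

Buffer and salt effects enter only through the well depth,
ε(I) = ε₀ + a√I. The sign is chosen so that added NaBr (a > 0) deepens the
attraction and raises cloud points, the salting-out direction observed for
lysozyme. ε carries units of kelvin (ε/k_B) throughout; no joules appear
in the API.

## Reduced variables and solvers

ε is temperature independent, so every dimensionless state function
depends on (T, ε) only through y = ε/T. All phase solvers work in (η, y):

- **Pressure derivatives.** βΠ and its first two η-derivatives are coded
  analytically (hand-derived chain rules through X(η) and the PY contact
  value), and checked against central differences at the 10⁻¹⁰ level.
- **Critical point.** (y_c, η_c) is a pure function of geometry, found by
  a nested solve: η*(y) minimises ∂P/∂η (bounded minimisation polished by
  Newton on ∂²P/∂η² = 0), then Brent's method drives min_η ∂P/∂η to zero
  in y. Residuals are ~10⁻¹²; T_c(ε) = ε/y_c. For the packaged lysozyme
  geometry y_c = 8.6037 and η_c = 0.2058 (γ_c ≈ 231 mg/mL).
- **Coexistence.** Two-variable Newton (scipy `root`, hybr) on
  (ln η_dilute, η_dense) with equal-βΠ/equal-βμ residuals; the log
  variable conditions the very dilute branch. Seeds come from the
  spinodal bracket widened by the mean-field factor √3; on failure or
  collapse onto the trivial equal root, a 30 000-point lower-convex-hull
  common-tangent scan of βA/V re-seeds the solve. Accepted points have
  residuals below 10⁻¹¹ (typically 10⁻¹⁵).
- **Binodal curves.** Downward continuation from T_c(1−10⁻³) with
  geometrically growing temperature offsets to a configurable floor
  (default 0.8 T_c, 40 points); fully deterministic.
- **Cloud points.** T_cloud(γ; ε) = ε / y*(γ) where y*(γ) is the reduced
  temperature at which γ sits on the binodal (dilute branch left of the
  dome apex, dense branch right of it, T_c exactly at it). y* is found by
  Brent bracketing on the branch offset (tolerance 10⁻¹³ in y, orders of
  magnitude tighter than the 10⁻³ K contract) and cached per (model, γ).
  A 150 K floor guards against chasing states far below any aqueous
  relevance.
- **Calibration.** Because T_cloud is exactly proportional to ε, the
  depth reproducing an observed cloud point is ε = y*(γ)·T_obs — a
  closed-form inversion rather than an outer bisection; uniqueness follows
  from the same proportionality. Depths outside the physical bracket
  [500, 5000] K raise a diagnostic bracket error. Salt-coefficient fits
  regress ε against √I (weighted by inverse variance when cloud-point
  uncertainties are supplied, OLS otherwise) through statsmodels;
  measurement uncertainty propagates into ε as σ_ε = (ε/T)·σ_T.

The fit of a is performed in ε-space (pooling all (I, ε) pairs across
protein concentrations), matching the observation that neither ε₀ nor a
varies significantly with γ; a T-space loss was considered and rejected as
it weights points unequally for no physical reason while the
proportionality makes both formulations equivalent at small noise.

## Measurement reductions

Standard bench formulas, each behind a typed series container:

- Stokes–Einstein D = k_BT/(6πη₀R_h); water viscosities 1.5182 / 0.8900
  mPa s at 5 / 25 °C are the conventional reference values.
- k_D from D = D₀(1 + k_D γ) with γ in g/mL so k_D carries mL/g; the k_D
  standard error uses the delta method on the slope/intercept ratio.
- Static scattering: count rates normalised by laser intensity,
  referenced to toluene (R_θ = I_sam/I_tol · R_θ^tol, R_θ^tol =
  14.0×10⁻⁶ cm⁻¹), optical constant K = 4π²n₀²(dn/dc)²/(N_Aλ⁴) with
  defaults λ₀ = 632.8 nm, dn/dc = 0.185 mL/g and n₀ = 1.332 (aqueous
  buffer; configurable — the instrument value should be used when known).
  Debye fit Kc/R = 1/Mw + 2B22·c by OLS; a non-positive intercept is
  reported with a warning (Mw undefined) rather than rejected, since
  strongly attractive systems can produce one.
- Ostwald viscometry η = η₀(ρt)/(ρ₀t₀); Jones–Dole fit of
  η/η₀ − 1 on the basis {√c, c}; the electrostatic A coefficient may be
  pinned to a Debye–Hückel value instead of fitted.
- "Semidilute window" bounds for the k_D and Debye fits are configurable
  concentration windows; the default uses all supplied points and the
  window actually used is recorded in the fit result.

## Synthetic data

The generator produces every stream the pipeline consumes from stated
ground truth: cloud-point series from the TPT1 binodal itself with
ε(I) = ε₀ + a√I; DLS, Debye and Jones–Dole series from their exact model
curves. Noise is additive Gaussian on the measured ordinate — the simplest
model consistent with the symmetric uncertainties such measurements
report — with fixed numpy Generator seeds; identical inputs give
byte-identical output. Default grids mirror bench practice for lysozyme:
NaBr ionic strengths 0.1–0.5 M, DLS concentrations 4–70 mg/mL, Debye
concentrations 1–9 mg/mL, viscometry 0.02–0.1 M. The recovery study uses
σ_T = 0.2 K at six ionic strengths spanning 0.1–0.5 M with 200 replicates
per buffer — problem sizes at which the whole study runs in seconds.

What the generator does not emulate: instrument systematics (drift, stray
light, cuvette condensation), DLS polydispersity and correlogram
inversion, multiple scattering at high concentration, or metastability of
the cloud-point measurement (the generated T_cloud is the equilibrium
binodal crossing). Passing recovery tests therefore demonstrate estimator
correctness and statistical calibration, not robustness to such artefacts
in real data.

## Numerical choices and degenerate inputs

- Packing fractions ≥ 0.74 (close packing) are rejected at the unit
  bridge; the coexistence solvers cap the liquid branch at η = 0.68.
- Reduced temperatures are capped at y = 200 when searching for a branch
  crossing, safely below floating-point overflow of e^y; concentrations
  outside the dome at all reachable y raise a diagnostic error.
- Two-point linear fits report zero standard errors (exact
  interpolation) instead of the undefined zero-degrees-of-freedom value.
- Monte-Carlo validation of f̄ uses the standard error under the
  closed-form null, which stays valid at radii where the contact
  probability is so small that a sample-based error estimate would
  degenerate.
- All randomness flows through `numpy.random.default_rng(seed)`; there is
  no global-state seeding anywhere.

## Known limitations

- The association term is first-order TPT: ring structures, bond
  cooperativity and site–site correlation are absent; dome widths are
  therefore only qualitatively comparable to experiment.
- ε is temperature independent, making all cloud points exactly
  proportional to ε; any real enthalpy/entropy decomposition of the
  effective attraction is outside the model.
- Calibration quality is limited by the ε(I) = ε₀ + a√I form; systematic
  curvature in ε vs √I (e.g. at high salt) would bias both parameters.
- The packaged buffer parameters apply to HEWL at pH 7.0 in 0.1 M
  buffers; pH dependence is not modelled.
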
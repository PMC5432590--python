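# Methods

This note documents the models behind xylemkit, the choices made where the
field's practice is operator-judged or under-specified, and what the
synthetic validation does and does not demonstrate.

## Vulnerability curves

PLC observations are modelled with the two-parameter logistic
PLC(Ψs) = 100/(1 + exp(α(Ψs − PLC50))). The upper asymptote is fixed at
100% by default because the linearized treatment statistics
(ln(100/PLC − 1) = α(Ψs − PLC50)) are defined on that form; a free
asymptote is available (`free_max=True`) for datasets whose flushed maxima
are suspect. The midpoint slope is reported as 25·α %/MPa, the analytic
|dPLC/dΨs| at PLC50 of the fixed-asymptote sigmoid — the only slope
definition consistent with this parameterization.

Fitting is plain nonlinear least squares (`scipy.optimize.curve_fit`) with
deterministic, data-driven starting values: PLC50 starts at the Ψs of the
observation nearest 50% loss, α at 4/(Ψs range). Uncertainty comes from
case-resampling bootstrap (observations resampled with replacement,
seeded; 1000 replicates by default) with percentile intervals; the
asymptotic NLS covariance is used when no bootstrap is requested. Data
whose PLC never crosses 50%, or whose fitted curve is essentially flat
(|α| < 10⁻³ MPa⁻¹), are flagged `degenerate` rather than rejected.

Sign convention: Ψs is stored as negative MPa throughout; no magnitudes
are flipped anywhere.

### Treatment comparison

`compare_treatments` fits OLS on the linearized response with Ψs,
treatment, and their interaction, and reports the joint Wald test that all
treatment-involving coefficients vanish plus the interaction-only test.
Observations at PLC exactly 0 or 100 are excluded (and counted) because
the transform is undefined there; the nonlinear fit uses them as-is. The
logit-like transform makes the error variance diverge toward the PLC
bounds, so the Wald tests use the HC3 heteroscedasticity-robust covariance
by default; in simulation this holds the nominal 5% size (measured 5.0%
over 400 null replicates) where the classical F-test rejects ~13%.
Per-treatment (α, PLC50) are back-solved from each group's fitted line
y = aΨs + b as α = a, PLC50 = −b/a.

## Pressure–volume curves

The analysis works in the classical transformed plane x = 100 − RWC,
y = −1/Ψ, where the post-turgor-loss (osmotic) phase is a straight line.
Because the classical wet-end cutoff is operator-judged, the package uses
an explicit rule. Starting from the 4 driest transformable points, the
candidate line is extended one point toward the wet end at a time; the
incoming point is accepted while its prediction residual against the line
fitted on the points accepted so far stays within 2 standard errors of a
new observation (residual SD scaled by the extrapolation leverage
√(1 + 1/k + (x−x̄)²/Sxx); the ratio is exactly t-distributed under
linearity). The turgor kink lifts y far above the osmotic line relative to
its residual scale, so the rule stops at the break without any absolute
threshold. The leverage correction matters: testing against a bare
residual-SD multiple either lets high-leverage wet-end points drag the
line across the break (if they are included in the refit) or falsely
rejects ~18% of genuine osmotic points per step at 2 degrees of freedom
(if they are not), biasing the turgor loss point dry. A hard R² floor is
available (`r2_min`) but off by default: R² is scale-dependent, and under
realistic weighing noise a perfectly genuine osmotic line can sit near
R² ≈ 0.87, so a 0.99 gate would truncate every fit to its 4 driest points.

From the accepted line y = c₀ − c₁x: π100 = −1/c₀ (the line at RWC = 100);
the turgor loss point is the wettest accepted point *evaluated on the
line* (conservative and deterministic; not the first rejected point), with
RWC_TLP that point's RWC; the apoplastic fraction af comes from the x
intercept x* via af = 1 − x*/100 (the line reaches y = 0 at RWC = 100·af),
clamped at 0 when the extrapolated intercept is negative. Turgor pressure
P = Ψ − π (π from the osmotic line) over the points wetter than the TLP
gives ε as the single OLS slope of P against symplastic relative water
content R_s = (RWC/100 − af)/(1 − af) — a mean bulk modulus, not an
RWC-dependent one; with fewer than 3 turgor-phase points ε is reported
absent. Total-RWC ε is available via `symplastic_epsilon=False`.

Known limitation: fitting in y = −1/Ψ space weights wet-end points
heavily, which is standard practice and left uncorrected. Under noisy
weights the RWC covariate is itself noisy, so the ε slope suffers
regression dilution (≈8–10% low at 1% weight noise in simulation) even
though the zero-noise analysis is exact.

## Theoretical conductivity

k_t = (πρ/128η)·Σdᵢ⁴ with ρ = 1000 kg m⁻³, η = 10⁻⁹ MPa·s and d in
meters gives mass flow per pressure gradient (kg m s⁻¹ MPa⁻¹); dividing by
the molar mass of water (0.018015 kg mol⁻¹) and scaling to mmol yields
k_t in mmol m s⁻¹ MPa⁻¹. The whole unit chain is spelled out in the code
and cross-checked in the tests against an independent scalar-loop oracle
to 1e-12 relative error. k_ts = k_t/LA (leaf area in m²) is reported in
mmol m⁻¹ s⁻¹ MPa⁻¹ (some published tables print these units with the
pressure exponent flipped; the dimensional analysis here is fixed).
Vessel lumens measured as areas are converted through the
equivalent-circle diameter d = 2√(A/π); no ellipse handling. When only
half of a near-symmetric petiole section is digitized, counts and the d⁴
sum are doubled. Default diameter classes are 5 µm wide
(<10, 10–15, …, 25–30, ≥30 µm), user-overridable.

## Conductances and binning

k_leaf = E/(Ψs − Ψl) and k_plant = E/(Ψpd − Ψl), with E in
mmol m⁻² s⁻¹ and potentials in MPa, so k is leaf-area-specific in
mmol m⁻² s⁻¹ MPa⁻¹. Units are fixed, never inferred from headers.
Reversed gradients return signed values with a flag — exclusion is a
pipeline decision, never silent. PLC inputs with k_i > k_max (measurement
noise) clamp to 0 with a flag rather than rejecting the sample.

Ψs classes are contiguous half-open intervals (−(i+1)w, −i w] anchored at
0 MPa; the class width is a user parameter defaulting to 0.2 MPa (field
practice averages "similar" Ψs values without a stated width; the anchor
at 0 makes the classes reproducible).

## Synthetic data

Each generator is a deterministic map from (parameters, seed) to a
dataset, and attaches its ground truth, so zero-noise outputs are exact
fixed points of the corresponding analysis (tested for all four kinds).

* **VC**: Ψs uniform over a range (default −2.2 to −0.2 MPa, matching the
  span over which petiole embolism develops), PLC from the logistic plus
  additive Gaussian noise (default σ = 5 PLC points, a typical
  petiole-to-petiole scatter), clamped to [0, 100].
* **PV**: the minimal forward model consistent with the classical
  parameter set — Boyle–van't Hoff osmotic dilution π = π100/R_s and a
  linear turgor decline P = max(0, −π100 − ε(1 − R_s)) with constant ε,
  Ψ = P + π, on a descending RWC grid (default 15 points from 100 to
  72%, which places roughly half the points beyond turgor loss for
  grapevine-like parameter values). Multiplicative Gaussian noise (default
  1%) applies to weights and Ψ. Any richer model (e.g. RWC-dependent ε)
  would be unconstrained by the parameters it is meant to validate.
* **Daily course**: a half-sine transpiration profile (06:00–18:00);
  Ψl = Ψpd − E/k_plant and Ψs = Ψl + E/k_leaf. The noise parameter applies
  multiplicatively to the recorded E and to each water-potential *drop*
  (pre-dawn exact) — applying it to the potentials themselves would make
  the per-record gradient error many times the nominal noise level, since
  |Ψ| is much larger than the drops. gs is E over a fixed nominal
  mole-fraction VPD (default 0.015); no stomatal model is implied or
  needed for conductance recovery. A companion constructed scenario
  (`simulate_decline_course`) prescribes a sigmoidal k_leaf(Ψs) decline
  for the decoupling analysis.
* **Vessels**: log-normal diameters (a standard description of conduit
  size distributions), areas back-computed as circles; default spread
  log_sd = 0.3 (≈30% CV, typical of petiole xylem).

Presets "WW", "TD", "SD" carry literature-typical parameter values for
well-watered, transient-deficit and sustained-deficit acclimated
grapevines (e.g. WW: PLC50 = −1.31 MPa, α = 4.32 MPa⁻¹;
SD: π100 = −1.10 MPa, ε = 7.17 MPa). They are convenience parameter sets
for simulation, clearly not measured data.

### What the synthetic validation shows — and does not

Parameter recovery on these generators verifies the estimation machinery:
that the fits are unbiased (or how biased) at realistic noise, that the
closed forms invert each other, that bootstrap intervals are calibrated
(≈95% coverage measured over 200 replicates), and that the treatment test
holds its size. It does not validate the forward models against real
leaves: real PV curves have over-rehydration plateaus, real VC data have
shoot-level correlation and non-uniform Ψs designs, and real daily courses
have VPD structure none of which is simulated. Conclusions about the
instruments and plants still require real measurements.

## Pipeline

`run_study` executes every stage with configured input, fanning one
top-level seed out to the stages via `numpy.random.SeedSequence` (all
derived seeds < 2³¹), and writes plain CSV/JSON with the seed recorded.
The decoupling summary operationalizes the k_leaf-versus-embolism
comparison: binned k_leaf is converted to percent loss relative to the
mean of the wettest Ψs class (the default baseline; any other reference
value can be supplied), fitted with the same sigmoid machinery, and
the Ψs at 50% k_leaf loss is differenced against the fitted PLC50. A
positive gap means leaf conductance declines at wetter potentials than
petiole embolism — the constructed synthetic study demonstrates recovery
of a known gap within bootstrap confidence intervals.

## Problem sizes

Default validation sizes — 200 replicates for VC recovery, 100 for PV
recovery, 400 null / 200 power replicates for the comparison test,
200×400 for bootstrap coverage — were chosen as the smallest runs whose
Monte-Carlo error is comfortably below the tolerances being checked
(e.g. SE of a mean PLC50 over 200 replicates ≈ 0.004 MPa against a
±0.05 MPa band).
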
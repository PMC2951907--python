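# Methods note

## Model and assumptions

Both formulations describe the uniporter as a carrier that binds two Ca²⁺
ions on one membrane face, translocates the doubly loaded complex (net
charge +4), and releases them on the other face. Initial-uptake conditions
are assumed: fluxes are evaluated pointwise at fixed concentrations and
membrane potential, with no time integration, matrix buffering, or feedback
of uptake on ΔΨ. Concentrations are free-ion activities treated as
concentrations; the total uniporter density is absorbed into the rate
constants, giving fluxes in nmol·mg⁻¹·s⁻¹ of mitochondrial protein.

Shared flux expression (README has the formulas): a two-site saturable
numerator `k_in (ca_e/K_e)² − k_out (ca_x/K_x)²` over a saturation
denominator `D`. Model 1 assumes fully cooperative binding (quadratic terms
only); Model 2 adds the singly loaded states (linear terms) to `D`. The
numerator is identical between Model 1 and Model 2.

The generalized formulation's translocation factor Φ(φ̃; nH) = [u/sinh u]^nH
with u = 2φ̃/nH is even, strictly positive, equal to 1 at φ̃ = 0, and
smooth everywhere; nH = 1 recovers the constant-field (GHK) rate constants
for a charge +4 species exactly. The barrier formulation's voltage factor
is exponential in |φ̃| and therefore kinked at ΔΨ = 0; the package exposes
both (`e_factor`, `beta_effective`) for diagnostic comparison. Matching the
generalized rate constants to the barrier form gives effective
displacements β_e(φ̃) = 1/2 + ln Φ/(4φ̃), β_x = 1 − β_e, smooth through 0.

Detailed balance holds by construction in the generalized formulation and
is enforced in the barrier formulation by the kinetic constraint
k_in0·K_x0² = k_out0·K_e0² together with the thermodynamic constraint
α_e + α_x + β_e + β_x = 1; the net flux then vanishes exactly at the Nernst
concentration ratio ca_x/ca_e = e^{2φ̃} for any parameter values.

## Parameters

| parameter | units | meaning | packaged defaults |
|---|---|---|---|
| k0 (k_in0, k_out0) | nmol·mg⁻¹·s⁻¹ | zero-potential translocation rate constant(s) | e.g. 0.0142 (liver), 0.0159 (heart), 1.99 (liver ΔΨ preparation) |
| K0 (K_e0, K_x0) | molar | zero-potential Ca²⁺ binding constant(s) | e.g. 45.6 µM (liver), 87.6 µM (heart) |
| nH | — | shape of the nonlinear potential profile (generalized) | 2.65 |
| α (α_e, α_x) | — | binding-site displacement into the field, ≥ 0 | 0 |
| β_e, β_x | — | barrier displacements (barrier formulation), β_e + β_x + 2α = 1 | 0.113 / 0.887 |
| m | — | Case-2 internal-constant scale (non-identifiable family) | 1 |

Thermodynamic context: F = 96485 C/mol, R = 8.314 J/(mol·K), T = 298.15 K
(overridable via `ThermoContext`); φ̃ = FΔΨ/RT ≈ 7.396 at 190 mV. Packaged
parameter sets are the published estimates for each tissue preparation,
formulation, model variant and case; rate constants differ between the
liver Ca²⁺-titration and liver ΔΨ-titration preparations because uniporter
density differs between preparations.

## Synthetic protocol generator

`make_protocol` reproduces the three study designs used by the original
experiments, and these defaults are the package's study conditions:

* `heart_ca_titration`, `liver_ca_titration`: 20 log-spaced external Ca²⁺
  points, 1–150 µM, at ΔΨ = 190 mV;
* `liver_dpsi_titration`: 15 potentials, 60–190 mV, at external Ca²⁺
  0.5/1.0/1.5 µM (45 points);
* matrix free Ca²⁺ fixed at 250 nM throughout.

`generate_dataset` emulates initial-rate measurements as
`rate = J · (1 + cv·ε)` with ε i.i.d. standard normal from a seeded
generator and cv = 0.05 by default. It emulates multiplicative measurement
scatter only — it does not model systematic digitization error, probe
calibration drift, preparation-to-preparation variability, rundown within
a titration, or correlated errors, all of which affect the historical
datasets the designs are modeled on. Provenance (seed, cv, generating
parameters, protocol) is recorded in the dataset and its CSV header.

## Estimation

The objective is the normalized mean residual error

    E = (1/N_exp) Σ_exp (1/N_data) Σ_i [(J_i^data − J_i^model)/J_max]²

with J_max the maximum measured rate of each experiment (per-experiment by
default; a global J_max is available via `FitPlan.normalization`).

Fitting is modular, in three stages: (1) per-tissue binding constants from
the Ca²⁺ titrations, with the rate constant as a nuisance amplitude (at
fixed ΔΨ the voltage factor is pure amplitude, so a provisional shape value
is immaterial); (2) voltage parameters from the ΔΨ titration with the
liver binding constant fixed; (3) per-preparation rate constants with all
shared parameters fixed. Each stage is a bounded trust-region least squares
(scipy `least_squares`, TRF) over log-transformed positive parameters, with
seeded log-uniform multistart (8 restarts by default) because single-start
fits of these models are initial-guess dependent. The heart dataset is
optional; the liver pair is required.

### Binding-displacement selection

α is a near-gauge direction under the protocol conditions: both numerator
terms of the flux are exactly α-invariant (the rate-constant factor
e^{±2(1−2α)φ̃} cancels against the binding shift e^{±2αφ̃}), so within a
single ΔΨ titration α acts only through the small denominator saturation
terms — flexible enough that noise alone can pull it to an interior
minimum, which then distorts every other dataset's rate-constant scale by
e^{4αφ̃}. Stage 2 therefore fits both an α-free and an α = 0 branch,
completes stage 3 under each, and retains α only on strong whole-corpus
evidence: the total-objective deviance improvement n·ln(E_α0/E_α) must
exceed 10. A spurious α shrinks the effective Ca²⁺-titration binding
constant by e^{−2αφ̃} and is decisively rejected by this comparison, while
a genuine displacement α ≳ 0.05 clears the threshold by orders of
magnitude. Otherwise α is profiled at its nonnegativity bound.

### Error propagation in the staged chain

Because stage 3 conditions on stage-1/2 estimates, the per-dataset rate
constants inherit their errors through the fixed-potential amplitude:
δk/k ≈ (∂lnΦ/∂ln nH)·δnH/nH + 2·δK/K with ∂lnΦ/∂ln nH ≈ 3.75 at
φ̃ ≈ 7.4, nH = 2.65. At the default noise level the binding constants and
nH recover with a few percent scatter per replicate, and the rate constants
with roughly two to three times that; replicate medians are unbiased (the
test suite checks medians over 50 replicates). Single-replicate rate
constant recoveries should therefore be read with ~10% uncertainty.

`parameter_sensitivity` reports the curvature of E under ±1% relative
perturbation of each estimate — a local identifiability index that is
near-zero along degenerate directions (the Case-2 m-family) and strictly
positive along determined ones.

## Numerical choices

* Φ and ln Φ are evaluated through a log-domain form with a series branch
  (`1 − u²/6 + 7u⁴/360` for |u| < 10⁻⁴) so the removable singularity at
  φ̃ = 0 is crossed smoothly; β_e(φ̃) likewise switches to its odd series
  −φ̃/(6nH) + 7φ̃³/(90nH³) near 0.
* Positive parameters are fit in log₁₀ space; displacements (α, β_e) in
  linear space with [0, 1] bounds.
* Optimizer tolerances default to 10⁻¹²; multistart winners are selected by
  final cost, and identical plans and datasets give identical results.
* All stochastic paths are seeded; datasets and CSV outputs are
  byte-reproducible given (seed, protocol, parameters).

## Design decisions

* Constraints are enforced by construction (`apply_case` parameterizes the
  constraint manifold) rather than by penalty, so every candidate during
  optimization satisfies them exactly; `constraint_residuals` verifies
  final sets at 10⁻⁹ relative.
* The Case-2 m-family is exposed (`case2_family`) and flagged in fit
  warnings instead of being silently fixed, since matrix-side constants are
  not identifiable from uptake data with matrix Ca²⁺ far below K_x0.
* Standard numerics are delegated to established libraries (scipy
  optimization, pandas CSV handling, PyYAML configs); the carrier models,
  constraints and staged-fit logic are implemented here because they are
  the substance of the package.

## Limitations

* Initial-rate fluxes only; no dynamic uptake traces, buffering, or
  ΔΨ feedback.
* The generator's noise model is idealized (see above); recoveries from it
  bound what the fitting machinery can do, not what historical data allow.
* Per-dataset rate constants carry amplified uncertainty from the staged
  chain (see error propagation); a joint all-parameter refit would tighten
  them but is deliberately not the default, to preserve the modular
  procedure the published estimates were obtained with.
* Case-2 internal constants are reported as one member of the m-degenerate
  family.
* α, β_e, β_x, nH are treated as constants over the fitted potential range;
  extrapolation far outside 60–190 mV is unvalidated.
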
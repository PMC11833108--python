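# Methods

## Scope and model structure

`pdlrom` models the reaction force of a periodontal-ligament specimen
under ramp-and-hold actuator displacement with one degree of freedom.
The full poro-visco-hyperelastic field problem is deliberately out of
scope: no mesh, no pore-pressure field, no Darcy solve. What remains is
the operational reduction used for parameter identification — an
elastic backbone F(x), a relaxation function G(t), their combination by
separation of variables or by discrete hereditary superposition, and
two empirical corrections (ramp-rate term, prior-test history term) —
plus the dimensionless analysis and permeability law that delimit the
poroelastic regime the reduction omits.

## Elastic backbone

One-term compressible hyperfoam law, isothermal throughout: the thermal
volume split that the general form carries (J = J_el·J_th, hatted
elastic stretches) is inert here, J_th = 1 and λ̂ = λ, because the in
vitro test is isothermal. The law is isotropic and carries no fibre
architecture; its three parameters are an averaged, specimen- and
load-case-specific description. `uniaxial_stress` implements the
closed-form nominal (first Piola–Kirchhoff) stress; its agreement with
the numerical gradient of the energy at the laterally relaxed state
(λ₂ = λ₃ = λ₁^(−ν), where ∂U/∂λ₂ = 0) is enforced in the test suite to
1e−8 relative, which pins down the nominal-stress interpretation.

Units are fixed package-wide — s, mm, N, stress in MPa — and never
inferred from files. μ in MPa makes p₈ (MPa/N) and typical soft-tissue
moduli consistent; only the product chain 2μ/(p₈α) enters the force, so
the unit choice is a convention, not a measurable.

The force mapping averages the tension and compression branch,
F(x) = ½(F(+x)+|F(−x)|), making F even in x; negative displacements are
folded to |x|. The domain ends where the compressive stretch would
vanish (p₉|x| ≥ 1).

Only the single-term law is supported. A multi-term variant would add
(μᵢ, αᵢ, βᵢ) triples; nothing in the campaign data motivates it.

## Relaxation function and its constraints

Three Prony branches represent the relaxation modulus; the count comes
from the decade rule: the data window (shortest sampling interval
0.5 s, longest record 900 s) spans lg(900/0.5) = 3.26 decades, one
branch per decade, nearest integer (three — fractional remainders below
half a decade do not add a branch).

Admissibility for a window (t_min, t_max):

* weights p₁, p₂, p₄, p₆ ∈ (0, 1), summing to one (so G(0) = 1);
* rates ordered with separation factor C = 8 (τ ratios ≥ 8), making
  cross-branch carry-over e^(−8) ≈ 3.4e−4 negligible — this justifies
  carrying only the slowest branch in the history term;
* τ₁ ≥ t_min (resolvable) and τ₃ ≤ t_max (observable).

`validate_constraints` reports rather than raises, so that candidate or
published-but-rounded series can be represented and examined: the
published per-test rows 4 and 12, for instance, violate the separation
factor by a rounding hair (printed ratios 7.99), and stored reference
rows are renormalized to the exact weight simplex before simulation.
Weights within 1e−6 of the open bounds pass validation but are listed
as near-bound. The stored-series tolerance on the weight sum is 1e−9;
identification satisfies it exactly by construction.

## Response assembly

Two modes are first-class because the product form and the discrete
superposition are genuinely different models during the ramp, and which
one stood behind the published joint fit is not determinable:

* **separable** — Y = F(x(t))·G(t); exact for a single instantaneous
  step, cheapest, used by default for single-test fits;
* **hereditary** — Y(t) = Σ ΔFᵢ G(t−tᵢ) with force-space increments
  ΔFᵢ = F(xᵢ) − F(xᵢ₋₁) on a uniform grid of step
  dt = min(t_sample, t_ramp/200) by default. Force-space increments are
  the natural finite-strain quasi-linear choice; strain-space
  increments with tangent-modulus weighting are not implemented.
  Because G is a sum of exponentials, the superposition is evaluated
  with an exact one-pole recursion per branch (a first-order IIR
  filter), O(n) instead of O(n²); the brute-force sum serves as test
  oracle. Halving dt at dt = t_ramp/400 moves the ramp-end value by
  under 0.5%.

Both modes are evaluated on the fine grid and linearly interpolated
onto the protocol's sampling grid. The hereditary value at ramp end
exceeds the separable one for a monotone ramp (early increments have
relaxed further in the superposition); the two bracket the recorded
peaks of the reference campaign.

The rate term H = p₁₀·x·e^(−p₁₁·t_ramp) captures the strain-rate
hardening visible as a near-constant hold-phase offset for fast ramps;
it is empirical and not part of the constitutive law. The history term
K approximates each earlier test by a rectangular displacement pulse of
height d_ramp between its ramp end and record end, carried by the
slowest branch only; K(0) is subtracted because each record is tared at
its start. Discarded campaign tests (1 and 13) stay in the pulse list —
they loaded the specimen regardless; consumers may exclude them.

## Poroelastic side

The permeability law k = k₀(n/n₀)²e^(M(λ−1)) was derived for
compression; in tension the package clamps k = k₀, since no evidence
supports extrapolating the law there. The porosity–stretch coupling is
the uniaxial solid-volume-conservation rule n = 1 − (1−n₀)/λ (J = λ),
a standard biphasic-mixture kinematic choice made here because the
coupling is not otherwise specified; it is documented and swappable.
Reference constants: k₀ = 8.81e−15 m², n₀ = 0.70, M = 14.2. Poroelastic
constants of the surrounding hard tissues ship as reference metadata
only — no field solver consumes them.

The Péclet analysis is exact bookkeeping: Pe·(t/τᵥ) = (L/L_d)² with
L_d = √(Dτᵥ). Regime boundaries at t/τᵥ = 0.1 and 10 (configurable)
label advection-dominated, transition, and diffusion-dominated
behaviour, boundaries inclusive in the transition. For the ligament in
situ (L = 0.1 mm, D = 1e−9 m²/s, τᵥ = 10 s) L_d equals the ligament
width, so Pe(1) = 1.

## Synthetic data

The generator wraps the simulator and emulates the reference campaign's
statistical structure: additive i.i.d. Gaussian force noise,
homoscedastic within a record and scaled to the record's noiseless peak
(default conditions: the 14-test protocol schedule with its printed
ramp times, displacements, sampling intervals and rest times; 2%
relative noise in recovery studies, the simplest model consistent with
a force transducer). Campaigns are generated sequentially so each test
inherits exactly the history pulses the model prescribes. Per-record
streams derive deterministically from (master seed, test id).

Taring is modelled as pinning the t = 0 sample at zero: a tare nulls
the static transducer offset so the record starts at zero, as the
measured records do. It does **not** subtract the first sample's random
noise from the whole record — that would inject a per-record constant
offset no real tare produces, and such offsets measurably destroy the
identifiability of the long-term weight p₁.

Not emulated: drift, temperature effects, tissue decomposition over the
five-hour campaign, heteroscedastic or correlated noise, and the
transducer latency that places measured force peaks ~1–5 s after the
ramp end (treated as latency, not modelled — the model peaks exactly at
t_ramp). Passing recovery tests therefore show the estimator works
under the assumed noise model, not that real records are this benign.

## Identification

Stage one scans the full factorial grid (default 5 levels per free
scalar, log-spaced for scales and time constants; neither resolution
nor the R² gate of 0.8 is prescribed anywhere, both are package
defaults) and ranks points by pooled R². Pooling weights every sample
equally, so long records dominate; per-test R² is reported alongside.
Stage two minimises the pooled squared residual with
trust-region-reflective damped least squares under constraints enforced
by construction: softmax logits for the weight simplex (exact), log
rates with log-ratio separations bounded below by log C, log transforms
for positive scalars, a logistic transform for ν ∈ (0, ½), and a smooth
hinge penalty for the rarely active τ₃ ≤ t_max bound, verified on the
result.

Identifiability findings, reflected in the API:

* μ and p₈ enter only as μ/p₈; when both are requested free, μ is held
  and the composite is reported (`FitResult.composite_scale`).
* The backbone quartet (α, ν, μ/p₈, p₉) is *sloppy* over the campaign's
  strain range (p₉x ≤ 0.18): starts more than ~10% away can converge
  into a valley with residuals at numerical zero but parameters far
  from the generating values. The two-stage design resolves this in
  practice — the scan's top-ranked grid point lies in the correct
  basin, from which refinement recovers noise-free generating
  parameters to machine precision. Single noisy records, by contrast,
  leave the weight/scale decomposition genuinely underdetermined (high
  R², scattered parameters), consistent with the large between-test
  standard deviations in the per-test reference table.

## Optimal-interpolation metamodel

Gauss–Markov estimation with a Gaussian (squared-exponential)
correlation, per-dimension lengths on unit-box-normalised parameters.
The technique's kernel and scales are not prescribed by its source;
defaults are ℓ = 0.5 and observation-error variance ε = 1e−6 (ε = 0 for
exact interpolation), tunable via leave-one-out cross-validation.
Estimation operates on anomalies about the per-component sample mean
(zero background for a single sample), so constant response fields are
reproduced exactly while a lone sample's influence still decays with
correlation. Each response time-sample is interpolated independently
through a shared factorised system (multiple right-hand sides);
appending a sample only extends the linear solve — there is no training
phase. Duplicate points with ε = 0 trigger a ridge fallback with a
warning. The surrogate optimum is located by a deterministic dense grid
(dimension ≤ 2; seeded scatter above) plus a Nelder–Mead polish, and
the refinement loop always returns the best *truly simulated* point.

## Problem sizes and numerical choices

Default experiment sizes: the full 14-test campaign (~33k force
samples pooled over the 12 valid records), 10 seeded replicates for
noisy recovery, a 500-point scan grid (5×4×5×5), a 10-call surrogate
budget with 4 corner samples and responses thinned to every 20th
sample. The acceptance script runs all of it in well under a minute on
one core; the O(n) recursion for the hereditary sum is what makes the
factorial scan and the fits cheap. Ties in peak detection break to the
earliest time; R² of a zero-variance reference is defined as 1 for a
perfect match and −∞ otherwise; fits that stop without meeting the
optimizer's criteria return best-so-far flagged `converged=False`.

## Known limitations

The model is specimen- and load-case-specific: p₈, p₉ absorb geometry,
and nothing transfers to other loading directions. The poroelastic
force contribution itself is not simulated — only its regime bounds
are computed. The rate term is phenomenology, and with a
non-randomised test sequence its cause (strain-rate hardening versus
specimen alteration over the campaign) cannot be separated. Published
per-test rows are rounded to three digits, which slightly violates
exact constraint arithmetic (weight sums 0.999–1.001, one separation
ratio at 7.99) and makes recomputed summary statistics differ from
printed ones in the last digit at most.
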
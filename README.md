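# pdlrom

Reduced order modelling of the periodontal ligament (PDL) — the soft
tissue that anchors a tooth root in alveolar bone — for ramp-and-hold
relaxation testing in the initial, mechanical phase of orthodontic
tooth movement.

In such a test the actuator displacement rises at constant speed to a
plateau,

    x(t) = v_ramp · t   for 0 ≤ t ≤ t_ramp,      x(t) = d_ramp   after,

and the decaying reaction force is recorded. `pdlrom` condenses the
specimen's poro-visco-hyperelastic behaviour into a one-degree-of-
freedom model of the actuator force, cheap enough for full-factorial
parameter studies, plus the dimensionless analysis that says *when* the
poroelastic contribution matters at all.

## The model

**Elastic backbone.** The ligament's ground substance follows a
one-term compressible hyperfoam (Storåkers) law with strain energy

    U = (2μ/α²) [ λ₁^α + λ₂^α + λ₃^α − 3 + (J^(−αβ) − 1)/β ],

parameters μ (MPa, the initial shear modulus), exponent α, and
compressibility β = ν/(1−2ν). Under uniaxial nominal stress the lateral
stretches relax to λ^(−ν) and

    σ(λ) = (2μ/α) (1 − λ^(−α(1+3β)/(1+2β))) λ^(α−1).

Actuator force and displacement map onto this law proportionally,
(σ, ε) = (p₈F, p₉x); because crown loading strains the ligament in both
tension and compression, the backbone force is the average
F(x) = ½(F(+x) + |F(−x)|) of the two branches.

**Relaxation.** A three-branch Prony function

    G(t) = p₁ + p₂e^(−p₃t) + p₄e^(−p₅t) + p₆e^(−p₇t),   Σ weights = 1,

with time constants τⱼ = 1/rate separated by at least C = 8 and
confined between the sampling interval and the record length. Three
branches follow from the data window spanning lg(900/0.5) = 3.26
decades.

**Response.** Two first-class modes: the separable product
Y = F(x(t))·G(t), and the hereditary (quasi-linear) superposition
Y(t) = Σᵢ ΔFᵢ·G(t−tᵢ) of force increments on a fine time grid. The
augmented model adds a strain-rate term H = p₁₀·x·e^(−p₁₁·t_ramp) and a
prior-test history term K(t) carrying the residual strain of every
earlier test of the campaign through the slowest Prony branch, with
K(0) subtracted because records are tared at test start.

**Poroelastic side.** Strain-dependent permeability
k = k₀(n/n₀)²e^(M(λ−1)) for compression (clamped at k₀ in tension), and
the Péclet analysis Pe·(t/τᵥ) = (L/L_d)², L_d = √(Dτᵥ): pore-fluid
advection dominates early, fades between t/τᵥ = 0.1 and 10, and
diffusion dominates once viscoelastic relaxation is essentially done.

**Identification.** Two stages, as cheap models permit: a full
factorial scan of the admissible parameter box gated on pooled R², then
constrained damped least squares with the weight simplex enforced
exactly by reparameterization and the rate ordering by log-ratio
bounds. An optimal-interpolation (Gauss–Markov) surrogate over sampled
parameter→response pairs steers refinement against an expensive
simulator, with no training phase to repeat when samples are added.

The package ships the 14-test reference campaign measured on a porcine
mandibular premolar (tests 1 and 13 discarded but kept for their strain
history) together with the published per-test and joint parameter
identifications, and a synthetic-record generator that reproduces the
campaign's statistical structure from known parameters.

## Worked example

```sh
python examples/simulate_relaxation_test.py
```

prints, for the 60-s-ramp 0.2-mm test of the packaged campaign with the
reference joint-fit parameters and full prior-test history:

```
test 10: ramp 0.2 mm in 60.0 s, hold to 660.1 s
   t [s]   x [mm]  F hered. [N]  F separ. [N]
     0.0    0.000         0.000         0.000
    30.0    0.100         0.638         0.530
    60.0    0.200         5.349         4.071
   120.0    0.200         3.961         3.667
   300.0    0.200         3.253         3.148
   660.0    0.200         2.711         2.670
hereditary: peak 5.35 N at 60.0 s
separable: peak 4.07 N at 60.0 s
recorded: peak 4.6 N at 61.9 s
```

The force rises progressively during the ramp (the hyperfoam backbone),
peaks at the ramp end and relaxes toward the long-term level
p₁·F(d_ramp). The two response modes bracket the recorded peak of
4.6 N: the hereditary sum relaxes early increments and sits above the
product form. `examples/` holds three more narrated scripts: noisy
generation + identification, the Péclet/permeability tables, and
surrogate-guided refinement; the same capabilities are scriptable via
the thin `pdlrom` command-line interface (`pdlrom simulate`,
`generate`, `fit`, `scan`, `surrogate`, `dimensionless`, `table1`).

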
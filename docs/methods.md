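# Methods

This note documents the models implemented in `geminicoev`, the
assumptions behind them, the numerical conventions, and what the
synthetic study conditions do and do not establish.

## 1. Ovulation-strategy selection

### Model

Two fixed genotypes are compared at a given resource endowment
E ∈ (0, 1): a double-ovulator *P* (two ova fertilised per cycle) and a
mono-ovulator *S*. Each fertilised embryo independently survives
gestation with probability 1 − m(E), where embryo/foetal mortality is
linear and decreasing in resources,

    m(E) = d − c·E,      c > 0,  c ≤ d ≤ 1.

A singleton birth has constant reproductive value R_s; a twin birth is
worth R_t(E) = a·E + b with a > 0 and R_s > b, so twinning is costly
(R_t < R_s) below the threshold E* = (R_s − b)/a and advantageous above
it. Genotype fitnesses follow from the embryo-survival lottery:

    W_P(E) = R_t(E)(1 − m)² + R_s·2m(1 − m)
    W_S(E) = R_s(1 − m)

Within-pregnancy embryo survival events are independent — the (1 − m)²
twin probability fixes that convention, and the simulator (§3) uses the
same one.

Assumptions: no trade-off between current and future reproduction, no
prenatal/postnatal allocation trade-off, and no evolution of plasticity
— the comparison is between fixed strategies at each E. The model's
point is precisely that the *sign* of W_P − W_S can change twice along
the gradient.

### The selection quadratic and its orientation

Direct algebra gives

    W_P − W_S = −(1 − m(E)) · (α_q E² + β_q E + γ_q),

with α_q = −ac, β_q = a(d − 1) + c(2R_s − b), γ_q = R_s(1 − 2d) +
b(d − 1). Since 1 − m ≥ 0, double-ovulation is favoured exactly where
the quadratic is negative; because α_q < 0 always (concave parabola),
that is outside the roots E₁ ≤ E₂. The package stores the quadratic in
this canonical form and defines the favoured flag as `quadratic < 0`;
the property suite confirms the orientation against the raw fitness
comparison over randomly sampled valid ecologies (1,000 ecologies ×
100-point grids; agreement required wherever |W_P − W_S| > 1e−10,
since at total mortality both fitnesses vanish and the sign is
undefined).

### Partition of resource space

Boundaries are drawn from {E₁, E₂, E*} ∩ (0, 1) — all root
configurations are enumerated (no real roots, tangency, roots outside
(0, E*), E* ≥ 1 truncated at 1) — and each maximal interval is
labelled twice, by twinning adaptiveness (R_t ≥ R_s) and by
double-ovulation advantage, both evaluated at the interval midpoint so
that labels agree with pointwise fitness comparison by construction.

Numerical conventions: a discriminant within ±1e−12 of zero is a
double root (tangency, no sign change, single boundary point);
candidate boundaries closer than `tol` (default 1e−9) to each other or
to the interval ends are merged, dropping zero-width slivers;
evaluation grids stay 1e−6 inside the open interval. Parameter sets
that would push m(E) outside [0, 1] are rejected at construction
rather than clamped — clamping would silently change the model. The
constraint on d is closed (d ≥ c rather than strict) so that the
boundary case d = c — mortality vanishing exactly at maximal resources
— is expressible; it changes nothing in the interior.

## 2. Twin-maternity prevalence

With constant per-pregnancy twinning probability x and P successful
pregnancies, independence across pregnancies gives

    T = 1 − (1 − x)^P.

Assumptions: P is independent of twinning outcomes (a twin birth does
not curtail future pregnancies) and x is constant across age and
parity — both counterfactual simplifications for real cohorts, where
twinning reduces subsequent fertility and x rises with maternal age.
T is monotone in both arguments and satisfies the complement identity
T(x, P₁+P₂) = 1 − (1 − T(x,P₁))(1 − T(x,P₂)), both enforced as
property tests; a 10⁶-career Monte Carlo oracle cross-checks the
closed form. Reported percentages are rounded to one decimal place
(the 37% case to the nearest integer, matching its customary
reporting).

## 3. Geminophilous redistribution

### Types and resources

Genotype Q twins with probability β per generation; the mutant Q̃ with
β̃ = β + δ (additive increment, δ ≥ 0, β̃ ≤ 1). Cultural types: A
(no institutions) and G (pool members). Everyone holds M resource
units and produces one birth per generation. Offspring survive
independently with probability S(r) of their per-offspring share r:

| type, outcome  | per-offspring share            |
|----------------|--------------------------------|
| A, singleton   | M                              |
| A, twin        | M/2 each                       |
| G, singleton   | (1 − α)(M − γ)                 |
| G, twin        | (M − γ + κ/T_G)/2 each         |

G-members all pay the fixed cost γ; the variable contribution
α(M − γ) is paid only by members who did **not** twin (twinners are
the recipients, not payers). The pool κ = α(M − γ) × (number of
G-type singleton producers) is split equally among the T_G realised
G-type twinners; when T_G = 0 the contributions are collected and
discarded, because the non-twinner share (1 − α)(M − γ) is
unconditional in this accounting.

### Survival function

The default is the exponential CDF S(r) = 1 − e^{−λr} (λ =
`lambda_surv`, per resource unit; default 2 in configs, putting S(M)
≈ 0.83 at M = 1 — a plausibly harsh pre-demographic-transition infant
survival). Note a structural fact: for this S, twinning is *never*
maladaptive in the bare sense S(M) > 2S(M/2), because the exponential
CDF is concave through the origin (algebraically 2(1 − e^{−z}) −
(1 − e^{−2z}) = (1 − e^{−z})² + (1 − e^{−z}) > 0). The framework's
starting premise — twinning costly absent institutions — therefore
requires a survival function with an accelerating (convex) region at
low resources. Survival is accordingly pluggable: any monotone map to
[0, 1] can be passed to every fitness, invasion and simulation entry
point, and `logistic_survival` (strictly increasing sigmoid) and
`step_survival` (threshold) are provided for such regimes. The
maladaptivity flag is *computed* for the configured S, never assumed.

### Analytic fitness

A-types: W_A(β) = (1 − β)S(M) + 2βS(M/2); strictly decreasing in β
whenever twinning is maladaptive.

G-types: the focal member's expected surviving offspring is the
expectation over its own Bernoulli(β) twin draw jointly with the
binomial twin counts of the other members (which set κ and T_G). The
pool accounting includes the focal individual's own realised outcome
in κ and T_G — the same bookkeeping the simulator applies, so the
analytic expectation and the simulated per-parent mean estimate the
same quantity (verified to 3 SE at 10⁵ replicates). Exact evaluation
enumerates the two binomials (pool sizes up to 20 members by default;
O(N_G²) terms); beyond the cap a seeded Monte Carlo estimator with
standard error takes over, and the two agree to Monte Carlo error on
random small-pool scenarios.

### Invasion condition and the conservative bound

With N − 1 non-twinning residents and one mutant who twins, κ =
α(M − γ)(N − 1) and T_G = 1, so invasion requires

    2 S((M − γ)(1 + α(N − 1))/2)  >  S((1 − α)(M − γ)).

Comparing the *arguments* of S gives a condition independent of S:
(1 + α(N − 1))/2 ≥ 1 − α ⇔ α(N + 1) ≥ 1. Hence α* = 1/(N + 1) is
sufficient for every strictly increasing S (at equality the arguments
tie and the factor two of twin offspring breaks the tie), and it is
sharp: for α* − ε there is a strictly increasing S (a logistic of
steepness 10¹⁰ centred between the two arguments, which differ by
≈(M − γ)ε(N + 1)/2) for which invasion fails. The community norm
"contribute about 1/N" is slightly more generous than α* and so always
suffices.

### Stochastic simulation

Per generation: (1) every individual draws twin/singleton
(Bernoulli with its genotype's rate); (2) the pool is computed from
realised G-type singleton producers and split among realised G-type
twinners; (3) every offspring survives independently with probability
S of its share per the table above; (4) the next generation of
constant size N is drawn by multinomial sampling of parents weighted
by realised surviving-offspring counts (Wright–Fisher regulation),
offspring inheriting genotype and cultural type clonally. Fixed-N
regulation was chosen over a branching process because the model
reasons in relative fitness and fixed N makes the neutral baseline
exact — a neutral mutant lineage fixes with probability 1/N — giving
the directional tests a clean null. Cultural type is vertically
inherited with no transformation rule; mixed-culture populations are
supported as initial conditions. There is no mutation during runs;
mutants are introduced in the initial counts. If no offspring survive
a generation the trajectory truncates with an explicit extinction
flag (the CLI exits with code 3 when nothing can be written).

RNG discipline: one root seed per run; replicate and absorption
experiments derive child seeds via `numpy.random.SeedSequence.spawn`
(reduced mod 2³¹). Identical seed + scenario reproduce trajectories
byte-for-byte.

## 4. Study conditions and problem sizes

The default configuration is the worked community-of-100 invasion
scenario: M = 1 (wealth normalised to one unit), γ = 0.1 (a 10%
membership cost), α = 1/99 (the "give about 1%" norm), λ = 2, β = 0
residents, one δ = 1 mutant. The verification suites use: 1,000
random ecologies × 100-point grids for the quadratic-orientation
check; 10⁵ one-generation replicates for simulation/analytic
agreement; 500 replicates × 15 generations for the neutral
random-walk check; 200 replicates for the all-A decline; and 1,000
absorption runs at N = 100 for the fixation-rate comparison against
the 1/N neutral baseline — sizes at which the 3-standard-error
criteria have comfortable resolving power while the whole suite runs
in seconds.

## 5. What the synthetic conditions do not show

All inputs here are model-generated; nothing is fit to data. The
prevalence formula ignores the empirical dependence of fertility on
twinning and of twinning on age/parity, so its percentages are
upper-bound illustrations of salience, not cohort estimates. The
ovulation model compares fixed genotypes at a fixed E and says nothing
about the dynamics or genetic architecture of plasticity. The
redistribution model treats polyovulation as a single clonal locus
(the phenotypic gambit), omits sexual reproduction and diploidy,
spatial structure, prestige/mate-choice pathways, cultural mutation or
conformity dynamics, and any equilibrium analysis beyond the printed
lone-mutant condition. Passing tests therefore establish internal
consistency of the models and simulator — not that these mechanisms
drive real-world twinning variation.
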
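# Methods

## The generalized mass-action model

The Q-cycle model is a system of 14 ordinary differential equations built
from 7 reactions under a *generalized* mass-action law: every reaction has
a rate `r_j = k_j · Π x_i` over an explicit list of kinetic factor
species, and a separate signed-integer stoichiometry map giving its net
effect. The two are deliberately decoupled because the canonical network
needs it: the Qi-site reduction depends kinetically on the ubiquinone pool
(x7) yet does not consume it — ordinary stoichiometric mass action cannot
express that reaction.

The canonical network tracks ubiquinol (x1), oxidized/reduced cytochrome c
(x2/x5), an electron budget (x3) that multiplies every rate law and is
consumed by every reaction, the Qo-site semiquinone (x4), P-side and
N-side protons (x6/x8), ubiquinone (x7), the three ETFDH flavin redox
states (x9/x10/x11), the two Qi-site semiquinone bookkeeping states
(x12/x13, one per monomer step of the dimeric enzyme), and the ETFDH-bound
semiquinone (x14). The two monomer Qo oxidations (r1, r3) and the two Qi
reductions (r2, r4) have pairwise identical rate laws but are kept as
distinct reaction instances — the emitted equations carry two identical
terms rather than a coefficient 2, and the single semiquinone production
term of x12 is attributed to r2, that of x13 to r4 (identical dynamics;
fixed bookkeeping for flux reports). Rate constants: k1–k4 = 5, k5 = 20;
the canonical constant table also lists k6 = k7 = 21, which enter no rate
law and are stored untouched. All quantities are dimensionless arbitrary
units with arbitrary time; no mapping to wet-lab units is attempted.

The electron budget x3 is a phenomenological device of the source model
(it throttles every reaction and eventually slows the whole system); it is
implemented exactly as specified, with no physical reinterpretation.

## Conservation pools

Conserved pools are computed as an integer basis of the left null space of
the stoichiometry matrix, in exact rational arithmetic (sympy), each
vector scaled to smallest integer form with a positive leading entry.
For the canonical network the 8-dimensional basis spans, among others, the
three chemically meaningful pools: cytochrome c (x2+x5 = 1.1), ETFDH
flavin (x9+x10+x11 = scenario level) and total quinone
(x1+x4+x7+x12+x13+x14 = 1.1). Simulations are required to hold each pool
within 1e-6 over the full horizon.

## Integration and observables

Integration uses adaptive LSODA with rtol 1e-8 / atol 1e-10, a dense
output grid of 1001 points, and a default horizon of t_end = 10 — chosen
so all three ETFDH scenarios approach quiescence while remaining cheap;
all are configurable. States in [−1e-9, 0) are treated as solver round-off
and clamped; anything lower is an error. The t = 0 output row is set to
the initial condition bit-exactly. AUC-type observables use the trapezoid
rule on the output grid; grid-refinement convergence (1001 vs 4001 points,
relative 1e-4) is part of the test suite. An independent fixed-step RK4
integrator over a hand-transcribed right-hand side serves as the oracle
for the adaptive solver (agreement within 1e-5 per component at dt 1e-4).

Steady state is declared at the first output time with max|dx/dt| below a
tolerance. Note the model's tails decay algebraically (products of
vanishing species), not exponentially: the wild type reaches 1e-2 around
t = 22 but is still above 1e-3 at t = 50. The electron budget never
empties under canonical conditions — cytochrome c runs out first — so
tight-tolerance quiescence is not reachable on practical horizons.

### The "standby" semiquinone

The model's qualitative claim is that ETFDH shortens the time semiquinone
radicals spend parked on complex III. Three dwell areas are reported:

* `semiquinone_auc_standby` = ∫ x4 dt (Qo-site radical) — the **standby
  metric**. Without ETFDH the N-side proton pool empties, the Qi
  reductions halt, and 0.35 a.u. of radical is stranded at the Qo site
  indefinitely; this area is strictly decreasing in ETFDH level
  (3.40 / 1.33 / 0.48 for levels 0 / 0.5 / 1 at the defaults).
* `semiquinone_auc_ciii` = ∫ (x12+x13) dt (Qi-site radicals) and
  `semiquinone_auc_total` (including the ETFDH-bound x14). These *increase*
  with ETFDH level at every horizon — and still do after normalizing by
  integrated throughput — simply because ETFDH multiplies Q-cycle flux
  several-fold. They are reported as data; the decreasing-standby claim is
  carried by the Qo-site area, which is where the model actually exhibits
  a stranded radical.

`compare_scenarios` reports all orderings as booleans rather than raising,
so the package can falsify as well as confirm the qualitative prediction.

## Trace fitting

An observed trace is modelled as baseline + gain·x5(t) + ε with unweighted
RSS loss (no error model is assumed for the absorbance record; weighted
variants would slot into the same residual hook). Gain and baseline are
nuisance parameters fitted by default since absorbance units are arbitrary
relative to model units. Optimization is bounded multistart local least
squares (scipy trust-region reflective), starts drawn uniformly within
bounds from a seeded generator; results are bit-reproducible given the
seed. The generic default is 8 starts; the ETFDH-level recovery wrapper
uses 4 — its 3-parameter problem (x9, gain, baseline; bounds [0,2],
[0.2,5], [−0.5,0.5]) is well conditioned and recovers a noiseless
heterozygote to ~1e-13. Integration failures inside the loss return a
large penalty with a warning instead of raising, keeping optimizers alive.

## Synthetic data

Trace generator: model trajectory × gain + baseline + i.i.d. Gaussian
noise (additive, absolute absorbance units — the simplest model consistent
with a spectrophotometer record). The genotype-recovery study uses 51
samples on [0, 10] and σ = 2% of the trace maximum, 20 seeded replicates
per genotype, classifying the estimate to the nearest of {0, 0.5, 1}.

Proteomics generator: protein sequences are built as n blocks of eight
filler residues (from a fixed K/R/P-free alphabet, seeded) terminated by
K, plus a short undetectable tail, so digestion yields exactly n
detectable peptides. PSM counts are Poisson with mean proportional to
complex molar abundance × effective NOP, normalized so expected counts sum
to the requested depth — the exact regime under which the slope-ratio
estimator is consistent. The generators return their ground truth; all
recovery tests consume only the data. What the generators do **not**
emulate: multiplicative/auto-correlated instrument noise, PSM
over-dispersion, shared peptides, missingness, per-protein response
variation. Passing recovery tests therefore demonstrate correctness of the
estimators under their own assumptions, not robustness to real-data
violations of them.

## Stoichiometry estimator

Digestion cleaves C-terminal to K/R, suppressed before proline, 0 missed
cleavages, detectability window 7–35 residues — standard bottom-up
heuristics, all configurable, since the upstream procedure's exact rules
are not published. Effective NOP defaults to identity response factors
(per-protein factors are an input hook). The per-complex regression is
zero-intercept by construction — a complex of zero abundance must give
zero expected counts — with a free-intercept diagnostic deliberately out
of the core path. The ratio's 95% interval is a percentile bootstrap
resampling proteins (the unit of replication) within each complex; the
synthetic benchmark (ETF:CIII abundance 1:2, 4 proteins per complex, depth
1e4) recovers the ratio within 15% of 0.5 in ≥ 18/20 seeds.

## Numerical choices and degenerate inputs

* Exact rational arithmetic for null spaces and for the brute-force slope
  oracle in the tests (float ternary search stalls at the √ε noise floor
  near a quadratic minimum).
* Δx6/Δx5 (protons per cytochrome c reduced) is flagged undefined, not
  raised, when Δx5 = 0; likewise a zero denominator slope in the ratio.
* A flat-zero trace drives the fitted gain to its lower bound with a
  near-zero ETFDH estimate and a large residual — a diagnosable, not
  exceptional, outcome.
* Trace points are sorted on construction, making the loss invariant to
  point order; duplicate times are rejected.

## Known limitations

The model is phenomenological: no thermodynamics, no membrane potential,
no explicit ROS kinetics (the leak narrative enters only through the
standby radical), no stochastic simulation, and rate constants are stated
values rather than measured ones. The inference machinery is validated on
synthetic truth only — the source analysis compares model and experiment
qualitatively, so there is no quantitative wet-lab target to fit.
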
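# Methods

## Problem and data

The package models five *in vitro* rooting responses of the G×N15 *Prunus*
rootstock — root number (RN), root length (RL, cm), rooting percentage
(R%, a proportion in [0, 1]), fresh and dry root weight (FW/DW, g) — as
functions of five macronutrient ion concentrations (NO₃⁻, NH₄⁺, K⁺, Ca²⁺,
Cl⁻, mM). The experimental design is a 3 × 3 × 4 factorial over four salts:
KNO₃ at 950/1425/1900 mg/L, NH₄NO₃ at 825/1238/1650 mg/L, and either
Ca(NO₃)₂·4H₂O (280/556 mg/L) or CaCl₂·2H₂O (220/440 mg/L), giving 36 media
with 6 replicates each. Only per-treatment means ± SE are available; the
replicate-level data the original models were fitted to are not.

## Salt → ion stoichiometry

mg/L divided by molar mass (g/mol) gives mmol/L. Molar masses are
KNO₃ 101.10, NH₄NO₃ 80.04, Ca(NO₃)₂·4H₂O 236.15, CaCl₂·2H₂O 147.02 —
the hydrate identities are pinned down by the published Ca²⁺ values
(556 mg/L → 2.35 mM works only for the tetrahydrate; 440 mg/L → 3.00 mM
only for the dihydrate). Nitrate accumulates from all three nitrate salts
(two per calcium nitrate). Two chloride conventions are exposed:

* `per_salt` (default): Cl⁻ equals the CaCl₂·2H₂O molarity. This reproduces
  the published ion table for all 36 media to ≤ 0.0098 mM.
* `stoichiometric`: Cl⁻ = 2 × CaCl₂·2H₂O molarity, which is what the
  chemistry says. It disagrees with the published table by exactly a factor
  of two on the 18 chloride media.

Whether the published halving is typographical or computational cannot be
decided from the text, so the faithful convention is the default and the
chemically strict one is available. Comparisons use unrounded values with a
0.02 mM tolerance; display rounds to 2 decimals.

Two source discrepancies resolved here: the methods text lists 278 mg/L for
half-strength calcium nitrate while the composition table prints 280 (280
matches Ca²⁺ = 1.18 mM and is used), and the printed hidden-layer sum index
"n−1" is read as the standard sum over the N inputs.

## Replicate synthesis

"±" is interpreted as the standard error of a 6-replicate mean, so each
replicate is drawn as mean + N(0, SE·√6) and clamped to the response's
physical domain (≥ 0; R% within [0, 1]). Clamping rather than truncated
resampling introduces negligible bias at the printed SE magnitudes (the
largest SE/mean ratios put the domain edge > 3 SD away for nearly all
treatments). RN replicates are kept continuous: the surrogate regresses a
continuous target and the printed means are non-integer.

Normalization is min–max onto [−1, 1], fitted on the full 216-row dataset
before the random 130/86 split (normalize-then-split, matching the original
workflow). The splitter guards against degenerate partitions by requiring
both partitions to touch at least 30 of the 36 media; at 216/36 this guard
essentially never triggers.

## Surrogate networks and training

Topology 5–8–1: hidden unit *i* computes tansig(Σₙ wₙᵢxₙ + bᵢ), with
tansig(n) = 2/(1+e^(−2n)) − 1 ≡ tanh(n); the output unit is linear. One
network per response; the five models are completely independent.

Training is Levenberg–Marquardt on the 130-row training partition with the
analytic Jacobian of the 57 parameters: solve (JᵀJ + λI)δ = −Jᵀr, accept a
step only if the SSE decreases (λ ÷ 10 on acceptance, × 10 on rejection,
abort above 10¹⁰ — at that point the gradient is numerically zero). This
makes the accepted-step loss trajectory monotone. Stopping: per-sample
training MSE ≤ 0.01 (normalized units) or 800 epochs; the weights with the
lowest recorded training MSE are returned, with the stop reason. A
full-batch gradient-descent-with-momentum trainer (learning rate 0.05,
momentum 0.9) is available as an alternative backend. Initialization is
seeded uniform [−0.5, 0.5] scaled by 1/√fan-in; experiments with plain
uniform and Nguyen–Widrow initialization reached the same training loss, so
the simplest seeded scheme is kept.

Reported metrics: R² = 1 − Σ(M−O)²/Σ(O−Ō)² (the standard coefficient of
determination; bounded published values are only consistent with the
squared-deviation denominator), RMSE, signed mean bias MBE = (1/n)Σ(M−O)
(published tables carry negative biases, so the signed form is used; the
absolute variant is exposed as MAE), and per-sample MSE (any ½ factor in a
training objective is an optimization constant; the goal of 0.01 is checked
against the per-sample mean so it is comparable across partition sizes).
Metrics are reported on both the original and the normalized scale — R² is
scale-invariant, RMSE/MBE are not — with original-scale as the headline.

`ResponseModel.predict` clamps predictions to the response's physical
domain by default (R% to [0, 1], the rest to ≥ 0), mirroring the replicate
clamping: the linear output unit happily extrapolates a proportion above 1
at the corners of the search box, which is meaningless for every downstream
use. The unclamped output remains available via `clip_domain=False`.

### What held-out R² can reach under this noise model

The test partition carries the same replicate noise as training, so even a
surrogate that recovers every treatment mean exactly has an R² ceiling of
var(means) / (var(means) + mean(SE²·6)). On the printed tables that ceiling
is ≈ 0.98 for R%, ≈ 0.93 for RN/FW, but only ≈ 0.86 for RL and ≈ 0.89 for
DW — RL's published held-out R² of 0.88 actually exceeds what the SE-implied
noise allows, so this pipeline's RL medians (~0.79–0.80) fall short of the
published value by construction, not by a training defect (training loss is
at the noise floor under all tested initializations). The generator's noise
level is fixed by the published SEs and is not adjusted.

## Sensitivity analysis

VSE is the model's RMSE (normalized space, all 216 rows) when one ion is
unavailable; VSR = VSE / full-model RMSE; ranks descend in VSR with ties
broken by the fixed ion order and flagged. Two probes are implemented:

* `hold_at_mean` (default): freeze the trained weights and pin the ion's
  column at its dataset mean.
* `retrain`: refit a reduced 4–8–1 network without the column.

Retraining looks like the natural reading of "unavailable", but it is
uninformative for this design: the ions are exactly collinear
(NO₃⁻ = K⁺ + NH₄⁺ + 2·Ca²⁺ on the nitrate media, and Cl⁻ > 0 identifies the
calcium-chloride branch), so a retrained network reconstructs any removed
ion from the remaining four and every VSR collapses toward 1. The frozen
probe is therefore the default. The same collinearity means the trained
network's attribution along the K⁺/NO₃⁻ direction is not identifiable:
K⁺-first and NO₃⁻-last emerge as the modal pattern for the well-resolved
responses (RN, R%, FW, DW), but for RL — whose means span only ~1.5 cm
against replicate noise of ~0.12 cm — the ranking is dominated by fit noise,
and NO₃⁻ vs Ca²⁺ for last place is a coin flip for R%. Published VSR
magnitudes are not reproducible under any probe tested (the exact original
protocol is unspecified); rank patterns, not magnitudes, are the meaningful
output. The error metric choice (RMSE) affects magnitudes only; any
monotone error measure yields the same ranks.

## Genetic algorithm

Real-coded individuals are 5-vectors of ion concentrations (mM) inside the
box spanned by the 36 media (per-ion data range). Defaults: population 50,
500 generations, fitness-proportionate (roulette-wheel) selection —
positive fitnesses are used as-is, otherwise all are shifted so the minimum
maps to a small positive floor — arithmetic-blend crossover applied per
pair with probability 0.85 (convex, hence bound-safe), per-gene Gaussian
mutation with probability 0.1 and SD = 0.1 × box width followed by clipping,
and one elite carried per generation (guaranteeing a non-decreasing best
fitness trajectory). Fitness is the clamped, denormalized model prediction;
each response is optimized independently (all five are maximization
problems). Non-finite candidate fitnesses are floored to the population
minimum and counted. Optimization runs in raw ion space; normalized space
would be equivalent under the affine map.

On a separable concave quadratic benchmark with a known interior maximum
the GA recovers the argmax to within 0.5 % of each box width and the
maximum to < 0.1 %.

Because the surrogate is unconstrained off the data manifold (most of the
5-D box violates the salt stoichiometry no physical medium can escape), its
global maximum often sits at a box corner where the network extrapolates;
optimal coordinates are therefore far more seed-sensitive than the predicted
optimum value, and should be read as a region suggestion, not a recipe.

## Benchmark surfaces

`synth.benchmark_surface` builds analytic ground-truth response surfaces
over the experimental ion box for end-to-end recovery tests: a separable
concave quadratic with configurable center, curvature and active ions, and
a variant shaped like the rooting-percentage landscape (low-K⁺ optimum,
peak 0.95). Treatments are sampled by stratified (Latin-hypercube-style)
draws; the exact argmax/maximum accompany the sample so model + optimizer
recovery can be asserted against a known truth.

## What the synthetic data does and does not show

The generator reproduces the first two moments of each treatment's
replicate distribution and the domain constraints — enough to exercise the
full pipeline and to test rank/optimum recovery against the published
tables. It does not reproduce within-experiment correlation structure
(replicates are drawn independently per response, whereas real explants
yield correlated RN/FW/DW), possible non-Gaussian skew in percentages near
the domain edges, or any block/operator effects. Passing tests therefore
validate the pipeline's faithfulness and internal consistency, not the
biology.

## Problem sizes and determinism

Default runs use the study's own sizes everywhere: 216 rows, 130/86 split,
800-epoch cap, population 50 × 500 generations. Multi-seed summaries use
10 seeds. Every stochastic stage (replicate draw, split, weight
initialization, GA) consumes an explicit seed derived from a single base
seed; reruns with the same configuration are byte-identical, which the run
manifest verifies via per-file SHA-256 checksums.
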
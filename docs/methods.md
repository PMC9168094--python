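# Methods

## Model and procedure

`lfhba` performs wrapper feature selection: candidate feature subsets are
scored by actually training a classifier on them, and a population
metaheuristic searches the subset space. Three layers make up the method.

**Continuous honey badger algorithm (HBA).** A population of N positions
in a box is updated by two moves. The *digging* move exploits the
neighbourhood of the incumbent best ("prey"):

    x_new = x_prey + F·β·I·x_prey + F·r3·α·d·|cos(2πr4)·(1 − cos(2πr5))|

with `d = x_prey − x`, direction flag `F ∈ {−1, +1}` (fair coin, +1 at the
0.5 boundary), food-finding ability `β = 6`, and density factor
`α = C·exp(−t/t_max)` with `C = 2`, which decays from C to C/e over the
run and schedules exploration → exploitation. The *honey* move is a guided
step `x_new = x_prey + F·r7·α·d`. The scent intensity follows an
inverse-square law computed **element-wise**:

    I_ij = r2_i · S_ij / (4π·d_ij²),   S_ij = (x_ij − x_{i+1,j})²

with one uniform `r2` per badger and the neighbour index wrapping
cyclically. The element-wise form (coordinate-wise squares, and fresh
uniforms r3, r4, r5, r7 per coordinate) follows the original HBA
formulation; it matters for feature selection because it lets a single
update flip individual mask bits. With scalar intensity and scalar draws,
all coordinates move coherently and the search cannot refine a mask by one
bit — in our small-dimension oracle experiments that variant found the
exhaustive optimum in only ~15–55 % of runs versus ~85–100 % for the
element-wise form. Squared distances are floored at ε = 10⁻¹² so a badger
sitting on the prey sees finite intensity, and the trigonometric factor is
taken in absolute value so the flag F alone carries the sign. Acceptance
is greedy (replace only on improvement) and positions are clamped to the
box after every update.

**Levy flight.** Heavy-tailed steps sampled per coordinate by the
Mantegna scheme: `s·u·σ / |r|^(1/β)` with `u ~ N(0, σ²)`, `r ~ N(0, 1)`,
scale `s = 0.01`, tail exponent `β = 1.5` (distinct from the HBA ability
β), and

    σ = [Γ(1+β)·sin(πβ/2) / (Γ((1+β)/2)·β·2^((β−1)/2))]^(1/β) ≈ 0.69657.

The 1/β exponent is required for σ to act as a normal scale; the
bracket-only variant (≈ 0.58137) occasionally seen in print is exposed
behind `mantegna_exponent=False`. The full update adds a uniformly chosen
population member and a deterministic spiral term:
`x_new = x_prey ⊙ Levy(D) + X_R + (y − x)·rand`, where for dimension index
D1 = 1..Dim, `r = r1 + 0.00565·D1`, `θ = −0.005·D1 + 3π/2`, `y = r·cosθ`,
`x = r·sinθ`, with base radius r1 = 10 (configurable integer in [1, 20]).
`rand` is one scalar uniform per update. |r| in the Mantegna denominator
is floored at 10⁻¹².

**LFHBA feature selection.** Positions live in [0, 1]^Dim; masks are
`bit_j = 1 iff x_j > 0.5` (strict, so 0.5 maps to 0). Per candidate per
iteration a fresh `P_i ~ U(0, 1)` selects the digging move (`P_i < 0.5`)
or the Levy move (otherwise, boundary included). The prose around the
method suggests the full HBA (digging + honey) on the first branch while
the operator-switch rule names only the digging step; both are
implemented, with the literal digging-only rule as default
(`hba_phase="full"` restores the honey coin). Fitness is
`λ·γ + (1−λ)·|mask|/Dim` with λ = 0.99 — λ is a convention (the standard
wrapper-selection weighting that keeps subset size a tie-breaker), not a
published value. γ is 1 − accuracy of a linear SVM (C = 1) on one fixed
stratified 80/20 hold-out per run: a fixed split keeps fitness
deterministic across candidates and avoids the cost of k-fold inside a
population loop; the split re-seeds up to 5 times if a class drops out.
Multi-class data uses one-vs-rest SVC with γ still 1 − overall accuracy.
Fitness values are memoized on the mask bit pattern. Empty masks are
repaired by flipping one uniformly chosen bit on (and lifting that
coordinate above threshold so position and mask stay consistent);
a `penalize` policy (fitness 1.0) is available. Ties keep the first-found
best; the only stopping rule is the iteration budget.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| N (pop_size) | 50 | population size; benchmark protocol value |
| max_iters | 1000 | iteration budget; benchmark protocol value |
| C | 2 | density-factor scale, α ∈ (C/e, C] |
| β (ability) | 6 | digging pull toward the prey |
| s | 0.01 | Levy step scale |
| β (tail) | 1.5 | Levy stability index, in (0, 2] |
| r1 (cycle_count) | 10 | spiral base radius, integer in [1, 20] |
| λ | 0.99 | loss vs subset-size weight in the fitness |

All randomness flows from one seeded `numpy` Generator per run; identical
seed, config and data give bit-identical results.

## Synthetic data

The generator emulates the intended input: fixed-width deep-feature
vectors (128 columns) with integer labels, a 2-class imbalanced default
(200/540, the ≈1:2.7 ratio of the public chest X-ray split at desk scale)
or a 4-class variant. `n_informative` columns (default 8) receive
class-conditional Gaussian means equally spaced `effect_size` noise-SDs
apart (default 3); all other columns are pure N(0, noise_sd²). This is
the minimal structure that makes recovery measurable: the generator does
**not** reproduce the correlation structure, heavy tails, or non-linear
class boundaries of real deep features, so passing recovery tests show
the search machinery works, not that the method attains any particular
accuracy on real images. The published headline accuracies (87.10 % CXR,
94.32 % OCT) require the original image archives and fine-tuned ensemble
extractors and are out of scope; the packaged score tables reproduce the
published comparison arithmetic (model-averaged accuracies, Friedman mean
ranks) exactly from the printed cells.

## What recovery tests can and cannot show

With per-column separation of 3 SD, any 2–3 planted columns already yield
zero hold-out loss on a desk-scale split (per-column Bayes error 6.7 %,
two columns ≈1.7 %, so zero errors on a ~150-sample hold-out are common),
and with λ = 0.99 the fitness then strictly prefers dropping further
columns. The fitness-optimal mask is therefore a *sparse subset* of the
planted features, not all of them: across 10 seeds the selector typically
keeps 2–6 columns of which almost all are planted (pooled hypergeometric
enrichment p ≈ 10⁻¹⁹ against random selection), while full 6-of-8
recovery does not occur — distinguishing a 6-feature from a 5-feature
subset would need hold-out error resolution below 0.05 %, i.e. thousands
of held-out samples. This is a property of the wrapper objective itself,
not a search failure; the acceptance suite asserts both properties and
reports them as measured.

## Numerical choices and degenerate inputs

- ε = 10⁻¹² guards both the intensity denominator and |r| in the Mantegna
  step.
- Bounds must be finite with lower ≤ upper; degenerate (lower = upper)
  boxes are allowed and collapse the population to a point.
- Zero-denominator metrics (e.g. precision with no positive predictions)
  return 0 with a warning.
- Friedman ranks: ties get averaged ranks; with `higher_is_better` the
  best method gets rank k, and mean ranks always sum to k(k+1)/2.
- Multi-class reports average one-vs-rest metrics weighted by class
  support by default (macro available); balanced accuracy is the mean
  per-class recall.
- Non-finite objective values abort a run with the iteration index.

## Problem sizes used in tests

The shipped suites use desk-scale settings chosen once: oracle
equivalence at Dim = 8 (N = 20, 200 iterations, 20 seeds, exhaustive
256-mask enumeration), planted recovery at 740 samples × 128 features
(N = 20, 100 iterations, 10 seeds), sphere sanity at Dim = 5 (N = 30, 200
iterations, 5 seeds). Full protocol sizes (N = 50, 1000 iterations)
remain the library defaults.

## Known limitations

- The Levy update's spiral offset (y − x ≈ r1 per coordinate) is large
  relative to the unit cube, so for feature selection many Levy proposals
  clamp toward the upper bound; the operator still contributes via small
  `rand` draws and the random-member term. This is inherent to the
  printed update, not a tuning artifact.
- The SVM hold-out split is fixed per run; fitness landscapes therefore
  reflect (and can overfit) that particular split. This is the standard
  cost of deterministic wrapper fitness.
- No constraint handling beyond box bounds, no maximization mode
  (negate the objective), no parallel populations, and no Friedman
  χ²/p-value machinery beyond mean ranks.
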
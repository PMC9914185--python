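# Methods

`poriaopt` models and optimizes the ultrasonic-assisted extraction of
bioactive components from *Poria cocos* sclerotium. Three process
factors — ethanol concentration X₁ (25–75 %), sonication time X₂
(30–50 min) and solvent volume X₃ (20–60 mL) — drive eight responses:
four lanostane triterpene acids (pachymic, trametenolic, tsugaric A and
dehydrotrametenolic acid, μg/g), total polysaccharides (mg glucose
equivalents/g), total phenolics (μg gallic-acid equivalents/g), DPPH
radical scavenging (%) and FRAP total antioxidant capacity (μmol/g).
The packaged dataset is a 17-run, three-factor Box–Behnken design
(12 edge runs + 5 centre replicates) with run means ± SD over n = 3
assay replicates.

## Response-surface model

Each response is fit on the coded factors (low/centre/high → −1/0/+1)
by ordinary least squares to the run means:

Y = α₀ + Σᵢ αᵢXᵢ + Σᵢ αᵢᵢXᵢ² + Σᵢ<ⱼ αᵢⱼXᵢXⱼ + Σ αᵢᵢⱼXᵢ²Xⱼ

Only run means are fit (the raw triplicates are not recoverable from a
mean ± SD table); pure error for the lack-of-fit test is taken from the
dispersion of the five centre-run means, which reproduces the
residual-df pattern of a means-based fit (model df 10, residual df 6 =
lack-of-fit 2 + pure error 4 for the 11-term models).

**Estimability.** On a 3-factor BBD the three cross-cubic terms with
i < j satisfy X₁²X₃ + X₂²X₃ ≡ X₃ (every edge run with X₃ = ±1 has
exactly one of X₁, X₂ at ±1), so the 13-column "full modified cubic"
matrix has rank 12. `fit_rsm` raises an aliasing error by default;
`on_alias="drop"` discards dependent columns via a greedy earliest-first
rank check, leaving fitted values, R² and the centre prediction
unchanged (they are properties of the column space).

**Term selection.** Three modes: `quadratic` (10 terms),
`full_modified_cubic` (13 terms, requires alias dropping), and the
default `auto` — the quadratic model plus the single cross-cubic
candidate (all six Xᵢ²Xⱼ orderings considered) with the smallest
partial-F p-value, added only when p < 0.05. `auto` reproduces the
uniform 10-model-df ANOVA structure reported for this dataset; on the
packaged data it selects X₁²X₃ for seven responses and X₂²X₃ for DA.
The exact per-response term sets used in the original Design-Expert
analysis are not recoverable, so non-centre predicted values can only be
matched approximately; centre predictions are exact for any hierarchical
basis containing the quadratic terms, because on a BBD the OLS centre
prediction equals the centre-replicate mean (all non-intercept columns
other than the Xᵢ² are orthogonal to the intercept, and the quadratic
block's normal equations force the centre fit through the centre mean).

**ANOVA statistics.** F-tests use upper-tail F probabilities with no
multiplicity correction. Adequate precision follows the standard DOE
signal-to-noise definition, (max fitted − min fitted) / √(p·MS_residual/n)
with p the parameter count and n the run count; values above 4 indicate
the model can navigate the design space.

## PCA and response grouping

The default PCA standardizes the 17×8 run-mean matrix (correlation PCA) —
the responses span four orders of magnitude in raw units, so covariance
PCA is dominated by the phenolics column and is offered only as a flag.
Two further conventions matter for comparing against explained-variance
figures produced by desktop statistics packages, which typically operate
on the full experiment table: `include_factors` appends the three factor
columns, and `replicate_level` expands each run into n_reps rows
reconstructed to match the printed mean and SD exactly. On the packaged
data the conventions give PC1/PC2 of 53.1/23.2 (run means, correlation),
97.2/2.3 (covariance), ≈52/22 (replicate rows) and ≈43.9/22.0
(replicate rows including factors); only the last matches the published
43.7 %/21.8 %, so that is the documented convention for reproducing the
published analysis. The replicate reconstruction is stochastic but
moment-exact; the Monte-Carlo spread of the explained percentages is a
few hundredths of a point.

Correlation grouping is a diagnostic, not the pipeline's authority:
responses are joined single-linkage wherever pairwise Pearson r ≥ 0.6,
and singletons attach to the group with which their best correlation is
moderate (0.4 < r < 0.6). The pipeline's operative grouping is the fixed
pair Group 1 = {PA, TA, TAA, DA}, Group 2 = {TPs, TPc, DPPH_SC, T_AOC}.

## Desirability optimization

Multi-response optimization uses Derringer–Suich desirability: for a
maximize goal, d = 0 at or below the lower anchor, 1 at or above the
upper anchor, a power-weighted ramp between; the composite D is the
importance-weighted geometric mean. Default anchors are each response's
observed min/max over the 17 runs with weight and importance 1 — all
configurable, since published desirability values depend on unstated
custom limits. The optimizer is a deterministic multistart: D is
evaluated on a 21³ coded grid and the best 20 points seed L-BFGS-B
polishes (tolerance 1e−6 in coded units).

When the surface predictions at the optimum exceed every observed value
— which happens for Group 1, where the fitted surfaces predict above the
observed maxima exactly as the original analysis did — D saturates at 1
over a region and the maximizer is non-unique. The reported point then
additionally maximizes the mean *unclipped* desirability over that
region (a penalized secondary search constrained to D ≥ 1 − 1e−9). This
tie-break selects the most-desirable-on-average point, keeps the result
unique and reproducible, and is the reason the Group-1 optimum is
reported with the solvent volume at its 60 mL bound. A composite
desirability of exactly 1 under min/max anchors is a statement about the
anchors, not about prediction quality; published values below 1 at
comparable optima imply wider, unstated anchor ranges.

## Neural-network surrogate

One network per response group: 3 inputs → 10 tansig hidden units →
m linear outputs (m = group size), inputs and outputs min–max scaled to
[−1, 1] on training-set ranges. tansig(n) = 2/(1+e^(−2n)) − 1 ≡ tanh(n)
is evaluated as tanh for stability. The 17 runs are split 70/15/15 into
training/validation/test by a seeded shuffle with largest-remainder
apportionment (ties broken train > validation > test), giving sizes
(12, 3, 2).

Training minimises the training-subset MSE by a damped Gauss–Newton
(Levenberg–Marquardt) schedule: per epoch one accepted step of
(JᵀJ + μI)δ = −Jᵀr with μ divided by 10 on acceptance and multiplied by
10 on rejection (μ₀ = 1e−3, abort at μ > 1e10). The residual Jacobian is
assembled analytically from backpropagation and is verified against
central finite differences in the test suite. Early stopping halts after
6 epochs without validation improvement (patience is configurable; the
value is a conventional choice for tiny networks) and the returned
weights are those of the best-validation epoch — on the packaged data
the validation minimum is typically reached within about 10 epochs.
Weight initialisation is seeded uniform(−0.5, 0.5); plain gradient
descent with momentum is available by config. With 12 training runs and
62–84 parameters the surrogate is deliberately over-parameterised and
its quality is seed-dependent — pooled R² across seeds ranges roughly
0.25–0.99 for Group 1 and 0.98–0.99 for Group 2 — which is why the
pipeline reports GA optima across several seeds rather than from one.

## Genetic algorithm

Real-coded, generational, MATLAB-toolbox-style operators: rank-scaled
fitness (weight ∝ 1/√rank), stochastic-uniform parent selection, elite
count ⌈0.05·population⌉ copied unchanged, intermediate crossover
(child = p₁ + u·(p₂ − p₁), u ~ U(0,1) per gene) for a 0.8 fraction of
the offspring, and mutation for the remainder. Default mutation is
Gaussian with scale (1 − gen/max_generations) of the per-gene box range
— coarse exploration early, fine refinement late; per-gene uniform
resampling within bounds is available by config but gives markedly worse
final precision and misses the 1 %-of-objective-range oracle agreement
the test suite enforces. All offspring are clipped to the box; only box
constraints arise here, so no nonlinear constraint handler is needed.
Defaults: population 50, 100 generations, no stall cutoff (a strict
no-improvement stall rule interacts badly with the annealed mutation
scale, freezing the search mid-anneal). Migration settings
(fraction 0.2, interval 20, forward ring) are carried in the config and
inert at the default single population.

The GA serves twice: seeding the network weights (chromosome = the
flattened 84-gene weight/bias vector for a 3-10-4 net, bounds ±2,
fitness = training+validation MSE of the decoded network, best
individual refined by LM training), and locating extraction optima by
minimising the negative composite desirability of surrogate predictions
over the factor box. Scalarizing a 4-response group through composite
desirability matches the response-surface stage and makes the two
optimizers directly comparable.

## Synthetic data

`synthetic` draws ground-truth polynomial surfaces over the coded
factors (seeded uniform coefficients, intercept raised so all
design-point means are positive) and realises BBD datasets as run means
and SDs of n_reps homoscedastic Gaussian replicates; a relative-noise
mode scales the SD with the surface range, since real assay SDs grow
with the measured level. The generator emulates exactly the structure
the response-surface model assumes — it does not emulate run-order
drift, heteroscedastic assay error or model misspecification, so
passing recovery tests demonstrate solver correctness, not robustness to
those real-data features. `ground_truth_optimum` brute-forces composite
desirability on a 101³ coded grid with a local polish and is the oracle
for both optimizers.

## Problem sizes and numerical choices

The test suite runs the full pipeline at its natural scale (17 runs,
8 responses); stochastic checks use 5 seeds for the ANN-GA stage and
20 seeded surfaces against a 51³ grid for the GA oracle property, with
the GA given the conventional 100·n_variables generation budget there.
Degenerate inputs are handled explicitly: zero-variance columns raise
scaling/correlation errors, zero pure error marks the lack-of-fit test
not testable, constant predictors report R² = 0, and a non-finite
objective value aborts the GA carrying the offending point.

## Known limitations

- The exact published per-response term sets, ANN split and seed are
  unknown; non-centre predictions, exact F/p values and the published
  ANN columns are reproduced only approximately or qualitatively.
- The Group-2 desirability optimum's time coordinate is term-set
  sensitive (30.9 min under `auto`; published 30.0 min); the ethanol and
  volume coordinates sit on bounds and are stable across bases.
- Composite desirability at the Group-1 optimum saturates at 1.0 under
  observed-range anchors (see above); published sub-unity values at such
  optima require unstated custom anchors.
- The surrogate is trained on 17 points and should not be extrapolated
  outside the factor box.
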
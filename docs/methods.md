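# Methods

`sepsisdyn` implements a dynamic-phenotyping analysis for early
emergency-department (ED) sepsis: standardized hourly feature abstraction,
a supervised representation encoder, consensus spectral clustering to
derive phenotypes, k-nearest-neighbour label transfer, and a one-step
Markov decision-process model of 3 h → 6 h phenotype transitions as a
function of early interventions. Because the EHR cohorts this kind of
analysis is run on are not public, the package ships a calibrated
synthetic cohort generator; every statement below about what the tests
establish should be read against what that generator does and does not
emulate.

## Synthetic cohort model

Each septic patient carries a latent phenotype `z3 ∈ {P1..P4}` drawn with
prevalences (33.8, 13.6, 16.6, 36.0)%. Phenotype severity is ordered
P2 < P1 < P4 < P3, matching the published adverse-outcome ordering.
Per-phenotype calibration anchors (all configurable):

| quantity | P1 | P2 | P3 | P4 |
|---|---|---|---|---|
| in-hospital mortality | 4.8% | 1.7% | 9.4% | 7.8% |
| antibiotics within 3 h | 52.8% | 37.0% | 86.4% | 71.4% |
| any lactate measurement | 67.6% | 35.6% | 97.4% | 88.6% |

Interventions are Bernoulli draws with phenotype-specific propensities;
fluid volume ≥ 30 mL/kg is nested within "fluids within 3 h" and
calibrated so its cohort-wide share is ≈ 26%. Hospice is drawn only among
survivors, so mortality and hospice are mutually exclusive and their
combined rate is the sum of the two.

**Transitions.** `z6` is drawn from a multinomial-logistic (softmax)
kernel: destination logits are a per-source baseline plus additive
log-odds shifts per intervention received. The baseline logits are solved
by a fixed-point (iterative-proportional-fitting) calibration so that the
kernel *marginalized over the default intervention distribution* equals a
target matrix with every diagonal 0.55 — hence an overall 45% transition
fraction — and a rarest transition P2→P3 of 1.2%. The calibration is
exact to machine precision. A softmax coefficient β placed on a single
destination's logit implies an exactly logistic one-vs-rest model for
that destination with odds ratio e^β (the other logits cancel), which is
what makes planted-effect recovery tests well-posed. The default
configuration carries the published-style intervention effects (early
antibiotics toward the lowest-mortality destination at OR 1.438, away
from the second-highest at 0.75; large fluid volumes toward the
highest-mortality destination at 1.227); because several destinations are
shifted at once, fitted one-vs-rest ORs under the *default* config are
not exactly the softmax coefficients (non-collapsibility), so recovery
tests plant a single coefficient.

**Measurements.** Forty clinical variables (4 statics, 8 vitals, 28 labs;
the schema is an explicit stand-in and fully user-overridable) evolve as
stationary AR(1) series around phenotype-specific means, with
autocorrelation 0.7; right-skewed labs are generated log-normally. Series
revert to the `z3` mean through hour 3 and to the `z6` mean afterwards, so
the 6 h snapshot genuinely carries the post-transition state. Phenotype
mean profiles are `base + (separation/10)·scale·(severity·λ + η)` with
fixed frozen loadings λ and phenotype-specific offsets η; `separation`
defaults to 8. Observation is two-stage: a per-patient×variable gate
(the "was it ordered at all" probability, phenotype-dependent; e.g. the
lactate row above) and an hourly within-patient sampling rate; gated-on
patients are guaranteed one draw within the first three hours, mimicking
the initial ED workup and making the marginal measured fraction equal the
gate probability.

**Controls.** The non-septic stratum (25% of the cohort) consists of
*attenuated twins*: each control is drawn around
`base + 0.5·(phenotype_mean − base)`. This encodes the claim that
infection-negative ED patients vary along the same organ-system axes as
septic ones, only less deranged — and it has a deliberate computational
consequence: a sepsis-vs-control classifier cannot separate the classes
with a single direction, because the boundary must enclose the healthy
centre along every phenotype's dysfunction axis. A simpler "global mean
minus a fixed dysfunction offset" control profile was tried first and
rejected: it makes the task rank-one separable, and the trained encoder's
representations then collapse the phenotype geometry (k-means ARI against
planted labels ≈ 0.1 versus ≈ 0.76 on the raw features).

**What the generator does not emulate:** real units and reference ranges,
inter-variable physiological correlation beyond the shared severity
loading, treatment effects on the measured trajectories themselves,
informative *timing* of measurements, site effects, or sepsis-3
adjudication. Passing tests therefore demonstrate algorithmic
correctness and calibrated recovery under the stated latent model — not
clinical validity on real EHR data.

## Preprocessing

Hourly bins are half-open `[h, h+1)` from triage; a bin with several
values takes their median (even counts: midpoint of the middle pair).
Statics are held constant from abstraction. Missing bins after the first
observation are filled by sample-and-hold; leading bins and
never-observed series take the global population mean, computed on the
raw scale from the reference cohort's observed values. Normality
transforms are per-variable `log1p`, chosen when the sample skewness of
observed values exceeds 1 and the variable is nonnegative; the choice is
recorded in the serialized normalizer so it is auditable.
Standardization moments are computed on the imputed, transformed
*snapshot at the fit horizon* (3 h, the derivation horizon), which makes
the reference snapshot standardize to exactly mean 0 / SD 1; computing
them on observed values only would leave imputation-induced offsets in
the snapshot columns, and the two definitions cannot both be exact.
The SD floor is 1e-8 (constant columns standardize to 0). All parameters
are frozen after fitting on the derivation cohort and reused verbatim for
the 6 h snapshot and for validation cohorts — the external-validation
contract.

## Representation encoder

A multilayer perceptron (40 → 128 → d, ReLU, sigmoid head, d = 10 by
default) is trained with Adam on binary cross-entropy to discriminate the
septic stratum from controls; training is deterministic given the seed.
The exported representation is the *pre-activation* of the penultimate
layer — a linear read-out of the wide hidden layer. Rectified penultimate
activations were measurably worse for downstream clustering (ReLU folds
half of every direction to zero, discarding within-class structure the
classification loss never needed); the linear read-out preserved planted
structure best in development experiments. Which layer of a sepsis
predictor one should cluster, and at what width, has no canonical answer;
both are parameters and are stored with the model.

Known limitation: even with the control design above, a binary
discriminative objective retains phenotype geometry only partially
(k-means ARI against planted phenotypes ≈ 0.4–0.6 on default cohorts,
versus ≈ 0.8 on the raw standardized features). Consensus clustering on
the encodings is *more consistent* than on raw features — the property
the pipeline is built around — but on this synthetic cohort it resolves a
coarser, highly stable structure rather than all four planted phenotypes.
The clustering machinery itself is validated on planted representation-
space blobs where ground truth is unambiguous; the pipeline can also be
configured to cluster the raw standardized features
(`cluster: {space: features}`), which on synthetic defaults recovers the
four phenotypes directly.

## Consensus spectral clustering

The affinity is Gaussian, `W_ij = exp(−‖x_i−x_j‖²/(2σ²))`. The default
bandwidth rule is *median-knn*: the median distance to the 7th nearest
neighbour, a local-scaling bandwidth. The classical median heuristic
(median of all pairwise distances) is implemented and selectable, but on
clustered data it sets σ near the *between*-cluster distance; the graph
is then nearly complete and resampled clustering is unstable in exactly
the way that destroys the consensus signal. Optional symmetrized m-NN
sparsification is available.

Spectral clustering is the Ng–Jordan–Weiss construction: eigenvectors of
the k smallest eigenvalues of `L = I − D^{−1/2} W D^{−1/2}`, rows of the
embedding normalized to unit length, then seeded k-means (20 restarts,
k-means++; sklearn's best-inertia tie-break). Zero-degree isolates —
possible only under sparsification — are removed from the eigenproblem
and assigned the label of their most similar non-isolated point.

The consensus loop draws R subsamples (fraction p, without replacement;
defaults R = 100, p = 0.8, k ∈ 2..6), shared across candidate k so one
eigendecomposition per subsample serves all k and CDF comparisons are
paired. `M(k)_ij` is the fraction of co-sampled runs in which i and j
were co-clustered; never-co-sampled pairs (rare at these defaults) get 0
and are tallied. The empirical CDF of the upper-triangle entries, its
trapezoid area A(k) and the relative increments Δ(k) are all computed and
emitted.

**Choice of k.** The default rule is PAC (proportion of ambiguous
clustering): `PAC(k) = CDF(0.9) − CDF(0.1)`, the mass of pairs that are
neither reliably together nor reliably apart. The chosen k is the largest
whose PAC is within 0.005 of the minimum; if even the best PAC exceeds
0.25, nothing clusters stably and the floor of the search range is
returned. A forward delta-area rule (smallest k with Δ(k+1) < 0.05) is
implemented and selectable, but it is structurally fragile when cluster
prevalences are very unequal: with shares (33.8, 13.6, 16.6, 36.0)%,
resolving the true fourth cluster adds only ≈ 0.07 relative area (the two
smallest clusters are cheap to merge) while splitting the 36% cluster at
k = 5 adds 0.03–0.09 even under perfect planted structure, so the 0.05
threshold straddles both. PAC separates the same cases by an order of
magnitude (PAC(4) = 0.000 vs PAC(5) ≥ 0.049 in development runs).
Additionally, any k whose consensus partition contains a cluster below 5%
of the cohort is disqualified from selection: a stably separating outlier
clump is not a phenotype. Final labels at the chosen k come from
average-linkage hierarchical clustering on the consensus distance 1 − M —
the consensus matrix itself is the object the method trusts.

## Transition models

The 3 h and 6 h labels are cross-tabulated into a row-stochastic
transition matrix with the overall transition fraction `1 − tr(N)/n`.
Destination models M1..M4 are one-vs-rest binomial GLMs (statsmodels
IRLS, gradient tolerance 1e-8, max 100 iterations) of "lands in
phenotype j at 6 h" on the three intervention indicators plus source
dummies (P1 reference); the sixteen pairwise models refit interventions
only within each source stratum. One-vs-rest is used rather than one
multinomial fit because the four destination models are reported
separately; their predicted probabilities need not sum to one and are not
renormalized. Confidence intervals are Wald (symmetric on the log-odds
scale); no multiplicity correction is applied. Fits flag
non-convergence and probable separation (|coef| > 15) instead of failing,
since rare transitions (the 1.2% cell) legitimately produce sparse
response vectors at moderate n. The state space widens automatically if
labels beyond 4 appear, so pipeline runs that select a different k still
produce the full set of tables.

## Label transfer and concordance

New patients (the 6 h snapshot; external cohorts) are assigned by
k-nearest neighbours (default k = 15, a conventional locality/noise
trade-off) under the same Gaussian similarity, with σ frozen at fit time.
Votes are similarity-weighted; ties break toward the larger summed
similarity, then the lower label — assignment is fully deterministic, and
since the kernel decreases strictly with distance the neighbour sets
coincide with Euclidean ones. Derivation/validation concordance is
reported as standardized differences of per-phenotype profile columns and
Spearman rank agreement of outcome-rate orderings.

## Reporting

Characterization tables give median (IQR) with Kruskal–Wallis rank-sum
tests for continuous variables (patient-level medians over the first six
hours) and n (%) with Pearson chi-square tests (no continuity correction;
these are four-group tables) for binary ones. Raw counts are always
stored alongside percentages so every printed figure is recomputable.
The missingness diagnostic reports observed / held / mean-imputed
fractions per phenotype × variable; `measured = observed + held` is the
"seen at least once by the horizon" fraction comparable to a
"patients with a lactate measurement" table row.

## Problem sizes and numerical choices

Simulation-based checks use the sizes stated with each check: share and
missingness calibration at n = 10,000; transition-fraction calibration at
n = 5,000 over 10 seeds; cluster-number recovery at n = 1,500 with R = 50
over 10 seeds; effect recovery at n = 20,000 with coverage over 200–250
replicates of n = 5,000 (latent layer only, which is exact for these
quantities and orders of magnitude faster than full table generation).
Dense eigendecompositions (`scipy.linalg.eigh`, smallest-k subset) are
used throughout; at the default consensus sizes a full run is a few
seconds per subsample set. Stochastic tests are derandomized with fixed
seeds at tolerances stated inline.
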
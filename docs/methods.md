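# Methods

`songcorpus` implements two analyses over a cross-cultural corpus of song
excerpts, each annotated with a behavioral context (the social function the
song serves: dance, lullaby, healing, ...), a languoid (Glottolog
glottocode), and a world region. This note documents the models, the
choices behind their defaults, the synthetic-data generator used for
validation, and the limits of what the tests show.

## Ensemble context classification

**Model.** A song's behavioral context is predicted from its vector of
acoustic features (38 by default; the pipeline is agnostic to their
identity) by an ensemble of L1-penalized (LASSO) multinomial logistic
models. One ensemble pass splits the songs into `k = 10` disjoint test
partitions; for each test partition, `n_boot = 10` class-balanced bootstrap
resamples are drawn from the other partitions and one model is fitted per
resample, voting on every test song. Repeating over `n_splits = 25`
independent splits gives every song exactly `n_splits × n_boot = 250`
votes; the reported label is the per-song modal vote.

**Why balanced bootstraps.** Contexts have unequal base rates in real
corpora (range 56–149 songs per context), and a single penalized fit drifts
toward the prevalent classes. Resampling with replacement *within* each
context so that all contexts contribute equally removes the base-rate
gradient from every individual fit. The per-class draw count is the size of
the largest training class (`max-class`), which oversamples minority
classes without discarding majority information; a `min-class` option
(downsampling) is available. Balance is exact on every resample, not on
average, and is asserted as such in tests.

**Penalty selection.** The inverse-penalty `C` is chosen by 5-fold
cross-validated multinomial deviance inside each bootstrap resample over
the grid {0.01, 0.1, 1, 10} (`penalty_selection="cv5"`), or fixed
(`"fixed[:C]"`) where thousands of fits are needed (permutation runs at
reduced scale). Feature standardization uses training-resample statistics
only; a leakage test plants a marker in the test partition and asserts the
fitted coefficients are unchanged.

**Solvers.** Multiclass fits use scikit-learn's saga solver (softmax + L1,
a single multinomial model rather than one-vs-rest). Two-class fits call
the equivalent liblinear routine directly, skipping the estimator wrapper's
per-fit re-validation; a test asserts prediction-level equivalence with the
public estimator.

**Evaluation.** Accuracy is compared against chance defined as
1/|contexts| (never the empirical base rate). The confusion matrix is
row-normalized within true contexts. Per-context sensitivity is
d′ = z(H) − z(FA) with H the diagonal confusion entry and FA the rate of
predicting the context among other-context songs; rates of exactly 0 or 1
are replaced by 1/(2N) and 1 − 1/(2N) (N the relevant denominator) so d′
stays finite. Modal-vote ties are broken toward the earlier context in the
canonical vocabulary order (dance, healing, love, lullaby, play,
procession, mourning, work, story, praise) and flagged.

**Significance.** The permutation test shuffles labels uniformly and
re-runs the entire ensemble per permutation (default 200; minimum 19). The
p-value is the proportion of permutations with accuracy *strictly higher*
than observed; this literal rule can return 0 and is anti-conservative
under ties, so an add-one smoothed variant ((1 + higher)/(1 + n)) is
available, and tie counts are reported. Per-context p-values apply the same
rule to per-context hit counts from the same permutations (the permutation
preserves class sizes, so counts and rates order identically).

## Variance partitioning (ICC)

**Model.** Each standardized feature y is decomposed, per song, as

    y = α + b[context] + u[languoid] + p[languoid] + g[languoid] + ε

with b ~ N(0, σ²_b I) (behavior), u ~ N(0, σ²_c I) (culture: i.i.d. per
glottocode), p ~ MVN(0, σ²_p K) (phylogeny), g ~ MVN(0, σ²_g exp(−d/ρ))
(geography), ε ~ N(0, σ²_e I). K is the Brownian-motion trait covariance
from the language tree — entry (i,j) is the shared root-to-MRCA path length
— rescaled to unit diagonal (correlation form) so σ²_p is on the same scale
as the other components; the raw form remains available. Geographic
distances are great-circle (haversine, Earth radius 6371 km) between
Glottolog coordinates, and the GP lengthscale ρ is estimated. Culture and
phylogeny are two random effects over the same glottocode grouping
(i.i.d. + tree-structured), the standard phylogenetic-mixed-model
decomposition. Behavior is a random effect with its own variance rather
than fixed contrasts, because a variance share is the quantity of interest.

**Inference.** The random effects are Gaussian and enter linearly, so they
are integrated out analytically: the marginal covariance is
Σ = σ²_e I + U M Uᵀ with U the song × (1 + contexts + languoids) incidence
(the leading column is the grand mean, folded in as a diffuse N(0, 100)
effect) and M the block-diagonal group covariance. The log-likelihood is
evaluated in the rank-r space (r ≤ 1 + C + L) via the Woodbury identity and
matrix determinant lemma, so cost per evaluation never touches the song
dimension. The remaining 2–6 parameters (log component SDs, log ρ) are
sampled with an affine-invariant ensemble MCMC (emcee) using
differential-evolution moves: `chains` (default 4) independent walker
ensembles of ≥ 2·dim+2 walkers, 1000 warmup + 1000 retained steps by
default. R-hat is computed with arviz over all walkers of all ensembles on
the sampled scale; any parameter with R̂ ≥ 1.05 flags the fit as
non-converged, and non-converged fits are excluded from battery summaries
with a count.

**Priors.** Half-normal(0, 1) on every component SD (responses are
standardized); inverse-gamma(2, median pairwise distance) on ρ, which puts
the prior mean at the middle of the observed distance range and vanishes at
0 and ∞. When the posterior mean of ρ exceeds 5× the maximum observed
distance the geographic kernel is effectively all-ones (confounded with the
intercept); the fit stays numerically stable through the 1e-8 diagonal
jitter and is flagged `near_singular_geo_kernel`.

**ICC.** For each posterior draw, the ICC of component k is
σ²_k / (Σ_j σ²_j + σ²_e) over the included components — the proportion of
variance explained. The point estimate is the posterior mean of per-draw
shares; the share-of-posterior-means is reported alongside, with central
95% intervals. Per draw, shares including the residual sum to one. σ²_g is
the GP marginal variance (the kernel has unit diagonal), so it enters the
denominator exactly as parameterized.

**Battery.** The default model battery fits, per feature: {behavior},
{culture}, {behavior, culture}, {behavior, culture, phylogeny},
{behavior, culture, geography}, and all four — the comparison that
separates overall context/culture effects from vertical (phylogenetic) and
horizontal (geographic) transmission. Songs whose glottocode lacks
coordinates are dropped from geography fits (with a count) and retained
elsewhere.

## Synthetic-data generator

The generator produces corpora with known ground truth so both stages can
be validated by parameter recovery; it emulates structure, not audio.

* **Tree**: pure-birth (Yule) process started from two root lineages, each
  splitting at `birth_rate` (default 1/unit time), stopped one
  exponential(n·λ) epoch after the n-th lineage appears, so the expected
  root-to-tip depth is Σ_{k=2..n} 1/(kλ). Tips are ultrametric by
  construction.
* **Locations**: latitude/longitude diffuse independently along branches
  (variance `location_diffusion`, default 30 deg²/unit length, clamped to
  valid ranges), so sister languoids are spatially closer on average —
  the phylogeny-aligned spatial autocorrelation real languoids show. A
  consequence worth stating: the geographic and Brownian kernels are
  *correlated* in generated data, and distinguishing them (e.g. the
  planted-geography checks) needs tens of languoids.
* **Features**: y = β_c + u_ℓ + p_ℓ + g_ℓ + ε with each term drawn from its
  generating distribution at configurable variances; features are i.i.d.
  redraws given the design. Defaults plant behavior/culture/residual shares
  of 0.3/0.3/0.4 on 40 languoids × 10 songs. Contexts are uniform by
  default (isolating the classifier's balancing machinery); a
  `context_weights` option reproduces corpus-like imbalance.

What the generator does **not** emulate: audio or real acoustic-feature
distributions (features are Gaussian composites), annotation noise,
glottocode granularity drift, cross-feature correlation, or uneven
languoid sampling depth. Passing recovery tests therefore shows the
estimators are correct under the model's own assumptions — not that real
songs satisfy those assumptions. One visible consequence: because every
synthetic feature carries an independent redraw of the context effect,
aggregate class separability grows with the feature count, and classifier
accuracy on generated corpora is far higher than anything achievable with
real, mutually correlated acoustic descriptors. Synthetic accuracies
demonstrate the machinery, not an expected effect size.

A statistical subtlety the tests account for: with correlated group
effects, the *empirical* variance of a generated feature is systematically
below Σσ² by the mean off-diagonal kernel correlation (the effects share a
common component that centering removes); the generator test checks the
exact analytic expectation tr(S)/n − 1ᵀS1/n², not the naive sum.

## Numerical choices and problem sizes

* PSD jitter 1e-8 on every kernel diagonal before factorization; kernels
  asserted symmetric within 1e-10.
* Lower-median convention for integer count summaries (even-length vectors
  report the lower middle value), matching integer corpus summaries.
* Zero-variance feature columns are centered to 0, flagged, and never
  divided by.
* Region vocabulary is a closed set of 38 tokens (the eHRAF world regions
  plus Western/Central/Eastern Europe). The default token list is a
  reconstruction; loaders accept a replacement vocabulary file for corpora
  annotated against a different region release.
* Validation suites run at deliberately reduced scale chosen for
  statistical adequacy per check: permutation calibration uses 100
  two-context 40-song datasets with a 2-partition, 5-split × 5-bootstrap
  ensemble and 99 permutations; recovery checks use 400-song, 40-languoid
  corpora with 2 MCMC chains × 500 retained draws. The full-scale defaults
  (10 partitions, 25 splits, 10 bootstraps; 4 chains × 1000 draws) are what
  the CLI runs.

## Known limitations

* The exponential GP treats geography as stationary and isotropic on the
  sphere; no barriers or anisotropy.
* No Ornstein–Uhlenbeck or other trait-evolution kernels beyond Brownian
  motion; no model comparison via information criteria.
* emcee walker ensembles are interacting, so walker-wise R-hat is a
  pragmatic convergence gate rather than an independent-chain diagnostic;
  the DE moves and long warmup make it conservative in practice.
* The strict permutation p-value can be anti-conservative under heavy vote
  ties on very small corpora; the add-one rule is recommended for
  publication use.
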
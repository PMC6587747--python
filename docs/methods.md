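# Methods

This note documents the statistical machinery, the synthetic-data
generative model, the defaults and the numerical conventions of
`corehybrid`, and what the package's tests do and do not establish about
real data.

## Prediction model

PLS1 regression links mid-parent metabolite abundances X (hybrids ×
analytes) to thousand grain weight y. The NIPALS deflation scheme is used:
for each latent factor a, the unit weight vector is w_a ∝ X'y on the
current residuals, scores t_a = X w_a, loadings p_a = X't_a/(t_a't_a),
q_a = y't_a/(t_a't_a), then X and y are deflated. Coefficients on the
original predictor scale follow from R = W (P'W)⁻¹, B = R q,
b0 = ȳ − x̄'B, so a stored model predicts without re-running the
deflation; factor-form and coefficient-form predictions agree to
round-off and score vectors are mutually orthogonal (both are tested, and
the implementation is cross-checked against an independent NIPALS
implementation and against ordinary least squares at full factor count).

Extraction stops when ‖X'y‖ or t't collapses relative to the initial data
scale (relative tolerance 1e-12); requesting more factors than the data
support raises an error that reports the achievable maximum. In a complete
diallel of 18 parents the mid-parent matrix has rank ≤ 18, so at most 17
factors exist after centring — the cap is data-dependent and reported, not
hard-coded. Cross-validation folds and permutation replicates fit with
`allow_fewer=True`, truncating silently instead of erroring, because fold
subsets can be rank-deficient even when the full data are not. A response
with no covariance against X (e.g. constant y) supports no factor at all;
`select_n_components` returns (1, [0.0]) for this degenerate case.

The factor count A* maximises training adjusted
R² = 1 − (1 − R²)(n − 1)/(n − k − 1) with k = number of latent factors,
ties going to the smaller count. The search ceiling defaults to
min(n_train − 2, n_markers, 30). Model-order selection by training
adjusted R² (rather than cross-validation) is a deliberate design choice —
it is how such models are commonly specified in practice; with a few hundred training hybrids the penalty
is weak and A* tends to sit high, which is visible in the grids the
pipeline prints.

VIP follows Wold's definition over the first a components,
VIP_j = sqrt(p Σ_a SSY_a (w_ja)²/Σ_a SSY_a) with SSY_a = q_a² t_a't_a;
mean VIP² = 1 identically (property-tested). The marker screen uses
Component-1 VIP of a PLS-DA model (classes coded 0/1) fitted with 4
components on the large/small TGW extremes of the diallel population,
threshold 1.5, strict inequality. Q² is estimated by stratified 10-fold
cross-validation (fold count reduced to the minority class size when
needed); folds reuse the global autoscaling — the scaling is learned on
the same extremes the model sees, so Q² here measures class separation,
not a fully nested validation. The permutation test uses the training R²
of the class-coded model as statistic with the add-one estimator
p = (1 + #{permuted ≥ observed})/(1 + n_perm), so the smallest achievable
p is 1/(1 + n_perm) (5e-4 at 1999 permutations); n_perm < 19 is rejected
because p could then never reach 0.05.

## Subgroups, core selection, compositions

TGW subgroups use fixed boundaries: large > 27, small < 24 g/1000 grains,
strict comparisons, so boundary values are medium. PCA is SVD-based on
column-centred data with a fixed sign convention (each loading column
oriented so its largest-magnitude entry is positive), which pins down the
PC1-score ranking. Core selection sorts scores descending (ties broken by
hybrid id), and keeps block leaders at positions 1, N+1, 2N+1, …, giving
ceil(n/N) hybrids that always include the top-ranked one; "one of every
N" readings based on random block members were rejected for determinism.
Because the mirrored PC1 orientation selects different block leaders, the
pipeline can evaluate both orientations (`orientations=("+", "-")`) and
report both grids; the default reports the fixed convention.

Training compositions are unions of per-population parts ("all", an
N-interval core set, or a seeded random half); the validation set is
every hybrid of both populations not in training. Predictability is the
Pearson correlation between observed and predicted TGW over validation
hybrids, per population, with a two-sided t-approximation p-value;
populations with fewer than 3 validation hybrids are reported as NaN.
Autoscaling parameters and A* are learned on training hybrids only — a
leakage test verifies that permuting validation phenotypes changes the
reported r but not a single prediction. Marker selection itself defaults
to screening on the whole diallel's subgroups, which predates the split
and is leakage-safe only for the second population;
`strict_selection=True` reselects markers within each composition's
training hybrids.

## Synthetic-data generative model

The generator emulates the study design: 18 diverse inbred parents crossed
in a complete diallel (ordered pairs, reciprocals included, selfs
excluded → 306 hybrids, phenotyped in 2012) and one CMS female crossed to
106 RIL males (106 hybrids, 2015). Diallel parents contribute two
replicate profiles (averaged before predictor construction); RIL lines and
the female one (their repeats pooled), mirroring the sampling design.

Each parental line's analyte profile is

    x = baseline + Λ z + (module loading) · F(module) + δ + ε,

with four variance layers chosen to reproduce, qualitatively, the
behaviour of real untargeted data:

- **baseline**: per-analyte lognormal level (median 30, log-sd 0.4),
  clamped at zero after noise — abundances are non-negative.
- **latent factors** z (6 per line, loadings scaled 1/√k): a global
  low-rank backbone. The two populations differ here in mean (an additive
  shift of 3 latent units, so PCA separates them — the silhouette of
  population labels in PC1/PC2 space is ~0.4-0.5) and in variance profile
  (`latent_divergence` = 0.85: the diallel panel varies mostly along the
  first half of the factors, the RIL family along the second — two line
  panels do not segregate the same axes).
- **modules** F: structured analytes come in correlated groups of
  `module_size` = 15 (feature-group redundancy — one metabolite yields
  several adduct/fragment features — plus pathway co-regulation), factor
  sd 2.5, per-analyte module loadings ~N(1, 0.25). Module factors are not
  independent across modules: each line's factors are a mixture
  √(1−w²)·own + w·(C_pop · own) with w = `module_mixing` = 0.75 and a
  population-specific random mixing matrix C_pop. Cross-module
  correlation patterns therefore differ between populations, which is the
  generator's "distant relatedness" mechanism: a model that leans on
  indirect (proxy-analyte) correlations learned in one population
  degrades in the other, while direct causal-analyte weights transfer.
- **analyte-specific heritable deviations** δ (sd 0.8) and per-sample
  instrument noise ε (sd 0.5). 60 % of analytes carry genetic structure
  at all; the rest are background features with instrument noise only.

TGW is strictly linear in mid-parent analyte values:
TGW_h = b0 + Σ_{j causal} e_j x_hj + offset(pop) + N(0, 0.5 g), with a
−1.5 g environment offset for 2015. Causal analytes are whole modules
(60 causal = 4 modules of 15) with direction-consistent per-analyte
effects (relative spread `effect_cv` = 0.25): a pathway that drives the
trait moves all its features together. The effect vector is rescaled so
the diallel population's genetic TGW sd equals `tgw_genetic_sd` = 2.0 g
(population-1 mean anchored at 25.5 g), which keeps the fixed 24/27 g
subgroup boundaries meaningful for any configuration — effect_sd and
effect_cv only shape relative magnitudes. The full truth (causal ids,
effects, intercept, offsets) is returned for recovery tests.

Why the correlated-module design matters: with 18 parents the diallel's
predictor matrix has ~17 effective dimensions, so any per-analyte
association statistic carries a chance-correlation floor of ~1/√17 ≈ 0.24
at the parent level. Sixty *independent* causal analytes would each
contribute at most corr ≈ √(1/60) ≈ 0.13 — undetectable by construction —
whereas causal signal concentrated in a few correlated modules rises to
√(1/4) ≈ 0.5 per analyte and becomes recoverable, matching the strong
inter-correlation reported for real predictive analytes. The same
structure creates the characteristic interior peak of the
marker-count-versus-predictability sweep: very small sets miss whole
causal modules, very large sets re-admit background features and
population-specific chance correlates.

All randomness derives from a single scenario seed via per-stage
`numpy` SeedSequence spawns; identical configurations give byte-identical
tables.

## What the synthetic scenario does not emulate

No raw spectra, retention-time drift, missing-value patterns or
QC-injection structure (the pipeline starts at the feature table); no
metabolite heterosis — hybrids are represented purely by mid-parent
values, an assumption the predictors share; no genotype-by-environment
interaction on effect sizes — environments act only as an additive offset,
so cross-environment difficulty arises from population structure, not
effect instability. Passing tests therefore show that the pipeline's
statistics behave as specified and that the workflow recovers a known
signal under realistic correlation structure; they do not certify
predictability levels on any real population.

## Numerical conventions and problem sizes

Sample standard deviations use the n−1 denominator throughout. The
sum-normalisation constant is the mean of the original row sums (the
choice is irrelevant downstream because analytes are autoscaled).
Constant columns are centred but never divided by zero (scale recorded as
1 and flagged). "More than 50 % nonzero" is a strict inequality. Pearson
predictability is NaN for fewer than 3 pairs or constant vectors. Floats
are written with 12 significant digits; write-then-read round-trips are
tested at that precision.

The default test suite runs the full study-scale scenario (306 + 106
hybrids, 800 analytes) once as a shared fixture plus scaled-down
scenarios per module; the whole suite takes well under a minute, and
`scripts/acceptance.py` (which adds a 1999-permutation test and the
marker sweep) a few seconds.
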
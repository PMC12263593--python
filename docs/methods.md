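# Methods

## The problem

A functional connectome (FC) is the matrix of Pearson correlations between
regional fMRI time series; its strict upper triangle is a vector of
r(r−1)/2 *edge features*. A small subset of edges carries an
individual-specific *fingerprint*: it distinguishes people from one another
and stays put when the same person changes cognitive state. This package
implements a deterministic, interpretable way to find those edges —
leverage-score row selection on the features × subjects population matrix —
and the downstream analyses that characterize the selected edge sets: their
similarity structure, their stability across age cohorts and across brain
parcellations, and the validation that they are age-invariant.

## Leverage-score selection

For a tall population matrix **M** ∈ ℝ^{m×n} (m edge features, n subjects),
let **U** be an orthonormal basis of the column space of **M**. The leverage
score of feature i is

  l_i = ‖U_{i,·}‖² = [ **M** (**M**ᵀ**M**)⁺ **M**ᵀ ]_{ii},

the i-th diagonal entry of the orthogonal projector onto the column space.
Scores lie in [0, 1], sum to rank(**M**), and measure how strongly a single
edge shapes the population's subspace — i.e. how much between-subject
structure it carries. Selection is deterministic: sort descending, keep the
top k, break ties by ascending edge index. Randomized leverage sampling is
deliberately not implemented; determinism is what makes feature sets
comparable across cohorts, tasks, and runs.

Numerics: **U** comes from a thin SVD; singular values below a relative
`rank_tolerance` (default 1e-10) are dropped so duplicated subjects or
tasks cannot inflate the basis. Scores are invariant to right-multiplication
of **M** by any invertible matrix (only the column space enters), which is
tested directly.

Edge order is the package-wide convention: row-major over pairs (i, j),
i < j, 0-based, with closed-form index ↔ pair maps. Feature-set operations
(intersection, consensus, region tallies) are only meaningful because every
stage shares this single ordering.

## Similarity structure

Two statistics summarize a feature set on a study: (a) inter-subject,
within-task — mean Pearson correlation over all unordered subject pairs'
feature-restricted vectors; (b) within-subject, cross-task — mean per-subject
correlation between two tasks' vectors. A fingerprinting feature set drives
(a) down and keeps (b) high. By default task-pair comparisons use the set
selected from the rest-task matrix; this wiring is overridable.

Significance is calibrated against size-matched uniform random subsets: the
null distribution of the same mean statistic over many draws. The empirical
p-value uses the add-one rule, (1 + #extreme)/(n_trials + 1), and is floored
at 1/(n_trials+1); a Gaussian tail probability computed from the null mean
and SD is reported alongside, because the empirical p cannot resolve below
its floor. Pairs whose restricted vectors are constant are skipped and
logged, never imputed; degeneracy is detected by exact range (max − min = 0)
rather than a floating-point SD test. Reported SDs are sample SDs over the
enumerated pairs (not over cohorts); the two are never conflated.

## Cohort stability and consensus

Subjects are sorted by (age, subject id) and cut into non-overlapping blocks
of `cohort_size` (50 on a real lifespan cohort; 20 in the synthetic test
bench so five cohorts fit in 100 subjects). Remainder subjects are dropped
by default (`merge_last` folds them into the final cohort). Selection runs
per (cohort, task) matrix; stability is the c × c matrix of pairwise
percentage intersections, 100·|A∩B|/k, with 100 on the diagonal. Summary
means are exposed for both scopes — consecutive cohort pairs (superdiagonal)
and all pairs (strict upper triangle) — since both are scientifically
meaningful. Intersection percentages presuppose a common k, so unequal-k
input is an error rather than silently min-normalized. Consensus features
are the intersection across all cohorts; an empty consensus is a valid,
logged outcome. Sex-stratified analyses are plain metadata filters feeding
the same partition/selection/intersection code path.

## Cross-atlas concordance

Agreement between parcellations is assessed in mm space. Endpoint regions of
selected edges are tallied over cohorts (both endpoints count once per
cohort set; a unique-per-cohort mode is available), the top half of
frequently hit regions kept (ceil(fraction · n_nonzero), ties by count then
id), and region sets matched across atlases by a centroid-in-region rule:
region a of atlas A matches iff atlas B's label at the voxel nearest to a's
centroid belongs to B's top set. This is the simplest deterministic
operationalization of "intersecting the coordinates" of two region sets; it
is declared, not canonical, and it is asymmetric, so both directions are
computed and reported. Agreement is the min-normalized overlap

  overlap(A, B) = |A∩B| / min(|A|, |B|),

a Dice variant robust to very different region sizes between fine- and
coarse-grained atlases. Because centroid matching is many-to-one, the match
count can exceed the smaller set's size; the coefficient saturates at 1 and
the event is logged. Voxel-level agreement (percent of A's labeled voxels
also labeled in B) requires a shared grid; resampling across grids is out of
scope.

## Age-invariance validation

Each candidate stable feature is regressed on age (OLS with intercept,
vectorized closed form; two-sided t-test on the slope, n−2 dof) and flagged
by Benjamini–Hochberg step-up at α = 0.001 (Benjamini–Yekutieli available).
Constant features get slope 0, p = 1 by convention. The predictive contrast
fits a linear model of age on the restricted features under seeded k-fold
CV (default 10) and reports per-fold MAE in years; when the feature count
reaches the training size, plain OLS is underdetermined and a fixed small
ridge penalty (α = 1.0) is used instead. Random baselines draw `n_sets`
uniform subsets size-matched to the stable set — the count and the set size
are separate knobs because they answer different questions. Fold assignment
is a seeded shuffle; an age-stratified option is not provided. Per-fold SD
and across-set SD are reported separately.

## ROI-coverage exclusion

Per subject, the functional mask is the set of voxels with mean intensity
strictly above 0.7 × that subject's grand mean; a region is excluded iff its
in-mask voxel fraction falls strictly below 0.5 for at least one subject
(boundary coverage exactly 0.5 is retained). Exclusion propagates to edge
space by dropping every edge touching an excluded region through a
deterministic re-indexing map; analyses run identically with or without the
exclusion applied.

## The synthetic study generator

The generator is the test bench: it produces studies with known ground
truth so every downstream stage can be validated against planted structure.
Edge value for subject s, task τ, edge e:

  x = μ(e) + δ_τ(e) + f(s,e)·1[e ∈ signature] + β·(age_s − midpoint)·1[e ∈ drift] + ε(s,τ,e),
  value = tanh(x),

with μ ~ N(0, group_mean_sd²) the population edge profile, δ_τ ~ N(0,
task_effect_sd²) task shifts, f ~ N(0, fingerprint_sd²) the per-subject
fingerprint (constant across tasks), β = drift_slope per year on a disjoint
drift set, and ε ~ N(0, noise_sd²) i.i.d. scan noise. tanh keeps values in
[−1, 1] while preserving monotone structure. Ages are uniform on 18–87 and
assigned sorted so cohort partitioning is deterministic; sexes alternate so
both strata are non-empty without an extra random stream.

Defaults — the standard study conditions used throughout the tests — are
100 subjects, 60 regions (1,770 edges), three tasks (rest, SMT, movie), 80
signature edges with fingerprint_sd 0.5, 40 drift edges at 0.01/year,
task_effect_sd 0.2, group_mean_sd 0.3, noise_sd 0.1. The variance ratios
are chosen so that the fingerprint dominates the planted edges while the
drift component is detectable but clearly weaker, which is the regime the
analyses assume; real within-task variance decompositions of lifespan FC
data are not published at this granularity, so these SDs are chosen for
testability, not realism. The generator emulates none of: hemodynamics,
spatial autocorrelation, motion artifacts, non-Gaussian noise, age-varying
noise. Passing tests therefore demonstrate correctness of the machinery and
recoverability of planted structure under the stated model — not
performance on real fMRI.

Time-series synthesis (for exercising the parcellation/correlation stage)
draws Gaussian series with a target population correlation, after repairing
the target to the nearest valid correlation matrix by eigenvalue clipping at
1e-8 and diagonal renormalization — deterministic and adequate at toy scale.
Toy atlas pairs are Voronoi parcellations of a shared voxel grid from seeded
center voxels (ties to the lowest region id), with centroids through a
diagonal voxel-size affine.

## Orchestration and reproducibility

The `connectoprint pipeline` command chains simulate → fc → select →
similarity → stability → atlas-overlap → age-invariance into a run
directory with a manifest (config snapshot, per-stage seeds, package
version, SHA-256 digests of outputs). A single master seed fans out to
per-stage sub-seeds as SHA-256("master:stage") mod 2³¹, so stages are
independently reproducible; identical config + seed reproduces outputs
bit-for-bit. The end-to-end atlas stage needs a region selection performed
independently in the second atlas's space; since the synthetic study lives
in the first atlas's region space, a second, independently seeded study of
matching region count is generated for that role.

Problem sizes in the bundled tests and the acceptance script are the
defaults above (plus the full 352,380-feature pool wherever the analysis is
purely combinatorial or sampling-based, which costs seconds); multi-seed
checks use 10–20 replicates.

## Known limitations

- The centroid matching rule is one of several defensible cross-atlas
  matching rules (any-voxel intersection, coordinate lists); results at
  coarse parcellations can differ between rules.
- Regional signals are voxel means; eigenvariate summaries are not
  implemented.
- No Fisher z-transform anywhere: all analyses operate on raw Pearson
  values in [−1, 1].
- The age model is linear; nonlinear aging trajectories and site/scanner
  covariates are out of scope.
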
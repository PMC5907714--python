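# Methods

`morphomod` implements a landmark-based geometric-morphometric workflow for
comparing shape variation, disparity and cranial modularity across equid
groups (domesticated horses H, Przewalski's horses P, donkeys D, zebras Z).
This note documents the models, the numerical choices, and what the bundled
simulation does and does not emulate.

## Superimposition

Configurations are `k x m` landmark matrices (`m` = 2 for teeth, 3 for crania
and mandibles). Generalized Procrustes analysis (GPA) centres each
configuration, scales it to unit centroid size, and rotates it onto the
current consensus with the Kabsch solution restricted to proper rotations
(handedness is never flipped; reflection enters only through the symmetry
decomposition). The consensus is re-estimated as the mean of the aligned
shapes and the loop stops when the unit-normalised consensus moves by less
than `1e-10` (Frobenius norm), with a cap of 100 iterations. The summed
squared residual to the consensus is recorded per iteration; it is
non-increasing by construction (each rotation and each consensus update is a
separate least-squares minimisation). No tangent-space projection is applied
by default; at the variance levels analysed here (Procrustes variance of
order 1e-3) the curvature correction is far below the statistical noise.

Crania digitised in two views are merged with a least-squares **rigid**
transform (rotation + translation, no scaling — both views are the same
physical specimen in the same units) fitted on at least three non-collinear
shared reference landmarks. The RMS misfit over the reference landmarks is
returned as a digitising-error diagnostic.

### Object symmetry

Crania and mandibles are bilaterally symmetric objects. Each aligned shape is
paired with its reflected copy whose left/right landmark labels are swapped
(bundled pairing tables cover the 62 cranial and 24 mandibular landmarks;
midline landmarks keep their labels). Originals and reflections are jointly
superimposed; the **symmetric component** of a specimen is the average of its
two copies and the **asymmetric component** the remainder, so the two
components reconstruct the jointly aligned shape exactly. Only the symmetric
component feeds the downstream analyses of bilateral structures; 2D tooth
data skip the decomposition entirely (a single tooth has no object symmetry).
Which coordinate axis is negated for the reflection is immaterial: the joint
superimposition rotates the reflections back onto the originals.

## Ordination, dimension selection and classification

PCA is the eigen-decomposition (via SVD) of the specimen covariance of the
flattened symmetric coordinates; numerically zero components are dropped,
eigenvalues are non-increasing and variance fractions sum to one.

Because `k·m` far exceeds `n`, downstream tests run on the first `N` PC
scores. `N` is chosen by leave-one-out (LOO) linear-discriminant
cross-validation averaged over repeated **balanced subsamples** (each group
subsampled without replacement to the smallest group's size), which keeps the
heavily unbalanced design (133/47/31/5) from letting the majority group
dominate the cross-validation; ties break toward the smallest `N`. On
unstructured data this LOO accuracy sits at or slightly below chance —
removing a specimen shifts its own group mean away from it — so the selector
cannot manufacture signal from noise.

Group differences in shape are tested with a permutation one-way ANOVA on
the first `N` scores: `F` is the ratio of between- to within-group mean
squares summed over dimensions, and the p-value is the fraction of label
permutations (observed statistic included, so `p >= 1/(permutations+1)`)
reaching the observed `F`.

Classification uses LDA with **equal priors** (matching the balanced-design
logic of the resampling; scikit-learn's implementation). The point estimate
and confusion matrix come from deterministic LOO over the full sample; the
confidence interval is the 2.5–97.5 percentile range of LOO accuracies over
balanced resampled designs. Squared Mahalanobis distances between group
means use the pooled within-group covariance in the same `N`-dimensional
space; tables print `D = sqrt(D²)`. Groups smaller than six specimens
(the Przewalski sample) are held out of the main classification; each
held-out specimen's identification probability per group is the fraction of
balanced resampled discriminant fits assigning it to that group.

## Disparity

Total disparity is the Procrustes variance: the summed squared deviation of
specimens from the grand mean over `n − 1`. Foote's partial disparity of
group `g` is `PD_g = Σ_{i∈g} d²(x_i, x̄_grand) / (n_total − 1)`, measured
against the **grand** mean so that group contributions are exactly additive
to the total. A `center="group"` variant (deviations from each group's own
mean) is available for sensitivity analysis; it omits the between-group
dispersion and is not additive.

## Modularity

The landmark correlation matrix contains absolute **congruence
coefficients**: for each landmark, the deviations of its `m` coordinates from
the mean position across all specimens form one vector, and the coefficient
for a pair of landmarks is the normalised inner product of their vectors.
For 62 landmarks this gives `C(62,2) = 1891` unique correlations.

Seventeen models are compared: four a-priori hypotheses (tissue origin with
two modules; the mammalian six-module scheme AON/CB/CV/MR/ORB/ZP; a
six-module functional scheme; a horse-specific face/braincase split), each in
four variants — (a) one within- and one between-module correlation, (b)
pooled within / separate between per module pair, (c) separate within /
pooled between, (d) separate within and between — plus a no-modularity null.
**The bundled hypothesis files are synthetic stand-ins constructed from the
anatomical descriptions of the 62 cranial landmarks**, not a published
assignment table; they are named `*_synthetic.txt` accordingly and any real
assignment table can be supplied in the same two-column format.

Each model partitions the 1891 correlations into sets. Within a set, the
correlations' Fisher z-transforms are modelled as Gaussian around
`atanh(rho)` with standard deviation `1/sqrt(n_specimens − 3)`; `rho` is fit
by grid search on `[0, 0.995]` in steps of 0.001. The model log-likelihood
sums over all correlations, the parameter count is `K = (#rho) + 1` (null:
`K = 2`), and models are ranked by `AICc = −2logL + 2K + 2K(K+1)/(n_corr −
K − 1)` with sample size `n_corr = 1891`. Empty sets (a module with a single
landmark has no within-module correlation) contribute no parameter. For
nested variants the fuller model's likelihood is never lower; for a
two-module hypothesis variants c and d induce the same partition (there is
only one module pair) and tie exactly.

For the winning hypothesis, each module's landmark subset is
**re-superimposed on its own** before computing per-module integration and
disparity, separately for domesticated horses (H) and pooled wild equids
(D/Z/P). Integration is the relative eigenvalue standard deviation of the
module's coordinate correlation matrix, `psi = sqrt(Σ(λ_i − λ̄)²/p) /
(λ̄·sqrt(p − 1))`, which is 0 at an identity correlation (no integration), 1
when one dimension carries everything, and equals `rho` exactly under an
exchangeable correlation of level `rho`. Module disparity reports both the
maximum and the mean Procrustes distance of specimens to the module
consensus; the comparison tables default to the maximum.

## The synthetic generator

`simulate.generate_dataset` emulates the statistical structure the analyses
assume rather than horse anatomy:

- a random mean shape that is exactly mirror-symmetric under the supplied
  pairing (midline landmarks on the symmetry plane);
- per-group mean offsets (symmetric displacement directions with a configured
  Frobenius norm);
- per-specimen symmetric deviations with block correlation: per axis, each
  independent landmark's deviation is `noise_sd · (sqrt(rho_b)·global +
  sqrt(rho_w − rho_b)·module + sqrt(1 − rho_w)·own)` with standard normal
  factors — exchangeable (compound-symmetry) correlation `rho_w` within a
  module and `rho_b` between modules — mirrored onto the paired side;
- independent Gaussian noise of scale `asymmetry_sd` breaking the symmetry;
- everything drawn from one seeded generator, so a seed fixes the dataset.

The `equid` preset fixes the study conditions: `k = 62`, `m = 3`, the
bundled cranial pairing, group sizes H 133 / Z 47 / D 31 / P 5, the
six-module assignment, `rho_within = 0.6`, `rho_between = 0.2`,
`noise_sd = 1.5` on a base shape of scale 50 (yielding Procrustes variances
of order 2e-3, the magnitude typical of cranial shape data), group offsets
placing zebras and donkeys as well-separated lineages and the Przewalski's
horses as a small displacement from the domestic horses, and
`asymmetry_sd = 0.3` for residual digitising asymmetry. These values were
fixed once as a realistic regime; they are conditions, not tuning knobs.

What the simulation does **not** emulate: allometry and size-correlated
shape, biomechanically plausible skull geometry, breed substructure within
the domestic sample, landmark-specific digitising error, and any difference
in integration *magnitude* between groups (both subsets share one covariance
model, so wild/domestic psi contrasts on simulated data reflect sampling and
group-offset geometry only). Tests passing on simulated data therefore
validate the estimators and the workflow, not any biological claim.

## Problem sizes and reproducibility

Library defaults are 1000 resampled designs and 999 permutations. The
bundled drivers and the acceptance script use 50–300 resamples and 499–999
permutations with `max_N = 10`, which stabilises the reported quantities to
the precision at which they are printed while keeping a full run in the
order of a minute on one CPU. Every stochastic stage takes an explicit seed;
the pipeline derives stage seeds by fixed offsets from the run seed, and
rerunning a config reproduces the output bundle bit for bit.

## Known limitations

- The EMMLi-style likelihood treats the 1891 correlations as independent
  observations; they are not (they share specimens), so AICc differences are
  a ranking device rather than calibrated evidence weights.
- Missing landmarks are rejected, not estimated.
- The congruence-coefficient convention for landmark correlations is one of
  several in use (per-axis correlation averaging is the main alternative);
  it is isolated in `landmark_correlation_matrix` and swappable.
- No sliding semilandmarks, no allometry regression, no phylogenetic
  correction.
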
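# Methods

## The health-space model

A health space is a 2-D embedding of graded health status. Each axis is
produced by one ordinal model fitted on axis-specific covariates: an
oxidation block (5 columns: age, sex, smoking, white-blood-cell and ALT
analogues) and a metabolism block (6 columns: age, sex, BMI,
triglyceride, HDL and glucose analogues), sharing age and sex. The
outcome is a J = 4 ordered label (healthy, one risk factor, two risk
factors, metabolic syndrome / disease).

The deep ordinal network (DONN) models all cumulative logits jointly,

    log Pr(Y > j | x) / Pr(Y ≤ j | x) = α_j + f(x)ᵀβ,

with a shared score `f(x)ᵀβ` and free threshold intercepts α_j. Because
the score is shared, the J−1 implied exceedance curves cannot cross as
a function of x; they can only cross if the fitted α are unordered,
which is not enforced during training but flagged afterwards
(`alpha_ordered`). In every training run of the test-suite conditions
the initialisation at the empirical cumulative log-odds makes the fitted
intercepts come out ordered.

The loss is the sum over thresholds of binary cross-entropies of the
exceedance indicators I(Y > j), evaluated in the numerically stable
softplus form `softplus(z) − z·t` (exact for |z| far beyond ±50). The
reported loss is the printed sum-over-samples form; the optimiser uses
the mean per minibatch so the learning rate is insensitive to batch
size.

### Training

Adam (lr 0.001, β₁ 0.9, β₂ 0.999), batch size 100, up to 150 epochs.
A 10% random validation split is held out; training stops after 10
epochs without improvement of the monitored loss and the best-epoch
parameters are restored. The monitored loss is the validation loss by
default; `monitor="train"` tracks the training loss instead, which is
the right choice when the objective is convex (zero hidden layers) and
the fit is meant to approximate a maximum-likelihood solution rather
than to generalise. Covariates are z-scored with training-split-side
statistics stored in the results object and reapplied to new data.
Everything (split, init, batch order) derives from one integer seed, so
fits are bit-reproducible.

The networks are small (p ≤ 6 inputs, hidden widths 32 and 16 chosen as
a sensible default for tabular inputs of this width), so the forward
and backward passes are implemented directly in numpy; a fit of
n = 20,000 rows takes on the order of a second.

Hidden representation and β are only identified jointly up to
scale/rotation; all recovery claims therefore target the composite
score (rank correlation with the true latent predictor) and the
predicted probabilities, never individual network weights.

### Binary variants and baseline

The four binary-DNN comparators use the identical architecture,
optimiser and hyperparameters with J = 2: `0 vs 3` drops the
intermediate groups and fits only the extremes (all rows are still
scored afterwards); the other three threshold the label at j = 0, 1, 2.
The proportional-odds baseline is fitted by maximum likelihood via
statsmodels' ordered-logit model and re-expressed in the same
"Y > j" orientation (α = −thresholds) so its linear predictor xᵀβ is
directly comparable as a health score.

## Score normalisation and orientation

Raw axis scores are unbounded linear predictors. Each axis is oriented
so that larger = worse: if the fitted score correlates negatively
(Spearman) with the ordinal label on the training cohort, its sign is
flipped and the flip recorded. Scores are then mapped to [0, 1] by
training-set min–max (training min/max hit 0 and 1 exactly; external
cohorts are clamped, with a count of clamped points kept), or
alternatively by a sigmoid centred at the mean fitted threshold. The
min–max option is the default because it reproduces an exact [0, 1]
range; the choice and all constants are recorded in the score metadata
and frozen at training time, so external cohorts are always scored on
the training scale without refitting.

## Health Space Index

Group separation is summarised by confidence-ellipse overlap. For each
group with at least 3 points, the ellipse is
{z : (z−c)ᵀΣ⁻¹(z−c) ≤ χ²₂(0.95)} with c and Σ the sample mean and
covariance (ridge 1e−8 added if singular, with a warning). The overlap
of a pair is the Jaccard index of the two elliptical regions —
intersection over union area — computed by indicator integration on a
512×512 grid over the 5%-padded union bounding box (error ≈ 1/512
relative), or by 200,000 uniform Monte-Carlo points (SE ≈ 0.001);
clearly disjoint ellipses short-circuit to exactly 0. The pairwise index
is 1 − Jaccard, so higher = better separated, and a model's score is
the unweighted mean over the 6 pairs of 4 groups. The construction —
confidence level, covariance estimator, overlap algorithm — follows the
common mean/covariance-ellipse convention with every constant exposed
as an argument; it is this package's own concrete realisation of the
index, so numeric parity with other implementations is not claimed.

Properties verified by the test suite: values in [0, 1]; exactly 1 for
far-apart groups and ~0 for identical clouds; invariance of every
pairwise value under a common affine map of all points; monotone
non-decrease as a group is translated away; grid/Monte-Carlo agreement
within 0.01; the two-circle case against the analytic lens area.

Clustering indices (silhouette, Davies-Bouldin, Calinski-Harabasz) are
computed with Euclidean distance on the normalized scores with the given
group labels, via scikit-learn, and are checked exactly (1e−10) against
brute-force implementations. Conventions for degenerate input: one
group is an error; singleton clusters contribute silhouette 0;
coincident centroids make Davies-Bouldin an error naming the pair; zero
within-cluster dispersion yields an infinite Calinski-Harabasz with a
warning.

## Model comparison and bootstrap

`evaluate_models` fits each of the six models once per axis on the
training cohort and scores any number of cohorts; external cohorts
never touch the fitted parameters or normalisation constants (verified
by hashing parameters before/after). `bootstrap_hsi` resamples the
training cohort with replacement, refits the model per replicate
(default; `refit=False` keeps the full-data fit and varies only the
scored sample) and reports the mean and percentile 95% CI of the
average HSI over B replicates; evaluation is on the replicate itself by
default, or out-of-bag with `out_of_bag=True` — both are offered
because either convention is defensible for measuring training-data
variability. Replicates missing a category the model needs are redrawn
(at most 10 times).

## Synthetic cohorts

The generator draws continuous covariates as standard normals and the
sex/smoking analogues as Bernoulli(0.5), with the first two columns
shared between blocks, then samples the label from

    Pr(Y > j | x) = σ((α_j + g(x)) / noise_scale),

where g is linear in the true block coefficients plus an optional
quadratic (c·age²) or interaction (c·age·sex) term, via inverse-CDF
sampling with one uniform draw per row. `noise_scale` = 1 is the exact
cumulative-logit model (required for clean parameter-recovery tests);
larger values blur the groups. Default true parameters (α = (2, 0, −2),
moderate mixed-sign β) give four reasonably balanced groups.

What the generator does *not* emulate: realistic covariate marginals or
correlations of survey data, missingness, measurement error, or the
clinical diagnosis-based derivation of group membership. Passing tests
therefore demonstrate correctness of the algorithms and qualitative
behaviour (e.g. neural models beating the linear baseline when the
generating process is nonlinear), not performance on any real cohort.

## Problem sizes

Defaults chosen as the package's study conditions: recovery experiments
at n = 20,000; the nonlinear DONN-vs-POM comparison on n = 5,000
cohorts over 5 seeds; the acceptance pipeline on n = 4,000 training /
n = 2,000 external cohorts with a B = 20 refitting bootstrap; unit
tests on 500–1,500-row cohorts with reduced epochs. The full-scale
procedure (e.g. B = 200) is available through the same arguments.

## Known limitations

- The ellipse-based index ignores within-group multimodality; a bimodal
  group gets one ellipse.
- Min–max normalisation is sensitive to single extreme training scores;
  the sigmoid alternative trades exact range for robustness.
- Binary 0-vs-3 models are fitted on a subset and can be overconfident
  when scoring intermediate groups.
- DONN intercept ordering is diagnosed, not constrained; severely
  under-sampled categories could produce unordered thresholds.
- The bootstrap refits with the replicate-derived seed, so its CI
  includes optimisation noise as well as sampling noise — intentional,
  since both are part of training-pipeline variability.
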
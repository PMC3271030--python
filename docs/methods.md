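# Methods

This note records the statistical model behind `healthspace`, the defaults
and the reasoning for the choices that were genuinely open.

## The health-space model

A placebo-controlled cross-over study measures each subject under both a
treated and a control (placebo) arm, typically at a baseline timepoint and
one or more later timepoints per period.  The method projects every
(subject, arm) observation into a space whose axes are *predefined
biological processes*; points near the origin resemble the average treated
state ("health" is defined operationally as the treated-group mean), points
near 1 resemble the average control state.

### Feature construction (`datamodel`)

Each axis lists its parameters with a feature kind: `baseline` (the value
at the earliest timepoint of that arm's period) and/or `mean_over_time`
(the arithmetic mean over all of that subject-arm's timepoints).  Baselines
are per-period, not study-global: after a wash-out, each cross-over period
has its own defensible starting state.  Rows are one per (subject, arm),
ordered arm-major (treated block first, subjects sorted within arm) so fold
assignment and exports are deterministic; the arm code is treated = 0,
control = 1, which also fixes the orientation of all downstream scores and
removes the usual PLS-DA sign ambiguity.

Missing data policy: a parameter column with more than 20% missing entries
is dropped from feature construction with a warning; sparser gaps are
imputed with the column mean within the same arm.  Mean imputation is the
least structured choice; anything smarter would inject assumptions the rest
of the pipeline cannot check.

### Per-axis PLS-DA with double cross-validation (`plsda`)

Each axis is a univariate-response PLS regression (NIPALS PLS1) of the arm
code on the autoscaled axis features.  Autoscaling uses the sample standard
deviation (n−1); zero-variance columns are centred, divided by 1 and
flagged rather than failed.  With as many components as the rank of the
centred design, PLS predictions coincide with ordinary least squares — the
test suite uses this, a closed-form simple-regression case, and
scikit-learn's `PLSRegression` as independent oracles.

Model complexity is selected by nested (double) cross-validation:

* **outer loop** — subjects are partitioned into `outer_folds` (default 7)
  groups; both arms of a subject always share a fold, so a held-out subject
  is never seen by the model that scores it, including its autoscaling
  constants;
* **inner loop** — within each outer training set, `inner_folds`
  (default 5) subject folds select the component count (1 …
  `max_components`, default 5) minimising the inner misclassification rate
  (prediction ≥ 0.5 ⇒ control); ties go to fewer components.  An RMSE
  criterion is available.

Published descriptions of this design rarely state fold counts, so 7/5 were
fixed once as round numbers giving ≥ 4 subjects per outer fold at the
default study size; they are configurable and every fold assignment derives
from the run seed.

The scores consumed downstream are the **out-of-fold prediction scores**
(unbiased; a label-permutation test in the suite verifies the mean null
misclassification sits at 0.5, which a non-nested CV would fail).  A refit
all-data model is always stored for projecting new subjects; the
refit-minus-oof anchor offset is reported as a diagnostic.

### Anchor scaling (`space`)

Per axis, all scores (both groups simultaneously) are mapped by
`s' = (s − m_T)/(m_C − m_T)` where `m_T`/`m_C` are the treated/control mean
scores (out-of-fold by default).  The treated mean lands exactly at 0 and
the control mean at 1, making scores comparable within an axis while
deliberately preventing quantitative comparison between axes — the axes
share parameters and are biologically interdependent, hence statistically
non-orthogonal; they are merely *displayed* on orthogonal plot axes.  An
axis whose group means coincide (span below 1e-12) cannot be anchored and
raises a degeneracy error; an axis whose out-of-fold misclassification is
≥ 0.4 triggers an "uninformative axis" warning.  Anchors, autoscaling
constants and regression vectors are serialized to a versioned JSON schema
so new subjects can be projected into an existing space without
re-estimation.

### Response vectors, clustering, outliers (`response`)

A subject's response is the per-axis difference control − treated of the
anchored scores, so a positive component means the treatment moved the
subject toward the healthy origin.  The sign convention is configurable.
Vectors are clustered by agglomerative hierarchical clustering with
Euclidean distance and average (UPGMA) linkage on the raw vectors — no
additional scaling — and cut at k clusters (default 2).  An automatic cut
(largest relative merge-height gap, k ≤ 6) exists for exploration and never
overrides an explicit k.  Cluster labels are renumbered by first appearance
in subject order, making the labelling deterministic and order-invariant.

Outlier rule: iteratively, a subject is flagged when it forms a singleton
branch at the top split of the tree *and* that merge height exceeds 3× the
median pairwise distance.  Flagged subjects (and any explicit exclusion
list) are removed from cluster labels but retained in all exports.  The
3× factor is deliberately conservative: on homogeneous Gaussian clouds the
false-flag rate is below 5% (tested over 50 seeds).

### Cluster characterization (`subgroups`)

Per parameter, a fixed-effects two-way ANOVA with factors cluster and
treatment is fitted on **per-subject-arm means** (one value per subject per
arm), so timepoints are never pseudo-replicated.  The interaction is tested
first; only parameters whose interaction is not significant have their main
effects interpreted.  Sums of squares are Type II (each effect adjusted for
the other main effect, the interaction excluded when testing mains), which
matches the interaction-first logic on the naturally unbalanced cluster
factor; Type III with sum-to-zero coding is available.  The F statistics
are computed by residual-sum-of-squares comparison of nested least-squares
fits — a dedicated implementation, because the characterization stage runs
tens of thousands of small ANOVAs in calibration studies; it is verified
against `statsmodels.anova_lm` to 1e-8 in the suite.

FDR families: the interaction p-values of all testable parameters form one
BH family; the parameters with non-significant interaction then form one
family per main effect.  The verdict per parameter is `interaction` when
the interaction survives FDR at α (default 0.05), otherwise the surviving
main effect with the smaller q (`cluster_main` wins ties), otherwise
`none`.  Constant or incomplete parameters are reported with verdict
`none` and a warning.  A subject-level random intercept is *not* modelled
(no mixed-effects ANOVA by design), which makes the test conservative for
parameters with large stable between-subject differences.

## The synthetic-study generator (`synth`)

The generator emulates the target design: `n_subjects` (default 33)
subjects, each measured under both arms at `n_timepoints` (default 2)
timepoints per period; parameters in named process blocks (defaults 7
oxidation, 18 inflammation, 115 metabolism — the `no-diet` preset uses
5/15/114); all parameters carry a treatment effect by default
(`frac_affected` = 1), since process axes are built from
treatment-responsive parameters.

The value model is

```
x[i, j, arm, t] = b[i, j] + eps[i, j, arm, t]
                + 1{arm = treated, j affected, t > t0} * d[block(j)] * m[group(i), block(j)]
```

with `b ~ N(0, subject_sd²)` a subject–parameter intercept shared across
arms and timepoints (default SD 1), `eps` zero-mean Gaussian noise with
within-block equicorrelation `within_block_corr` (default 0.3, implemented
as a shared block factor per sample) and scale `noise_sd` (default 1),
block effect sizes `d` (default 1, a standardized shift), and subgroup
multipliers `m`.  The default two subgroups (50/50) are
inflammation/oxidation responders (multipliers 1.5/1.5/0.3) and metabolic
responders (0.3/0.3/1.5).  Effects appear only at post-baseline timepoints
of the treated arm.  All randomness flows from one `numpy` generator seeded
by the config, so identical config + seed is byte-identical.

What the generator does *not* emulate: real metabolite identities and
scales, log-normal/heavy-tailed concentration distributions, period or
order effects (reported absent in the motivating design), drift over
timepoints, and platform-specific missingness.  Passing recovery tests on
this generator therefore demonstrates the pipeline's mechanics —
leakage-free scoring, correct anchoring, correct clustering and testing —
not performance on any real cohort.

### A note on attainable recovery at the default settings

Two structural facts limit subgroup recovery at the default effect size
d = 1.  First, the treatment effect exists only at post-baseline timepoints
while axis features average all timepoints of a period, so the realized
per-feature shift is d/2.  Second, the equicorrelated block noise shares a
factor across all parameters of a block — the same direction in feature
space as the planted (uniform) treatment shift — so no linear axis model
can separate it from signal; it survives into the response vectors with
per-axis SD comparable to the planted between-subgroup gap.  Consequently
per-subject subgroup assignment at d = 1 sits near chance even for an
oracle axis (a fact the acceptance suite reports honestly), although the
*group-level* response pattern (which processes each subgroup moved on) is
recovered clearly.  Sharper per-subject recovery requires either larger
planted effects, weaker shared-block noise, or subgroup contrasts that are
not parallel to the shared noise direction.

## Problem sizes used in the checks

Oracle-equivalence checks (PLS vs OLS, UPGMA vs brute force, ANOVA vs GLM)
run at n ≤ 24 where exhaustive oracles are exact.  Calibration checks use
reduced studies chosen once: the null-FDR screen runs 100 seeds at 20
subjects with 4/4/8 parameter blocks (calibration does not depend on block
sizes), double-CV honesty runs 20 seeds at 20 subjects × 50 features, and
the subgroup-recovery and planted-interaction checks run 50 seeds at the
full default design (33 subjects, 7/18/115).

## Known limitations

* Two arms only; the method is defined for a binary contrast.
* No weighting of parameters within an axis; every feature enters the
  autoscaled PLS on equal footing.
* No mixed-effects/repeated-measures ANOVA in the characterization stage.
* `project` (scoring new subjects in a frozen space) is an enabling
  extension beyond the core construction; anchors are not re-estimated, so
  projected cohorts inherit the training cohort's calibration.
* No absolute cross-study "health" calibration: the origin is defined by
  the treated group of the study at hand.
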
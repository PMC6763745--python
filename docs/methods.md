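# Methods

This note documents the models, procedures and numerical choices behind
fcpipe, and what the synthetic test bed does and does not establish about
real data.

## Connectivity features

Per subject, functional connectivity is the sample Pearson correlation
between every pair of region time series. Features are the
variance-normalized Fisher transform of the upper triangle,

    Z_ij = sqrt(n - 3) * arctanh(r_ij),

with `n` the subject's own timepoint count. The `sqrt(n - 3)` factor is
the reciprocal of the asymptotic standard deviation of `arctanh(r)` under
independence, so null features are approximately standard normal
regardless of scan length — the property that makes edges comparable
across sites whose scans differ in duration. Each subject is transformed
with their own `n` (a pooled `n` would silently re-weight sites); the
plain `arctanh` variant is available via `variance_normalized=False` /
`--fisher-constant none` and recorded in the run manifest.

Numerical choices: correlations are clipped to |r| ≤ 1 − 1e−12 before
`arctanh`, so duplicate columns yield large finite features rather than
infinities; the correlation matrix is symmetrized and its diagonal pinned
to 1 to remove floating-point asymmetry from `numpy.corrcoef`.

### Exclusion policy

A region whose time series has zero variance (all-zero *or* constant —
Pearson correlation is undefined either way) is a "null region" hit.
After cerebellum removal and hit detection, the policy is: if at most
`subject_threshold` distinct subjects are affected, drop those subjects;
otherwise drop the affected regions for everyone. The default threshold
of 10 sits between the two regimes the policy must reproduce (a handful
of affected subjects → drop subjects; over a hundred → drop regions) and
is configurable, since only the extremes are externally anchored.

## Classification

ASD (+1) vs. TD (−1) is separated by a soft-margin linear-kernel SVM
(hinge loss, penalty `c` on slack, default `c = 1`, solver tolerance
1e−8 for reproducibility). No feature standardization and no class
reweighting are applied by default, and no hyperparameter search is
performed. The solver is scikit-learn's `SVC(kernel="linear")`; the unit
tests verify its solution against an independently coded dual quadratic
program to 1e−6.

Generalization is estimated by **leave-site-out cross-validation**: one
fold per acquisition site, trained on the remaining sites. This probes
transfer across batch effects rather than within-sample noise, which is
the relevant question for multi-site cohorts. AUC uses the rank
(Mann-Whitney) estimator with ties counted half; sensitivity counts ASD
as positive; fold aggregation reports mean and sample standard deviation
(ddof = 1).

## Permutation test on weights

To assign significance to individual edges, the classifier is fit once on
the true labels of the entire cohort (no cross-validation) and refit
under B label permutations; each edge's observed |w_j| is compared with
its own permutation distribution:

    p_j = (1 + #{b : |w_perm(b, j)| >= |w_obs(j)|}) / (B + 1).

The add-one estimator keeps p strictly positive and valid; at the default
B = 10,000 the minimum attainable p is ~1e−4, which resolves the
strictest reporting tier (p < 0.001). With B = 999 the minimum is exactly
1/1000, which passes the 0.005 tier but not 0.001; the result carries a
warning when B cannot resolve the strictest requested tier. Edges with
p < 0.01 are called over-connected when w_j > 0 and under-connected when
w_j < 0, reported at tiers 0.01 / 0.005 / 0.001 (an edge's tier is the
strictest threshold its p-value strictly passes), and tabulated by
unordered Mesulam division pairs. Permutation streams derive
deterministically from `(seed, b)`, so results are reproducible and
parallelizable-in-principle. Shuffles span all subjects; a
`stratify_by_site` flag restricts them within site for sensitivity
analysis (off by default).

This is deliberately a **per-edge screen with no multiple-testing
correction**, matching the tiered-threshold reporting convention it
implements; the run manifest records this prominently. A max-statistic or
FDR-corrected variant would answer a different (family-wise) question.

### Power regime

The per-edge weight test only has power when features outnumber subjects
(m > n), the regime connectome analyses live in (e.g. m = 5995 edges vs.
187 subjects). With true labels and a real group difference the margin is
wide, so *all* observed weights are small (‖w‖ scales inversely with the
margin); under permuted labels the fit spreads comparable weight over the
available features. When m < n, random-label fits concentrate large
weights on few features and swamp the observed ones, so nothing is
called. The property tests and acceptance checks therefore use m > n
configurations; users analysing low-dimensional feature sets should
prefer mass-univariate tests.

## Supporting statistics

- **Within-site matching**: Shapiro-Wilk (alpha 0.05) on each group gates
  a pooled-variance two-sample t-test (Welch by flag) vs. Mann-Whitney U.
  The U statistic is reported as a z-score from the normal approximation
  with continuity and tie correction; the exact null distribution is used
  when both groups have n ≤ 8.
- **Cross-site comparisons**: one-way ANOVA when every site's sample
  passes normality, else Kruskal-Wallis; post-hocs are pairwise tests of
  the same family with Bonferroni-multiplied p-values (capped at 1).
- **Benjamini-Hochberg**: standard step-up, largest k with
  p_(k) ≤ k·q/m (inclusive); implemented directly because the boundary
  convention matters, and cross-checked against statsmodels and an
  exhaustive oracle in the tests.
- **Site-effect screen**: run on control (TD) subjects only, so
  diagnosis-related differences cannot masquerade as site effects; each
  site's TD features are compared edge-wise against all other TD pooled,
  with BH FDR at q ≤ 0.05 across edges. Sites with fewer than 2 controls
  are skipped with a warning.
- **Clinical correlations**: Spearman rho computed as Pearson on average
  ranks with a two-sided t-approximation p (exactly what the test-suite
  oracle recomputes); missing scores are dropped pairwise, ADOS scores
  exist only for the ASD group so those correlations are ASD-only by
  construction, and FIQ is evaluated within each group separately.
  Correlations use the Fisher-normalized features, consistent with the
  classifier's input representation.

## Synthetic cohort generator

The generator defines the study conditions every stage is validated
under. Each subject's T×N series is drawn from a zero-mean multivariate
normal whose correlation matrix is the identity except for:

- **planted edges** — disjoint region pairs with group-specific target
  correlations (`r_asd > r_td` encodes over-connectivity); targets are
  enforced in the *population* matrix, so sample correlations estimate
  them without post-hoc manipulation;
- **site effects** — a symmetric per-edge perturbation drawn once per
  site, uniform in [−site_shift, +site_shift]. After perturbation the
  matrix must have minimum eigenvalue ≥ 1e−8; otherwise the perturbation
  is redrawn (up to 100 times, then the generator fails loudly).

Phenotypes are per-site, per-group normals: age is clipped into the
site's eligible range (default 6.5–13 years, so generated cohorts pass
the default selection funnel by construction), ADOS Gotham total and
severity are generated for ASD subjects only and clipped to their
instrument ranges ([0, 28] and [1, 10]) before rounding. A configurable
number of subjects receive one all-zero region column to exercise the
exclusion machinery.

The default four-site configuration reproduces a published pediatric
cohort's structure: sites KKI/NYU/UCLA/UM with ASD/TD counts 18/24,
33/23, 23/21, 28/20 (190 subjects; 102 ASD, 88 TD) and per-site
age/FIQ/ADOS means and standard deviations. Scan minutes are mapped to
timepoints at 30 volumes/minute (a nominal 2 s sampling interval) —
source tables report durations in minutes only, so the mapping is a
generator choice. Three null-region subjects are planted by default,
restricted to the three shorter-scan sites, so the exclusion stage
reduces 190 to 187 while the longest-scan site's held-out fold keeps all
48 subjects — mirroring the cohort structure in which the excluded
subjects did not come from that site. The default region count is N = 30
(m = 435 > 187 subjects, inside the test's power regime) to keep desk-
scale runs fast; N is configurable.

Randomness: one global seed; site perturbations, each subject's series
and the null-column placement are drawn from sub-streams derived from
`(seed, role, index)` via `numpy.random.SeedSequence`, so output is
bit-identical across runs and independent of generation order.

**What the generator does not emulate**: autocorrelated BOLD dynamics,
motion artifacts, physiological noise, preprocessing-pipeline variance,
hemodynamic differences between groups, or realistic network topology
(the background correlation structure is the identity). Passing tests
demonstrate that the *pipeline machinery* is correct and calibrated under
Gaussian conditions with known ground truth — not that the method's
published effect sizes or AUCs generalize, and not that the permutation
screen is robust to the dependence structure of real connectomes.

## Problem sizes in tests and acceptance checks

The statistical checks run at deliberately small scale: null calibration
uses 60 subjects × 20 regions × 200 permutations × 20 seeds;
ground-truth recovery one planted edge (Δr = 0.5) in 100 subjects at
T = 300 with B = 999; end-to-end determinism a 12-region run with B = 99.
These sizes were chosen so the whole suite recomputes every claim it
makes in a few minutes while staying in the regimes (m > n for the
permutation screen) where the method is meant to operate.

## Known limitations

- The permutation screen's per-edge p-values are not corrected across
  edges (by design, see above) and are granular at 1/(B+1).
- The exclusion-policy threshold between "drop subjects" and "drop
  regions" is an interpolation between two anchored extremes.
- `SiteSpec` models phenotypes as independent normals; real covariance
  between age, IQ and symptom scores is not emulated, so clinical
  correlations on default synthetic cohorts are null except through the
  planted FC structure.
- Partial correlation, tangent-space and dynamic connectivity estimators
  are out of scope, as are NIfTI volume I/O and voxel-level parcellation.
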
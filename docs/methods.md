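# Methods

`cfpreg` re-implements, as one tested pipeline over synthetic cohorts, two
linked analyses of longitudinal cell-free RNA (cfRNA) measured in maternal
plasma: (1) regression of time-to-delivery on placental transcript
abundances, and (2) classification of spontaneous preterm delivery
(delivery before 37 weeks) from a screened marker panel. The clinical
cohorts behind the original analyses are not publicly deposited, so the
package ships a synthetic-cohort generator that reproduces the statistical
structure those analyses rely on; all tests and the acceptance script run
against it. Everything below is the package's own account of what is
modelled and why.

## Synthetic cohorts

**Trajectories.** Each transcript g has an expected log10 relative
abundance mu_g(t) over gestational age t (decimal weeks), from one of three
families:

- *rise* — a 3-parameter logistic, b_g + A_g / (1 + exp(-s_g (t - m_g))),
  for placenta- and fetal-liver-specific transcripts whose plasma levels
  climb through gestation. Baseline b_g sits below the detection floor, so
  these transcripts vanish postpartum.
- *early_peak* — a lognormal-in-time bump peaking at m_g weeks in the first
  trimester (the CGB / chorionic gonadotropin pattern), then decaying.
- *rise_with_baseline* — a logistic rise on a detectable maternal floor,
  for immune and ubiquitous transcripts that persist after delivery.

Postpartum handling is a step: for t greater than the delivery age the
curve drops to b_g immediately. No decay constant is modelled because the
emulated data show a collapse within the first postpartum week.

**Noise and censoring.** Measurements are mu_g(t) plus Gaussian noise on
the log10 scale (multiplicative lognormal on the linear scale, matching
qPCR error behaviour), with per-gene SD around 0.2 decades. Values below
the limit of detection (LOD, default 0 on the log10 relative scale) are
left-censored to the LOD and flagged undetected rather than dropped, so
detection-based tests keep their inputs.

**Designs.** The default study layout mirrors the three-cohort structure:
a weekly-sampled term cohort split 21 train / 10 validation (enrollment
uniform in weeks 5-12, one draw per gestational week plus one postpartum
draw), and two sparse risk cohorts of 15 (8 preterm) and 23 (5 preterm)
women with one draw inside a stated gestational window. Preterm counts per
cohort are exact (round(fraction x n)), not binomial, so simulated cohorts
match the emulated group sizes. Term deliveries are normal(40, 1.25) weeks
truncated at >= 37; preterm deliveries are uniform(29, 36.5).

**Preterm effect.** `inject_preterm_effect` shifts preterm subjects'
values for chosen genes by g x (pooled preterm/term SD of the unmodified
table), so the realized standardized effect equals the requested Hedges' g
up to sampling error. The default panel effect is g = 1.2 on the seven
marker transcripts. For the sequencing stage, counts are negative binomial
with common dispersion phi (variance mu + phi mu^2; phi = 0 degenerates to
Poisson), library sizes lognormal around 2x10^5, and per-gene fold-changes
2^(g_seq x w_i x sqrt(phi)/ln 2) in preterm libraries, where the
deterministic weights w_i in [0.4, 1.6] spread effect sizes across genes
the way real screens do. One seed determines every output byte.

**What the generator does not emulate.** Gene-gene noise correlation
beyond shared trajectory shape, plate/batch effects, RNA degradation,
progesterone pharmacology, covariate structure (BMI, parity effects), and
any mechanistic pathway coupling. Passing tests therefore demonstrate that
the *procedures* behave as claimed under the assumed statistical structure,
not that the biological effect sizes are attainable in real plasma.

## Gestational-age model

The response for every antepartum draw is y = GA_delivery - GA_draw
(weeks); features are log10 abundances. The regressor is a random forest
(500 trees for final fits, sklearn defaults for feature subsampling,
`min_samples_leaf = 5`). The leaf floor is the package's smoothing choice
for noisy qPCR features: with fully grown trees, irrelevant features act as
a tree-decorrelating regularizer and can *lower* CV error, which defeats
subset-size selection; a modest leaf size removes that artifact.

**Subset selection.** True best-subset search over 51 genes is infeasible
(2^51 subsets), so selection is greedy forward search ranked by repeated
subject-level k-fold CV RMSE. Two safeguards matter:

- folds split *by woman*, never by sample — longitudinal draws of one
  pregnancy never straddle train and test;
- the greedy path's own scores suffer winner's curse (each step takes the
  minimum over many candidates), so every prefix of the path is re-scored
  on independent folds and the one-standard-error rule is applied to that
  unbiased trace: the smallest subset whose mean RMSE is within one SE of
  the minimum wins. Ties in candidate ranking break by gene symbol.

Default CV is 10-fold repeated 10 times; the packaged analysis and
acceptance runs use 5-fold repeated twice with 50-tree selection forests —
problem sizes chosen so a full run completes on one CPU in minutes — and
the recovery test suite uses a 12-gene candidate panel (3 staggered signal
risers + 9 flat nulls) with 30-tree selection forests at 20 seeds.

**Evaluation.** Training-cohort performance is reported on *out-of-fold*
predictions (subject-level 10-fold), validation on a disjoint cohort.
Per-trimester RMSE uses T1 <= 13 < T2 <= 27 < T3 (standard obstetric
convention, boundary to the earlier bin), PP for postpartum draws.
Postpartum RMSE is reported but is structurally poor here: the model trains
on antepartum draws only, and in the synthetic panel a postpartum profile
(placental signal collapsed) resembles early pregnancy, so trees extrapolate
badly. This is a known limitation of the antepartum-only training contract,
not a bug.

**Deviation table.** Per woman, the expected delivery GA for a trimester
set is the mean of (GA_draw + y_hat) over her draws in those trimesters;
the deviation is observed minus expected, binned into {< -2, -1 to -2,
+/-1, +1 to +2, > +2} weeks with boundaries assigned to the inner bin (the
printed bins overlap at their edges; this is the package's disambiguation).
The ultrasound-like baseline assumes delivery at 40 weeks from a
first-trimester GA estimate simulated as truth + normal(0, 0.7) weeks
error, since no imaging exists in this artifact. The "within 14 days"
metric is the fraction with |deviation| <= 2 weeks.

## Preterm discovery (counts)

Libraries are scaled to the geometric-mean library size and rounded (the
equal-library assumption of the conditional exact test; the original
normalization is not public, so this stand-in is logged in output
metadata). Dispersion is a pooled method-of-moments estimate: least-squares
regression through the origin of (var - mean) on mean^2 across all (gene,
group) cells, truncated at zero. It is adequate for a common-dispersion
exact test but mildly biased low at very small group sizes; no
tagwise/trended shrinkage is attempted.

**NB exact test.** Conditional on a gene's total count, the group-1
subtotal has a distribution proportional to the product of two NB pmfs with
sizes n1/phi and n2/phi; the success probability cancels, leaving pure
gamma-function weights. The two-sided p doubles the smaller tail
probability, capped at 1 (the construction is otherwise ambiguous). phi = 0
reduces exactly to a binomial(total, n1/(n1+n2)) split test, and the
implementation is verified against full enumeration for small totals.

**Second screen.** The parametric GLM tests used alongside the exact test
in the emulated analysis are out of scope; a seeded two-sided permutation
test on the difference of group-mean log2 CPM substitutes (exhaustive over
label splits when that is cheaper than the requested draws; otherwise
p = (1 + #extreme)/(n_perm + 1) with n_perm = 4999, giving a p floor of
2x10^-4 so the p < 0.001 intersection rule remains attainable). A gene is
*significant* only when both tests give p < 0.001. The intersection
inherits the permutation test's power ceiling at 8 vs 7 libraries: with a
standardized log-scale effect of 2 the per-gene probability of a
permutation p < 0.001 is roughly 0.35-0.4, so the intersection calls far
fewer genes than the exact test alone. The tests freeze bounds derived from
simulation at these sizes rather than aspirational counts.

**Clustering and concordance.** Sample clustering is agglomerative
(Euclidean, average linkage) on per-gene z-scores cut at two clusters, with
agreement defined as the best label-pairing accuracy. Cross-platform
concordance is the Pearson r between per-gene log2 fold-changes from the
count stage and from an independently simulated qPCR replication of the
same genes.

## Preterm classifier

The screen computes, per panel gene, Hedges' g (pooled-SD standardized mean
difference with small-sample factor J = 1 - 3/(4(n1+n2) - 9)),
a permutation p for the mean difference, Benjamini-Hochberg q-values over
the panel, and a Fisher exact test on 2x2 counts of samples above/below the
term-group median split by outcome (the dichotomization is a config choice;
nothing in the emulated analysis pins it). A gene *passes* at q <= 0.05 and
g >= 0.8; the classifier uses the top seven genes ranked by descending g
(ties by symbol), mirroring the emulated design where exactly seven genes
passed. At 8 preterm vs 26 term samples the strict passing list is itself
noisy — per-gene passing probability is about 0.55 at a true g of 1.2 —
which is why ranking, not the pass/fail cut, feeds the ensemble.

Every unique 3-gene combination of those genes scores a sample by the mean
z-score of its genes against the *term-group training reference* (mean and
SD per gene; zero-SD genes are dropped with a warning). Each combination
gets an operating threshold maximizing Youden's J on training data; the
ensemble predicts preterm when at least half the combinations fire
(vote threshold 0.5, config-exposed). Reported "mean AUC" is the arithmetic
mean of per-combination pair-counting AUCs (ties count 1/2), on training
data for the discovery cohort and on the subject-disjoint validation
cohort. One shared decision rule is used for all combinations; per-combo
bespoke rules are not modelled.

## Numerical and design notes

- All randomness flows from one integer seed; pipeline stages derive their
  own seeds as (seed x 1000003 + crc32(stage)) mod 2^31, so any stage can be
  re-run alone and reproduce its outputs byte for byte.
- Correlation analysis uses per-gestational-week mean profiles, antepartum
  weeks only; constant profiles give a *missing* correlation, never 0.
  Heatmap ordering canonicalizes genes lexicographically before
  average-linkage clustering on 1 - r, making the leaf order invariant to
  input column permutations.
- BH q-values use the step-up formula with enforced monotonicity; Fisher's
  test sums hypergeometric probabilities <= the observed table's (with a
  1 + 1e-7 relative guard against floating-point ties, the convention used
  by standard implementations).
- Degenerate inputs have defined behaviour throughout: zero pooled SD gives
  signed-infinite g with a warning (excluded from screens), zero-margin
  2x2 tables give p = 1 with a flag, zero-count libraries are excluded from
  CPM, singleton correlation groups give missing medians with a warning.
- Relative abundance follows the delta-Ct convention 2^(Ct_ref - Ct)
  against a designated reference assay; the chosen convention is recorded in
  the matrix metadata sidecar.

## Known limitations

- Headline numbers of the emulated study (fit r, per-trimester RMSE,
  AUCs, confusion counts) are not reproduction targets: they depend on
  undeposited clinical data. The pipeline reports the analogous quantities
  computed on its synthetic cohorts.
- The permutation-test substitute caps the DE intersection rule's power at
  small n (see above); conclusions about "number of significant genes" in
  pipeline reports reflect that ceiling.
- Postpartum time-to-delivery predictions are unreliable by construction
  (antepartum-only training).
- The dispersion estimator is a pooled moment estimator, biased low by
  ~20-40% at 7-8 samples per group; the exact test tolerates this but
  borderline p-values near the 0.001 cut can shift.
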
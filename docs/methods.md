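# Methods

This note documents the models behind `noisecare`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions the implementation commits to.

## Noise dosimetry

All decibel arithmetic happens in the power domain (`10^(L/10)`); values
are only rounded for presentation. The daily personal noise exposure level
follows ISO 9612: `LAeq,Te` is the duration-weighted energetic mean of
workstation levels over the effective duration `Te = Σ t_i`, and
`LEP,d = LAeq,Te + 10·log10(Te/T0)` with the reference duration fixed at
`T0 = 8 h`. Shift length is not assumed; `Te` always comes from the
supplied task durations.

Exposure categories use *closed* boundaries for the middle band: below
50 dBA is low, 50–60 dBA inclusive is moderate, above 60 dBA is high. The
verbal rule "less than 50 … 50 to 60 … higher than 60" puts both boundary
values in the moderate band, and the implementation documents exactly that.

A noise map is one energetic mean per measurement point over its repeated
readings. Conflicting coordinates or departments for a single point id are
an error rather than silently collapsed.

## Questionnaire scoring

* **Weinstein noise sensitivity**: 21 items scored 0–5, total 0–105. The
  0-based item coding is forced by the 0–105 total range. Reverse-keying is
  configurable and defaults to *none*, since no standard key is bundled;
  a reversed item contributes `5 − raw`.
* **Annoyance**: a single 0–100 visual-analogue value; no item structure.
* **Quality of patient care**: 65 items scored 1–4 in three subscales
  (psychosocial 28, communicational 13, physical 24). Fixed cut-offs:
  total <130 / 130–195 / 196–260; psychosocial <56 / 56–84 / 85–112;
  communicational <26 / 26–39 / 40–52; physical <48 / 48–72 / 73–96. The
  middle band is labelled `partly_desirable` throughout.

Percentile-based categories (sensitivity, annoyance) use the sample's own
quartiles under the linear-interpolation definition (Hyndman–Fan type 7,
numpy's default): strictly below Q25 → low, strictly above Q75 → high,
ties and the interior → moderate. On continuous scores this converges to
25/50/25% shares.

Cronbach's alpha is the standard `k/(k−1)·(1 − Σ var(item)/var(total))`
with sample (ddof = 1) variances.

**Item imputation** runs EM under a multivariate-normal working model:
conditional means given the observed cells, with the conditional covariance
feeding the second-moment update, iterated to parameter convergence
(ridge 1e-6 for numerical stability), then rounded and clipped into the
item's legal range. Records missing more than 20% of their items (default,
configurable) are excluded and flagged rather than imputed. This routine is
for *numeric item matrices*; categorical missingness at the network level
is instead handled natively by EM parameter learning, which needs no
pre-imputation.

## The Bayesian network

Seven ternary nodes with fixed state orders — `low/moderate/high` for the
noise variables, `undesirable/partly_desirable/desirable` for care — and
the expert arc set (15 arcs): exposure→sensitivity; exposure and
sensitivity→annoyance; exposure, sensitivity and annoyance→each care
aspect; the three aspects→overall quality. A packaged 4-node alternative
(`table3_network.json`) conditions quality *directly* on the three noise
variables and carries a published conditional table for it, with parent
priors set to the published category frequencies; both parameterizations
appear in the source material and both are supported. One published row of
that table prints as (0.273, 0.455, 0.273), which sums to 1.001; the
fixture stores the evident unrounded values 3/11, 5/11, 3/11.

* **Inference** is exact variable elimination with a greedy min-fill
  ordering, validated in the test suite against brute-force enumeration of
  the full joint on random networks of up to 8 ternary nodes (agreement to
  1e-9). Evidence with zero marginal probability raises an error rather
  than returning a zero vector.
* **EM learning** handles missing categorical cells exactly: the E-step
  enumerates each incomplete record's completions and weights them by
  their joint probability under the current parameters; the M-step
  normalizes expected family counts. Parent configurations with zero
  expected count receive the uniform row — the same convention visible in
  published tables as 0.333/0.333/0.334 rows. Initialization is uniform
  rows with seeded Dirichlet jitter (concentration 50) to break symmetry;
  a single start by default. The observed-data log-likelihood is recorded
  per iteration and must be non-decreasing; a decrease raises an error
  because it can only indicate an implementation bug. Convergence is an
  improvement below `tol = 1e-6` or `max_iter = 100`. No smoothing
  pseudo-counts are added by default (published tables contain exact 0.000
  and 1.000 entries); Laplace smoothing is available behind a flag.
* **Prediction** is the maximum-posterior state; exact ties break by the
  declared state order.

## Delta-p and influence values

Delta-p clamps an evidence assignment (one or several nodes) at 100% and
reports, per node and state, `posterior − prior` in percentage points.
Deltas across a node's states sum to zero by construction; an evidence
node's own clamped state shows `100 − prior`. Presentation rounds to whole
points with an explicit sign (`+13%`, `−21%`); machine output keeps full
precision.

The influence value of an arc is not given a formula in the source
material, so the package defines it explicitly and configurably: the mean,
over all co-parent configurations and all unordered pairs of the parent's
states, of the Euclidean distance between the child's two conditional
distributions. It is zero iff the child's distribution ignores the parent,
and reaches √2 for a maximal binary flip. Hellinger distance (bounded by
1) is available as an alternative metric. Rankings sort descending with
ties broken by (parent, child) name order.

## Cross-validation

Records are shuffled with a seeded generator and split into k near-equal
folds (sizes differ by at most one; 209 records in 10 folds gives nine of
21 and one of 20). Unstratified splitting is the default — matching a
plain random division — with stratification available because a rare class
(about 9% undesirable at n = 209) makes empty-class training folds
plausible. Per fold, CPTs are re-learned by EM on the training folds and
each held-out record's quality category is predicted with *all other
variables observed* as evidence — the maximal-information default, since
nothing narrower is canonical. When the unsmoothed fold model assigns a
held-out evidence combination probability zero, the prediction falls back
to the target's prior marginal (with a warning) rather than failing.

Reported metrics: the aggregated 3×3 confusion matrix (fixed state order),
accuracy, macro one-vs-rest recall ("sensitivity") and true-negative rate
("specificity") — macro averaging is stated explicitly because a single
printed value for a 3-class problem is otherwise ambiguous — and
one-vs-rest trapezoidal AUC per class plus the unweighted macro mean,
computed from held-out posteriors. Degenerate classes (no positives or no
negatives) are skipped with a warning.

## The synthetic-data generator

The generator exists so the full pipeline is exercisable without the
(undeposited) study data. It emulates:

* a ground-truth network over the seven variables whose default CPTs are
  documented constants calibrated so sampled marginals approximate the
  published category frequencies (root prior = published counts/209;
  child rows are the target marginal log-linearly tilted per parent level,
  with tilt strengths chosen so that exposure drives annoyance more
  strongly than sensitivity does, and the aspects couple tightly to
  overall quality). These defaults are *not* the study's unpublished
  fitted parameters;
* ancestral sampling of category-level cohorts (default n = 209);
* item-level expansion: a target total drawn inside the category's score
  band and distributed over items by a constrained multinomial; quality
  subscale totals are drawn jointly so subscale and total categories hold
  simultaneously, resampling the subscale categories (with a warning) for
  combinations whose score bands cannot intersect;
* a measurement grid (10 repeats per point, Gaussian around department
  base levels spanning 46.5–64 dBA on a 5 m lattice) plus two-workstation
  assignments per nurse whose recomputed LEP,d lands in the assigned
  exposure category by construction;
* missing-completely-at-random cell deletion (default rate 0.05; the
  source material does not report its missingness rate, so it is left
  configurable).

One structural fact deserves emphasis: for percentile-categorized scales,
at most `ceil(0.25·(n−1))` sample values can lie strictly below the 25th
percentile, so a cohort in which more than ~25% of records carry the
"low" (or "high") category *cannot* be realized exactly by any score
assignment. The expansion therefore relabels the minimal number of surplus
records to "moderate", warns, and returns the updated table; the
round-trip identity (expand → rescore reproduces every category) holds on
the returned table. Quartile anchors are pinned by tying the extreme
moderate scores to their band edges so the interpolated percentiles land
exactly on category boundaries.

What the generator does **not** emulate: item-level responses correlated
beyond what the category bands impose, non-MCAR missingness, spatial
autocorrelation of noise beyond department means, or pandemic-era effects.
Passing tests therefore demonstrate that the *algorithms* are correct and
the pipeline is self-consistent, not that real cohorts share these
distributions.

## Problem sizes and statistical power of the test suite

The suite runs at deliberately modest sizes chosen for statistical
adequacy: inference is cross-checked on 200 random networks; EM parameter
recovery uses a complete n = 5000 cohort from a chain truth net whose
mixing rows are bounded away from the simplex boundary, so every parent
configuration carries roughly 1700 expected counts and the total-variation
bound of 0.05 sits several standard errors above pure sampling noise;
chance-level classification uses n = 3000; marginal checks use n = 50000
draws against a ±0.02 binomial band. The end-to-end report runs the full
n = 209 pipeline with a 150-point grid.

## Known limitations

* Noise is summarized by level only; frequency content and psychoacoustic
  indices are out of scope.
* The influence-value metric is a package definition (documented above),
  so its numerical values are not comparable across tools that define the
  quantity differently.
* EM uses a single start by default; multimodal likelihoods from heavily
  missing data may benefit from the multi-start option.
* The MVN working model for item imputation treats ordinal items as
  continuous and relies on rounding/clipping; for heavily skewed items a
  latent-ordinal model would be more faithful.
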
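# Methods

## The problem

Predicting which locally advanced rectal cancer (LARC) patients will
respond to neoadjuvant chemoradiation (nCRT) from a pre-treatment tumor
expression profile. Absolute expression values transfer poorly between
cohorts: platform, batch and normalization differences swamp moderate
biological signals. This package therefore works entirely with
**within-sample relative expression orderings (REOs)**: for a gene pair
(a, b) and one sample, the only datum used is whether G_a > G_b. Any
strictly increasing transform of one sample's values — a batch effect
surrogate, a normalization choice, a platform monotonicity — leaves every
REO unchanged, so a classifier built on REOs needs no between-sample
normalization at all (none is performed anywhere in this package).

## The discovery procedure

1. **Reversal screen.** For every candidate gene pair, count the samples
   showing G_a > G_b in each class. A pair is a *reversal pair* when the
   majority orientation differs between responders and non-responders and
   the majority is statistically stable in **both** classes by an exact
   one-sided binomial test against 1/2 (default alpha 0.05 per class).
   Records are normalized so gene_a > gene_b is the responder-dominant
   direction. Design notes:
   - *Both-group criterion.* Requiring per-class stability (rather than a
     single pooled association test) is the strict reading standard in the
     REO / top-scoring-pair literature; a pooled variant was considered and
     rejected because it admits pairs whose "reversal" is driven by one
     class only. The one-sided tail on the dominant orientation is the
     default; a two-sided flag exists.
   - *Ties count as REVERSE* ("not strictly greater"): deterministic, no
     third state, measure-zero on continuous data.
   - *No multiple-testing correction*: the screen is deliberately
     permissive (raw p < alpha); the forest ranking downstream is the
     effective filter. On a null pair with 40 samples per class the
     probability of passing is ≈ 2·P(X ≥ 26 | 40, ½)² ≈ 3·10⁻³, so a
     124,750-pair enumeration admits a few hundred false pairs — by
     design, not by accident.
   - Full pairwise enumeration is refused above 2,000 genes (≈ 2M pairs)
     unless explicitly overridden; a top-variance pre-filter hook is
     provided but off by default.

2. **Random-forest ranking.** Each reversal pair becomes one binary
   feature per sample — 1 iff the sample shows the pair's responder
   orientation. This indicator is the only encoding that preserves exactly
   the rank information the screen used, keeping the whole chain
   REO-invariant. A Gini random forest is fit and pairs are ranked by mean
   decrease Gini (MDG). The published model's hyperparameters (ntree =
   2500, mtry = 88) are the defaults in the analysis scripts; mtry falls
   back to floor(sqrt(p)) when unset. Forest randomness is seeded, and the
   output records seed + scikit-learn version; forests are not bit-portable
   across libraries, so nothing downstream assumes bit-exact forests —
   ranking quality is asserted distributionally (a perfectly separating
   feature reaches rank 1 in ≥ 95/100 seeded runs).

3. **Best top-N selection.** Only prefixes of the MDG ranking are
   considered. For N = 1..n_max (default cap 500, configurable up to the
   full ranking) every training sample is classified by majority vote over
   the top-N pairs; the signature is the *smallest* N attaining the
   maximum resubstitution accuracy (parsimony on ties; no internal
   cross-validation — selection is defined on training accuracy). The full
   (N, accuracy) curve is retained in the signature's provenance.

## Applying a signature

A sample votes "response" on each evaluable pair with G_a > G_b. The
**response ratio** (votes / evaluable pairs) is the continuous score used
for ROC and high/low grouping; the hard label is a strict majority
(> half). An exact tie on an even pair count is called non-responder — the
conservative call, recommending no treatment benefit without majority
evidence. Pairs with genes missing from a platform are dropped per sample
(with a warning above 20% missing genes), so a signature discovered on one
array can be scored on another; a sample with zero evaluable pairs is an
error. Cohorts without response labels are split at the **median**
response-pair count (strictly above = high; ties at the median go low).

## Evaluation

Responders are the positive class. Sensitivity, specificity and accuracy
come with exact Clopper–Pearson 95% intervals (beta-quantile closed form).
AUC is the midrank Mann–Whitney statistic (equal to the trapezoidal area
under the empirical ROC curve) with a DeLong CI computed from placement
values; DeLong is implemented here because no pre-installed package
exposes it. Per-gene differential expression between classes uses Welch's
t-test (safer default than pooled variance when "t-test" is all that is
specified; a pooled variant would be a one-line change); genes with zero
variance in both classes report NA.

## Survival

Disease-free survival (months from surgery to relapse or last follow-up)
is compared between signature-defined groups with Kaplan–Meier curves and
the log-rank test, and with a Cox proportional-hazards model adjusted for
stage, age and gender (stage and gender as indicator contrasts, age
continuous). Tied event times use the Efron approximation (lifelines'
default; less biased than Breslow). Mean DFS per arm is reported as the
restricted mean survival time over the observed follow-up window — the
only mean well-defined under censoring; this is an interpretation, since
an "average survival time" under censoring is otherwise ambiguous.
Complete separation / monotone likelihood in the Cox fit surfaces as an
explicit error.

## The synthetic world

The generator emulates exactly the structure the method assumes:

- Per-gene baseline log2 means ~ Uniform(4, 12) (typical microarray
  range), Gaussian noise sd 1.0.
- Planted pairs: orientation forced to the responder direction with
  probability `stability_resp` in responders and `1 − stability_nonresp`
  in non-responders, by swapping the two values where needed. Swapping is
  applied to the final (noisy) values so the per-class orientation
  frequencies are **exact**, matching the binomial model of the screen.
  Both partners of a planted pair share a baseline mean so the planted
  signal lives in the ordering, not in abundance.
- Batch surrogates: per-sample strictly increasing distortions from a
  seeded family (affine, power on shifted-positive values, logistic warp).
- Survival: exponential DFS with baseline mean 48 months for
  non-responders (a realistic colorectal DFS scale) and hazard ×
  `hr_true` (default 0.25) for responders; independent censoring at the
  configured rate (default 30%), implemented as a Bernoulli censoring
  indicator with a uniform fractional censoring time, so the realized
  censoring fraction matches the rate.
- Reference world defaults: 500 genes, 50 planted pairs (100 planted
  genes, 400 null genes), 40 + 40 samples, stability 0.95 per class.
- The gene layout (means, planted pair assignment) and the per-sample
  draws come from separate seeded streams, so a train cohort and a
  held-out cohort can share one world.

What the generator does **not** emulate: gene–gene correlation structure,
probe-level effects, and platform-specific detection floors. A green
recovery test therefore establishes that the pipeline recovers planted
ordering signal through monotone distortion and noise — not that it would
reproduce any specific clinical cohort's results.

One known emergent property: forcing a pair's orientation shifts each
partner gene's class-conditional marginal (by up to ~1 SD), which makes
some pairs between a planted gene and a null gene genuinely class
informative. The screen finds these "induced" pairs along with null false
positives, so screen-level precision against the planted list is low
(~0.04 in the reference world) even at perfect recall; the forest ranking
concentrates the planted pairs at the top (typically ≥ 48 of the top 50),
which is the method's own design logic.

## Numerical choices

- Exact binomial tails everywhere (no normal approximation): class sizes
  in this domain are at most a few hundred.
- The screen's p-values are computed from the orientation counts under the
  *stored* (normalized) gene order, so tie handling stays consistent after
  normalization.
- Pair records are canonicalized lexicographically; MDG ties break by pair
  id, making rankings deterministic at a fixed seed.
- All randomness fans out from one top-level seed via
  `numpy.random.SeedSequence`; derived seeds are kept below 2³¹.

## Known limitations

- Selection considers only ranking prefixes (no subset search), and
  training accuracy is resubstitution accuracy — both by specification of
  the procedure, both optimistic relative to nested validation.
- The published signature's discovery run is not reproducible here:
  the original cohorts are external downloads, the original forest's seed
  is library-specific, and the screen's exact criterion in the original
  analysis is under-specified (the expected reversal-pair count on the
  original training cohort is documented, not asserted).
- Printed 95% CIs in the source study's results are narrower than exact
  Clopper–Pearson intervals at those sample sizes; this package implements
  the textbook interval and does not chase those widths.
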
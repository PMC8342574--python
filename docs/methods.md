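# Methods

## The twin model

`twinbiome` estimates how much of the between-woman variation in a
vaginal bacterial taxon's relative abundance is attributable to host
genetics, using the classical twin design.  Monozygotic (MZ) co-twins
share all segregating genes; dizygotic (DZ) co-twins share half on
average.  Both kinds of pairs share rearing environment.  If a taxon's
abundance correlates more strongly within MZ pairs than within DZ
pairs, the excess resemblance is evidence of additive genetic control.

The phenotype is `y = arcsin(sqrt(p))`, the arcsine-square-root
transform of the taxon's per-sample proportion, which approximately
stabilizes the variance of compositional proportions.  A twin pair's
phenotypes are modelled as bivariate normal with a shared mean mu and
covariance implied by additive-genetic (A), common-environment (C) and
unique-environment (E) variances:

    var(y)      = a2 + c2 + e2
    cov(MZ)     = a2 + c2
    cov(DZ)     = a2/2 + c2

E absorbs measurement error, so e2 > 0 always.  The log-likelihood is
the sum of bivariate normal log-densities over independent pairs; MZ
and DZ groups share mu and the variance components.  Narrow-sense
heritability h2 is the standardized A component, a2 / (a2 + c2 + e2).

Internally the per-zygosity likelihood is evaluated from the six
sufficient statistics (n, Σy1, Σy2, Σy1², Σy2², Σy1y2), which makes an
evaluation O(1) in the number of pairs and keeps large simulation
studies cheap.  A non-positive-definite implied covariance returns -inf
rather than raising, so the optimizer can roam freely.

### Parameterizations

* `direct` (default): a2 and c2 are unbounded reals; e2 is kept
  positive through an internal log transform.  Negative point estimates
  and negative confidence bounds are meaningful outputs here — they
  flag data whose DZ resemblance exceeds what any nonnegative genetic
  decomposition allows.  The null value of a dropped component is
  interior to the parameter space, so likelihood-ratio statistics have
  their standard central chi-square reference distribution.
* `path`: variances are squares of path coefficients, enforcing
  a2, c2 >= 0.  With a true component at the boundary the LRT is then
  conservative (the usual 50:50 mixture caveat); the package does not
  apply a mixture correction, matching common practice.

### Fitting

Models ACE, AE, CE and E are fit by maximizing the exact pair
likelihood with Nelder-Mead from five deterministic starting points
(a moment-based start — a2 = 2(cov_MZ - cov_DZ), c2 = 2cov_DZ - cov_MZ,
e2 = the remainder — plus four fixed perturbations that spread the
starting variance across components).  Convergence tolerance is 1e-8 on
-2 log L.  The E model (iid normal) is solved in closed form.  The best
of the five solutions is kept; a fit where no start converges is
reported with `converged=False`, never silently.

The headline heritability and its p-value are taken from the AE model
and the AE-vs-E likelihood-ratio test (1 df): the reporting convention
here presents A and E components per taxon and ancestry stratum, with
the full ACE/AE/CE/E ladder retained in the nested-model report.  Each
(taxon x ancestry stratum) combination is fit separately; the mean
model is a single grand mean with no covariates.  Only complete pairs
enter the likelihood — participants whose co-twin lacks a retained
sample are excluded, not FIML-imputed.  Tests use alpha = 0.05 with no
multiplicity adjustment (few taxa survive the abundance filter); a
Bonferroni-style correction can be applied downstream from the reported
p-values if desired.

### Confidence intervals

Default intervals are profile likelihood: the bound for a component is
where the profile -2 log L rises by the chi-square(1) quantile (3.8415
at 95%) above its minimum, found by bracketing outward from the MLE and
Brent root-finding, with the remaining parameters re-optimized at every
pinned value.  E's interval is always strictly positive; A's lower
bound may be negative under the direct parameterization.  Wald
(observed-information) intervals are available as a cheap alternative
via `method="wald"`; they agree with profile intervals at large n but
are symmetric by construction.

## Input processing

* **Read-depth screen** — samples need `total_reads >= 5000` (the
  threshold is inclusive and configurable via `--min-reads`).  The
  depth is the per-sample total read count including reads the
  classifier left unassigned; a flag switches the proportion
  denominator to assigned-only reads.
* **Proportions** — counts divided by per-sample total reads by
  default, so unassigned reads dilute all taxa equally and the
  proportions are robust to truncation of the taxon list.
* **Pair assembly** — pairs are joined on `pair_id`; members are
  ordered lexicographically by participant id (the likelihood is
  exchangeable, so ordering cannot affect results — tested).
  Discordant zygosity or >2 members per pair are hard errors.
* **Taxon filter** — the joint rule: a taxon is analyzable when its
  proportion reaches `min_within_subject_proportion` in at least
  `subject_fraction` of the analysis population (both inclusive).
  Presets: primary 20%/10%, expanded 2.5%/1%.  The joint reading is the
  default because a disjoint reading (prevalence and abundance checked
  separately) admits taxa with near-zero abundance in most carriers,
  which defeats the filter's purpose of guaranteeing covariance
  information; `--filter-mode disjoint` preserves the alternative.
  The filter is applied to the analysis population (after the depth
  screen and singleton exclusion), pooled across strata.
* **Menopause sensitivity subset** — `--age-cutoff 51` retains
  participants aged <= 51 (inclusive: "older than 51" are removed);
  a pair losing one member cascades to exclusion of the other.

## Descriptive statistics

2x2 cohort contrasts (zygosity, bacterial vaginosis, smoking by
ancestry) use the Yates continuity-corrected chi-square, with the
correction capped so a cell with |O-E| < 0.5 contributes zero.  The
correction is on by default because descriptive contrasts of this size
conventionally report corrected statistics; `correction=False` gives
the uncorrected test.  The bacterial-vaginosis contrast excludes the
"not sure" level and missing values; other contrasts exclude missing
values only.  Continuous contrasts (BMI, age, pH) use Welch's
unequal-variance t-test computed from group summary statistics
(mean, sd, n), so they can be reproduced from a published descriptive
table without participant-level data.

## Synthetic cohorts

Participant-level vaginal microbiome twin data are controlled-access,
so the generator produces cohorts with the covariance structure the
model assumes:

1. per pair, draw A (MZ: identical; DZ: bivariate, correlation 1/2),
   C (shared), E (independent) from centered normals with variances
   (a2, c2, e2); `y = mu + A + C + E`;
2. clamp y to [0, pi/2] and set the focal-taxon proportion to sin²(y);
3. split part of the remaining compositional mass across sparse
   nuisance taxa (Bernoulli presence at rate `sparsity`, gamma weights),
   leaving a remainder of unassigned reads;
4. draw per-sample depth from a gamma-Poisson (negative-binomial) law
   with mean `mean_depth` and shape `depth_dispersion`, and read counts
   multinomially;
5. emit one member of a random 5% of pairs without a sample
   (singletons), plus per-participant ages and covariates.

Defaults are one ancestry stratum of 84 MZ + 38 DZ pairs, h2 = 0.347,
mu = pi/4 and total variance 0.08.  The variance is deliberately small
relative to the [0, pi/2] range: with sd ~ 0.28, boundary clamping
affects well under 1% of draws (asserted in tests), so the Gaussian
variance-component model is nearly exactly correct on the transformed
scale.  Depth defaults (mean 20 000, shape 4) leave a few percent of
samples below the 5000-read screen so the depth filter is exercised.

What the generator does **not** emulate: the strong bimodality of real
vaginal communities (community state types), the zero-inflation of
rare taxa in carriers, pH coupling, or longitudinal dynamics.  Passing
calibration tests therefore demonstrates that the estimator recovers
the truth *when the model's assumptions hold*, not that real vaginal
microbiome phenotypes satisfy those assumptions.

## Calibration studies and their scales

The acceptance studies (also run by `scripts/acceptance.py`) use
problem sizes chosen to keep Monte-Carlo error well below the bands
they are checked against:

* parameter recovery: 5 replicates at 2000 MZ + 2000 DZ pairs;
* type-I error of the AE-vs-E LRT: 500 null replicates at 300+300;
* 95% profile-CI coverage: 300 replicates at 500+500;
* Falconer cross-check `h2 ~ 2(r_MZ - r_DZ)`: one cohort of
  20 000 + 20 000 pairs;
* grid-search oracle equivalence: exhaustive coarse-to-fine search
  over (mu, a2, e2) on 40-pair datasets.

## Numerical choices

* Transform clamp tolerance: proportions within 1e-9 of [0, 1] are
  clamped; values further outside raise.
* Filter thresholds are inclusive (>=) at both boundaries, as is the
  read-depth screen and the age cutoff.
* Report files are written with a fixed float format and contain no
  timestamps, so identical configurations yield byte-identical output.
* Per-replicate seeds in simulation studies are derived from the base
  seed by a fixed affine map modulo 2^31.

## Known limitations

* No ADE model, sex-limitation, GxE moderation or bivariate models.
* No FIML for incomplete pairs; singletons are discarded.
* The LRT/AIC ladder treats the direct parameterization's unbounded
  null as exact; boundary-corrected inference for the path
  parameterization is not implemented.
* The generator's Dirichlet-style nuisance taxa are exchangeable; no
  attempt is made to mimic real taxon co-occurrence structure.
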
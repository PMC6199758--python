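# Methods

This note documents the statistical models implemented in `secretosurv`,
the assumptions behind the synthetic-data generator, the numerical choices
that matter for reproducing results, and the package's known limitations.

## The analysis problem

A potency study of this kind observes a small number of MSC preparations
(five is typical), each characterized twice: by a multiplex
immunoassay/ELISA panel of secreted-analyte concentrations (pg/mL), and by
the survival curve of an irradiated animal cohort that received the
preparation, sampled at a shared grid of timepoints (21 points over 50
days is typical).  The analysis asks which analytes track survival, and
builds a regression that predicts a full survival curve from a new
concentration profile.

## Preprocessing

Raw per-well readouts are collapsed to one value per (preparation,
analyte) by the arithmetic mean of technical replicates.  When cell
numbers differ across culture conditions, each preparation's row is
rescaled by a positive cell-number normalization factor.  Analytes whose
concentrations never rise above the assay's lower limit of detection carry
no information and are removed — only when *every* sample is below the
LOD; an analyte detected in some samples is kept as measured.  (A
substitute-LOD/2 policy is available for sensitivity analyses, but
imputation is not the default: at these panel sizes a wholly undetected
analyte is better excluded than invented.)  All processing steps are
logged in the matrix metadata.

## Per-timepoint Pearson screen

For analyte j and timepoint t, the screen computes the sample Pearson
correlation ρ across preparations between concentration and survival
proportion, with the two-sided p-value from the exact t transform
t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom.  A (j, t) cell is a hit
when |ρ| > ρ* **and** p < α (defaults ρ* = 0.875, α = 0.05).  Timepoints
where survival does not vary across preparations (e.g. everyone alive
during the early lag phase) leave ρ undefined; they are marked
non-evaluable and excluded rather than scored as ρ = 0, so the early
all-alive grid points cannot dilute the aggregate.

An analyte is an aggregate hit when the joint criterion holds at a chosen
fraction of its evaluable timepoints.  The default aggregation is the
majority (≥ 50%); "all", "any", and arbitrary fractions are selectable.
"All" is fragile to a single noisy timepoint and "any" inflates hits;
majority is the middle course.  In practice survival columns at different
timepoints are strongly dependent (they share the group ordering), so the
three rules usually agree.

Two facts about this screen at n = 5 deserve emphasis.  First, the
two-sided critical |ρ| at α = 0.05 with 3 degrees of freedom is ≈ 0.8783,
so the joint criterion is nearly a single constraint at the default
thresholds; both are still applied literally.  Second, the screen applies
no multiplicity correction across analytes (by design); with ~27
uninformative analytes a per-analyte 5% chance-hit rate yields on the
order of one false hit per screen.  Exact recovery of an informative set
from a 5-preparation design is therefore not a realistic expectation — see
Limitations.

## Stiffness screen

Per-well concentrations are pooled across replicates and correlated with
substratum stiffness (kPa) by Spearman rank correlation with mid-ranks for
ties; because the statistic is rank-based, any strictly monotone coding of
the stiffness levels (raw kPa, log-kPa, level index) gives identical
results.  The per-analyte significance threshold is Bonferroni-corrected,
α/m with m the number of analytes tested (0.05/45 ≈ 0.0011 for a 45-plex
panel).

The t approximation to the Spearman p-value is accurate near the center
but anti-conservative in the far tail that Bonferroni probes: at 12 wells
(3 stiffness levels × 4 replicates) it understates p ≈ 0.001 tail
probabilities roughly two-fold, which measurably inflates the familywise
error.  The screen therefore computes exact permutation p-values by
default: with stiffness taking only a few distinct values, the permutation
distribution of the rank statistic collapses to multinomial partitions of
the concentration ranks over the level groups (12!/(4!)³ = 34,650 for the
default design), which is enumerated once and cached.  Designs with more
than 2×10⁵ partitions fall back to the t approximation automatically, and
`p_method="t-approx"` forces it.  The generic `spearman_rho` primitive
keeps the t approximation, as is conventional.

## PLSR model

Let X (n × p) be the concentration matrix and Y (n × q) the survival
matrix.  Both blocks are column-standardized to mean 0 and sample
(n−1-denominator) standard deviation 1, which prevents high-abundance
analytes from dominating purely by magnitude.  Zero-variance columns are
mapped to zeros, flagged, excluded from variance-explained denominators,
and restored to their constant training value on de-standardization; the
day-0 survival column (all ones) is the standing example.

The default algorithm is SIMPLS: at each step the X-weight vector is the
dominant left singular vector of the projected cross-covariance matrix S,
scores are normalized, and S is deflated by an orthogonal basis of the
X-loadings.  SIMPLS is the algorithm behind MATLAB's `plsregress`, and its
variance accounting (‖p_a‖² and ‖q_a‖² against the standardized block sums
of squares) matches that convention.  A deflation-based PLS2
(`algorithm="nipals"`) is also provided; its weight fixed point is
computed exactly as the dominant left singular vector of the deflated XᵀY
(no iterative convergence tolerance).  The two algorithms coincide for a
univariate response and differ slightly for multivariate responses; both
are deterministic.  Component signs are fixed so that the
largest-magnitude entry of each X-weight vector is positive, making
loading maps and rankings reproducible.

The fitted model stores the coefficient matrix B of shape (p+1) × q on the
standardized scale with the intercept row first (identically zero up to
floating point, since both blocks are centered; the row is kept for the
prediction contract [1 | x_std]·B).  Prediction standardizes new
concentrations with the *training* standardizer, applies B, and
de-standardizes with the training Y standardizer to survival-proportion
scale; a flag returns the raw standardized prediction.  Two optional
post-processing steps are recorded in the output metadata: clipping to
[0, 1] (on by default — proportions are physical) and projection to the
best non-increasing curve by pool-adjacent-violators (off by default, so
the raw regression behaviour stays visible).  Raw predictions need not be
valid survival curves and are stored in a non-strict curve container.

The number of components defaults to A = 2: in this study design two
components capture the large majority of both blocks' variance, and a 2-D
loading space is what the biomarker-proximity step projects into.
A ≤ min(n−1, p) is enforced.

## Biomarker ranking and consensus

Each analyte's 2-D loading vector is compared with every timepoint's
loading vector; the proximity score is the maximum cosine similarity
(angle only — Euclidean distance conflates loading magnitude, i.e.
variance, with direction; a Euclidean mode is available for sensitivity
analysis).  Analytes are ranked by descending proximity with ties broken
by name; analytes whose cosines to every timepoint are negative are
reported separately as anti-correlated, and degenerate (zero-loading)
analytes are excluded with a warning.  The consensus biomarker set is the
intersection of the Pearson-screen hits with the proximity top-k, where k
defaults to the Pearson hit-list size; it is reported ordered by name with
the sizes of both input lists.

A caveat measured during development: a 2-D cosine is a weak
discriminator.  Informative analytes sit at proximity > 0.98, but
uninformative analytes with small, randomly-oriented loadings can land
inside the angular span of the timepoint loadings and score almost as
high.  The proximity rank order is therefore reliable for the strongest
markers but not a sharp classifier of the informative set; the Euclidean
mode separates planted from noise analytes noticeably better in
simulation.

## Survival statistics

Kaplan–Meier curves use the product-limit form S(t) = Π(1 − dᵢ/nᵢ) over
death times; censored subjects leave the risk set after their censoring
time, so a subject censored at a death time still counts as at risk for
those deaths.  Median survival is the first death time with S(t) ≤ 0.5 and
is reported as undefined when the curve never reaches 0.5 within
follow-up (the convention of the common graphing packages).

The two-group log-rank (Mantel–Cox) test pools tied death times into one
stratum, computes expected deaths and the hypergeometric variance from
each 2×2 risk table, and refers (O_A − E_A)²/V to χ² on 1 df.  The
Mantel–Haenszel hazard ratio is exp((O_A − E_A)/V) with 95% CI
exp((O_A − E_A)/V ± 1.96/√V); the reference group is the second argument.
The alternative (O_A/E_A)/(O_B/E_B) estimator is selectable.  Both are
score-type approximations: they are accurate near HR = 1 and drift for
large ratios when event fractions are high (see Limitations).

Welch's t statistic uses the Satterthwaite degrees of freedom, with
one-sided tails available in both directions.  Familywise adjustment
defaults to Holm (uniformly no larger than Bonferroni at the same FWER);
plain Bonferroni is selectable for strict replication of analyses that
used it.

## Synthetic-data generator

The generator produces data with exactly the dependence structure the
analysis assumes, so recovery tests are well-posed:

* Latent potency θ_g per preparation, equally spaced on [0, 1] by default
  so that a 5-group design always spans the potency range (random scores
  via a flag).
* Informative analyte j: concentration a_j + b_j·θ_g + ε with
  a_j ~ U(50, 500) pg/mL, b_j between 0.5× and 1.5× the baseline (so
  concentrations roughly double across the potency range), and relative
  noise ε ~ N(0, (noise_sd·a_j)²) truncated at zero; noise_sd defaults to
  0.05, a typical multiplex technical CV.  Uninformative analytes are
  potency-independent noise around their baseline.
* Survival S_g(t) = exp(−exp(−β·θ_g)·Λ(t)) with β = 2 and a
  piecewise-linear baseline cumulative hazard Λ that is zero during an
  8-day lag (radiation-injury deaths do not begin immediately) and rises
  to 2.0 at day 50.  These defaults span endpoint survivals from ~14% to
  ~76% across the potency range, matching the spread such studies report,
  and make the early timepoints non-evaluable for the screen, exercising
  that code path.
* Event tables draw death times per subject from Exponential(λ_g) with
  administrative censoring at day 50 (cohorts of 9–12 by default), so the
  true hazard ratio between cohorts is the ratio of their rates.
* The stiffness table draws well concentrations
  intercept + slope·(−log₁₀ stiffness) + N(0, noise_sd) with intercepts in
  [100, 500] pg/mL, so a positive slope means expression rises as the
  substratum softens; the all-zero-slope default is the null table used
  for familywise-error checks.

A second expression/survival mode (`latent_rank=2`) mixes three template
survival curves with per-group simplex weights and makes concentrations
affine in the two mixing weights; noise-free data from this mode are
exactly rank 2 after standardization, so a two-component fit captures 100%
of the response variance and reproduces the training curves exactly —
the reference condition for the parity (observed-vs-fitted slope ≈ 1)
check.

All randomness flows through numpy's PCG64 generator from an explicit
integer seed recorded in every output; the pipeline derives per-stage
substreams from the run seed via `SeedSequence` spawn keys, so identical
configs reproduce identical outputs byte for byte.

What the generator does *not* emulate: correlated analytes (real secretome
panels are strongly co-regulated), assay heteroscedasticity beyond a
constant CV, non-proportional hazards, inter-animal frailty, and
measurement error in the survival proportions themselves.  Passing
recovery tests on this generator therefore demonstrates correctness of
the algorithms under the model's own assumptions, not robustness of the
biology.

## Verification scales

The statistical test suites run at fixed, moderate problem sizes chosen to
give tight Monte-Carlo error while keeping the default test run fast:
PLSR reference-equivalence over 50 random problems (n = 6–10, p = 5–12,
q = 1–8); log-rank type-I error over 1000 null simulations at 50
subjects/group; hazard-ratio recovery at 500 subjects/group over 20 seeds,
with cohort hazards anchored to endpoint survivals of 55.6% and 87.5%
(true HR 4.4) — the light-event regime in which the score-type estimator
is close to unbiased; familywise error over 200 null screens of 45
analytes; Kaplan–Meier convergence at 2000 subjects.

## Limitations

* **Five preparations are very few.**  At n = 5 the Pearson screen's joint
  criterion has an exact 5% per-analyte chance-hit rate, and with ~27
  uninformative analytes the probability of a screen with zero false hits
  is only ≈ 0.95²⁷ ≈ 0.26.  The PLSR consensus filters some but not all
  chance correlates (a chance correlate genuinely correlates with the
  latent score in that sample).  Exact recovery of a planted biomarker set
  therefore fails in most simulated studies regardless of noise level;
  users should read the hit list as a strong-candidate ranking, not a
  classification.
* **Cosine proximity is weakly discriminative in 2-D** (above); the
  Euclidean flag is the recommended sensitivity check.
* **The Mantel–Haenszel/Peto hazard-ratio estimator is biased away from 1
  for large ratios** when most subjects experience events (measured ≈ +18%
  at a true HR of 4.4 with ~95% cumulative mortality); in light-event
  regimes it is accurate to within a few percent.  For unbiased estimation
  at large ratios a Cox model is the right tool and is out of scope here.
* **The t-approximate Spearman p-value is anti-conservative in the extreme
  tail** at small well counts; the exact permutation default exists for
  precisely this reason and should not be switched off for
  Bonferroni-corrected screens of small designs.
* Survival curves are modelled as given proportions; the PLSR stage does
  not propagate the sampling uncertainty of the underlying cohorts into
  its predictions.
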
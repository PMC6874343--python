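# Methods

## The model

`sdtlatent` estimates item difficulty and person ability on a common latent
axis from scored m-alternative forced-choice (m-AFC) trials, using the
signal-detection account of the task rather than an item-response-theory
curve imposed from outside.

Each of the m response alternatives on a trial is assumed to elicit an
internal response; the alternative with the largest internal response is
chosen. The correct alternative's internal response is drawn from N(d', 1)
and each of the m−1 incorrect alternatives' from N(0, 1) — the equal-variance
Gaussian assumption. d' is in pooled-standard-deviation units, and because
the axis origin is arbitrary the incorrect-choice mean and common SD are
normalized to 0 and 1 without loss of generality. Probability correct is

    L_m(d') = ∫ φ(x − d') [Φ(x)]^(m−1) dx ,

with φ, Φ the standard normal density and CDF. The latent-variable extension
sets d' = θ_i − b_h for person i responding to item h: θ is person ability
and b item difficulty, both in d' units. Chance performance (p = 1/m) sits
exactly at θ − b = 0 for every m, so b = 0 means "as hard as the average
person can just guess at" and negative b means an easier item.

## Estimation

A full joint MLE over all θ and b is computationally unattractive, so two
estimators are provided.

**Two-stage approximation.** All responses to an item are first treated as
repeated measures from a single "average" person anchored at θ = 0: the
observed proportion correct p_h inverts through L_m to b_h = −L_m⁻¹(p_h).
Confidence intervals come from Wilson score intervals on the binomial
proportion, mapped through the same inverse (the endpoint order flips
because b = −d'). Each person measure is then an independent one-parameter
MLE given the item measures, with the standard error taken as
(−ℓ″(θ̂))^(−1/2), the reciprocal square root of the observed information
from a central second difference (step 10⁻³ d').

**Alternating refinement ("EM").** Starting from the two-stage fit, item
measures are re-estimated by per-item 1-D MLE given the current person
measures, then person measures given the new item measures, until the
largest absolute parameter change falls below `tol` (default 10⁻⁴ d',
comfortably below reporting precision; default `max_iter` 100). The
likelihood depends only on differences θ − b, so after every cycle the mean
person measure is subtracted from all θ and all b — a translation that
leaves the likelihood invariant — keeping the average person at θ = 0.
Each half-step is an exact coordinate maximization, so the joint
log-likelihood is non-decreasing across the trace (to ~10⁻⁹ numerical
slack); non-convergence at `max_iter` is reported as a flag, never an
exception.

Score-degenerate items (0 or all correct) and persons (all correct or all
incorrect) have no finite MLE, and keeping them in the refinement lets
their monotone likelihood drag the whole solution along a slow drift.
They therefore keep their stage-1 estimates, are flagged, and are excluded
from the refinement likelihood — the convention Rasch practice applies to
extreme scores. The exclusion is closed iteratively (dropping an extreme
item can make a person extreme on the remaining items), and the anchoring
mean and trace log-likelihood are taken over the estimable subtable.

The two-stage fit is fast and close to the refined fit, but when persons
are heterogeneous the pooled average-person proportion flattens the
psychometric curve and mildly compresses the scale; measured contrasts
(e.g. a paired condition effect) are therefore slightly attenuated under
the approximation and essentially unbiased under the refinement. The
paired-effect summary reports the mean matched difference in θ with a
normal-approximation CI.

## Numerical choices

- L_m is evaluated by order-64 Gauss–Hermite quadrature after centering at
  d' (the integrand is a Gaussian times a bounded monotone factor); measured
  absolute error against adaptive quadrature is ≲10⁻¹² over d' ∈ [−6, 6],
  m ≤ 8. The inverse uses bracket doubling from [−10, 10] plus Brent's
  method to a residual below 10⁻¹⁰ in probability.
- Person/item 1-D likelihood searches run on [−10, 10] d' with bounded
  Brent refinement to 10⁻⁶. Summation order inside the likelihood is fixed
  by sorting, so estimates are bit-identical under row permutations.
- Degenerate item scores (0 or n correct) have no finite inverse; the
  proportion is replaced by (x + 0.5)/(n + 1), keeping the estimate finite
  and ordinal with neighbours, and the item is flagged. Degenerate persons
  (all correct / all incorrect) have a monotone likelihood; θ̂ is clamped to
  the ±10 search bound, flagged, and its SE left undefined (NaN).
- Wilson endpoints at degenerate counts touch 0 or 1 exactly; those
  endpoints are pulled inside the unit interval by a quarter-count,
  1/(4(n+2)), so the d' mapping stays finite.
- Default confidence level 0.95 throughout.

## Rasch comparator

The dichotomous Rasch model, P(correct) = logistic(θ − b) in logits, is the
special case of the generalized choice-probability integral with a
point-mass (Dirac delta) correct-choice density and a logistic noise CDF at
m = 2 — the sifting property collapses the integral to the logistic. The
package fits it by joint maximum likelihood: damped alternating Newton
updates of person and item parameters, mean item measure anchored at 0 (the
usual Rasch convention), convergence at 10⁻⁵ logits, with extreme-score
persons/items excluded (their MLEs are infinite) and listed in the result.
No bias correction is applied; the comparison is about scale relations, not
about optimal Rasch estimation.

`compare_rasch_sdt` regresses Rasch logits on SDT d' item measures by OLS
within each m group. Because SDT anchors chance at b = 0 for all m while the
Rasch scale anchors the mean item, mixed-m data produce lines with
(approximately) shared slope but different intercepts. For near-homogeneous
persons the slope approaches the logistic/normal scaling constant
1.7/√2 ≈ 1.20 for 2-AFC items; person heterogeneity inflates it — simulated
slopes run ≈1.24 at person SD 0.3 up to ≈1.6 at SD 1.2 — so slopes observed
on real data depend on the person distribution, and the package's test
asserts a band rather than the idealized constant.

## The simulator

`make_truth` + `simulate_responses` emulate a two-condition clinical
forced-choice study: 50 subjects each counted as two "persons" (one per
condition), 192 items in 8 blocks, one third 2-AFC and two thirds 3-AFC,
with each subject randomly assigned the odd or even blocks to the treated
condition — so the two persons of a subject answer disjoint item sets, and
disjoint person groups respond to disjoint blocks. A `complete` design
(everyone answers everything) is available for calibration studies. The
condition effect is an additive shift on treated-person ability; generating
distributions default to θ ~ N(0, 0.8) and b ~ N(−1, 1), chosen as
realistic for a battery designed to be mostly doable (items easier than the
average person). These defaults are simulation conventions, not empirical
claims.

Two modes exist: `model` draws scores through L_m; `mechanistic` draws the
internal responses themselves and scores the maximum. The modes are equal
in distribution, which makes the mechanistic sampler an independent oracle
for the quadrature. All randomness flows from an explicit integer seed
through `numpy.random.default_rng`; identical inputs give bit-identical
tables.

What the simulator does not emulate: real stimuli, response times,
criterion-dependent (yes–no) behaviour, learning or fatigue across blocks,
and rater uncertainty about the truth state. Passing recovery tests show
the estimators invert the model they assume; they cannot certify that real
forced-choice data satisfy the equal-variance, criterion-free assumptions.

## Problem sizes used in the test suite

Unit tests run on 40-person × 30-item simulations; the full-scale recovery
checks use one seeded 200-person × 192-item complete-design simulation
(100 subjects × 2 conditions, true condition effect 0.552 d'), fitted by
both estimators, chosen to match the scale of the motivating study design.
Monte-Carlo oracle comparisons use 10⁶ draws per grid point with one
spawned child stream per point.

## Known limitations

- The two-stage scale compression noted above: contrasts estimated under
  the approximation are mildly conservative when person spread is large.
- JMLE Rasch estimates are inconsistent for finite item counts (no (n−1)/n
  correction is applied); this slightly inflates comparison slopes.
- Degenerate-score handling is a pragmatic convention; estimates for
  flagged items/persons should not be interpreted as MLEs.
- No infit/outfit or other model-fit indices are computed.
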
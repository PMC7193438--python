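# Methods

## Measurement model

Items are dichotomous and Rasch-calibrated: the probability of a correct
response depends only on the difference between the person measure θ and
the item difficulty *b*, P = exp(θ−b)/(1+exp(θ−b)), both in logits.  The
bank is *between-item* multidimensional — each item loads on exactly one of
the five developmental domains (cognitive, language, gross motor, fine
motor, social), and the domains are correlated at the person level.  No
discrimination or guessing parameters are modelled; item calibration is an
input, not something the package estimates.

Probabilities are evaluated through the numerically stable logistic
(`scipy.special.expit` / `log_expit`), so logit differences up to the
bank's extremes (±8 ability against ∓7.35 difficulty, and far beyond)
neither overflow nor collapse to exact 0/1.  Missing responses are excluded
from likelihood and information sums, never imputed.

## Estimation

Per-domain maximum likelihood uses Newton–Raphson: Δθ = (raw score −
expected score) / information.  The Rasch log-likelihood is globally
concave in θ, so the only safeguards needed are a 1-logit cap per step and
step-halving whenever a proposed step would decrease the log-likelihood;
convergence is declared at |Δθ| < 1e−4 (cap 50 iterations).  Perfect and
zero raw scores have no finite maximizer and are clamped to ±8 logits — the
ability range the bank is built for — with a `clamped` flag rather than
dropping the person, which keeps adaptive sessions alive.

The joint MAP estimator places a zero-mean multivariate-normal prior with
the configured cross-domain covariance on the five measures and finds the
posterior mode by damped Newton on the joint gradient (score minus prior
precision times θ); its SEMs are posterior standard deviations.  Inside the
adaptive engine the MAP path is used only while a domain's response pattern
is all-correct/all-incorrect; once mixed, the domain switches to plain MLE.
Final session estimates stay on this path: a domain whose pattern never
mixes reports the finite shrinkage estimate, not a ±8 clamp.  (Clamped
finals were considered and rejected: they put extreme outliers into
precisely the short, easy-to-stop sessions, destroying the agreement
between adaptive and full-bank scores that is the point of the design.)

SEM is 1/√(Σ p(1−p)) over administered items at the current estimate.  Two
reliability conventions coexist deliberately:

- **Stop rule / single measure:** R = 1 − SEM², the unit-true-variance
  identity (SEM ≈ 0.447 ⇔ R = 0.80).
- **Sample summaries:** R = 1/(1 + mean SEM²), i.e. true variance over
  observed variance with unit true variance and the error variance
  estimated by the mean squared SEM.  With wide uniform difficulty ranges,
  asymptotic SEMs of near-extreme patterns overstate realized error; the
  ratio form remains consistent with the squared truth–estimate correlation
  (within ≈0.05 per domain in the packaged simulations) where the
  subtraction form 1 − mean(SEM²) can even go negative.

Person fit uses standardized residuals z = (x−p)/√(p(1−p)): the outfit mean
square is mean(z²) over administered items (expectation 1 under the model),
and |z| > 2 flags an individual response as aberrant.  Note that with items
up to ~9 logits away from a person, z² on a rare surprising response
reaches ~10⁴, so per-domain outfit means over 1000 persons are heavy-tailed
(observed ~0.83–1.39 at the true measures across seeds); only the mean over
persons *and* domains is a stable calibration check.

## Adaptive engine

The provisional information matrix is M = Σ⁻¹ + diag_d(Σ item information
administered in domain d), evaluated at the provisional measures.  Seeding M
with the prior precision Σ⁻¹ makes determinant maximization well defined
from the first item; with an identity covariance it reduces to greedy
maximum-information selection.  A candidate in domain d changes M by a
rank-one term, so det(M′) = det(M)(1 + u·(M⁻¹)_dd) and the engine ranks
candidates by u·(M⁻¹)_dd in closed form; the test suite checks this against
brute-force determinant evaluation along random session walks.  Exact ties
resolve to the lowest item id, making transcripts reproducible.

Stop rules per domain, evaluated after every response: bank exhaustion
stops unconditionally; otherwise, after the minimum of 3 items, a domain
stops when reliability (1 − SEM²) ≥ 0.80 **or** the mean of the last 3
absolute estimate changes is < 0.05 logits.  The criteria combine by OR —
the reading that produces short adaptive tests; requiring both would make
stopping nearly unreachable for banks whose per-domain information tops out
near 1.  Only the answered domain is re-estimated per step, but the full
information matrix is refreshed for the next selection.

Nonadaptive testing (NAT) scores a complete response row by per-domain MLE
over every item and is the reference mode for the Monte Carlo comparison.

## Synthetic data generator

The generator emulates the study design the packaged bank mirrors: five
domains of 11/13/19/18/14 items (75 total) with difficulties drawn
uniformly over −7.35..8.03 logits (only the range of the real calibrated
pool is public, hence uniform); 1000 examinees per cohort with
standard-normal domain measures, exchangeable cross-domain correlation 0.9
(approximating the high observed between-domain consistency of such
instruments), clamped to [−8, 8]; responses drawn cell-wise from the Rasch
probability.  Each generator is a pure function of its configuration
including the seed, with separate derived streams for bank, abilities and
responses.  The packaged `data/music_bank_synthetic.csv` is one frozen draw
of this generator (seed 20240501) and is synthetic — it reproduces the
layout and difficulty range of the real instrument, not its individual item
difficulties.

What the generator does **not** emulate: polytomous responses, aberrant
responders (careless/guessing patterns beyond model noise), item drift, age
dependence of item applicability, and any clustering of difficulties the
real calibrated pool may have.  Passing simulations therefore demonstrate
the internal consistency and efficiency of the adaptive machinery under the
stated model, not clinical performance of a particular instrument.

## Monte Carlo comparison

`run_comparison` draws one cohort and one complete response matrix, then
scores every person by NAT and by MCAT *replaying the same row*, so the
length and precision differences are paired and attributable to item
selection alone.  Reported: per-domain mean lengths and estimates, the
savings percentage 100·(75 − mean MCAT total)/75, per-domain MCAT/NAT and
truth/NAT correlations, SEM-based reliabilities, covariance/correlation of
NAT estimates, and Welch two-sample tests (the unequal-variance form, since
nothing guarantees equal spread) on the five per-domain mean lengths and
mean abilities.  Under the default conditions the engine saves ≈42% of
items with per-domain MCAT/NAT correlations ≥ 0.92; the length test is
significant at 0.05 and the ability test is not.  Cross-domain correlations
of *estimates* are attenuated from the true 0.9 by measurement error, close
to the classical ρ·√(R_d R_d′) prediction — with ~1–19 informative items
per domain they land near 0.3–0.4, and reliabilities near 0.4–0.5.

Default problem sizes — 1000 persons for cohort-level quantities, a few
hundred for illustrative runs, 10⁴ replicates for distributional checks —
were chosen as the smallest sizes at which the reported quantities are
stable to well within their decision tolerances.

## Strata and cutoffs

Separation G = √(R/(1−R)); strata H = floor((4G+1)/3), floored at one.
Equal-population thresholds are standard-logistic quantiles log(k/(H−k))
rounded to one decimal — the only rule consistent with the conventional
threshold sets (0; ±0.7; −1.1/0/1.1; −1.4/−0.4/0.4/1.4).  Adjacent-gap
validation against the customary 1.4–5.0-logit guideline is advisory: the
four- and five-strata conventional sets themselves sit 1.1 and 1.0 logits
apart and are reported as below-guideline, not rejected.  Global
classification applies the three-strata scheme to the arithmetic mean of
the domain measures; boundary values classify upward.  Domain delay flags
use strict inequality (measure < cutoff fails); the packaged age table
carries only the published 24-month row — other ages need a user-supplied
table.

## Numerical and degenerate-input choices

- Probabilities are clipped away from exact 0/1 by one ulp so logs and
  standardized residuals stay finite.
- Covariance matrices must be symmetric positive definite (eigenvalue
  check); the exchangeable constructor enforces ρ ∈ (−1/(k−1), 1), with
  correlation 1 handled as a degenerate shared draw in the generator.
- An empty response set is an error for MLE/SEM but returns the prior mean
  from MAP.
- Bank difficulties outside ±10 logits warn (screening banks should not
  reach there) but load.
- CSV round trips write difficulties at `repr` precision so write→read→write
  is byte-identical.

## Known limitations

Dichotomous items only; no content balancing or exposure control; item
parameters are trusted as given (no calibration, no drift handling); the
reliability-0.80 stop rule is effectively unreachable for banks whose
difficulties are spread uniformly over ~15 logits (maximum per-domain
information ≈ 1.2), so stopping there is driven by the stability rule; and
the strata machinery assumes the logistic population convention used by the
equal-probability cutoffs.
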
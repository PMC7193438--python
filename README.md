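# raschcat

Multidimensional computerized adaptive testing (MCAT) for Rasch-calibrated
developmental screening item banks.

Developmental screening instruments for toddlers — five-domain tools
covering cognitive, language, gross-motor, fine-motor and social skills —
traditionally administer every item of every subscale. `raschcat` implements
the adaptive alternative for dichotomous, Rasch-calibrated banks: items are
chosen one at a time to be maximally informative about the child's current
provisional measures across all correlated domains, and each domain stops as
soon as its measure is precise or stable enough. The package is aimed at
psychometricians and screening-tool developers who want to simulate,
validate, or run such adaptive administrations.

## The model and the engine

Person measures θ and item difficulties *b* share one logit scale; the
dichotomous Rasch model gives the success probability

    P(x = 1 | θ, b) = exp(θ − b) / (1 + exp(θ − b))

with item information *p(1 − p)* and person SEM = 1/√(Σ information).
Domain measures are estimated by Newton–Raphson maximum likelihood (the
update is score/information, i.e. observed − expected over information); a
multivariate-normal MAP estimator across domains keeps provisional measures
finite before a mixed response pattern exists.

Next-item selection is **D-optimal**: with prior covariance Σ across the
five domains, the provisional information matrix is
M = Σ⁻¹ + diag(accumulated domain information), and the chosen item
maximizes det(M′) over all unanswered items — equivalently (rank-one
update) the product of its information and the corresponding diagonal of
M⁻¹. A domain stops after at least 3 items when its person reliability
(1 − SEM²) reaches 0.80 or the mean of its last three absolute measure
changes falls below 0.05 logits.

Reliability also drives interpretation: separation G = √(R/(1−R)) yields
H = (4G+1)/3 strata (0.67 → 2, 0.80 → 3, 0.90 → 4), with equal-population
cutoffs at the standard-logistic quantiles log(k/(H−k)) — e.g. ±0.7 logits
for three strata — and per-domain delay flags against age-specific cutoff
tables.

## Worked example

```python
from raschcat import fixture_bank, run_comparison

report = run_comparison(fixture_bank(), n_persons=200, seed=42)
print(f"savings: {report.savings_percent:.2f}%")
print(f"mean adaptive items: {report.mcat_mean_total_items:.1f} of 75")
for d in report.domains:
    print(f"  {d:12s} NAT {report.nat_items_by_domain[d]:2d} items -> "
          f"MCAT {report.mcat_mean_items_by_domain[d]:.1f}, "
          f"score corr {report.mcat_nat_correlation_by_domain[d]:.3f}")
```

prints

```
savings: 42.10%
mean adaptive items: 43.4 of 75
  cognitive    NAT 11 items -> MCAT 8.4, score corr 0.993
  language     NAT 13 items -> MCAT 7.6, score corr 0.986
  gross_motor  NAT 19 items -> MCAT 9.9, score corr 0.956
  fine_motor   NAT 18 items -> MCAT 8.2, score corr 0.948
  social       NAT 14 items -> MCAT 9.4, score corr 0.948
```

Each of 200 simulated children is scored twice from the same recorded
response row: nonadaptively (NAT — all 75 items) and adaptively (MCAT).
The adaptive engine needs ~42% fewer items while its per-domain measures
correlate ≥ 0.94 with the full-bank scores.

The same machinery is exposed on the command line:

```sh
raschcat cutoffs --reliability 0.80
# reliability: 0.8
# strata: 3
# thresholds (logits): -0.7, 0.7
# cumulative probabilities: 0.33, 0.67
raschcat bank simulate --items-per-domain 11,13,19,18,14 --seed 1 --out bank.csv
raschcat study run --n-persons 1000 --seed 1 --out study_out/
raschcat cat interactive --bank bank.csv --age-months 24
```

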
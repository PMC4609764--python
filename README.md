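# pcurve-meta

Random-effects meta-analysis and p-curve evidential-value testing for
two-arm randomized-trial summaries, motivated by the question of whether
exercise truly reduces BMI z-score in overweight and obese children and
adolescents — or whether the published significant findings reflect
selective reporting.

## What it computes

**Per-study effects.** Each trial reports, per arm, the sample size *n*,
the mean change in BMI z-score, and the SD of that change. The study
effect is the mean-difference *d* = exercise − control (negative favours
exercise), with variance from the pooled two-sample formula
*v* = *s*²ₚ(1/*n*₁ + 1/*n*₂) and inference on the normal deviate
*z* = *d*/√*v*. Multi-arm studies are collapsed (moment-preserving merge of
the intervention arms) so each study contributes one independent p-value.

**Random-effects pooling.** DerSimonian–Laird: fixed-effect weights
*w*ᵢ = 1/*v*ᵢ give Cochran's *Q* = Σ*w*ᵢ(*d*ᵢ − *d̄*)², the moment
estimator τ̂² = max(0, (*Q* − (*k*−1))/(Σ*w* − Σ*w*²/Σ*w*)), and
random-effects weights 1/(*v*ᵢ + τ̂²). Heterogeneity is summarized by
*I*² = 100·max(0, (*Q* − df)/*Q*) with a test-based (Higgins–Thompson)
95% confidence interval on *H* = √(*Q*/(*k*−1)).

**p-curve.** The distribution of the *significant* two-sided p-values
(p < .05, effect in the hypothesized direction). Each is converted to a
pp-value — the conditional probability of a result at least as extreme
under a stated hypothesis — and pooled with Fisher's method,
χ² = −2Σln *pp* on 2*k* df, for three inferences:

| channel | pp-value | a small combined p means |
|---|---|---|
| right-skew | p/.05 | the studies contain evidential value |
| flatter than 33% power | conditional exceedance under a noncentral alternative calibrated to 33% power | the studies lack evidential value |
| left-skew | 1 − p/.05 | the p-values pile up just below .05: intense p-hacking |

pp-values are winsorized to [0.01, 0.99] for robustness. A synthetic-trial
generator (honest and optionally stopped regimes) provides corpora with
known truth for validating all of this; `pcurve_meta.validate` measures
type-I error, calibration at 33% power, left-skew detection power and
pooled-CI coverage by seeded Monte Carlo.

## Worked example

```sh
$ python examples/pcurve_from_pvalues.py
6 significant studies included, 4 excluded (p >= .05)

        right_skew: chi2 =  24.61, df = 12, p = 0.0168
   flatter_than_33: chi2 =   9.57, df = 12, p = 0.6536
         left_skew: chi2 =   5.42, df = 12, p = 0.9423

inference: contains evidential value
```

Ten studies entered, six were significant, so each Fisher test runs on
2 × 6 = 12 df. The right-skew χ² is significant (p = .017): low p-values
dominate, which only a true effect produces. The flatness test does not
fire (the curve is steeper than 33% power would make it) and the left-skew
test finds no pile-up near .05 — no sign of p-hacking.

The other examples cover random-effects pooling of a synthetic corpus
(`meta_analysis.py`), the file-based pipeline (`full_pipeline.py`) and
left-skew detection of optional stopping (`phacking_detection.py`). The
same functionality is exposed on the command line:

```sh
pcurve-meta simulate --seed 12345 --out corpus.csv
pcurve-meta analyze --in corpus.csv --out report.json
pcurve-meta bins --in report.json --out bins.csv
pcurve-meta validate --reps 2000 --seed 1
```

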
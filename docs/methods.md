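# Methods

## Effect model

The unit of analysis is a two-arm randomized trial summarized per arm by
(n, mean change in BMI z-score, SD of change). The study effect is
d = m₁ − m₂ (exercise minus control; negative = benefit), with sampling
variance v = s²ₚ(1/n₁ + 1/n₂), where s²ₚ is the df-weighted pooled
variance of the two arms. We deliberately use the pooled (not Welch) form
and refer z = d/√v to the standard normal rather than Student's t: the
procedure being implemented defines per-study p-values as two-sided normal
tail probabilities of z-deviates, and all downstream machinery (pp-values,
the 33%-power calibration) is built on that convention. The small-sample
consequences are quantified under *Limitations*. A zero effect maps to
p = 1; p is floored at 1e-300 so its logarithm stays finite when |z| is
extreme. If both arms report zero SD no inference is possible and a
degenerate-variance error is raised.

Studies with several intervention arms are collapsed before effect
computation by merging the exercise arms into one preserving moments
(n = Σnᵢ, n-weighted mean, SD from the combined-group sum of squares).
This keeps one comparison per study — required because Fisher's method
assumes independent p-values — and preserves the participant count,
unlike averaging per-arm effect sizes.

## Random-effects pooling

DerSimonian–Laird throughout: Q = Σwᵢ(dᵢ − d̄_FE)² with wᵢ = 1/vᵢ;
τ̂² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)); pooling weights 1/(vᵢ + τ̂²);
normal-theory 95% CI. Alternative τ² estimators (REML, Paule–Mandel) and
the Knapp–Hartung adjustment are out of scope. k = 1 is a defined
degenerate case (Q = 0, τ² = 0, I² = 0, q_p = 1).

I² = 100·max(0, (Q − (k−1))/Q). Its 95% CI is the test-based interval on
H = √(Q/(k−1)): normal bounds on ln H with
SE(ln H) = (ln Q − ln(k−1)) / (2(√(2Q) − √(2k−3))) when Q > k, else the
small-Q fallback √((1 − 1/(3(k−2)²))/(2(k−2))); bounds transform through
I² = 100(H² − 1)/H² and truncate at 0. This method — rather than the
Q-profile interval that metafor defaults to — is what reproduces the
reference analysis's printed upper bound (Q = 21.5, k = 10 → 79.2%). When
the interval is undefined (k < 3 or Q = 0) the pooled result reports the
collapsed interval [0, I²]. The pooling itself was cross-checked against
metafor's `rma(method="DL")` to ten decimals.

## p-curve

Only studies with two-sided p strictly below α = .05 *and* d < 0 enter.
The directionality requirement is our addition: p-curve's logic requires
all included results to test the same directional hypothesis, so a
significant effect in the wrong direction is excluded with a warning
rather than silently pooled. The boundary p = .05 is excluded.

Channels, per included study:

- right-skew: pp = p/α — uniform under the null, conditional on
  significance;
- flatness: with z_obs = Φ⁻¹(1 − p/2) and extremity
  E = P(|Z| ≥ z_obs) for Z ~ N(δ₃₃, 1), pp = (S − E)/S with S = 1/3 —
  the probability under 33% power, conditional on significance, of a
  p-value at least as *large* as observed;
- left-skew: pp = 1 − p/α.

δ₃₃ solves [1 − Φ(z_{.975} − δ)] + Φ(−z_{.975} − δ) = 1/3 by Brent root
finding on δ ∈ [0, 10] (power is monotone there) to |power error| < 1e-10,
giving δ ≈ 1.5286. The two-sided (folded-normal) form of the power and
extremity expressions is used consistently; for the z-test the solution is
the same for every study regardless of sample size, which enters only when
back-computing the implied standardized effect. All pp-values are
winsorized to [0.01, 0.99] before combination, which also bounds each
combined χ² to [−2k ln .99, −2k ln .01].

Fisher combination: χ² = −2Σ ln pp on 2k df, upper tail from scipy's
chi-square survival function (validated against the closed-form even-df
series to 1e-10). Verdict labelling: significant right-skew ⇒ "contains
evidential value"; otherwise significant flatness ⇒ "lacks evidential
value", with significant left-skew additionally flagging intense
p-hacking; neither ⇒ inconclusive. All three tests are always reported.

## Synthetic trial generator

Per study: true effect θᵢ ~ N(θ, τ²); per-arm n uniform on n_range; arm
mean changes ~ N(true mean, σ²/n) around a zero control drift; arm SDs
drawn as σ·√(χ²_{n−1}/(n−1)) so downstream computations see estimated, not
known, variances — what real trial summaries carry. A single seeded
generator is threaded through all draws; identical configs reproduce
corpora bit for bit.

Defaults emulate the reference corpus: k = 10; per-arm n on [20, 64]
(expected total ≈ 840 over 20 arms, matching ~835 participants);
θ = −0.06 BMI z-score units; σ = 0.25, a realistic change-score SD for
pediatric BMI z-scores; τ = 0.068, calibrated so the expected I² is ≈ 58%
via I² ≈ τ²/(τ² + v̄) with v̄ the mean within-study variance. One printed
feature of the reference corpus is *not* reproduced: with θ = −0.06 and
I² ≈ 58% only ~30% of studies reach significance in expectation, not 6/10;
the triple (pooled effect, heterogeneity, significance fraction) is
mutually inconsistent for any σ under this model, and we preserve the
first two. The generator also omits covariates, non-normal noise and
individual-level data by design; conclusions from passing tests transfer
to real corpora only to the extent those features are irrelevant.

The optional-stopping generator accrues `batch_size` participants per arm
per look and freezes at the first look with two-sided p < α (either
direction — analysts stop on "significance") or at `max_looks`. With
max_looks = 1 it reduces to honest sampling. The canonical *intense*
regime used for validation (`validate.INTENSE_HACKING`) peeks after every
10 participants per arm for up to 100 looks: fine, prolonged peeking makes
the p-value cross .05 gently and pile up just beneath it, whereas coarse
accrual overshoots to small p at the stopping look and dilutes the
left-skew signature.

## Validation design

Operating characteristics are estimated on "published literature" corpora:

- **Type-I error (right-skew).** Null corpora (θ = τ = 0, k = 10, per-arm
  n on [30, 60], σ = 0.3) are simulated until 2000 contain at least one
  includable study (under the null and the directionality rule ~78%
  contain none, so conditioning on a defined test is the only denominator
  that makes "type-I error" meaningful); the rejection fraction among
  those is reported.
- **Flatness calibration.** Studies simulated at exactly δ₃₃ and
  conditioned on significance: the flatness pp-values must be uniform
  (KS), and the flatness test must reject at ≈ its nominal level over
  corpora of six significant studies.
- **Left-skew power.** Replicates are literatures of 15 significant,
  direction-consistent studies harvested from the intense optional-
  stopping regime — the selective-reporting scenario p-curve models. The
  15-study replicate size reflects that Fisher-combined left-skew needs a
  substantial set of barely-significant results before detection is
  reliable.
- **Coverage.** 1000 heterogeneous corpora (θ = −0.06, τ = 0.05) for the
  pooled CI's coverage and the estimator's unbiasedness.

These scales keep the full battery under a minute on one CPU.

## Limitations

Two genuine small-sample properties of the procedure, quantified by the
validation suite, are worth knowing:

- **The z-convention is mildly anti-conservative for small trials.** With
  arm SDs estimated from 30–60 participants, d/√v̂ is t-distributed on
  ~60–120 df; referring it to the normal inflates exactly the sub-.05 tail
  that p-curve conditions on. The validation suite measures a right-skew
  type-I error of ≈ 0.07 rather than 0.05 under the null regime above —
  conditional on significance, z-based p-values are not quite uniform
  (e.g. P(p < .01 | p < .05) ≈ 0.22, not 0.20). Exact per-study t-tests
  would remove this, at the cost of departing from the z-deviate effect
  contract this implementation follows.
- **The DL normal-theory CI undercovers at k = 10.** The suite measures
  ≈ 92% coverage under the heterogeneous regime (θ = −0.06, τ = 0.05)
  instead of 95%. About half the shortfall is the classic DL small-k
  effect (with known variances the same regime gives ≈ 94%), the rest the
  estimated-variance noise the generator realistically injects.
  Knapp–Hartung-type corrections would repair this but are out of scope.

Numerical notes: winsorization bounds protect Fisher's method from
underflowing pp-values; two-sided p is computed via erfc and floored at
1e-300; ties at d = 0 give p = 1; the chi-square upper tail and the
noncentrality root-finder are scipy routines validated in the test suite
against independent closed forms and Monte Carlo.
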
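"""Per-study effect sizes and random-effects pooling for two-arm trials.

The unit of analysis is a randomized trial reporting, per arm, the sample
size, the mean change in BMI z-score from baseline, and the SD of that
change.  The study effect is the difference in mean change (exercise minus
control), with variance from the degrees-of-freedom-pooled two-sample
formula ``sp^2 * (1/n1 + 1/n2)``.  Inference per study is on the normal
deviate z = d / se (two-sided).

Pooling uses the DerSimonian-Laird moment estimator of the between-study
variance tau^2, with heterogeneity quantified by Cochran's Q and
I^2 = 100 * max(0, (Q - df) / Q).  The I^2 confidence interval is the
test-based (Higgins-Thompson) interval on H = sqrt(Q / (k - 1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .exceptions import DegenerateVarianceError

__all__ = [
    "ArmSummary",
    "StudyRecord",
    "EffectEstimate",
    "MetaResult",
    "compute_effect",
    "collapse_multiarm",
    "pool_random_effects",
    "compute_i2",
    "i2_confint",
    "q_pvalue",
    "two_sided_p",
]

_Z975 = 1.959963984540054  # standard-normal 0.975 quantile


def two_sided_p(z: float) -> float:
    """Two-sided standard-normal tail probability of a z statistic.

    ``z = 0`` maps to ``p = 1``.  Uses ``erfc`` for accuracy deep in the
    tails; results are floored at 1e-300 so p stays strictly positive (and
    its logarithm finite) even when ``erfc`` underflows around |z| > 38.
    """
    return max(math.erfc(abs(z) / math.sqrt(2.0)), 1e-300)


@dataclass(frozen=True)
class ArmSummary:
    """Change-score summary for one trial arm.

    Parameters
    ----------
    n : int
        Number of participants analysed in the arm (>= 2).
    mean_change : float
        Mean within-arm change in BMI z-score (follow-up minus baseline).
    sd_change : float
        Standard deviation of the change scores (>= 0).
    """

    n: int
    mean_change: float
    sd_change: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int,)) and self.n >= 2):
            raise ValueError(f"ArmSummary.n must be an integer >= 2, got {self.n!r}")
        for name in ("mean_change", "sd_change"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"ArmSummary.{name} must be finite, got {v!r}")
        if self.sd_change < 0:
            raise ValueError(f"ArmSummary.sd_change must be >= 0, got {self.sd_change!r}")


@dataclass(frozen=True)
class StudyRecord:
    """One randomized trial: one or more exercise arms and a single control arm."""

    study_id: str
    exercise_arms: tuple[ArmSummary, ...]
    control_arm: ArmSummary

    def __post_init__(self) -> None:
        if isinstance(self.exercise_arms, list):
            object.__setattr__(self, "exercise_arms", tuple(self.exercise_arms))
        if len(self.exercise_arms) < 1:
            raise ValueError(f"StudyRecord {self.study_id!r} needs >= 1 exercise arm")

    @property
    def n_total(self) -> int:
        return sum(a.n for a in self.exercise_arms) + self.control_arm.n

    @property
    def is_multiarm(self) -> bool:
        return len(self.exercise_arms) > 1


@dataclass(frozen=True)
class EffectEstimate:
    """Mean-difference effect of one study with its normal-theory inference.

    ``d`` is exercise minus control mean change (negative favours exercise),
    ``v`` its sampling variance, ``z = d / sqrt(v)`` and ``p`` the two-sided
    normal tail probability.
    """

    study_id: str
    d: float
    v: float
    se: float
    z: float
    p: float

    def __post_init__(self) -> None:
        if not (self.v > 0 and math.isfinite(self.v)):
            raise ValueError(f"EffectEstimate.v must be finite and > 0, got {self.v!r}")
        if not (0 < self.p <= 1):
            raise ValueError(f"EffectEstimate.p must lie in (0, 1], got {self.p!r}")


@dataclass(frozen=True)
class MetaResult:
    """Random-effects pooled result with heterogeneity statistics.

    ``i2`` and its confidence bounds are percentages; ``tau2`` is the
    DerSimonian-Laird between-study variance on the squared effect scale.
    """

    k: int
    pooled_d: float
    pooled_se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    q_df: int
    q_p: float
    i2: float
    i2_low: float
    i2_high: float


def compute_effect(study: StudyRecord) -> EffectEstimate:
    """Mean-difference effect estimate for a single-exercise-arm study.

    The variance of ``d`` uses the pooled two-sample form
    ``sp^2 * (1/n1 + 1/n2)`` with ``sp^2`` the df-weighted average of the
    two arm variances.  Multi-arm studies must be collapsed first with
    :func:`collapse_multiarm`.

    Raises
    ------
    ValueError
        If the study still carries more than one exercise arm.
    DegenerateVarianceError
        If both arms report zero SD (no sampling variability to infer from).
    """
    if study.is_multiarm:
        raise ValueError(
            f"study {study.study_id!r} has {len(study.exercise_arms)} exercise arms; "
            "collapse_multiarm first"
        )
    ex = study.exercise_arms[0]
    ct = study.control_arm
    d = ex.mean_change - ct.mean_change
    sp2 = ((ex.n - 1) * ex.sd_change**2 + (ct.n - 1) * ct.sd_change**2) / (ex.n + ct.n - 2)
    if sp2 <= 0:
        raise DegenerateVarianceError(
            f"study {study.study_id!r}: both arms have zero change-score SD"
        )
    v = sp2 * (1.0 / ex.n + 1.0 / ct.n)
    se = math.sqrt(v)
    z = d / se
    return EffectEstimate(study_id=study.study_id, d=d, v=v, se=se, z=z, p=two_sided_p(z))


def collapse_multiarm(study: StudyRecord) -> StudyRecord:
    """Merge all exercise arms of a study into one, preserving moments.

    The merged arm has ``n = sum(n_i)``, the n-weighted mean change, and the
    SD recovered from the combined-group sum of squares
    ``sum((n_i - 1) s_i^2) + sum(n_i (m_i - m)^2)`` over ``n - 1`` df — i.e.
    exactly the SD one would compute from the concatenated raw samples.
    Studies with a single exercise arm are returned unchanged.
    """
    if not study.is_multiarm:
        return study
    arms = study.exercise_arms
    n = sum(a.n for a in arms)
    mean = sum(a.n * a.mean_change for a in arms) / n
    ss = sum((a.n - 1) * a.sd_change**2 + a.n * (a.mean_change - mean) ** 2 for a in arms)
    sd = math.sqrt(ss / (n - 1))
    merged = ArmSummary(n=n, mean_change=mean, sd_change=sd)
    return StudyRecord(
        study_id=study.study_id, exercise_arms=(merged,), control_arm=study.control_arm
    )


def compute_i2(Q: float, k: int) -> float:
    """Higgins I^2 heterogeneity percentage, ``100 * max(0, (Q - df) / Q)``.

    Returns 0 when ``Q == 0``.  Requires ``k >= 2``.
    """
    if k < 2:
        raise ValueError(f"compute_i2 requires k >= 2 studies, got {k}")
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q}")
    if Q == 0:
        return 0.0
    return 100.0 * max(0.0, (Q - (k - 1)) / Q)


def i2_confint(Q: float, k: int) -> tuple[float, float]:
    """Test-based 95% confidence interval for I^2, in percent.

    Works on ``H = sqrt(Q / (k - 1))``: a normal interval on ``ln H`` with

    ``SE(ln H) = (ln Q - ln(k-1)) / (2 (sqrt(2Q) - sqrt(2k-3)))``  if Q > k,

    falling back to ``sqrt((1 - 1/(3(k-2)^2)) / (2(k-2)))`` otherwise, then
    transformed through ``I^2 = 100 (H^2 - 1) / H^2`` and truncated below
    at zero.  Requires ``Q > 0`` and ``k >= 3``.
    """
    if k < 3:
        raise ValueError(f"i2_confint requires k >= 3 studies, got {k}")
    if Q <= 0:
        raise ValueError(f"i2_confint requires Q > 0, got {Q}")
    ln_h = 0.5 * math.log(Q / (k - 1))
    if Q > k:
        se = 0.5 * (math.log(Q) - math.log(k - 1)) / (math.sqrt(2 * Q) - math.sqrt(2 * k - 3))
    else:
        se = math.sqrt(1.0 / (2 * (k - 2)) * (1.0 - 1.0 / (3 * (k - 2) ** 2)))

    def _to_i2(ln_h_bound: float) -> float:
        h2 = math.exp(2.0 * ln_h_bound)
        return max(0.0, 100.0 * (h2 - 1.0) / h2)

    return _to_i2(ln_h - _Z975 * se), _to_i2(ln_h + _Z975 * se)


def q_pvalue(Q: float, k: int) -> float:
    """Upper-tail chi-square probability of Cochran's Q on ``k - 1`` df."""
    if k < 2:
        raise ValueError(f"q_pvalue requires k >= 2 studies, got {k}")
    return float(stats.chi2.sf(Q, k - 1))


def pool_random_effects(effects: Sequence[EffectEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of study effects.

    Fixed-effect weights ``w_i = 1/v_i`` give Cochran's
    ``Q = sum w_i (d_i - d_FE)^2``; the moment estimator
    ``tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w))`` feeds
    random-effects weights ``1 / (v_i + tau2)``, from which the pooled
    mean difference, its SE and a normal-theory 95% CI follow.

    ``k = 1`` is a defined degenerate case: the study's own estimate with
    ``Q = 0``, ``tau2 = 0``, ``i2 = 0`` and ``q_p = 1``.  The I^2 interval
    is the test-based one when computable (``k >= 3`` and ``Q > 0``),
    otherwise it collapses to ``[0, i2]``.
    """
    k = len(effects)
    if k == 0:
        raise ValueError("pool_random_effects requires at least one study")
    w = [1.0 / e.v for e in effects]
    sw = sum(w)
    d_fe = sum(wi * e.d for wi, e in zip(w, effects)) / sw
    Q = sum(wi * (e.d - d_fe) ** 2 for wi, e in zip(w, effects))

    if k == 1:
        e = effects[0]
        return MetaResult(
            k=1, pooled_d=e.d, pooled_se=e.se,
            ci_low=e.d - _Z975 * e.se, ci_high=e.d + _Z975 * e.se,
            tau2=0.0, Q=0.0, q_df=0, q_p=1.0, i2=0.0, i2_low=0.0, i2_high=0.0,
        )

    c = sw - sum(wi * wi for wi in w) / sw
    tau2 = max(0.0, (Q - (k - 1)) / c) if c > 0 else 0.0
    w_re = [1.0 / (e.v + tau2) for e in effects]
    sw_re = sum(w_re)
    pooled_d = sum(wi * e.d for wi, e in zip(w_re, effects)) / sw_re
    pooled_se = math.sqrt(1.0 / sw_re)
    i2 = compute_i2(Q, k)
    if k >= 3 and Q > 0:
        i2_low, i2_high = i2_confint(Q, k)
    else:
        i2_low, i2_high = 0.0, i2
    return MetaResult(
        k=k,
        pooled_d=pooled_d,
        pooled_se=pooled_se,
        ci_low=pooled_d - _Z975 * pooled_se,
        ci_high=pooled_d + _Z975 * pooled_se,
        tau2=tau2,
        Q=Q,
        q_df=k - 1,
        q_p=q_pvalue(Q, k),
        i2=i2,
        i2_low=i2_low,
        i2_high=i2_high,
    )
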
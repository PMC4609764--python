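"""Synthetic two-arm trial corpora with known statistical structure.

Emulates a body of small randomized trials of exercise on BMI z-score in
overweight/obese children and adolescents: each study i has a true mean
difference theta_i ~ Normal(theta, tau^2) (negative = exercise benefit);
observed arm mean changes are drawn around the arm's true mean with SD
sigma / sqrt(n), and arm SD estimates are drawn from the scaled chi
distribution ``sigma * sqrt(chi2_{n-1} / (n-1))`` so that downstream
pooled-variance computations see realistic noise rather than known
variances.

The default configuration mimics a 10-study corpus totalling roughly 835
participants with moderate between-study heterogeneity (expected
I^2 ~ 58%).

A second generator produces *optionally stopped* ("p-hacked") studies:
participants accrue per arm in batches and the study's two-sided p is
recomputed at each interim look; the study freezes at the first look with
p below the stopping threshold, or at the final look.  Under a true null
this converts would-be nonsignificant studies into barely significant
ones, piling p-values up just below .05 — the left-skew signature the
p-curve's third channel is designed to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .meta import ArmSummary, StudyRecord, two_sided_p

__all__ = [
    "GeneratorConfig",
    "HackingConfig",
    "generate_trials",
    "generate_phacked_trials",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the honest trial generator.

    Defaults emulate the reference corpus: k = 10 studies, per-arm sizes
    uniform on [20, 64] (expected total ~ 840 participants over 20 arms),
    a true pooled benefit of -0.06 BMI z-score units, within-arm
    change-score SD of 0.25, and between-study SD tau = 0.068 calibrated so
    the expected I^2 is about 58%.
    """

    k: int = 10
    theta: float = -0.06
    tau: float = 0.068
    n_range: tuple[int, int] = (20, 64)
    sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.k, int) and self.k >= 1):
            raise ConfigurationError(f"k must be an integer >= 1, got {self.k!r}")
        if not (math.isfinite(self.theta)):
            raise ConfigurationError(f"theta must be finite, got {self.theta!r}")
        if not (math.isfinite(self.tau) and self.tau >= 0):
            raise ConfigurationError(f"tau must be >= 0, got {self.tau!r}")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ConfigurationError(f"sigma must be > 0, got {self.sigma!r}")
        lo, hi = self.n_range
        if not (isinstance(lo, int) and isinstance(hi, int) and 2 <= lo <= hi):
            raise ConfigurationError(
                f"n_range must be an integer pair with 2 <= min <= max, got {self.n_range!r}"
            )


@dataclass(frozen=True)
class HackingConfig:
    """Optional-stopping regime: accrual batch size per arm per look,
    maximum number of interim looks, and the stopping threshold on the
    two-sided p."""

    batch_size: int = 10
    max_looks: int = 20
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (isinstance(self.batch_size, int) and self.batch_size >= 1):
            raise ConfigurationError(
                f"batch_size must be an integer >= 1, got {self.batch_size!r}"
            )
        if not (isinstance(self.max_looks, int) and self.max_looks >= 1):
            raise ConfigurationError(
                f"max_looks must be an integer >= 1, got {self.max_looks!r}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha!r}")


def generate_trials(config: GeneratorConfig) -> list[StudyRecord]:
    """Draw an honest corpus of ``config.k`` two-arm studies.

    Per study: theta_i ~ N(theta, tau^2); arm sizes uniform on n_range;
    exercise mean change ~ N(theta_i, sigma^2/n1) around a zero control
    drift; control mean change ~ N(0, sigma^2/n2); arm SDs are scaled-chi
    draws with the arm's df.  Identical config (including seed) reproduces
    the identical corpus bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k
    theta_i = rng.normal(config.theta, config.tau, size=k)
    n = rng.integers(config.n_range[0], config.n_range[1] + 1, size=(k, 2))
    eps = rng.standard_normal(size=(k, 2))
    chi2 = np.column_stack(
        [rng.chisquare(n[:, 0] - 1), rng.chisquare(n[:, 1] - 1)]
    )
    sd = config.sigma * np.sqrt(chi2 / (n - 1))

    studies = []
    for i in range(k):
        n1, n2 = int(n[i, 0]), int(n[i, 1])
        m1 = theta_i[i] + eps[i, 0] * config.sigma / math.sqrt(n1)
        m2 = eps[i, 1] * config.sigma / math.sqrt(n2)
        studies.append(
            StudyRecord(
                study_id=f"S{i + 1:02d}",
                exercise_arms=(ArmSummary(n1, float(m1), float(sd[i, 0])),),
                control_arm=ArmSummary(n2, float(m2), float(sd[i, 1])),
            )
        )
    return studies


def _interim_p(s1: float, ss1: float, s2: float, ss2: float, n1: int, n2: int) -> float | None:
    """Two-sided p of the pooled-variance z-test from running sums, or None
    if it is not yet computable (an arm below 2 or zero pooled variance)."""
    if n1 < 2 or n2 < 2:
        return None
    m1, m2 = s1 / n1, s2 / n2
    var1 = (ss1 - n1 * m1 * m1) / (n1 - 1)
    var2 = (ss2 - n2 * m2 * m2) / (n2 - 1)
    sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    if sp2 <= 0:
        return None
    z = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return two_sided_p(z)


def generate_phacked_trials(
    config: GeneratorConfig, hacking: HackingConfig
) -> list[StudyRecord]:
    """Draw ``config.k`` studies subjected to optional stopping.

    Each study accrues ``batch_size`` participants per arm per look,
    recomputes the pooled-variance two-sided p after each look, and freezes
    at the first look with p < ``hacking.alpha`` or after ``max_looks``
    looks.  The returned records carry the frozen arm summaries.  With
    ``max_looks = 1`` this reduces to honest sampling at
    n = ``batch_size`` per arm.

    The canonical validation regime uses ``config.theta = 0`` (no true
    effect), where every stop on significance is a false positive; nonzero
    theta is permitted.
    """
    rng = np.random.default_rng(config.seed)
    b = hacking.batch_size
    studies = []
    for i in range(config.k):
        theta_i = rng.normal(config.theta, config.tau)
        s1 = ss1 = s2 = ss2 = 0.0
        n1 = n2 = 0
        for _look in range(hacking.max_looks):
            x1 = rng.normal(theta_i, config.sigma, size=b)
            x2 = rng.normal(0.0, config.sigma, size=b)
            s1 += x1.sum()
            ss1 += (x1 * x1).sum()
            s2 += x2.sum()
            ss2 += (x2 * x2).sum()
            n1 += b
            n2 += b
            p = _interim_p(s1, ss1, s2, ss2, n1, n2)
            if p is not None and p < hacking.alpha:
                break
        m1, m2 = s1 / n1, s2 / n2
        # guard df=0 when batch_size=1 and max_looks=1 is excluded by n>=2
        sd1 = math.sqrt(max(0.0, (ss1 - n1 * m1 * m1) / (n1 - 1)))
        sd2 = math.sqrt(max(0.0, (ss2 - n2 * m2 * m2) / (n2 - 1)))
        studies.append(
            StudyRecord(
                study_id=f"H{i + 1:02d}",
                exercise_arms=(ArmSummary(n1, m1, sd1),),
                control_arm=ArmSummary(n2, m2, sd2),
            )
        )
    return studies
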
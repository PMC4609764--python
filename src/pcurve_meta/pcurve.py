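"""The p-curve evidential-value procedure.

A p-curve is the distribution of the statistically significant two-sided
p-values (p < .05) in a set of studies.  If the studies probe a true effect
the curve is right-skewed (many very small p-values); if there is no effect
it is flat; if nonsignificant results were massaged into barely significant
ones it is left-skewed (a pile-up just below .05).

The procedure converts each significant p-value into a *pp-value* — the
probability, under a stated hypothesis and conditional on significance, of
a p-value at least as extreme as the one observed — and pools the pp-values
with Fisher's method (chi-square on 2k df).  Three channels are tested:

right-skew
    pp = p / alpha.  Small combined p => the curve is right-skewed and the
    study set contains evidential value.
flatter than 33% power
    pp recomputed under a noncentral (shifted-normal) alternative
    calibrated to 33% power, as the probability of a p-value at least as
    *large* as observed.  Small combined p => the studies are even flatter
    than a meagre 33% power would produce, i.e. they lack evidential value.
left-skew
    pp = 1 - p/alpha.  Small combined p => pile-up near alpha, the
    signature of intense p-hacking.

pp-values are winsorized at [0.01, 0.99] before pooling so single extreme
studies cannot dominate the chi-square.

All study p-values here derive from z-tests (normal deviates of mean
differences), so the noncentral machinery is the shifted-normal special
case; the power calibration solves for the noncentrality delta such that a
two-sided z-test at level alpha has exactly the reference power.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import EmptyPCurveError
from .meta import EffectEstimate

__all__ = [
    "PCurveConfig",
    "PPValueSet",
    "PCurveTest",
    "PCurveResult",
    "select_significant",
    "pp_right",
    "pp_left",
    "pp_33",
    "ncp_for_power",
    "implied_effect",
    "winsorize",
    "fisher_combine",
    "fisher_pvalue",
    "run_pcurve",
    "LABEL_RIGHT",
    "LABEL_FLAT",
    "LABEL_LEFT",
]

LABEL_RIGHT = "right_skew"
LABEL_FLAT = "flatter_than_33"
LABEL_LEFT = "left_skew"


@dataclass(frozen=True)
class PCurveConfig:
    """Tuning constants of the p-curve procedure.

    alpha : significance cutoff defining which studies enter (default .05).
    power_ref : reference power for the flatness channel (default 1/3).
    winsor_low, winsor_high : clamp bounds applied to every pp-value.
    inference_alpha : threshold applied to the three combined chi-square
        tests when labelling the verdict.
    """

    alpha: float = 0.05
    power_ref: float = 1.0 / 3.0
    winsor_low: float = 0.01
    winsor_high: float = 0.99
    inference_alpha: float = 0.05

    def __post_init__(self) -> None:
        from .exceptions import ConfigurationError

        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.power_ref < 1:
            raise ConfigurationError(f"power_ref must lie in (0, 1), got {self.power_ref}")
        if not 0 < self.winsor_low < self.winsor_high < 1:
            raise ConfigurationError(
                f"winsor bounds must satisfy 0 < low < high < 1, got "
                f"winsor_low={self.winsor_low}, winsor_high={self.winsor_high}"
            )
        if not 0 < self.inference_alpha < 1:
            raise ConfigurationError(
                f"inference_alpha must lie in (0, 1), got {self.inference_alpha}"
            )


@dataclass(frozen=True)
class PPValueSet:
    """Winsorized pp-values of one significant study, one per channel.

    ``winsorized`` flags which channels were clamped; the raw values are
    recoverable as ``p_obs / alpha``, its complement, and the flatness
    formula respectively.
    """

    study_id: str
    p_obs: float
    pp_right: float
    pp_33: float
    pp_left: float
    winsorized: Mapping[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class PCurveTest:
    """One Fisher-combined chi-square test (chi2, df, upper-tail p)."""

    chi2: float
    df: int
    p: float
    label: str = ""


@dataclass(frozen=True)
class PCurveResult:
    """The three skew tests plus the labelled verdict for a study set."""

    tests: tuple[PCurveTest, PCurveTest, PCurveTest]
    n_significant: int
    n_excluded: int
    inference: str
    pp_values: tuple[PPValueSet, ...] = ()

    def test(self, label: str) -> PCurveTest:
        for t in self.tests:
            if t.label == label:
                return t
        raise KeyError(label)


def select_significant(
    effects: Sequence[EffectEstimate], config: PCurveConfig = PCurveConfig()
) -> tuple[list[EffectEstimate], int]:
    """Filter the studies that enter the p-curve.

    A study enters iff its two-sided p is strictly below ``config.alpha``
    *and* its effect favours exercise (d < 0).  A significant effect in the
    wrong direction cannot support the directional hypothesis, so it is
    excluded with a warning.  Returns the retained studies in input order
    and the number excluded.
    """
    if len(effects) == 0:
        raise ValueError("select_significant requires a nonempty study list")
    included: list[EffectEstimate] = []
    for e in effects:
        if e.p < config.alpha and e.d < 0:
            included.append(e)
        elif e.p < config.alpha:
            warnings.warn(
                f"study {e.study_id!r} is significant (p={e.p:.4g}) but in the "
                "direction opposite the hypothesis; excluded from the p-curve",
                stacklevel=2,
            )
    if not included:
        raise EmptyPCurveError(
            "no study is significant in the hypothesized direction; "
            "the p-curve tests are undefined"
        )
    return included, len(effects) - len(included)


def pp_right(p_obs: float, config: PCurveConfig = PCurveConfig()) -> float:
    """Null pp-value of a significant p: ``p_obs / alpha`` (pre-winsorizing).

    Under a true null, significant two-sided p-values are uniform on
    (0, alpha), so this ratio is uniform on (0, 1).
    """
    if not 0 < p_obs < config.alpha:
        raise ValueError(
            f"pp_right requires 0 < p_obs < alpha={config.alpha}, got {p_obs}"
        )
    return p_obs / config.alpha


def pp_left(pp_right_value: float) -> float:
    """Left-skew pp-value: the complement ``1 - pp_right`` (pre-winsorizing)."""
    if not 0 < pp_right_value < 1:
        raise ValueError(f"pp_left requires a value in (0, 1), got {pp_right_value}")
    return 1.0 - pp_right_value


def _two_sided_power(ncp, alpha: float):
    """Power of the two-sided level-alpha z-test at noncentrality ``ncp``."""
    z_crit = stats.norm.isf(alpha / 2.0)
    return stats.norm.sf(z_crit - ncp) + stats.norm.cdf(-z_crit - ncp)


def ncp_for_power(
    n_exercise: int | None = None,
    n_control: int | None = None,
    config: PCurveConfig = PCurveConfig(),
) -> float:
    """Noncentrality delta at which the two-sided z-test has the reference power.

    Solves ``[1 - Phi(z_crit - delta)] + Phi(-z_crit - delta) = power_ref``
    by bracketed root-finding on delta in [0, 10] to a power error below
    1e-10.  For the z-test the solution does not depend on the sample sizes;
    they are accepted so the implied standardized effect
    ``delta * sqrt((n1 + n2) / (n1 n2))`` stays recoverable via
    :func:`implied_effect`.
    """
    target = config.power_ref
    f = lambda d: _two_sided_power(d, config.alpha) - target  # noqa: E731
    lo, hi = 0.0, 10.0
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError(
            f"power root not bracketed on [0, 10]: f(0)={f(lo):.3g}, f(10)={f(hi):.3g} "
            f"(alpha={config.alpha}, power_ref={target})"
        )
    delta = optimize.brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    assert abs(_two_sided_power(delta, config.alpha) - target) < 1e-10
    return float(delta)


def implied_effect(delta: float, n_exercise: int, n_control: int) -> float:
    """Standardized mean difference implied by a noncentrality for given arm sizes."""
    return delta * math.sqrt((n_exercise + n_control) / (n_exercise * n_control))


def pp_33(p_obs, ncp: float, config: PCurveConfig = PCurveConfig()):
    """Flatness pp-value of a significant p under the reference-power alternative.

    With ``z_obs = Phi^{-1}(1 - p/2)`` and extremity
    ``E = P(|Z| >= z_obs)`` for ``Z ~ Normal(ncp, 1)``, returns
    ``(S - E) / S`` with ``S = power_ref`` — the probability, under the
    reference power and conditional on significance, of a p-value at least
    as large as the one observed.  Clamped to [0, 1]; winsorizing is applied
    separately.  Accepts scalars or arrays.
    """
    p = np.asarray(p_obs, dtype=float)
    if np.any((p <= 0) | (p >= config.alpha)):
        raise ValueError(
            f"pp_33 requires 0 < p_obs < alpha={config.alpha}, got {p_obs}"
        )
    z_obs = stats.norm.isf(p / 2.0)
    extremity = stats.norm.sf(z_obs - ncp) + stats.norm.cdf(-z_obs - ncp)
    s = config.power_ref
    out = np.clip((s - extremity) / s, 0.0, 1.0)
    return float(out) if np.isscalar(p_obs) else out


def winsorize(pp, config: PCurveConfig = PCurveConfig()):
    """Clamp a pp-value (scalar or array) to ``[winsor_low, winsor_high]``."""
    out = np.clip(pp, config.winsor_low, config.winsor_high)
    return float(out) if np.isscalar(pp) else out


def fisher_pvalue(chi2_stat: float, df: int) -> float:
    """Upper-tail chi-square probability of a Fisher combined statistic."""
    if df <= 0 or df % 2 != 0:
        raise ValueError(f"Fisher's method needs a positive even df, got {df}")
    return float(stats.chi2.sf(chi2_stat, df))


def fisher_combine(pps: Iterable[float]) -> PCurveTest:
    """Fisher's method: ``chi2 = -2 sum ln(pp)`` on ``2k`` df.

    Any pp of exactly 0 is a domain error (winsorize first); pp = 1
    contributes nothing.
    """
    pps = list(pps)
    if not pps:
        raise ValueError("fisher_combine requires at least one pp-value")
    for pp in pps:
        if not 0 < pp <= 1:
            raise ValueError(f"pp-values must lie in (0, 1], got {pp}")
    chi2_stat = -2.0 * sum(math.log(pp) for pp in pps)
    df = 2 * len(pps)
    return PCurveTest(chi2=chi2_stat, df=df, p=fisher_pvalue(chi2_stat, df))


# Verdict strings used by run_pcurve
INFERENCE_EVIDENTIAL = "contains evidential value"
INFERENCE_LACKS = "lacks evidential value"
INFERENCE_LACKS_HACKED = "lacks evidential value and intensely p-hacked"
INFERENCE_HACKED = "intensely p-hacked"
INFERENCE_INCONCLUSIVE = "inconclusive"


def run_pcurve(
    effects: Sequence[EffectEstimate],
    sizes: Mapping[str, tuple[int, int]] | None = None,
    config: PCurveConfig = PCurveConfig(),
) -> PCurveResult:
    """Run the full three-channel p-curve on a set of study effects.

    Selects the significant, directionally consistent studies, builds the
    right-skew / flatness / left-skew pp-values per study, winsorizes each,
    pools each channel with Fisher's method, and labels the verdict:
    significant right-skew means the set contains evidential value;
    otherwise a significant flatness test means it lacks evidential value,
    and a significant left-skew test additionally flags intense p-hacking.

    ``sizes`` optionally maps study_id to (n_exercise, n_control); for the
    z-test specialization the reference-power noncentrality is the same for
    every study, so sizes only matter for reporting implied effects.
    """
    included, n_excluded = select_significant(effects, config)
    delta = ncp_for_power(config=config)

    pp_sets: list[PPValueSet] = []
    for e in included:
        raw_r = pp_right(e.p, config)
        raw_f = pp_33(e.p, delta, config)
        raw_l = pp_left(raw_r)
        w_r = winsorize(raw_r, config)
        w_f = winsorize(raw_f, config)
        w_l = winsorize(raw_l, config)
        pp_sets.append(
            PPValueSet(
                study_id=e.study_id,
                p_obs=e.p,
                pp_right=w_r,
                pp_33=w_f,
                pp_left=w_l,
                winsorized={
                    "right": w_r != raw_r,
                    "flat": w_f != raw_f,
                    "left": w_l != raw_l,
                },
            )
        )

    t_right = fisher_combine([s.pp_right for s in pp_sets])
    t_flat = fisher_combine([s.pp_33 for s in pp_sets])
    t_left = fisher_combine([s.pp_left for s in pp_sets])
    tests = (
        PCurveTest(t_right.chi2, t_right.df, t_right.p, LABEL_RIGHT),
        PCurveTest(t_flat.chi2, t_flat.df, t_flat.p, LABEL_FLAT),
        PCurveTest(t_left.chi2, t_left.df, t_left.p, LABEL_LEFT),
    )

    a = config.inference_alpha
    if tests[0].p <= a:
        inference = INFERENCE_EVIDENTIAL
    elif tests[1].p <= a and tests[2].p <= a:
        inference = INFERENCE_LACKS_HACKED
    elif tests[1].p <= a:
        inference = INFERENCE_LACKS
    elif tests[2].p <= a:
        inference = INFERENCE_HACKED
    else:
        inference = INFERENCE_INCONCLUSIVE

    return PCurveResult(
        tests=tests,
        n_significant=len(included),
        n_excluded=n_excluded,
        inference=inference,
        pp_values=tuple(pp_sets),
    )
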
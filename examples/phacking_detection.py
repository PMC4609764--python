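"""Show the left-skew channel catching optional stopping.

Builds two published literatures of 15 significant studies each: one
harvested from honest null studies (pure selective publication), one from
null studies that peeked at the data after every 10 participants per arm
and stopped at the first significant look.  Only the second should pile
p-values up just below .05 and trigger the left-skew test.
"""

import warnings

import numpy as np

from pcurve_meta import GeneratorConfig, compute_effect, generate_trials, run_pcurve
from pcurve_meta.validate import INTENSE_HACKING, harvest_significant_hacked

warnings.filterwarnings("ignore", message=".*opposite the hypothesis.*")


def harvest_honest(n, seed):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        cfg = GeneratorConfig(k=50, theta=0.0, tau=0.0, seed=int(rng.integers(2**31)))
        for s in generate_trials(cfg):
            e = compute_effect(s)
            if e.p < 0.05 and e.d < 0:
                out.append(e)
                if len(out) == n:
                    break
    return out


for name, effects in [
    ("honest-but-selected", harvest_honest(15, seed=7)),
    ("optionally stopped", harvest_significant_hacked(15, hacking=INTENSE_HACKING, seed=7)),
]:
    p = np.array([e.p for e in effects])
    res = run_pcurve(effects)
    left = res.test("left_skew")
    print(f"{name}: {np.mean(p > 0.04):.0%} of p-values in (.04,.05]; "
          f"left-skew chi2 = {left.chi2:.1f} (df {left.df}, p = {left.p:.4f})")
    print(f"  inference: {res.inference}")

print("\nBoth literatures contain only significant findings; the left-skew "
      "test separates honest selection from data peeking.")
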
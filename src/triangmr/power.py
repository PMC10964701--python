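"""Statistical power of two-sample MR with a binary outcome.

The IV estimator's Wald test has approximate non-centrality
ncp = n_outcome * cf*(1-cf) * r2_xz * log(OR)^2, where cf is the outcome
case fraction, r2_xz the variance of the exposure explained by the
instruments, and OR the true causal odds ratio per exposure SD.  Power of
the two-sided level-alpha test is
Phi(-z_{1-a/2} + sqrt(ncp)) + Phi(-z_{1-a/2} - sqrt(ncp)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["PowerResult", "mr_power_binary"]


@dataclass
class PowerResult:
    power: float
    ncp: float
    alpha: float
    n_outcome: int
    case_fraction: float
    r2_xz: float
    true_or: float


def mr_power_binary(n_outcome: int, case_fraction: float, r2_xz: float,
                    true_or: float, alpha: float = 0.05) -> PowerResult:
    """Approximate power of the two-sided causal Wald test.

    Power equals alpha when the true OR is 1 or the instruments explain no
    exposure variance, and is symmetric in OR <-> 1/OR.
    """
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0,1)")
    if not 0 <= r2_xz <= 1:
        raise ValueError("r2_xz must be in [0,1]")
    if true_or <= 0:
        raise ValueError("true_or must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if n_outcome <= 0:
        raise ValueError("n_outcome must be positive")
    if r2_xz == 0 and true_or != 1.0:
        warnings.warn("r2_xz = 0: the instrument carries no signal; "
                      "power equals alpha")
    b = np.log(true_or)
    ncp = n_outcome * case_fraction * (1 - case_fraction) * r2_xz * b ** 2
    zq = norm.ppf(1 - alpha / 2)
    power = float(norm.cdf(-zq + np.sqrt(ncp)) + norm.cdf(-zq - np.sqrt(ncp)))
    return PowerResult(power=power, ncp=float(ncp), alpha=alpha,
                       n_outcome=n_outcome, case_fraction=case_fraction,
                       r2_xz=r2_xz, true_or=true_or)
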
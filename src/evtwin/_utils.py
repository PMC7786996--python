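"""Small shared numerics: logit transforms, quantiles, reporting helpers."""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit as _logit

#: Clamping bounds applied to true beta values before the logit transform,
#: so that logit never produces infinities.
BETA_FLOOR = 0.001
BETA_CEIL = 0.999


def clamp_beta(x):
    """Clamp beta values into the open interval used ahead of logit."""
    return np.clip(x, BETA_FLOOR, BETA_CEIL)


def logit(p):
    return _logit(clamp_beta(np.asarray(p, dtype=float)))


def inv_logit(x):
    return expit(x)


def quantile(x, q):
    """Linear-interpolation ("type 7") quantile, the single convention used
    for IQR gating, coverage cuts and epsilon calibration."""
    return np.quantile(np.asarray(x, dtype=float), q, method="linear")


def iqr(x) -> float:
    """Inter-quartile range q0.75 - q0.25 with interpolated quantiles."""
    q25, q75 = quantile(x, [0.25, 0.75])
    return float(q75 - q25)


def percent(k: int, n: int, ndigits: int = 0) -> float:
    """Share of ``k`` out of ``n`` expressed in percent, rounded for reports."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * k / n, ndigits)
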
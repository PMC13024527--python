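"""Clinical sample-size calculators for diagnostic-device studies.

Two estimators are provided, following standard medical-device trial
guidance:

* **single-arm target-value design** — compares an expected performance rate
  ``PT`` (e.g. model accuracy) against a pre-specified minimum acceptable
  threshold ``P0``:

      n = [ z_{1-α/2} √(P0(1-P0)) + z_{1-β} √(PT(1-PT)) ]² / (PT - P0)²

* **diagnostic-accuracy design** — sizes the positive group from the expected
  sensitivity (and the negative group from specificity) ``P`` at a chosen
  half-width ``Δ`` of the (1-α) confidence interval:

      n = P(1-P) z_{1-α/2}² / Δ²

Both results are rounded half-up to an integer by default (``ceil=True``
gives the conservative round-up convention), and a dropout adjustment
``n / (1 - dropout)`` is available.

Normal quantiles come from the exact inverse CDF; ``rounded_quantiles=True``
substitutes the 2–3 digit constants (1.96, 0.842) used in printed worked
examples — both conventions give identical integer sizes on typical inputs.
"""

from __future__ import annotations

import math

from scipy.stats import norm

__all__ = ["single_arm_n", "diagnostic_n", "adjust_for_dropout"]

# printed-constant quantiles used in worked examples
_ROUNDED_Z = {0.975: 1.96, 0.8: 0.842, 0.9: 1.282, 0.95: 1.645}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _z(p: float, rounded: bool) -> float:
    if rounded and round(p, 3) in _ROUNDED_Z:
        return _ROUNDED_Z[round(p, 3)]
    return float(norm.ppf(p))


def single_arm_n(pt: float, p0: float, alpha: float = 0.05, power: float = 0.8,
                 ceil: bool = False, rounded_quantiles: bool = False) -> int:
    """Per-group size for a single-arm target-value trial.

    Parameters
    ----------
    pt : expected performance rate of the device under test, in (0, 1).
    p0 : minimum acceptable rate (the target value), in (0, 1); must differ
        from ``pt``.
    alpha : two-sided type-I error rate.
    power : 1 - β.
    """
    for name, v in (("pt", pt), ("p0", p0)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1), got {v}")
    if pt == p0:
        raise ZeroDivisionError("pt must differ from p0 (zero effect size)")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must lie in (0, 1)")
    za = _z(1.0 - alpha / 2.0, rounded_quantiles)
    zb = _z(power, rounded_quantiles)
    num = (za * math.sqrt(p0 * (1.0 - p0)) + zb * math.sqrt(pt * (1.0 - pt))) ** 2
    n = num / (pt - p0) ** 2
    return math.ceil(n) if ceil else _round_half_up(n)


def diagnostic_n(p: float, delta: float, alpha: float = 0.05,
                 ceil: bool = False, rounded_quantiles: bool = False) -> int:
    """Per-group size for a diagnostic accuracy study.

    ``p`` is the expected sensitivity (positive group) or specificity
    (negative group); ``delta`` is the allowable half-width of its
    (1 - alpha) confidence interval, conventionally 0.05–0.10.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if delta <= 0:
        raise ValueError("delta must be positive")
    za = _z(1.0 - alpha / 2.0, rounded_quantiles)
    n = p * (1.0 - p) * za ** 2 / delta ** 2
    return math.ceil(n) if ceil else _round_half_up(n)


def adjust_for_dropout(n: int, dropout: float, ceil: bool = False) -> int:
    """Inflate a sample size for an anticipated dropout fraction."""
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    adj = n / (1.0 - dropout)
    return math.ceil(adj) if ceil else _round_half_up(adj)
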
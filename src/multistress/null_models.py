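"""Five null models for the joint mortality effect of two independent stressors.

Given the individual stress effects ``e_A`` and ``e_B`` (mortality fractions
relative to control), each model predicts the joint effect under a different
assumption about how independently acting stressors combine:

- **Simple Addition** — ``e_A + e_B`` (truncated at 1); assumes perfectly
  anti-correlated sensitivities.
- **Multiplicative** — ``e_A + e_B - e_A e_B`` (probabilistic sum /
  Bliss independence); uncorrelated sensitivities.
- **Dominance** — ``max(e_A, e_B)``; perfectly correlated sensitivities.
- **Concentration Addition** — Loewe additivity: intensities are
  exchangeable once scaled by relative potency ``gamma``, the ratio of the
  two curves' half-effect intensities; the joint effect is curve A
  evaluated at ``SI_A + gamma * SI_B``.
- **Stressor Addition** — every stressor consumes a share of a common
  "general stress capacity": effects are mapped to capacity quantiles,
  summed, and mapped back through the capacity CDF. The capacity
  distribution defaults to a symmetric beta(3.2, 3.2).

Raw predictions above 100% mortality are truncated to 1 inside each model
and flagged, so downstream statistics only ever see attainable mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy import stats

from .effect_curves import EffectCurve, evaluate, half_effect_intensity

__all__ = [
    "MODEL_IDS",
    "StressCapacity",
    "JointPrediction",
    "simple_addition",
    "multiplicative",
    "dominance",
    "concentration_addition",
    "stressor_addition",
    "predict_all",
]

#: Canonical model order used throughout reports.
MODEL_IDS = (
    "simple_addition",
    "multiplicative",
    "dominance",
    "concentration_addition",
    "stressor_addition",
)


@dataclass(frozen=True)
class StressCapacity:
    """Population distribution of general stress capacity on [0, 1].

    A symmetric beta with ``alpha = beta = 3.2`` by default. ``cdf`` maps a
    general stress level to the mortality fraction it causes; ``quantile``
    maps a mortality fraction back to the stress level that would cause it.
    """

    alpha: float = 3.2
    beta: float = 3.2

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be positive")

    @property
    def _dist(self):
        return stats.beta(self.alpha, self.beta)

    def cdf(self, x):
        return self._dist.cdf(np.clip(x, 0.0, 1.0))

    def quantile(self, p):
        q = self._dist.ppf(np.clip(p, 0.0, 1.0))
        # scipy's ppf underflows to nan for subnormal probabilities; the
        # true quantile there is indistinguishable from the support endpoint
        if np.any(np.isnan(q)):
            q = np.where(np.isnan(q), np.where(np.asarray(p) < 0.5, 0.0, 1.0), q)
        return q


@dataclass(frozen=True)
class JointPrediction:
    """One model's joint-effect prediction for a single condition."""

    model_id: str
    predicted_mortality: float
    truncated_flag: bool = False

    def __post_init__(self):
        if not 0.0 <= self.predicted_mortality <= 1.0:
            raise ValueError(
                f"prediction outside [0,1]: {self.predicted_mortality!r}"
            )


def _check_effect(name: str, e: float) -> float:
    e = float(e)
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"{name} must be a mortality fraction in [0, 1], got {e!r}")
    return e


def simple_addition(effect_a: float, effect_b: float) -> JointPrediction:
    """Joint effect as the plain sum of the individual effects."""
    ea, eb = _check_effect("effect_a", effect_a), _check_effect("effect_b", effect_b)
    raw = ea + eb
    return JointPrediction("simple_addition", min(raw, 1.0), raw > 1.0)


def multiplicative(effect_a: float, effect_b: float) -> JointPrediction:
    """Joint effect as the probabilistic sum (Bliss independence)."""
    ea, eb = _check_effect("effect_a", effect_a), _check_effect("effect_b", effect_b)
    return JointPrediction("multiplicative", ea + eb - ea * eb, False)


def dominance(effect_a: float, effect_b: float) -> JointPrediction:
    """Joint effect equal to the larger individual effect."""
    ea, eb = _check_effect("effect_a", effect_a), _check_effect("effect_b", effect_b)
    return JointPrediction("dominance", max(ea, eb), False)


def concentration_addition(
    curve_a: EffectCurve,
    curve_b: EffectCurve,
    si_a: float,
    si_b: float,
) -> JointPrediction:
    """Loewe-additive joint effect, anchored on curve A.

    ``gamma = h_A / h_B`` where ``h`` is each curve's half-effect intensity;
    the prediction is ``f_A(SI_A + gamma * SI_B)`` with the argument clamped
    to 1 (clamping sets the truncation flag). The two curves must share an
    effect limit, otherwise "half the effect-size limit" is ambiguous.
    """
    if abs(curve_a.limit - curve_b.limit) > 1e-12:
        raise ValueError(
            "concentration addition requires curves with equal effect limits; "
            f"got {curve_a.limit!r} and {curve_b.limit!r}"
        )
    for name, si in (("si_a", si_a), ("si_b", si_b)):
        if not 0.0 <= si <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {si!r}")
    ha = half_effect_intensity(curve_a)
    hb = half_effect_intensity(curve_b)
    if ha <= 0.0 or hb <= 0.0:
        raise ValueError("degenerate curve: zero half-effect intensity")
    gamma = ha / hb
    raw_arg = si_a + gamma * si_b
    pred = evaluate(curve_a, min(raw_arg, 1.0))
    return JointPrediction("concentration_addition", pred, raw_arg > 1.0)


def stressor_addition(
    effect_a: float,
    effect_b: float,
    capacity: StressCapacity | None = None,
) -> JointPrediction:
    """Joint effect via summation of general stress levels.

    Effects are converted to stress levels through the capacity quantile
    function, summed, and converted back through the CDF. A stress sum
    beyond the capacity support (> 1) saturates at certain death and sets
    the truncation flag.
    """
    ea, eb = _check_effect("effect_a", effect_a), _check_effect("effect_b", effect_b)
    cap = capacity if capacity is not None else StressCapacity()
    stress = float(cap.quantile(ea)) + float(cap.quantile(eb))
    return JointPrediction(
        "stressor_addition", float(cap.cdf(min(stress, 1.0))), stress > 1.0
    )


def predict_all(
    curve_a: EffectCurve,
    curve_b: EffectCurve,
    si_a: float,
    si_b: float,
    capacity: StressCapacity | None = None,
) -> Dict[str, JointPrediction]:
    """Evaluate both individual effects and all five null models.

    Returns predictions keyed by model id, in canonical order.
    """
    cap = capacity if capacity is not None else StressCapacity()
    ea = evaluate(curve_a, si_a)
    eb = evaluate(curve_b, si_b)
    return {
        "simple_addition": simple_addition(ea, eb),
        "multiplicative": multiplicative(ea, eb),
        "dominance": dominance(ea, eb),
        "concentration_addition": concentration_addition(curve_a, curve_b, si_a, si_b),
        "stressor_addition": stressor_addition(ea, eb, cap),
    }
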
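"""Stressor-effect relationships: monotone curves mapping intensity to mortality.

A stressor-effect relationship maps a normalized stressor intensity
``x in [0, 1]`` to a population mortality fraction in ``[0, limit]``.
Five named shapes are built in (linear, accelerating, diminishing,
steep_middle, steep_extremes); all are anchored at ``f(0) = 0`` and
``f(1) = limit`` and are strictly increasing. Custom shapes can be
registered programmatically or loaded from a YAML/JSON config as monotone
piecewise-linear breakpoint lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, Mapping

import numpy as np
from scipy import stats

__all__ = [
    "EffectCurve",
    "UnattainableEffectError",
    "SHAPE_IDS",
    "register_shape",
    "registered_shapes",
    "load_shape_config",
    "evaluate",
    "invert",
    "half_effect_intensity",
    "scale_to_scope",
]

#: Bisection tolerance (in intensity units) for curve inversion.
INVERT_XTOL = 1e-9


class UnattainableEffectError(ValueError):
    """Requested effect exceeds the curve's maximum (its ``limit``)."""

    def __init__(self, effect: float, limit: float):
        self.effect = effect
        self.limit = limit
        super().__init__(
            f"effect {effect!r} exceeds the curve's effect limit {limit!r}"
        )


# ---------------------------------------------------------------------------
# shape registry
# ---------------------------------------------------------------------------

# Unit shapes map [0,1] -> [0,1] with f(0)=0, f(1)=1, strictly increasing.
# The two "steep" shapes are CDFs of symmetric beta distributions: beta(3,3)
# concentrates slope in the middle, beta(1/3, 1/3) at the extremes.
_steep_middle = stats.beta(3.0, 3.0)
_steep_extremes = stats.beta(1.0 / 3.0, 1.0 / 3.0)

_UNIT_SHAPES: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda x: x,
    "accelerating": lambda x: x**2,
    "diminishing": lambda x: 1.0 - (1.0 - x) ** 2,
    "steep_middle": _steep_middle.cdf,
    "steep_extremes": _steep_extremes.cdf,
}

#: The default five shapes, in canonical order.
SHAPE_IDS = ("linear", "accelerating", "diminishing", "steep_middle", "steep_extremes")


def register_shape(shape_id: str, unit_fn: Callable[[np.ndarray], np.ndarray],
                   *, validate: bool = True) -> None:
    """Register a custom unit shape ``f: [0,1] -> [0,1]``.

    ``unit_fn`` must be vectorized (accept ndarrays), anchored at
    ``f(0)=0``/``f(1)=1`` and non-decreasing; these are checked on a dense
    grid when ``validate`` is true.
    """
    if validate:
        x = np.linspace(0.0, 1.0, 513)
        y = np.asarray(unit_fn(x), dtype=float)
        if not (abs(y[0]) < 1e-9 and abs(y[-1] - 1.0) < 1e-9):
            raise ValueError(f"shape {shape_id!r} is not anchored at (0,0) and (1,1)")
        if np.any(np.diff(y) < -1e-12):
            raise ValueError(f"shape {shape_id!r} is not monotone non-decreasing")
    _UNIT_SHAPES[shape_id] = unit_fn


def registered_shapes() -> tuple:
    """Names of all currently registered shapes."""
    return tuple(_UNIT_SHAPES)


def load_shape_config(config: Mapping) -> None:
    """Register shapes from a config mapping.

    Expected structure ``{"shapes": {name: [[x0, y0], [x1, y1], ...]}}``
    with monotone breakpoints anchored at (0,0) and (1,1); curves are
    interpolated piecewise-linearly between breakpoints.
    """
    for name, pts in dict(config.get("shapes", {})).items():
        arr = np.asarray(pts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError(f"shape {name!r}: breakpoints must be an (n,2) list")
        xs, ys = arr[:, 0], arr[:, 1]
        if np.any(np.diff(xs) <= 0):
            raise ValueError(f"shape {name!r}: breakpoint x-values must increase")
        register_shape(name, lambda x, xs=xs, ys=ys: np.interp(x, xs, ys))


# ---------------------------------------------------------------------------
# curve type and operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectCurve:
    """A monotone stressor-effect relationship.

    Parameters
    ----------
    shape_id
        Name of a registered shape.
    limit
        Maximum mortality fraction, in (0, 1]. ``evaluate(1) == limit``.
    """

    shape_id: str
    limit: float = 1.0

    def __post_init__(self):
        if self.shape_id not in _UNIT_SHAPES:
            raise KeyError(
                f"unknown shape {self.shape_id!r}; registered: {registered_shapes()}"
            )
        if not 0.0 < self.limit <= 1.0:
            raise ValueError(f"limit must be in (0, 1], got {self.limit!r}")

    # methods mirror the module-level operations for convenience
    def evaluate(self, intensity):
        return evaluate(self, intensity)

    def invert(self, effect):
        return invert(self, effect)

    @property
    def unit_fn(self) -> Callable:
        return _UNIT_SHAPES[self.shape_id]


def evaluate(curve: EffectCurve, intensity):
    """Mortality fraction caused by a single stressor at ``intensity``.

    Accepts scalars or ndarrays; intensities outside [0, 1] raise
    ``ValueError``.
    """
    x = np.asarray(intensity, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError(f"intensity must lie in [0, 1], got {intensity!r}")
    out = curve.limit * np.asarray(curve.unit_fn(x), dtype=float)
    return float(out) if np.isscalar(intensity) or out.ndim == 0 else out


def invert(curve: EffectCurve, effect: float) -> float:
    """Smallest intensity ``x`` with ``evaluate(curve, x) >= effect``.

    Bisection to an absolute x-tolerance of 1e-9, used even for shapes with
    closed-form inverses so that user-registered shapes need only provide
    ``evaluate``.
    """
    e = float(effect)
    if e < 0.0:
        raise ValueError(f"effect must be non-negative, got {effect!r}")
    if e > curve.limit + 1e-12:
        raise UnattainableEffectError(e, curve.limit)
    e = min(e, curve.limit)
    if e == 0.0:
        return 0.0
    if e == curve.limit:
        # the limit is attained exactly at 1 by anchoring; bisection would
        # stop early where the CDF-style shapes saturate in float arithmetic
        return 1.0
    lo, hi = 0.0, 1.0  # invariant: f(lo) < e <= f(hi)
    while hi - lo > INVERT_XTOL:
        mid = 0.5 * (lo + hi)
        if evaluate(curve, mid) >= e:
            hi = mid
        else:
            lo = mid
    return hi


def half_effect_intensity(curve: EffectCurve) -> float:
    """Intensity at which the curve reaches half its effect limit.

    This is the relative-potency anchor used by Concentration Addition:
    scaling the limit does not move it, since half of a scaled limit is
    reached at the same intensity.
    """
    return invert(curve, curve.limit / 2.0)


def scale_to_scope(curve: EffectCurve, scope: float) -> EffectCurve:
    """Rescale the curve's maximum effect to ``scope``, preserving shape.

    Used when a control group already shows mortality ``c``: the maximum
    additional (stress-attributable) mortality is ``1 - c``, so curves are
    rescaled to that scope before intensities are inferred.
    """
    if not scope > 0.0:
        raise ValueError(f"scope must be positive, got {scope!r}")
    if scope > 1.0:
        raise ValueError(f"scope must be <= 1, got {scope!r}")
    return replace(curve, limit=scope)
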
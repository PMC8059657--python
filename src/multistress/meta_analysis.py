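"""Classify factorial two-stressor experiments against the null-model envelope.

Ingests 2x2 factorial survival/mortality experiments (control, stressor-A-only,
stressor-B-only, combined), converts everything to mortality, derives the
individual and joint stress effects as treatment-minus-control differences,
filters out records where a "stressor" increased survival, predicts the joint
effect under all five null models — Concentration Addition swept over all 25
ordered shape combinations with the curves rescaled to the experiment's scope
(1 - control mortality) — and classifies each observation as below, within, or
above the closed envelope of predictions. Per-model bias (mean of
prediction - observed) and precision (SD of the same differences) summarize
each model's accuracy across the collection.

Input CSV schema (header required)::

    experiment_id, endpoint_kind, control, stressor_a, stressor_b, combined
    [, n_control, n_a, n_b, n_ab, source]

``endpoint_kind`` is ``survival`` or ``mortality``; all four group values are
proportions in [0, 1] on that endpoint's scale.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .effect_curves import (
    SHAPE_IDS,
    EffectCurve,
    UnattainableEffectError,
    invert,
    scale_to_scope,
)
from .null_models import (
    MODEL_IDS,
    StressCapacity,
    dominance,
    multiplicative,
    simple_addition,
    stressor_addition,
)

__all__ = [
    "FactorialExperiment",
    "ExperimentEffects",
    "EnvelopeClassification",
    "ExperimentValidationError",
    "load_experiments",
    "derive_effects",
    "filter_experiments",
    "predict_envelope",
    "classify_all",
    "bias_precision",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "experiment_id",
    "endpoint_kind",
    "control",
    "stressor_a",
    "stressor_b",
    "combined",
)
OPTIONAL_COLUMNS = ("n_control", "n_a", "n_b", "n_ab", "source")
CA_SUMMARIES = ("mean", "median", "min", "max")


class ExperimentValidationError(ValueError):
    """Raised when input rows violate the experiment schema; lists every row."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid experiment table:\n" + "\n".join(self.problems)
        )


@dataclass(frozen=True)
class FactorialExperiment:
    """One full-factorial two-stressor experiment (proportions per arm)."""

    experiment_id: str
    endpoint_kind: str  # "survival" or "mortality"
    control_value: float
    a_only_value: float
    b_only_value: float
    combined_value: float
    group_sizes: Optional[Dict[str, int]] = None
    source: str = ""

    def __post_init__(self):
        if self.endpoint_kind not in ("survival", "mortality"):
            raise ValueError(
                f"endpoint_kind must be 'survival' or 'mortality', "
                f"got {self.endpoint_kind!r}"
            )
        for name in ("control_value", "a_only_value", "b_only_value", "combined_value"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0,1], got {v!r}")

    def mortality(self, arm: str) -> float:
        """Arm value on the mortality scale (survival endpoints are flipped)."""
        v = {
            "control": self.control_value,
            "a": self.a_only_value,
            "b": self.b_only_value,
            "ab": self.combined_value,
        }[arm]
        return 1.0 - v if self.endpoint_kind == "survival" else v


@dataclass(frozen=True)
class ExperimentEffects:
    """Derived stress effects for one experiment (mortality-difference scale)."""

    experiment_id: str
    effect_a: float
    effect_b: float
    observed_joint: float
    scope: float  # 1 - control mortality: mortality still available to cause


@dataclass(frozen=True)
class EnvelopeClassification:
    """Null-model predictions and envelope category for one experiment."""

    experiment_id: str
    predictions: Dict[str, float]  # four direct models
    ca_values: Tuple[float, ...]  # concentration addition, per shape pair
    ca_summary: float
    envelope_low: float
    envelope_high: float
    observed_joint: float
    category: str  # below | within | above


# ---------------------------------------------------------------------------
# ingestion and effect derivation
# ---------------------------------------------------------------------------

def load_experiments(path) -> List[FactorialExperiment]:
    """Read and validate a factorial-experiment CSV.

    Every offending row is reported (with its row number) in a single
    :class:`ExperimentValidationError`; nothing is silently dropped.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ExperimentValidationError(
            [f"missing required column(s): {', '.join(missing)}"]
        )
    problems: List[str] = []
    records: List[FactorialExperiment] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        try:
            sizes = None
            if all(c in df.columns for c in ("n_control", "n_a", "n_b", "n_ab")):
                raw = {k: row[f"n_{k2}"] for k, k2 in
                       [("control", "control"), ("a", "a"), ("b", "b"), ("ab", "ab")]}
                if all(pd.notna(v) for v in raw.values()):
                    sizes = {k: int(v) for k, v in raw.items()}
            records.append(
                FactorialExperiment(
                    experiment_id=str(row["experiment_id"]),
                    endpoint_kind=str(row["endpoint_kind"]).strip().lower(),
                    control_value=float(row["control"]),
                    a_only_value=float(row["stressor_a"]),
                    b_only_value=float(row["stressor_b"]),
                    combined_value=float(row["combined"]),
                    group_sizes=sizes,
                    source=str(row["source"]) if "source" in df.columns
                    and pd.notna(row.get("source")) else "",
                )
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"row {rowno}: {exc}")
    if problems:
        raise ExperimentValidationError(problems)
    return records


def derive_effects(exp: FactorialExperiment) -> ExperimentEffects:
    """Individual and joint stress effects as treatment-minus-control mortality.

    Effects may be negative here (a "stressor" that decreased mortality);
    filtering is a separate, explicit step.
    """
    c = exp.mortality("control")
    return ExperimentEffects(
        experiment_id=exp.experiment_id,
        effect_a=exp.mortality("a") - c,
        effect_b=exp.mortality("b") - c,
        observed_joint=exp.mortality("ab") - c,
        scope=1.0 - c,
    )


def filter_experiments(
    effects: Iterable[ExperimentEffects],
) -> Tuple[List[ExperimentEffects], List[Tuple[ExperimentEffects, str]]]:
    """Split records into (kept, excluded-with-reason).

    A record is excluded when either individual "stressor" increased
    survival (negative derived effect) — such exposures are not stressors
    under the working definition. The observed joint effect is *not*
    filtered on.
    """
    kept: List[ExperimentEffects] = []
    excluded: List[Tuple[ExperimentEffects, str]] = []
    for eff in effects:
        reasons = []
        if eff.effect_a < 0.0:
            reasons.append("stressor A increased survival")
        if eff.effect_b < 0.0:
            reasons.append("stressor B increased survival")
        if reasons:
            excluded.append((eff, "; ".join(reasons)))
        else:
            kept.append(eff)
    return kept, excluded


# ---------------------------------------------------------------------------
# envelope prediction and classification
# ---------------------------------------------------------------------------

def _ca_sweep(
    effects: ExperimentEffects,
    shapes: Sequence[str],
    ) -> List[float]:
    """Concentration Addition over all ordered shape pairs, scope-scaled.

    For each (shape_a, shape_b): rescale both unit curves to the
    experiment's scope, invert the observed individual effects to implied
    intensities, and apply the potency-weighted intensity sum anchored on
    curve A. Effects fractionally above scope (rounding in source tables)
    are clipped to scope, i.e. implied intensity 1, with a log entry.
    """
    scaled = {s: scale_to_scope(EffectCurve(s), effects.scope) for s in shapes}
    # implied intensity per shape per role, and half-effect intensities,
    # computed once per shape rather than once per pair
    half = {s: invert(scaled[s], scaled[s].limit / 2.0) for s in shapes}

    def implied(shape: str, eff: float, label: str) -> float:
        curve = scaled[shape]
        if eff > curve.limit:
            logger.info(
                "experiment %s: effect %s %.4f exceeds scope %.4f; "
                "clipping implied intensity to 1",
                effects.experiment_id, label, eff, curve.limit,
            )
            return 1.0
        return invert(curve, eff)

    si_a = {s: implied(s, effects.effect_a, "A") for s in shapes}
    si_b = {s: implied(s, effects.effect_b, "B") for s in shapes}
    out: List[float] = []
    for sa, sb in itertools.product(shapes, shapes):
        gamma = half[sa] / half[sb]
        arg = min(si_a[sa] + gamma * si_b[sb], 1.0)
        out.append(float(scaled[sa].evaluate(arg)))
    return out


def predict_envelope(
    effects: ExperimentEffects,
    shapes: Sequence[str] = SHAPE_IDS,
    capacity: StressCapacity | None = None,
    ca_summary: str = "mean",
) -> EnvelopeClassification:
    """Five null-model predictions and the envelope category for one record.

    Simple Addition, Multiplicative, Dominance and Stressor Addition come
    straight from the derived effects; Concentration Addition contributes
    its full 25-value shape sweep to the envelope and a configurable
    summary (mean by default) as its point prediction. Predictions are
    truncated at 1 (total mortality), not additionally at scope. The
    envelope is the closed interval [min, max] over all predictions.
    """
    if ca_summary not in CA_SUMMARIES:
        raise ValueError(f"ca_summary must be one of {CA_SUMMARIES}")
    if effects.scope <= 0.0:
        raise ValueError(
            f"experiment {effects.experiment_id}: control mortality is 1 "
            "(scope 0); no stress effect is observable"
        )
    cap = capacity if capacity is not None else StressCapacity()
    ea = min(max(effects.effect_a, 0.0), 1.0)
    eb = min(max(effects.effect_b, 0.0), 1.0)
    direct = {
        "simple_addition": simple_addition(ea, eb).predicted_mortality,
        "multiplicative": multiplicative(ea, eb).predicted_mortality,
        "dominance": dominance(ea, eb).predicted_mortality,
        "stressor_addition": stressor_addition(ea, eb, cap).predicted_mortality,
    }
    ca_values = tuple(_ca_sweep(effects, shapes))
    summary = {
        "mean": np.mean,
        "median": np.median,
        "min": np.min,
        "max": np.max,
    }[ca_summary](ca_values)
    all_preds = list(direct.values()) + list(ca_values)
    lo, hi = float(min(all_preds)), float(max(all_preds))
    obs = effects.observed_joint
    if obs < lo:
        category = "below"
    elif obs > hi:
        category = "above"
    else:
        category = "within"
    return EnvelopeClassification(
        experiment_id=effects.experiment_id,
        predictions=direct,
        ca_values=ca_values,
        ca_summary=float(summary),
        envelope_low=lo,
        envelope_high=hi,
        observed_joint=obs,
        category=category,
    )


def _classification_frame(
    classifications: Sequence[EnvelopeClassification],
) -> pd.DataFrame:
    rows = []
    for c in classifications:
        row = {"experiment_id": c.experiment_id, **c.predictions}
        row["concentration_addition"] = c.ca_summary
        row.update(
            ca_min=min(c.ca_values),
            ca_max=max(c.ca_values),
            envelope_low=c.envelope_low,
            envelope_high=c.envelope_high,
            observed_joint=c.observed_joint,
            category=c.category,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def classify_all(
    effects: Iterable[ExperimentEffects],
    shapes: Sequence[str] = SHAPE_IDS,
    capacity: StressCapacity | None = None,
    ca_summary: str = "mean",
    sa_agreement_window: float = 0.05,
) -> Dict[str, object]:
    """Classify every experiment and summarize the breakdown.

    Returns a dict with the per-experiment ``table`` (a DataFrame), the
    ``breakdown_pct`` of below/within/above categories, and
    ``within_sa_window_pct``, the share of observations within
    ``sa_agreement_window`` (default 5 mortality points) of the Simple
    Addition prediction.
    """
    classifications = [
        predict_envelope(e, shapes, capacity, ca_summary) for e in effects
    ]
    if not classifications:
        raise ValueError("no experiments to classify")
    table = _classification_frame(classifications)
    n = len(table)
    breakdown = {
        cat: 100.0 * (table["category"] == cat).sum() / n
        for cat in ("below", "within", "above")
    }
    near_sa = (
        (table["observed_joint"] - table["simple_addition"]).abs()
        <= sa_agreement_window + 1e-12
    )
    return {
        "table": table,
        "n": n,
        "breakdown_pct": breakdown,
        "within_sa_window_pct": 100.0 * near_sa.sum() / n,
        "classifications": classifications,
    }


def bias_precision(
    classifications: Sequence[EnvelopeClassification],
) -> pd.DataFrame:
    """Per-model bias and precision, in percentage points.

    bias = mean(prediction - observed); precision = sample SD of the same
    differences. Concentration Addition uses its configured sweep summary
    (the per-experiment mean over the 25 shape combinations by default).
    """
    if len(classifications) < 2:
        raise ValueError("precision is undefined for fewer than 2 experiments")
    rows = []
    for m in MODEL_IDS:
        diffs = np.array(
            [
                (c.ca_summary if m == "concentration_addition" else c.predictions[m])
                - c.observed_joint
                for c in classifications
            ]
        )
        rows.append(
            {
                "model": m,
                "bias_pct": 100.0 * diffs.mean(),
                "precision_pct": 100.0 * diffs.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)
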
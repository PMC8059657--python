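"""Full-grid simulation comparing the five null models.

Enumerates every combination of two stressor intensities (a regular grid on
(0, 1]) and two stressor-effect-curve shapes, computes all five null-model
joint-effect predictions per condition, and derives the study's headline
quantities: per-condition divergence (max - min prediction) and deviation
(SD across models), distributional summaries, differences relative to the
Simple Addition baseline, the precautionary-model analysis, and a McFadden
pseudo-R² attribution of prediction variance to the input variables.

The default grid (step 0.01, five shapes) has 100 x 100 x 5 x 5 = 250,000
conditions; the whole run is vectorized and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .effect_curves import SHAPE_IDS, EffectCurve, half_effect_intensity
from .null_models import MODEL_IDS, StressCapacity, predict_all

__all__ = [
    "ParameterSet",
    "PredictionSet",
    "build_grid",
    "run_simulation",
    "predict_set",
    "summarize_divergence",
    "compare_to_simple_addition",
    "precautionary_analysis",
    "attribute_variance",
]

#: Tolerance for deciding that a model ties the per-condition maximum.
TIE_TOL = 1e-12

#: Default precaution levels (fractions below the across-model maximum).
DEFAULT_PRECAUTION_LEVELS = (0.0, 0.01, 0.05, 0.10, 0.20)


@dataclass(frozen=True)
class ParameterSet:
    """One simulation condition."""

    si_a: float
    si_b: float
    shape_a: str
    shape_b: str


@dataclass(frozen=True)
class PredictionSet:
    """Five predictions plus divergence/deviation for one condition."""

    params: ParameterSet
    predictions: Dict[str, float]
    divergence: float
    deviation: float
    max_models: frozenset


def _intensity_values(step: float) -> np.ndarray:
    if not 0.0 < step <= 1.0:
        raise ValueError(f"intensity step must lie in (0, 1], got {step!r}")
    n = int(round(1.0 / step))
    return np.round(np.arange(1, n + 1) * step, 12)


def build_grid(
    intensity_step: float = 0.01,
    shapes: Sequence[str] = SHAPE_IDS,
) -> pd.DataFrame:
    """Enumerate all (shape_a, shape_b, si_a, si_b) conditions.

    Intensities run over the regular grid ``step, 2*step, ..., 1`` — the
    zero endpoint (absent stressor) is excluded, so the default step 0.01
    with five shapes yields exactly 250,000 conditions.
    """
    shapes = list(shapes)
    if not shapes:
        raise ValueError("at least one shape is required")
    v = _intensity_values(intensity_step)
    idx = pd.MultiIndex.from_product(
        [shapes, shapes, v, v], names=["shape_a", "shape_b", "si_a", "si_b"]
    )
    return idx.to_frame(index=False)[["si_a", "si_b", "shape_a", "shape_b"]]


def _vector_predictions(
    si_a: np.ndarray,
    si_b: np.ndarray,
    curve_a: EffectCurve,
    curve_b: EffectCurve,
    capacity: StressCapacity,
) -> Dict[str, np.ndarray]:
    """All five model predictions for intensity vectors under one shape pair."""
    ea = curve_a.evaluate(si_a)
    eb = curve_b.evaluate(si_b)
    gamma = half_effect_intensity(curve_a) / half_effect_intensity(curve_b)
    ca_arg = np.minimum(si_a + gamma * si_b, 1.0)
    stress = capacity.quantile(ea) + capacity.quantile(eb)
    return {
        "simple_addition": np.minimum(ea + eb, 1.0),
        "multiplicative": ea + eb - ea * eb,
        "dominance": np.maximum(ea, eb),
        "concentration_addition": curve_a.evaluate(ca_arg),
        "stressor_addition": capacity.cdf(np.minimum(stress, 1.0)),
    }


def run_simulation(
    grid: pd.DataFrame,
    capacity: StressCapacity | None = None,
    sd_ddof: int = 1,
) -> pd.DataFrame:
    """Compute the five predictions, divergence and deviation for every row.

    Returns the grid with one column per model plus ``divergence``
    (max - min prediction) and ``deviation`` (standard deviation across the
    five predictions; sample SD with ``ddof=1`` by default). Fully
    deterministic: identical grids give bit-identical tables.
    """
    cap = capacity if capacity is not None else StressCapacity()
    out = grid.reset_index(drop=True).copy()
    n = len(out)
    cols = {m: np.empty(n) for m in MODEL_IDS}
    pairs = out.groupby(["shape_a", "shape_b"], sort=False).indices
    for (sa, sb), rows in pairs.items():
        preds = _vector_predictions(
            out["si_a"].to_numpy()[rows],
            out["si_b"].to_numpy()[rows],
            EffectCurve(sa),
            EffectCurve(sb),
            cap,
        )
        for m in MODEL_IDS:
            cols[m][rows] = preds[m]
    for m in MODEL_IDS:
        out[m] = cols[m]
    p = out[list(MODEL_IDS)].to_numpy()
    out["divergence"] = p.max(axis=1) - p.min(axis=1)
    out["deviation"] = p.std(axis=1, ddof=sd_ddof)
    return out


def predict_set(params: ParameterSet, capacity: StressCapacity | None = None,
                sd_ddof: int = 1) -> PredictionSet:
    """Scalar (non-vectorized) path for a single condition."""
    preds = predict_all(
        EffectCurve(params.shape_a),
        EffectCurve(params.shape_b),
        params.si_a,
        params.si_b,
        capacity,
    )
    values = {m: p.predicted_mortality for m, p in preds.items()}
    arr = np.array([values[m] for m in MODEL_IDS])
    mx = arr.max()
    return PredictionSet(
        params=params,
        predictions=values,
        divergence=float(mx - arr.min()),
        deviation=float(arr.std(ddof=sd_ddof)),
        max_models=frozenset(m for m in MODEL_IDS if values[m] >= mx - TIE_TOL),
    )


def summarize_divergence(results: pd.DataFrame) -> Dict[str, float]:
    """Medians, means and quartiles of divergence/deviation, in % points."""
    if len(results) == 0:
        raise ValueError("no simulation results to summarize")
    out: Dict[str, float] = {}
    for name in ("divergence", "deviation"):
        x = results[name].to_numpy() * 100.0
        out[f"median_{name}_pct"] = float(np.median(x))
        out[f"mean_{name}_pct"] = float(np.mean(x))
        out[f"q25_{name}_pct"] = float(np.percentile(x, 25))
        out[f"q75_{name}_pct"] = float(np.percentile(x, 75))
    return out


def compare_to_simple_addition(results: pd.DataFrame) -> Dict[str, object]:
    """Distribution of (model - Simple Addition) differences, in % points.

    Reports per-model min/max/mean differences and the overall extremes
    across all models and conditions.
    """
    if len(results) == 0:
        raise ValueError("no simulation results to compare")
    base = results["simple_addition"].to_numpy()
    per_model = {}
    for m in MODEL_IDS:
        if m == "simple_addition":
            continue
        d = (results[m].to_numpy() - base) * 100.0
        per_model[m] = {
            "min_diff_pct": float(d.min()),
            "max_diff_pct": float(d.max()),
            "mean_diff_pct": float(d.mean()),
        }
    return {
        "per_model": per_model,
        "max_positive_diff_pct": max(v["max_diff_pct"] for v in per_model.values()),
        "max_negative_diff_pct": min(v["min_diff_pct"] for v in per_model.values()),
    }


def precautionary_analysis(
    results: pd.DataFrame,
    precaution_levels: Iterable[float] = DEFAULT_PRECAUTION_LEVELS,
) -> Dict[str, object]:
    """Which models come closest to the across-model maximum, and where.

    Two views:

    - ``max_counts``: per model, the number of conditions where its
      prediction ties the across-model maximum (ties credit every
      attaining model).
    - ``precaution_map``: a long-format table with one row per
      (si_a, si_b, level): for each intensity pair and tolerance
      ``level``, the models whose prediction is within ``level`` of the
      maximum across ALL shape combinations at that intensity pair;
      "none" when no model qualifies everywhere.
    """
    levels = [float(l) for l in precaution_levels]
    if any(l < 0 or l > 1 for l in levels):
        raise ValueError("precaution levels must lie in [0, 1]")
    p = results[list(MODEL_IDS)].to_numpy()
    row_max = p.max(axis=1, keepdims=True)
    at_max = p >= row_max - TIE_TOL
    max_counts = {m: int(at_max[:, j].sum()) for j, m in enumerate(MODEL_IDS)}

    # shortfall of each model from the per-condition maximum, then the worst
    # shortfall over all shape pairs at each intensity pair
    shortfall = pd.DataFrame(row_max - p, columns=list(MODEL_IDS))
    shortfall[["si_a", "si_b"]] = results[["si_a", "si_b"]].to_numpy()
    worst = shortfall.groupby(["si_a", "si_b"], sort=True).max()

    records: List[dict] = []
    w = worst[list(MODEL_IDS)].to_numpy()
    for level in levels:
        ok = w <= level + TIE_TOL
        for (sia, sib), row in zip(worst.index, ok):
            models = [m for m, flag in zip(MODEL_IDS, row) if flag]
            records.append(
                {
                    "si_a": sia,
                    "si_b": sib,
                    "level": level,
                    "models": ",".join(models) if models else "none",
                }
            )
    return {"max_counts": max_counts, "precaution_map": pd.DataFrame(records)}


def _bernoulli_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    """Bernoulli-form log-likelihood on fractional responses.

    ``sum(y ln mu + (1-y) ln(1-mu))``, with no combinatorial constant — the
    constant must be omitted consistently for the McFadden ratio to be
    meaningful on fractional data.
    """
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(np.sum(xlogy(y, mu) + xlogy(1.0 - y, 1.0 - mu)))


def attribute_variance(results: pd.DataFrame) -> pd.DataFrame:
    """McFadden pseudo-R² of each input variable for predicted mortality.

    Stacks the results long (one row per condition x model; response = the
    truncated predicted mortality fraction), then for each variable in
    {si_a, si_b, shape_a, shape_b, model} fits a univariate binomial-family
    GLM (logit link; intensities continuous, shapes/model categorical) and
    reports ``1 - llh(model) / llh(intercept-only)``.
    """
    import statsmodels.api as sm

    if len(results) == 0:
        raise ValueError("no simulation results to attribute")
    long = results.melt(
        id_vars=["si_a", "si_b", "shape_a", "shape_b"],
        value_vars=list(MODEL_IDS),
        var_name="model",
        value_name="mortality",
    )
    y = long["mortality"].to_numpy()
    if np.all(y == y[0]):
        raise ValueError("degenerate response: pseudo-R² undefined")
    ll_null = _bernoulli_loglik(y, np.full_like(y, y.mean()))

    rows = []
    for var in ("si_a", "si_b", "shape_a", "shape_b", "model"):
        if var in ("si_a", "si_b"):
            X = long[[var]].to_numpy(dtype=float)
        else:
            X = pd.get_dummies(long[var], drop_first=True, dtype=float).to_numpy()
        X = sm.add_constant(X, has_constant="add")
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        ll = _bernoulli_loglik(y, np.asarray(fit.mu))
        rows.append({"variable": var, "pseudo_r2": 1.0 - ll / ll_null})
    return pd.DataFrame(rows)
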
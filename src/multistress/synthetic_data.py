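"""Seeded generator of factorial two-stressor experiments with known truth.

Emulates the statistical structure of the factorial survival/mortality
experiments the meta-analysis pipeline ingests: per experiment, two
stressor-effect curve shapes and intensities are drawn, individual effects
are computed from the curves rescaled to the experiment's scope
(1 - control mortality), the true joint effect follows a chosen generating
null model, and the four arm mortalities are observed either exactly
("infinite" groups) or as binomial proportions at a finite group size.
Ground truth (true effects, true joint, generating model) is returned
separately so tests can assert recovery without leaking truth into the
analysis path.

Randomness is fully determined by the config seed; each experiment uses its
own substream keyed by index, so adding or removing experiments never
shifts the draws of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .effect_curves import SHAPE_IDS, EffectCurve, scale_to_scope
from .meta_analysis import FactorialExperiment
from .null_models import (
    MODEL_IDS,
    StressCapacity,
    concentration_addition,
    dominance,
    multiplicative,
    simple_addition,
    stressor_addition,
)

__all__ = ["GeneratorConfig", "generate", "perturb_to_interaction", "experiments_to_frame"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design knobs for the synthetic factorial experiments.

    Defaults describe a generic stress-ecology compilation: intensities
    anywhere on (0, 1), control mortality up to 20%, binomial groups of 50
    individuals per arm.
    """

    n_experiments: int = 500
    generating_model: str = "multiplicative"
    shape_pool: Sequence[str] = SHAPE_IDS
    intensity_range: Tuple[float, float] = (0.05, 0.95)
    control_mortality_max: float = 0.2
    group_size: Optional[int] = 50  # None means noise-free ("infinite")
    seed: int = 0
    composition: str = "additive"  # arm mortality = control + effect, capped
    protective_stressor_prob: float = 0.0  # chance stressor A *reduces* mortality
    capacity: StressCapacity = field(default_factory=StressCapacity)

    def __post_init__(self):
        if self.n_experiments <= 0:
            raise ValueError("n_experiments must be positive")
        if self.generating_model not in MODEL_IDS:
            raise ValueError(f"unknown generating model {self.generating_model!r}")
        lo, hi = self.intensity_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("intensity_range must satisfy 0 <= lo < hi <= 1")
        if not 0.0 <= self.control_mortality_max < 1.0:
            raise ValueError("control_mortality_max must lie in [0, 1)")
        if self.group_size is not None and self.group_size <= 0:
            raise ValueError("group_size must be positive (or None for noise-free)")
        if self.composition not in ("additive", "independent"):
            raise ValueError("composition must be 'additive' or 'independent'")
        if not 0.0 <= self.protective_stressor_prob <= 1.0:
            raise ValueError("protective_stressor_prob must lie in [0, 1]")


def _true_joint(
    model: str,
    curve_a: EffectCurve,
    curve_b: EffectCurve,
    si_a: float,
    si_b: float,
    ea: float,
    eb: float,
    capacity: StressCapacity,
) -> float:
    if model == "simple_addition":
        return simple_addition(ea, eb).predicted_mortality
    if model == "multiplicative":
        return multiplicative(ea, eb).predicted_mortality
    if model == "dominance":
        return dominance(ea, eb).predicted_mortality
    if model == "concentration_addition":
        return concentration_addition(curve_a, curve_b, si_a, si_b).predicted_mortality
    return stressor_addition(ea, eb, capacity).predicted_mortality


def _compose(control: float, effect: float, composition: str) -> float:
    """Arm mortality from control mortality and a stress effect."""
    if composition == "independent":
        return 1.0 - (1.0 - control) * (1.0 - effect)
    return min(control + effect, 1.0)


def generate(
    config: GeneratorConfig,
) -> Tuple[List[FactorialExperiment], pd.DataFrame]:
    """Draw the experiments; returns (experiments, ground-truth table).

    The truth table has one row per experiment with the drawn shapes,
    intensities, control mortality, true effects and true joint effect —
    for test assertions only, never consumed by the analysis pipeline.

    Note: with the default "additive" composition the stressor-Addition-
    style cap (arm mortality <= 1) can bind when control + joint > 1; with
    ``control_mortality_max = 0`` it never binds and noise-free round trips
    are exact.
    """
    experiments: List[FactorialExperiment] = []
    truth_rows = []
    pool = list(config.shape_pool)
    lo, hi = config.intensity_range
    for i in range(config.n_experiments):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(i,)))
        shape_a, shape_b = str(rng.choice(pool)), str(rng.choice(pool))
        si_a = rng.uniform(lo, hi)
        si_b = rng.uniform(lo, hi)
        control = (
            rng.uniform(0.0, config.control_mortality_max)
            if config.control_mortality_max > 0
            else 0.0
        )
        scope = 1.0 - control
        curve_a = scale_to_scope(EffectCurve(shape_a), scope)
        curve_b = scale_to_scope(EffectCurve(shape_b), scope)
        ea = curve_a.evaluate(si_a)
        eb = curve_b.evaluate(si_b)
        protective = rng.uniform() < config.protective_stressor_prob
        joint = _true_joint(
            config.generating_model, curve_a, curve_b, si_a, si_b, ea, eb,
            config.capacity,
        )
        p_control = control
        if protective:
            # a "stressor" that actually reduces mortality below control;
            # such records must be caught by the meta-analysis filter
            p_a = max(control - ea, 0.0)
        else:
            p_a = _compose(control, ea, config.composition)
        p_b = _compose(control, eb, config.composition)
        p_ab = _compose(control, joint, config.composition)
        probs = {"control": p_control, "a": p_a, "b": p_b, "ab": p_ab}
        if config.group_size is None:
            observed = probs
            sizes = None
        else:
            n = config.group_size
            observed = {
                arm: rng.binomial(n, p) / n for arm, p in probs.items()
            }
            sizes = {arm: n for arm in probs}
        experiments.append(
            FactorialExperiment(
                experiment_id=f"synth-{i:04d}",
                endpoint_kind="mortality",
                control_value=observed["control"],
                a_only_value=observed["a"],
                b_only_value=observed["b"],
                combined_value=observed["ab"],
                group_sizes=sizes,
                source="synthetic",
            )
        )
        truth_rows.append(
            {
                "experiment_id": f"synth-{i:04d}",
                "generating_model": config.generating_model,
                "shape_a": shape_a,
                "shape_b": shape_b,
                "si_a": si_a,
                "si_b": si_b,
                "control_mortality": control,
                "true_effect_a": ea,
                "true_effect_b": eb,
                "true_joint": joint,
                "protective_a": protective,
            }
        )
    return experiments, pd.DataFrame(truth_rows)


def perturb_to_interaction(
    experiments: Sequence[FactorialExperiment],
    synergy_shift: float,
) -> List[FactorialExperiment]:
    """Shift every combined arm's *mortality* by ``synergy_shift`` points.

    Positive shifts manufacture synergistic (above-envelope) cases,
    negative shifts antagonistic ones; other arms are untouched and the
    result is clamped to [0, 1]. Survival-endpoint records are shifted on
    the mortality scale and converted back.
    """
    if not np.isfinite(synergy_shift):
        raise ValueError("synergy_shift must be finite")
    delta = synergy_shift / 100.0
    out = []
    for exp in experiments:
        mort = exp.mortality("ab")
        shifted = min(max(mort + delta, 0.0), 1.0)
        new_value = 1.0 - shifted if exp.endpoint_kind == "survival" else shifted
        out.append(
            FactorialExperiment(
                experiment_id=exp.experiment_id,
                endpoint_kind=exp.endpoint_kind,
                control_value=exp.control_value,
                a_only_value=exp.a_only_value,
                b_only_value=exp.b_only_value,
                combined_value=new_value,
                group_sizes=exp.group_sizes,
                source=exp.source,
            )
        )
    return out


def experiments_to_frame(experiments: Sequence[FactorialExperiment]) -> pd.DataFrame:
    """Experiments as a DataFrame in the meta-analysis CSV schema."""
    rows = []
    for exp in experiments:
        row = {
            "experiment_id": exp.experiment_id,
            "endpoint_kind": exp.endpoint_kind,
            "control": exp.control_value,
            "stressor_a": exp.a_only_value,
            "stressor_b": exp.b_only_value,
            "combined": exp.combined_value,
            "source": exp.source,
        }
        if exp.group_sizes:
            row.update(
                n_control=exp.group_sizes["control"],
                n_a=exp.group_sizes["a"],
                n_b=exp.group_sizes["b"],
                n_ab=exp.group_sizes["ab"],
            )
        rows.append(row)
    return pd.DataFrame(rows)
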
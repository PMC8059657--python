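# Methods

## Scope and model family

The package predicts population mortality under two co-occurring stressors
from five null models of independent action, compares the models against
each other over a simulation grid, and confronts them with (real or
synthetic) 2×2 factorial experiments. Everything is binary-stressor: none of
the formulas generalize mechanically to three or more stressors, and no
attempt is made here.

All effects are mortality *fractions* internally; human-facing reports
multiply by 100 and print one decimal. Raw predictions above 1 (possible for
Simple Addition, for the Concentration Addition intensity sum, and for the
Stressor Addition stress sum) are truncated to 1 inside each model and
flagged, so every downstream statistic sees attainable mortalities only.

### Stressor-effect curves

A stressor-effect relationship maps normalized intensity `x ∈ [0,1]` to
mortality in `[0, limit]`, anchored at `f(0)=0`, `f(1)=limit`, strictly
increasing. The registry defaults are the simplest smooth monotone family
matching the five qualitative shape names:

| shape | unit form |
|---|---|
| linear | `x` |
| accelerating | `x²` |
| diminishing | `1 − (1−x)²` |
| steep_middle | CDF of beta(3, 3) |
| steep_extremes | CDF of beta(1/3, 1/3) |

These exact functional forms are a package choice: the shape family is a
registry precisely so alternates can be swapped in (programmatically or from
a YAML breakpoint list) without touching any downstream code. Headline
grid statistics depend on this choice; the figures quoted below are for the
default registry and are recomputed, not assumed, by the analysis scripts.

Curve inversion uses bisection to an absolute intensity tolerance of 1e−9
even for shapes with closed-form inverses, so user-registered shapes need
only provide an evaluate function. Two endpoint conventions: `invert(c, 0) =
0`, and `invert(c, limit) = 1` exactly (the CDF-style shapes saturate to the
limit within float precision slightly before `x = 1`, which would otherwise
stop the bisection early).

### Stress capacity

The Stressor Addition model's general-stress-capacity distribution is a
symmetric beta with `α = β = 3.2` on [0, 1] — the parameterization
established for this model in the ecotoxicological literature. Its quantile
function is pinned to `q(0)=0`, `q(1)=1` so absent and total effects pass
through exactly; subnormal probabilities, where the underlying incomplete
beta inverse underflows, map to the nearer support endpoint. The stress sum
is clamped to the support before the CDF is applied (numerically identical
to letting the CDF saturate).

### Concentration Addition anchoring

The model is evaluated anchored on curve A: `f_A(SI_A + γ·SI_B)` with
`γ = h_A / h_B`, the ratio of half-effect intensities. For non-parallel
curves this is asymmetric under stressor relabeling; no averaging with the
B-anchored form is done. The meta-analysis shape sweep covers both
orderings anyway, since every shape appears in both roles across the 25
ordered combinations. The two curves must share an effect limit, otherwise
"half the effect limit" is ambiguous between them.

## Simulation study

Grid: intensities `0.01, 0.02, …, 1.00` for each stressor (the zero
endpoint — an absent stressor — is excluded from the grid and covered by
unit tests) crossed with all 25 ordered shape pairs: 250,000 conditions.
The run is fully vectorized and deterministic; repeated runs are
bit-identical.

Per condition: the five truncated predictions, **divergence** = max − min,
and **deviation** = standard deviation across the five predictions (sample
SD, `ddof=1`; the divisor is configurable since either convention is
defensible for five fixed models). Deviation ≤ divergence always.

Under the default registry the grid yields (recomputed by
`analysis/01_simulate_grid.py`): median divergence 22.6 points, median
deviation 10.0 points, extremes vs Simple Addition +51.0 / −50.0 points,
and Stressor Addition attaining the across-model maximum in 221,715 of the
250,000 conditions — the most of any model, yet far from all conditions, so
no single model is a universal precautionary choice. The −50-point extreme
is registry-independent (it is the analytic bound of Dominance below
truncated Simple Addition, attained at `e_A = e_B = 0.5`); the positive
extreme and the medians move with the shape registry. Two structural facts
worth noting: Dominance ≤ Multiplicative ≤ Simple Addition pointwise
(algebraic), and on this grid Stressor Addition never fell below Simple
Addition (grid-verified, not claimed analytically).

**Precautionary analysis.** A model is counted as attaining the maximum when
its prediction is within 1e−12 of the per-condition max (ties credit every
attaining model). The precaution map asks, per intensity pair and tolerance
ε ∈ {0, 0.01, 0.05, 0.10, 0.20}: which models are never more than ε below
the across-model maximum over *all* 25 shape pairs at that intensity pair;
cells with no such model are "none".

**Variance attribution.** The per-condition predictions are stacked long
(condition × model, 1.25M rows; response = truncated predicted mortality
fraction) and each input variable — `si_a`, `si_b` continuous, `shape_a`,
`shape_b`, `model` categorical — enters alone in a binomial-family GLM with
logit link (statsmodels). McFadden pseudo-R² is `1 − ℓ/ℓ₀` with both
log-likelihoods computed in Bernoulli form `Σ[y ln μ + (1−y) ln(1−μ)]` on
the fractional responses, omitting the combinatorial constant everywhere
(it only cancels from the ratio if omitted consistently); the null model is
the intercept-only fit, whose mean is the response mean. Under the default
registry: si_a 0.111, si_b 0.109, shape_a 0.011, shape_b 0.014, model 0.043
— the intensities dominate every other input, so single-stressor
dose-response information matters more to the predicted joint effect than
either the curve-shape assumption or the choice of null model.

## Meta-analysis pipeline

Input experiments are 2×2 factorial proportions (control / A-only / B-only /
combined), on either a survival or mortality endpoint; survival values are
flipped (`1 − x`) on ingestion and the two endpoint conventions are
downstream-identical. Stress effects are treatment-minus-control mortality
differences; the *scope* is `1 − control mortality`, the mortality still
available for stressors to cause.

Filtering removes experiments where either individual "stressor" *reduced*
mortality (negative derived effect) — such exposures are not stressors under
the working definition. Negative *joint* effects are retained and classified
(they land below the envelope); the filter names only the individual arms.

Per experiment: Simple Addition, Multiplicative, Dominance and Stressor
Addition are computed directly from the derived effects; Concentration
Addition is computed for all 25 ordered shape combinations, with both
curves rescaled to the experiment's scope (shape preserved, limit = scope),
observed effects inverted to implied intensities, and the potency-weighted
intensity sum evaluated on curve A. Effects marginally above scope (possible
from rounding in source tables) clip the implied intensity at 1, with a log
entry. Predictions are truncated at 1 but *not* additionally at scope —
scope enters only through the curve rescaling.

The **envelope** is the closed interval [min, max] over the four direct
predictions plus all 25 CA values; an observation exactly on a bound counts
as "within" (closed intervals avoid knife-edge exclusions; the convention is
recorded in every report sidecar). For per-model **bias** (mean of
prediction − observed) and **precision** (sample SD of the same
differences), Concentration Addition is summarized per experiment by the
mean of its 25 sweep values; min / median / max are selectable, and the
choice is logged, since a 25-value sweep has no single canonical point
prediction. A report also includes the share of observations within ±5
mortality points of the Simple Addition prediction, the conventional
single-model benchmark.

## Synthetic experiments

The generator emulates the statistical structure of published factorial
compilations: per experiment, shapes for both stressors drawn from a pool,
intensities uniform on (0.05, 0.95), control mortality uniform on
[0, 0.2], true effects from the scope-rescaled curves, the true joint
effect from a chosen generating null model, and arm mortalities observed
either exactly (`group_size=None`) or as binomial proportions at 50
individuals per arm by default — a typical bench-experiment arm size. Arm
mortality composes control and stress additively (`control + effect`,
capped at 1), mirroring the treatment-minus-control effect definition; a
conditional-independence composition (`1 − (1−c)(1−e)`) is available behind
a flag since the effect-extraction convention constrains only the
difference. A protective-stressor mode draws arms whose "stressor" lowers
mortality, to exercise the filter. Randomness is a single seed fanned out
into per-experiment substreams keyed by experiment index, so extending a
dataset never changes existing draws.

Two caveats the tests make explicit. With nonzero control mortality the cap
`control + joint ≤ 1` can bind, and the nonnegative-effect filter selects
on noisy effects; both mechanisms leave a small bias in the generating
model that does *not* vanish with group size. Noise-free exactness and
binomial consistency checks therefore use zero control mortality, where
neither mechanism operates and the generating model is exactly unbiased.
The generator does not emulate publication bias, between-study
heterogeneity, taxonomic structure, or correlated arm sizes — passing
recovery tests shows the pipeline's arithmetic is right, not that real
compilations are this well behaved.

## Problem sizes and runtime

The full 250,000-condition grid runs in a few seconds; the five GLMs on the
1.25M-row stacked table take ~20 s. Synthetic recovery uses 500 experiments
at group size 50 (and 12–15 noise-free experiments per generating model in
the exactness checks) — large enough that binomial standard errors on the
bias are a fraction of a point, small enough to iterate freely.

## Known limitations

- The five registry shapes are a reconstruction by qualitative name; any
  statistic aggregated over the shape grid (medians of divergence and
  deviation, the positive extreme vs Simple Addition, pseudo-R² magnitudes)
  moves if the registry is swapped. The ordering results (Dominance lowest,
  Stressor Addition most often maximal, intensities the dominant driver)
  were robust across every registry variant exercised.
- Concentration Addition's A-anchoring is asymmetric for non-parallel
  curves; users comparing "A then B" vs "B then A" should sweep both, as
  the meta-analysis does.
- Mortality only: four of the five models have published analogues for
  continuous endpoints (growth, reproduction), but the Stressor Addition
  capacity construction does not, and no continuous-endpoint support is
  provided.
- Group sizes, where present in input tables, are carried but unused — no
  variance weighting of experiments is performed.
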
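"""Implausibility filtering and information-criterion model selection.

Before a fitted family competes for "best-fitting", it must pass a set of
prespecified plausibility conditions, evaluated in a fixed order so the
recorded reasons are comparable across runs:

1. ``nonconverged`` — the optimizer failed or the observed information
   matrix could not be inverted (no further checks are possible);
2. ``non_descending_survival`` — S(t) fails to decrease after time 0 on
   a geometric evaluation grid (catches degenerate numerics; the
   standard families are monotone by construction);
3. ``wide_ci_first_event`` — the 95% CI of S(t) at the first observed
   event time spans more than 0.80 of survival probability, i.e. the
   curve is essentially unidentified where the data begin;
4. ``infinite_estimate`` — the median, 1%-survival horizon, or
   own-horizon RMST point estimate is not finite (defective fits whose
   survival plateaus above 1%), or the median's sampled CI bounds are
   not finite;
5. ``median_beyond_population_max`` — the fitted median exceeds the
   largest event time in the ground-truth population.

Selection then takes the minimal information criterion among the
plausible fits.  Exact ties go to the family with fewer parameters, then
to a fixed family order, so selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimands import draw_parameters
from .families import FAMILY_ORDER
from .fitting import FittedModel

__all__ = [
    "PlausibilityVerdict",
    "SelectionResult",
    "CRITERIA",
    "assess_plausibility",
    "select_best",
]

#: selection criteria; ``true_family`` means "force the generating family"
CRITERIA = ("aic", "bic", "aicc", "bicc", "true_family")

REASONS = (
    "nonconverged",
    "non_descending_survival",
    "wide_ci_first_event",
    "infinite_estimate",
    "median_beyond_population_max",
)

_GRID_POINTS = 200
_CI_WIDTH_LIMIT = 0.80


@dataclass
class PlausibilityVerdict:
    plausible: bool
    reasons: tuple = ()

    def __post_init__(self):
        assert self.plausible == (len(self.reasons) == 0)


@dataclass
class SelectionResult:
    """Outcome of best-fit selection for one dataset and criterion."""

    criterion: str
    chosen_family: str | None
    chosen_index: int | None
    was_true_family: bool
    n_excluded: int

    @property
    def no_selection(self) -> bool:
        return self.chosen_family is None


def _tail_bounds(values: np.ndarray):
    """2.5/97.5 percentile bounds where draws may be infinite (or NaN,
    treated as infinite): a bound is +inf once the tail mass of bad draws
    reaches it."""
    v = np.where(np.isnan(values), np.inf, values)
    with np.errstate(invalid="ignore"):
        lo, hi = np.percentile(v, [2.5, 97.5])
    return (
        lo if np.isfinite(lo) else np.inf,
        hi if np.isfinite(hi) else np.inf,
    )


def _survival_grid(th_candidate: float, fallback: float) -> np.ndarray:
    upper = 2.0 * th_candidate if np.isfinite(th_candidate) else 2.0 * fallback
    return np.geomspace(upper / 1e4, upper, _GRID_POINTS)


def assess_plausibility(
    model: FittedModel,
    times,
    events,
    pop_max_event_time: float,
    b_ci: int = 1000,
    rng: np.random.Generator | None = None,
) -> PlausibilityVerdict:
    """Apply the prespecified implausibility conditions to one fit.

    ``pop_max_event_time`` is the largest event time (from enrollment) in
    the ground-truth population; ``times``/``events`` are the dataset the
    model was fitted to.  Always returns a verdict, never raises.
    """
    if not np.isfinite(pop_max_event_time):
        raise ValueError("pop_max_event_time must be finite")
    if not model.converged or model.cov is None:
        return PlausibilityVerdict(False, ("nonconverged",))
    if rng is None:
        rng = np.random.default_rng()

    fam, params = model.family, model.params
    reasons = []

    median = float(fam.quantile(0.5, params))
    th = float(fam.quantile(0.99, params))

    # 2. survival must descend after time 0
    grid = _survival_grid(th, pop_max_event_time)
    s_grid = fam.sf(grid, params)
    if np.any(np.diff(s_grid) > 1e-10) or not np.all(np.isfinite(s_grid)):
        reasons.append("non_descending_survival")

    # 3. CI of S(t) at the first observed event time
    events = np.asarray(events).astype(bool)
    t_first = float(np.min(np.asarray(times, dtype=float)[events]))
    with np.errstate(all="ignore"):  # extreme draws overflow legitimately
        draws = np.atleast_2d(draw_parameters(model, b_ci, rng))
        s_first = np.ravel(fam.sf(t_first, draws))
        median_d = np.ravel(fam.quantile(0.5, draws))
    s_first = s_first[np.isfinite(s_first)]
    if s_first.size:
        s_lo, s_hi = np.percentile(s_first, [2.5, 97.5])
        if s_hi - s_lo > _CI_WIDTH_LIMIT:
            reasons.append("wide_ci_first_event")

    # 4. finite point estimators (median, horizon, own-horizon RMST) and
    # median CI bounds.  The horizon's *sampled* CI is deliberately not
    # required to be finite: a near-exponential Gompertz fit always has
    # parameter draws whose survival plateaus above 1%, so that
    # requirement would disqualify the family almost everywhere rather
    # than only where the fit itself is degenerate.
    bounds = list(_tail_bounds(median_d))
    bounds += [median, th]  # own-horizon RMST is finite iff th is
    if not np.all(np.isfinite(bounds)):
        reasons.append("infinite_estimate")

    # 5. median within the population's observed event range
    if np.isfinite(median) and median > pop_max_event_time:
        reasons.append("median_beyond_population_max")

    return PlausibilityVerdict(len(reasons) == 0, tuple(reasons))


def _ic_value(model: FittedModel, criterion: str) -> float:
    val = getattr(model, criterion)
    return val if np.isfinite(val) else np.inf


def select_best(
    models: list,
    verdicts: list,
    criterion: str,
    true_family: str = "exponential",
) -> SelectionResult:
    """Pick the best-fitting plausible family for one dataset.

    ``criterion`` is one of ``aic``/``bic``/``aicc``/``bicc`` (minimal
    value wins) or ``true_family`` (the generating family is forced,
    provided it is plausible).  When no model is plausible — the
    simulations at the study's settings never produced this — an explicit
    no-selection result is returned.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    if len(models) != len(verdicts):
        raise ValueError("models and verdicts must align")
    plausible = [i for i, v in enumerate(verdicts) if v.plausible]
    n_excluded = len(models) - len(plausible)

    if criterion == "true_family":
        idx = next(
            (i for i in plausible if models[i].family.name == true_family),
            None,
        )
        return SelectionResult(
            criterion=criterion,
            chosen_family=true_family if idx is not None else None,
            chosen_index=idx,
            was_true_family=idx is not None,
            n_excluded=n_excluded,
        )

    if not plausible:
        return SelectionResult(criterion, None, None, False, n_excluded)

    def sort_key(i):
        m = models[i]
        return (
            _ic_value(m, criterion),
            m.n_params,
            FAMILY_ORDER.index(m.family.name),
        )

    best = min(plausible, key=sort_key)
    name = models[best].family.name
    return SelectionResult(
        criterion=criterion,
        chosen_family=name,
        chosen_index=best,
        was_true_family=name == true_family,
        n_excluded=n_excluded,
    )
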
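"""Scenario exploration: single-axis what-ifs and sufficiency analysis.

Mirrors the dashboard workflow: vary one input at a time (provider count,
availability, review time, contact fraction, cadence, or population) and
report the resulting coverage, plus the minimal change on each axis that
makes capacity meet or exceed demand.  "Meets or exceeds" is judged on the
raw (uncapped) capacity/demand ratio, since the reported value saturates at
exactly 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import InvalidAxisError, InvalidParameterError
from .model import Cohort, Scenario, coverage, projected_demand

__all__ = [
    "AXES",
    "ScenarioModification",
    "evaluate_modification",
    "min_providers_for_full_coverage",
    "max_minutes_per_review",
    "required_hours",
    "sufficiency_table",
]

# Fixed enumeration order; also the sort order of sufficiency_table rows.
AXES = (
    "n_providers",
    "hours_per_period",
    "minutes_per_review",
    "contact_fraction",
    "review_frequency",
    "population",
)

_POOL_AXES = frozenset({"n_providers", "hours_per_period", "minutes_per_review"})

# Numerical guard for grid/ceiling arithmetic on exact-boundary cases.
_EPS = 1e-9


@dataclass(frozen=True)
class ScenarioModification:
    """One single-axis change and its effect on reported coverage.

    ``status`` is "ok" for an applicable change, "already_covered" when the
    baseline already meets demand, or "unreachable" when no value on this
    axis alone attains full coverage.
    """

    axis: str
    baseline_value: float
    modified_value: float | None
    resulting_coverage: int | None
    delta_coverage: int | None
    status: str = "ok"


def _uniform_cohort_value(cohorts: list[Cohort], attr: str) -> float:
    values = {getattr(c, attr) for c in cohorts}
    if not values:
        raise InvalidParameterError("scenario has no cohorts")
    if len(values) > 1:
        raise InvalidAxisError(
            f"axis {attr!r} requires a uniform baseline across cohorts; "
            f"found {sorted(values)} — modify cohorts directly instead"
        )
    return values.pop()


def _baseline_value(scenario: Scenario, axis: str) -> float:
    if axis not in AXES:
        raise InvalidAxisError(f"unknown axis {axis!r}; valid axes: {', '.join(AXES)}")
    if axis in _POOL_AXES:
        return getattr(scenario.pool, axis)
    if axis == "population":
        return sum(c.enrolled for c in scenario.cohorts)
    return _uniform_cohort_value(scenario.cohorts, axis)


def _with_axis(scenario: Scenario, axis: str, value: float) -> Scenario:
    """Rebuild the scenario with one axis set to ``value``."""
    if axis not in AXES:
        raise InvalidAxisError(f"unknown axis {axis!r}; valid axes: {', '.join(AXES)}")
    if axis in _POOL_AXES:
        return scenario.with_pool(**{axis: value})
    if axis == "population":
        total = sum(c.enrolled for c in scenario.cohorts)
        if value < 0:
            raise InvalidParameterError("population must be >= 0")
        if total == 0:
            raise InvalidParameterError(
                "cannot rescale a zero population; set cohort counts directly"
            )
        scale = value / total
        cohorts = [replace(c, enrolled=c.enrolled * scale) for c in scenario.cohorts]
        return replace(scenario, cohorts=cohorts)
    # contact_fraction / review_frequency: set the common value on all cohorts
    _uniform_cohort_value(scenario.cohorts, axis)
    cohorts = [replace(c, **{axis: value}) for c in scenario.cohorts]
    return replace(scenario, cohorts=cohorts)


def evaluate_modification(
    scenario: Scenario, axis: str, new_value: float
) -> ScenarioModification:
    """Recompute coverage with exactly one axis changed.

    ``delta_coverage`` is the difference of reported (integer percent)
    coverages, matching how the dashboard quotes scenario effects.
    """
    baseline_value = _baseline_value(scenario, axis)
    base_reported = scenario.coverage().reported_coverage
    modified = _with_axis(scenario, axis, new_value)
    new_reported = modified.coverage().reported_coverage
    return ScenarioModification(
        axis=axis,
        baseline_value=baseline_value,
        modified_value=new_value,
        resulting_coverage=new_reported,
        delta_coverage=new_reported - base_reported,
    )


def min_providers_for_full_coverage(scenario: Scenario) -> int:
    """Smallest integer provider count whose capacity meets demand.

    Closed-form inversion of K = r*m*h:  m* = ceil(D / (r*h)).  Returns 0
    when demand is zero (any workforce suffices).
    """
    demand = scenario.demand
    if demand == 0:
        return 0
    per_provider = scenario.pool.reviews_per_provider_hour * scenario.pool.hours_per_period
    return max(1, math.ceil(demand / per_provider - _EPS))


def max_minutes_per_review(scenario: Scenario) -> float:
    """Longest average review time at which capacity still meets demand.

    t* = 60*m*h / D; raw coverage at t* is exactly 100.  Returns ``inf``
    when demand is zero.  Not defined when the pool's review rate is
    overridden directly (capacity is then independent of review time).
    """
    if scenario.pool.review_capacity_override is not None:
        raise InvalidAxisError(
            "minutes_per_review axis is inapplicable when review_capacity_override is set"
        )
    demand = scenario.demand
    if demand == 0:
        return math.inf
    return 60.0 * scenario.pool.n_providers * scenario.pool.hours_per_period / demand


def required_hours(scenario: Scenario) -> float:
    """Hours per provider per period at which capacity exactly meets demand.

    h* = D / (r*m); returns 0 when demand is zero.
    """
    demand = scenario.demand
    if demand == 0:
        return 0.0
    return demand / (scenario.pool.reviews_per_provider_hour * scenario.pool.n_providers)


def _snap(value: float, step: float, direction: str) -> float:
    """Snap to the step grid, conservatively (toward more capacity)."""
    if direction == "up":
        return math.ceil(value / step - _EPS) * step
    return math.floor(value / step + _EPS) * step


def _demand_axis_row(scenario: Scenario, axis: str, step: float) -> ScenarioModification:
    """Minimal reduction on a demand-side axis reaching full coverage."""
    base_value = _baseline_value(scenario, axis)
    base_reported = scenario.coverage().reported_coverage
    capacity = scenario.capacity
    demand = scenario.demand
    # demand is linear in the axis value with a nonnegative intercept
    # (population holds new_per_period fixed), so solve value* directly.
    if axis == "population":
        intercept = projected_demand(
            [replace(c, enrolled=0.0) for c in scenario.cohorts]
        )
        slope = (demand - intercept) / base_value if base_value > 0 else 0.0
    else:
        intercept = 0.0
        slope = demand / base_value if base_value > 0 else 0.0
    if slope <= 0 or capacity < intercept - _EPS:
        return ScenarioModification(
            axis, base_value, None, None, None, status="unreachable"
        )
    target = (capacity - intercept) / slope
    snapped = max(0.0 if axis != "review_frequency" else step, _snap(target, step, "down"))
    if axis == "population":
        snapped = float(math.floor(target + _EPS))
    candidate = _with_axis(scenario, axis, snapped)
    result = candidate.coverage()
    if result.raw_coverage < 100.0 - _EPS:
        return ScenarioModification(
            axis, base_value, None, None, None, status="unreachable"
        )
    return ScenarioModification(
        axis,
        base_value,
        snapped,
        result.reported_coverage,
        result.reported_coverage - base_reported,
        status="ok",
    )


def sufficiency_table(
    scenario: Scenario, axes: tuple[str, ...] = AXES
) -> list[ScenarioModification]:
    """Minimal single-axis changes sufficient for capacity >= demand.

    One row per requested axis, in the fixed enumeration order.  Continuous
    pool axes are reported at 0.1 resolution and cohort fractions at 0.01,
    both rounded toward more capacity; provider and population counts are
    integers.  Axes that cannot reach full coverage alone are flagged
    ``unreachable``.
    """
    unknown = set(axes) - set(AXES)
    if unknown:
        raise InvalidAxisError(f"unknown axes: {sorted(unknown)}")
    base = scenario.coverage()
    rows: list[ScenarioModification] = []
    for axis in sorted(axes, key=AXES.index):
        try:
            base_value = _baseline_value(scenario, axis)
        except InvalidAxisError:
            # mixed per-cohort values: no single-axis change exists
            rows.append(
                ScenarioModification(axis, math.nan, None, None, None,
                                     status="not_applicable")
            )
            continue
        if base.raw_coverage >= 100.0:
            rows.append(
                ScenarioModification(
                    axis, base_value, base_value, base.reported_coverage, 0,
                    status="already_covered",
                )
            )
            continue
        if axis == "n_providers":
            m_star = min_providers_for_full_coverage(scenario)
            result = scenario.with_pool(n_providers=m_star).coverage()
            rows.append(
                ScenarioModification(
                    axis, base_value, float(m_star), result.reported_coverage,
                    result.reported_coverage - base.reported_coverage,
                )
            )
        elif axis == "hours_per_period":
            h_star = _snap(required_hours(scenario), 0.1, "up")
            result = scenario.with_pool(hours_per_period=h_star).coverage()
            rows.append(
                ScenarioModification(
                    axis, base_value, h_star, result.reported_coverage,
                    result.reported_coverage - base.reported_coverage,
                )
            )
        elif axis == "minutes_per_review":
            t_star = _snap(max_minutes_per_review(scenario), 0.1, "down")
            if t_star < 0.1 - _EPS:
                rows.append(
                    ScenarioModification(
                        axis, base_value, None, None, None, status="unreachable"
                    )
                )
            else:
                result = scenario.with_pool(minutes_per_review=t_star).coverage()
                rows.append(
                    ScenarioModification(
                        axis, base_value, t_star, result.reported_coverage,
                        result.reported_coverage - base.reported_coverage,
                    )
                )
        else:
            step = 1.0 if axis == "population" else 0.01
            rows.append(_demand_axis_row(scenario, axis, step))
    return rows
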
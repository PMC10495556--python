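"""Monte-Carlo workload simulator for RPM review demand.

The deterministic model works with expected values; real flagged and
contacted counts fluctuate week to week.  This simulator draws, per period,

* flagged counts from a Binomial over the patients shown for review, and
* a period-level contacted/flagged ratio from a Normal distribution
  truncated to [0, 1] (default mean 0.518, SD 0.171, matching the
  dispersion of the study clinic's weekly ratio),

and pushes contacts that exceed capacity into a FIFO backlog, so the demand
variance the average-based model ignores can be quantified as shortfall
probabilities and backlog sizes.

The ratio is drawn once per period rather than per patient: the observed
quantity is a period-level ratio, and per-patient Bernoulli thinning would
understate its dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidParameterError
from .model import (
    Cohort,
    ProviderPool,
    project_population,
    projected_capacity,
    round_half_up,
)

__all__ = [
    "SimulationConfig",
    "SimulatedPeriod",
    "ShortfallSummary",
    "draw_contact_ratios",
    "simulate",
    "shortfall_summary",
    "periods_to_frame",
]


def draw_contact_ratios(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    """Draw period-level contacted/flagged ratios, truncated to [0, 1].

    With sd = 0 the distribution is degenerate at ``mean``.
    """
    if not 0.0 <= mean <= 1.0:
        raise InvalidParameterError("contact_ratio_mean must be in [0, 1]")
    if sd < 0:
        raise InvalidParameterError("contact_ratio_sd must be >= 0")
    if sd == 0:
        return np.full(n, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation inputs on top of the deterministic cohorts.

    ``flag_probability`` is either one probability applied to every cohort
    or a mapping from cohort name to probability; it is the chance that a
    reviewed patient is flagged in a period.  ``shown_draw`` selects how
    fractional expected shown counts become integers: "round" (half-up,
    default) or "poisson".
    """

    cohorts: list[Cohort]
    n_periods: int
    flag_probability: float | dict[str, float] = 0.3
    contact_ratio_mean: float = 0.518
    contact_ratio_sd: float = 0.171
    n_replicates: int = 1
    seed: int | None = None
    shown_draw: str = "round"

    def __post_init__(self):
        if self.n_periods < 1:
            raise InvalidParameterError("n_periods must be >= 1")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if not 0.0 <= self.contact_ratio_mean <= 1.0:
            raise InvalidParameterError("contact_ratio_mean must be in [0, 1]")
        if self.contact_ratio_sd < 0:
            raise InvalidParameterError("contact_ratio_sd must be >= 0")
        if self.shown_draw not in ("round", "poisson"):
            raise InvalidParameterError("shown_draw must be 'round' or 'poisson'")
        for p in self._flag_probs().values():
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("flag_probability must be in [0, 1]")

    def _flag_probs(self) -> dict[str, float]:
        if isinstance(self.flag_probability, dict):
            missing = {c.name for c in self.cohorts} - set(self.flag_probability)
            if missing:
                raise InvalidParameterError(
                    f"flag_probability missing for cohorts: {sorted(missing)}"
                )
            return dict(self.flag_probability)
        return {c.name: float(self.flag_probability) for c in self.cohorts}


@dataclass(frozen=True)
class SimulatedPeriod:
    """One simulated review period.

    ``shortfall`` is the number of this period's contacts deferred to the
    backlog (carried-over contacts are served first, FIFO); ``backlog`` is
    the cumulative deferred total at period end; ``served`` is the number of
    contacts cleared this period.
    """

    period: int
    shown: int
    flagged: int
    contacted: int
    capacity: float
    served: float
    shortfall: float
    backlog: float


def simulate(config: SimulationConfig, pool: ProviderPool) -> list[list[SimulatedPeriod]]:
    """Run the Monte-Carlo workload simulation.

    Returns one list of :class:`SimulatedPeriod` per replicate.  A single
    seeded generator drives all draws in a fixed order (per period: flagged
    per cohort, then the contact ratio), so a fixed seed reproduces output
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    flag_probs = config._flag_probs()
    capacity = projected_capacity(pool)
    trajectory = project_population(config.cohorts, config.n_periods)

    # expected shown per cohort per period, fixed across replicates
    expected_shown = {
        c.name: c.review_frequency * trajectory.counts[c.name].to_numpy()
        for c in config.cohorts
    }

    replicates: list[list[SimulatedPeriod]] = []
    for _ in range(config.n_replicates):
        backlog = 0.0
        periods: list[SimulatedPeriod] = []
        for k in range(config.n_periods):
            shown = 0
            flagged = 0
            for c in config.cohorts:
                mu = expected_shown[c.name][k]
                n_shown = (
                    int(rng.poisson(mu))
                    if config.shown_draw == "poisson"
                    else round_half_up(mu)
                )
                shown += n_shown
                flagged += int(rng.binomial(n_shown, flag_probs[c.name]))
            ratio = float(draw_contact_ratios(
                rng, 1, config.contact_ratio_mean, config.contact_ratio_sd
            )[0])
            contacted = round_half_up(flagged * ratio)

            served_backlog = min(backlog, capacity)
            served_new = min(contacted, capacity - served_backlog)
            shortfall = contacted - served_new
            backlog = backlog - served_backlog + shortfall
            periods.append(
                SimulatedPeriod(
                    period=k,
                    shown=shown,
                    flagged=flagged,
                    contacted=contacted,
                    capacity=capacity,
                    served=served_backlog + served_new,
                    shortfall=shortfall,
                    backlog=backlog,
                )
            )
        replicates.append(periods)
    return replicates


def periods_to_frame(periods: list[SimulatedPeriod]) -> pd.DataFrame:
    """One replicate as a tidy DataFrame (one row per period)."""
    return pd.DataFrame([p.__dict__ for p in periods]).set_index("period")


@dataclass(frozen=True)
class ShortfallSummary:
    """Shortfall and backlog statistics over replicates.

    ``per_replicate`` has one row per replicate; ``pooled`` aggregates all
    replicates.  ``pooled_coverage`` is total capacity as a capped percent
    of total contacts demanded, the stochastic analogue of the
    deterministic coverage percentage.
    """

    per_replicate: pd.DataFrame
    pooled: dict = field(default_factory=dict)


def shortfall_summary(replicates: list[list[SimulatedPeriod]]) -> ShortfallSummary:
    """Summarize shortfall risk across simulation replicates."""
    rows = []
    all_coverages: list[float] = []
    total_contacted = 0.0
    total_capacity = 0.0
    for i, periods in enumerate(replicates):
        contacted = np.array([p.contacted for p in periods], dtype=float)
        capacity = np.array([p.capacity for p in periods], dtype=float)
        backlog = np.array([p.backlog for p in periods], dtype=float)
        shortfall = np.array([p.shortfall for p in periods], dtype=float)
        with np.errstate(divide="ignore"):
            period_cov = np.where(
                contacted > 0, np.minimum(100.0, 100.0 * capacity / contacted), 100.0
            )
        all_coverages.extend(period_cov.tolist())
        total_contacted += contacted.sum()
        total_capacity += capacity.sum()
        rows.append(
            {
                "replicate": i,
                "any_shortfall": bool((shortfall > 0).any()),
                "n_shortfall_periods": int((shortfall > 0).sum()),
                "mean_backlog": float(backlog.mean()),
                "peak_backlog": float(backlog.max()),
                "final_backlog": float(backlog[-1]),
                "mean_period_coverage": float(period_cov.mean()),
            }
        )
    frame = pd.DataFrame(rows).set_index("replicate")
    cov = np.array(all_coverages)
    pooled = {
        "prob_any_shortfall": float(frame["any_shortfall"].mean()),
        "mean_backlog": float(frame["mean_backlog"].mean()),
        "peak_backlog": float(frame["peak_backlog"].max()),
        "mean_period_coverage": float(cov.mean()),
        "pooled_coverage": (
            min(100.0, 100.0 * total_capacity / total_contacted)
            if total_contacted > 0
            else 100.0
        ),
        "coverage_quantiles": {
            q: float(np.quantile(cov, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        },
    }
    return ShortfallSummary(per_replicate=frame, pooled=pooled)
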
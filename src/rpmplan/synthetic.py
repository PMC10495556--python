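"""Synthetic historical logs and scenario presets.

The study clinic's operational logs are not public, so tests and examples
run on synthetic logs with the same statistical structure: a shown-for-review
count that grows steadily over time, flagged counts that are a Binomial
thinning of shown, and a period-level contacted/flagged ratio drawn from a
Normal truncated to [0, 1] with mean 51.8% and SD 17.1% — the clinic's
reported ratio statistics over March 2020 to April 2022.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np

from .errors import InvalidParameterError, UnknownPresetError
from .history import PeriodRecord
from .model import round_half_up
from .simulator import draw_contact_ratios

__all__ = ["GeneratorConfig", "generate_log", "generate_scenario", "SCENARIO_PRESETS"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters for the synthetic-log generator.

    Defaults emulate the study clinic: a shown count starting around 200
    patients drifting up by one per week, roughly 30% of shown patients
    flagged, and the reported contacted/flagged ratio calibration.  The
    growth model is "linear" (shown = initial + k*growth) by default; the
    "logistic" option saturates at ``carrying_capacity``.
    """

    n_periods: int
    initial_shown: float = 200.0
    shown_growth_per_period: float = 1.0
    flag_probability: float = 0.3
    contact_ratio_mean: float = 0.518
    contact_ratio_sd: float = 0.171
    seed: int | None = None
    growth_model: str = "linear"
    carrying_capacity: float | None = None
    start_date: date = date(2020, 3, 2)
    period_days: int = 7

    def __post_init__(self):
        if self.n_periods < 1:
            raise InvalidParameterError("n_periods must be >= 1")
        if self.initial_shown < 0:
            raise InvalidParameterError("initial_shown must be >= 0")
        if not 0.0 <= self.flag_probability <= 1.0:
            raise InvalidParameterError("flag_probability must be in [0, 1]")
        if not 0.0 <= self.contact_ratio_mean <= 1.0:
            raise InvalidParameterError("contact_ratio_mean must be in [0, 1]")
        if self.contact_ratio_sd < 0:
            raise InvalidParameterError("contact_ratio_sd must be >= 0")
        if self.growth_model not in ("linear", "logistic"):
            raise InvalidParameterError("growth_model must be 'linear' or 'logistic'")
        if self.growth_model == "logistic" and (
            self.carrying_capacity is None or self.carrying_capacity <= 0
        ):
            raise InvalidParameterError(
                "logistic growth requires a positive carrying_capacity"
            )

    def expected_shown(self, k: int) -> float:
        if self.growth_model == "linear":
            return self.initial_shown + k * self.shown_growth_per_period
        # discrete logistic drift toward the carrying capacity
        n = self.initial_shown
        for _ in range(k):
            n += self.shown_growth_per_period * (1.0 - n / self.carrying_capacity)
        return n


def generate_log(config: GeneratorConfig) -> list[PeriodRecord]:
    """Generate a synthetic historical log.

    Per period k: shown = round(expected shown), flagged ~ Binomial(shown,
    flag_probability), contacted = round(flagged * ratio) with the ratio
    drawn from the truncated normal.  The count inequalities
    contacted <= flagged <= shown hold by construction, and a fixed seed
    yields a byte-identical log.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    for k in range(config.n_periods):
        shown = max(0, round_half_up(config.expected_shown(k)))
        flagged = int(rng.binomial(shown, config.flag_probability))
        ratio = float(
            draw_contact_ratios(
                rng, 1, config.contact_ratio_mean, config.contact_ratio_sd
            )[0]
        )
        contacted = min(flagged, round_half_up(flagged * ratio))
        records.append(
            PeriodRecord(
                period_start=config.start_date + timedelta(days=k * config.period_days),
                shown=shown,
                flagged=flagged,
                contacted=contacted,
            )
        )
    return records


# Scenario presets as plain config mappings (see rpmplan.config for I/O).
# "baseline_study": the study clinic as of spring 2022 — three reviewers at
# 4 h/week and 10 min/review (capacity 72 reviews/week), two weekly-cadence
# cohorts of newly diagnosed patients and one monthly-cadence cohort.  The
# clinic never published its baseline contact fractions, so they are null
# placeholders the user must fill in; defaulting silently would fabricate
# data.  "toy": small hand-checkable numbers (D = 1*0.25*(38+2) = 10,
# K = 2/h * 1 * 1 h = 2, coverage 20%).
SCENARIO_PRESETS: dict[str, dict] = {
    "baseline_study": {
        "period_label": "week",
        "cohorts": [
            {
                "name": "4T_study",
                "enrolled": 133,
                "new_per_period": 0.0,
                "graduation_fraction": 0.0,
                "review_frequency": 1.0,
                "contact_fraction": None,
            },
            {
                "name": "4T_pilot",
                "enrolled": 135,
                "new_per_period": 0.0,
                "graduation_fraction": 0.0,
                "review_frequency": 1.0,
                "contact_fraction": None,
            },
            {
                "name": "TIPS",
                "enrolled": 94,
                "new_per_period": 0.0,
                "graduation_fraction": 0.0,
                "review_frequency": 0.25,
                "contact_fraction": None,
            },
        ],
        "pool": {
            "n_providers": 3,
            "hours_per_period": 4.0,
            "minutes_per_review": 10.0,
        },
    },
    "toy": {
        "period_label": "week",
        "cohorts": [
            {
                "name": "toy",
                "enrolled": 38,
                "new_per_period": 2.0,
                "graduation_fraction": 0.0,
                "review_frequency": 1.0,
                "contact_fraction": 0.25,
            }
        ],
        "pool": {
            "n_providers": 1,
            "hours_per_period": 1.0,
            "minutes_per_review": 30.0,
        },
    },
}


def generate_scenario(preset_name: str) -> dict:
    """Return a named scenario preset as a config mapping.

    The "baseline_study" preset leaves contact fractions as null
    placeholders that the user must set before the scenario can be loaded.
    """
    try:
        preset = SCENARIO_PRESETS[preset_name]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {preset_name!r}; available: "
            f"{', '.join(sorted(SCENARIO_PRESETS))}"
        )
    # deep-ish copy so callers can fill placeholders without mutating the preset
    return {
        "period_label": preset["period_label"],
        "cohorts": [dict(c) for c in preset["cohorts"]],
        "pool": dict(preset["pool"]),
    }
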
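"""Scenario and calibration config I/O (YAML).

The scenario file schema is part of the public contract::

    period_label: week            # optional
    cohorts:
      - name: 4T_study
        enrolled: 133
        new_per_period: 0.0
        graduation_fraction: 0.0
        review_frequency: 1.0
        contact_fraction: 0.4
    pool:
      n_providers: 3
      hours_per_period: 4.0
      minutes_per_review: 10.0

Key names round-trip exactly through :func:`read_scenario` /
:func:`write_scenario`.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .history import CalibrationFit
from .model import Cohort, ProviderPool, Scenario

__all__ = [
    "read_scenario",
    "write_scenario",
    "scenario_to_mapping",
    "scenario_from_mapping",
    "write_calibration",
    "read_calibration",
]

_COHORT_KEYS = (
    "name",
    "enrolled",
    "new_per_period",
    "graduation_fraction",
    "review_frequency",
    "contact_fraction",
)
_POOL_KEYS = ("n_providers", "hours_per_period", "minutes_per_review")


def scenario_from_mapping(data: dict) -> Scenario:
    """Build a Scenario from a config mapping (as read from YAML)."""
    if "pool" not in data or "cohorts" not in data:
        raise InvalidParameterError("scenario config requires 'cohorts' and 'pool'")
    cohorts = []
    for entry in data["cohorts"]:
        unknown = set(entry) - set(_COHORT_KEYS)
        if unknown:
            raise InvalidParameterError(f"unknown cohort keys: {sorted(unknown)}")
        if entry.get("contact_fraction") is None:
            raise InvalidParameterError(
                f"cohort {entry.get('name')!r}: contact_fraction is unset "
                "(null placeholder) — set it before loading"
            )
        cohorts.append(
            Cohort(
                name=str(entry["name"]),
                enrolled=float(entry["enrolled"]),
                contact_fraction=float(entry["contact_fraction"]),
                review_frequency=float(entry.get("review_frequency", 1.0)),
                new_per_period=float(entry.get("new_per_period", 0.0)),
                graduation_fraction=float(entry.get("graduation_fraction", 0.0)),
            )
        )
    pool_data = dict(data["pool"])
    unknown = set(pool_data) - set(_POOL_KEYS) - {"review_capacity_override"}
    if unknown:
        raise InvalidParameterError(f"unknown pool keys: {sorted(unknown)}")
    pool = ProviderPool(
        n_providers=int(pool_data["n_providers"]),
        hours_per_period=float(pool_data["hours_per_period"]),
        minutes_per_review=float(pool_data["minutes_per_review"]),
        review_capacity_override=pool_data.get("review_capacity_override"),
    )
    return Scenario(
        cohorts=cohorts, pool=pool, period_label=str(data.get("period_label", "week"))
    )


def scenario_to_mapping(scenario: Scenario) -> dict:
    """Serialize a Scenario to the config mapping (inverse of from_mapping)."""
    data: dict = {
        "period_label": scenario.period_label,
        "cohorts": [
            {
                "name": c.name,
                "enrolled": c.enrolled,
                "new_per_period": c.new_per_period,
                "graduation_fraction": c.graduation_fraction,
                "review_frequency": c.review_frequency,
                "contact_fraction": c.contact_fraction,
            }
            for c in scenario.cohorts
        ],
        "pool": {
            "n_providers": scenario.pool.n_providers,
            "hours_per_period": scenario.pool.hours_per_period,
            "minutes_per_review": scenario.pool.minutes_per_review,
        },
    }
    if scenario.pool.review_capacity_override is not None:
        data["pool"]["review_capacity_override"] = scenario.pool.review_capacity_override
    return data


def read_scenario(path: str | Path) -> Scenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidParameterError(f"{path}: not a scenario config mapping")
    return scenario_from_mapping(data)


def write_scenario(scenario: Scenario | dict, path: str | Path) -> None:
    """Write a scenario (or a raw preset mapping with placeholders) to YAML."""
    data = scenario if isinstance(scenario, dict) else scenario_to_mapping(scenario)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_calibration(fit: CalibrationFit, path: str | Path) -> None:
    """Write a fitted calibration as a simulation-config fragment."""
    data = {
        "contact_ratio_mean": fit.contact_ratio_mean,
        "contact_ratio_sd": fit.contact_ratio_sd,
        "flag_probability": fit.flag_probability,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_calibration(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    expected = {"contact_ratio_mean", "contact_ratio_sd", "flag_probability"}
    if not isinstance(data, dict) or not expected <= set(data):
        raise InvalidParameterError(f"{path}: not a calibration fragment")
    return {k: float(data[k]) for k in expected}
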
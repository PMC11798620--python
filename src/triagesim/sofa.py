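"""Sequential Organ Failure Assessment (SOFA) calculator.

Six organ systems -- respiration, coagulation, liver, cardiovascular, central
nervous system, renal -- each score 0 (normal) to 4 (most deranged); the total
is their sum, 0-24.  Every triage protocol in this package consumes the total.

The component thresholds follow the standard published SOFA table and ship as
a versioned data file (``data/sofa_thresholds.yaml``) so an alternative
dialect can be swapped in.  The bundled scenario cohort carries SOFA totals
directly, so this module is exercised by its own validation suite rather than
by the allocation pipeline.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "SofaComponents",
    "SofaError",
    "component_score",
    "total_sofa",
    "load_threshold_table",
    "SYSTEMS",
]

SYSTEMS = ("respiration", "coagulation", "liver", "cardiovascular", "cns", "renal")


class SofaError(ValueError):
    """Unknown organ system or non-physiological measurement."""


class SofaComponents(BaseModel):
    """The six organ-system subscores, each 0-4."""

    model_config = ConfigDict(frozen=True)

    respiration: int = Field(ge=0, le=4)
    coagulation: int = Field(ge=0, le=4)
    liver: int = Field(ge=0, le=4)
    cardiovascular: int = Field(ge=0, le=4)
    cns: int = Field(ge=0, le=4)
    renal: int = Field(ge=0, le=4)


@lru_cache(maxsize=1)
def load_threshold_table() -> dict:
    """Load the shipped SOFA threshold table (cached)."""
    text = resources.files("triagesim").joinpath("data/sofa_thresholds.yaml").read_text()
    return yaml.safe_load(text)


def _score_lower_worse(value: float, breakpoints: list[float]) -> int:
    # score s when value < breakpoints[s-1]; breakpoints are descending
    score = 0
    for s, bp in enumerate(breakpoints, start=1):
        if value < bp:
            score = s
    return score


def _score_higher_worse(value: float, breakpoints: list[float]) -> int:
    score = 0
    for s, bp in enumerate(breakpoints, start=1):
        if value >= bp:
            score = s
    return score


def _renal_score(measurement: Union[float, Mapping[str, float]], spec: dict) -> int:
    """Creatinine and urine-output criteria; the worse of the two governs."""
    if isinstance(measurement, Mapping):
        creat = measurement.get("creatinine")
        urine = measurement.get("urine_output_ml_day")
    else:
        creat, urine = float(measurement), None
    scores = []
    if creat is not None:
        if creat < 0:
            raise SofaError(f"creatinine must be >= 0, got {creat}")
        scores.append(_score_higher_worse(float(creat), spec["breakpoints"]))
    if urine is not None:
        if urine < 0:
            raise SofaError(f"urine output must be >= 0, got {urine}")
        uo = spec["urine_output"]["thresholds"]
        if urine < uo[4]:
            scores.append(4)
        elif urine < uo[3]:
            scores.append(3)
        else:
            scores.append(0)
    if not scores:
        raise SofaError("renal measurement needs creatinine and/or urine_output_ml_day")
    return max(scores)


def _cardiovascular_score(
    measurement: Union[float, Mapping[str, float]], spec: dict
) -> int:
    """MAP below 70 mmHg scores 1; vasopressor requirements score 2-4.

    Accepts a bare mean arterial pressure (mmHg) or a mapping with any of
    ``map``, ``dopamine``, ``dobutamine`` (truthy), ``epinephrine``,
    ``norepinephrine`` (catecholamine doses in ug/kg/min).
    """
    if not isinstance(measurement, Mapping):
        measurement = {"map": float(measurement)}
    cuts = spec["dose_cutoffs"]
    dop = measurement.get("dopamine", 0.0) or 0.0
    epi = measurement.get("epinephrine", 0.0) or 0.0
    nor = measurement.get("norepinephrine", 0.0) or 0.0
    if min(dop, epi, nor) < 0:
        raise SofaError("vasopressor doses must be >= 0")
    if dop > cuts["dopamine_high"] or epi > cuts["epi_norepi"] or nor > cuts["epi_norepi"]:
        return 4
    if dop > cuts["dopamine_low"] or epi > 0 or nor > 0:
        return 3
    if dop > 0 or measurement.get("dobutamine"):
        return 2
    map_value = measurement.get("map")
    if map_value is None:
        raise SofaError("cardiovascular measurement needs a MAP or a vasopressor dose")
    if map_value < 0:
        raise SofaError(f"MAP must be >= 0, got {map_value}")
    return 1 if map_value < spec["hypotension_map"] else 0


def component_score(
    system: str, measurement: Union[float, Mapping[str, float]]
) -> int:
    """Score one organ system from a physiological measurement.

    Parameters
    ----------
    system : str
        One of ``respiration`` (PaO2/FiO2, mmHg), ``coagulation`` (platelets,
        10^3/uL), ``liver`` (bilirubin, mg/dL), ``cardiovascular`` (MAP mmHg
        or a vasopressor mapping), ``cns`` (Glasgow Coma Scale), ``renal``
        (creatinine mg/dL or a mapping with urine output).

    Returns
    -------
    int
        Subscore 0-4, monotone in severity.
    """
    table = load_threshold_table()["systems"]
    if system not in table:
        raise SofaError(f"unknown organ system {system!r}; expected one of {SYSTEMS}")
    spec = table[system]
    if system == "renal":
        return _renal_score(measurement, spec)
    if system == "cardiovascular":
        return _cardiovascular_score(measurement, spec)
    value = float(measurement)  # type: ignore[arg-type]
    if value < 0:
        raise SofaError(f"{spec['measurement']} must be >= 0, got {value}")
    if system == "cns" and not (3 <= value <= 15):
        raise SofaError(f"Glasgow Coma Scale must lie in 3..15, got {value}")
    if spec["direction"] == "lower_worse":
        return _score_lower_worse(value, spec["breakpoints"])
    return _score_higher_worse(value, spec["breakpoints"])


def total_sofa(components: SofaComponents) -> int:
    """Sum of the six subscores; 0 (all normal) to 24 (all maximal)."""
    return (
        components.respiration
        + components.coagulation
        + components.liver
        + components.cardiovascular
        + components.cns
        + components.renal
    )
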
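"""Indicator variable specifications for the adolescent lifestyle battery.

The default battery is the 10-indicator set used throughout the package:
continuous BMI at ages 12/14/17, ordinal leisure-time physical activity at
12 (3 levels) and 14/17 (4 levels), and ordinal smoking status and binge
drinking at 14/17 (4 levels each).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class IndicatorSpec:
    """One classification indicator.

    Parameters
    ----------
    name : str
        Column name in the cohort table; unique within a battery.
    kind : str
        ``"ordinal"`` or ``"continuous"``.
    n_categories : int or None
        Number of ordered categories (ordinal only, coded ``0..C-1``).
    timepoint : str
        Label for the measurement wave (informational).
    """

    name: str
    kind: str
    n_categories: int | None = None
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("ordinal", "continuous"):
            raise ValueError(f"unknown indicator kind {self.kind!r}")
        if self.kind == "ordinal":
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError(f"{self.name}: ordinal indicators need >=2 categories")
        elif self.n_categories is not None:
            raise ValueError(f"{self.name}: continuous indicators take no n_categories")


def default_indicator_specs() -> list[IndicatorSpec]:
    """The standard 10-indicator adolescent lifestyle battery."""
    return [
        IndicatorSpec("bmi12", "continuous", timepoint="age 12"),
        IndicatorSpec("bmi14", "continuous", timepoint="age 14"),
        IndicatorSpec("bmi17", "continuous", timepoint="age 17"),
        IndicatorSpec("ltpa12", "ordinal", 3, timepoint="age 12"),
        IndicatorSpec("ltpa14", "ordinal", 4, timepoint="age 14"),
        IndicatorSpec("ltpa17", "ordinal", 4, timepoint="age 17"),
        IndicatorSpec("smoke14", "ordinal", 4, timepoint="age 14"),
        IndicatorSpec("smoke17", "ordinal", 4, timepoint="age 17"),
        IndicatorSpec("binge14", "ordinal", 4, timepoint="age 14"),
        IndicatorSpec("binge17", "ordinal", 4, timepoint="age 17"),
    ]


def validate_specs(specs: list[IndicatorSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("indicator names must be unique")
    if not specs:
        raise ValueError("at least one indicator required")
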
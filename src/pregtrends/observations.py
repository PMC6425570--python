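"""Typed observations produced by the data-classification rule engines.

A raw abortion or intention datum, after passing through the decision
logic, becomes a :class:`ClassifiedObservation`: a statement about one
model indicator that is either a point estimate, a one-sided bound
(minimum / maximum), or an interval, carrying labeled additive error
variance components and, where applicable, a link to a regional
under-reporting inflation factor or to the recall-bias model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import pandas as pd

__all__ = [
    "ClassifiedObservation",
    "INDICATOR_SCALES",
    "ERROR_COMPONENT_LABELS",
    "observations_to_frame",
    "observations_from_frame",
]

#: Indicator -> transformed scale used by the inference module.
INDICATOR_SCALES = {
    "abortion_count": "log",
    "abortion_rate": "log",
    "pct_births_unintended": "logit",
    "pct_pregnancies_unintended": "logit",
    "pct_marital_births_intended": "logit",
}

#: Recognised error-component labels (variances on the transformed scale).
ERROR_COMPONENT_LABELS = (
    "sampling",
    "non_probability",
    "subgroup",
    "multiplier",
    "complications",
    "legal_count",
    "nonsampling_default",
)

BOUNDS = ("point", "minimum", "maximum", "interval")


@dataclass
class ClassifiedObservation:
    country: str
    period: int
    indicator: str
    bound: str = "point"
    value: float = float("nan")
    value_high: Optional[float] = None
    #: label -> variance on the transformed scale; None = use config default.
    error_components: dict = field(default_factory=dict)
    inflation_link: str = "none"  # "none" | "regional_inflation_factor"
    truncation: Optional[float] = None
    recall_bias_flag: bool = False
    region: Optional[str] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None
    datum_id: Optional[str] = None
    audit: str = ""

    def __post_init__(self) -> None:
        if self.bound not in BOUNDS:
            raise ValueError(f"unknown bound type {self.bound!r}")
        if not self.excluded and self.indicator not in INDICATOR_SCALES:
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.bound == "interval":
            if self.value_high is None:
                raise ValueError("interval observation requires value_high")
            if self.value > self.value_high:
                raise ValueError(
                    f"interval low {self.value} exceeds high {self.value_high}"
                )
        for label in self.error_components:
            if label not in ERROR_COMPONENT_LABELS:
                raise ValueError(f"unknown error component {label!r}")

    def add_component(self, label: str, variance: Optional[float] = None) -> None:
        if label not in ERROR_COMPONENT_LABELS:
            raise ValueError(f"unknown error component {label!r}")
        self.error_components[label] = variance

    def note(self, message: str) -> None:
        self.audit = f"{self.audit} -> {message}" if self.audit else message

    @property
    def scale(self) -> str:
        return INDICATOR_SCALES[self.indicator]


def observations_to_frame(observations: list[ClassifiedObservation]) -> pd.DataFrame:
    rows = []
    for i, obs in enumerate(observations):
        d = asdict(obs)
        d["obs_id"] = i
        d["error_components"] = json.dumps(d["error_components"])
        rows.append(d)
    return pd.DataFrame(rows)


def observations_from_frame(frame: pd.DataFrame) -> list[ClassifiedObservation]:
    out = []
    for row in frame.to_dict("records"):
        row = dict(row)
        row.pop("obs_id", None)
        row["error_components"] = {
            k: v for k, v in json.loads(row["error_components"]).items()
        }
        if pd.isna(row.get("value_high")):
            row["value_high"] = None
        if pd.isna(row.get("truncation")):
            row["truncation"] = None
        for key in ("region", "exclusion_reason", "datum_id"):
            if pd.isna(row.get(key)):
                row[key] = None
        row["period"] = int(row["period"])
        out.append(ClassifiedObservation(**row))
    return out
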
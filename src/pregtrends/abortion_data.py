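"""Decision logic classifying abortion datums into typed observations.

Raw abortion data are heterogeneous: official statistics of varying
completeness, surveys of women subject to under-reporting, and indirect
abortion-incidence-complications-method (AICM) studies.  Each datum is
routed through a decision tree that determines whether it informs the
model as a point estimate, a minimum, a maximum, or an interval, and
which error-variance components attach to it.

Official statistics are screened by six ordered questions: legality of
abortion, acknowledged completeness (the 90% cutoff), comparison against
survey-of-women estimates, informal-sector provision, an expert
implausibility review, and inclusion of spontaneous abortions.  The
first triggered screen classifies the datum as a minimum; a datum
passing all screens is a point estimate with a nonsampling error term.
Counts that include spontaneous abortions are revised downward via the
pregnancy identity (pregnancies = 1.2 births + 1.1 induced abortions).

Surveys of women become points linked to a regional under-reporting
inflation factor when the region has paired survey/official information,
and minimums otherwise.  AICM datums get distinct multiplier and
complications error terms, the latter truncated on the right at the
total complication count (including miscarriage-related complications).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .observations import ClassifiedObservation

__all__ = [
    "AbortionDatum",
    "ClassificationError",
    "classify_abortion_datum",
    "classify_official",
    "spontaneous_adjust",
    "aicm_observation",
    "subgroup_error",
    "COMPLETENESS_CUTOFF",
]

#: Official statistics acknowledged as counting fewer than this fraction
#: of abortions are classified as minimum estimates.
COMPLETENESS_CUTOFF = 0.90


class ClassificationError(ValueError):
    """A datum hit a branch the decision logic does not cover."""


@dataclass
class AbortionDatum:
    country: str
    period: int
    source: str  # "published_study" | "official_statistic"
    reported_count: float = float("nan")  # m; may include spontaneous abortions
    live_births: float = float("nan")  # b, same coverage period as m
    special_population: bool = False
    national_probability_sample: bool = True
    method: str = "registry"  # "womens_reports" | "aicm" | "registry"
    subgroup_breakdown: bool = False
    legal_broadly_available: bool = True
    acknowledged_completeness: Optional[float] = None  # None = unknown
    below_survey_estimate: Optional[bool] = None  # country-level flag
    period_quality_established: bool = False  # stated per-period exception
    informal_sector_substantial: bool = False
    implausible_per_review: bool = False  # human review outcome, input flag
    includes_spontaneous: bool = False
    sampling_variance: Optional[float] = None  # log-scale, surveys of women
    aicm_complications_treated: Optional[float] = None
    aicm_total_complications: Optional[float] = None
    aicm_multiplier: Optional[float] = None
    aicm_legal_abortions: Optional[float] = None
    datum_id: Optional[str] = None
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.acknowledged_completeness is not None and not (
            0.0 <= self.acknowledged_completeness <= 1.0
        ):
            raise ValueError("acknowledged_completeness must lie in [0, 1]")
        if (
            self.aicm_complications_treated is not None
            and self.aicm_total_complications is not None
            and self.aicm_complications_treated > self.aicm_total_complications
        ):
            raise ValueError(
                "complications treated exceeds total complications incl. miscarriage"
            )


def _base_observation(d: AbortionDatum) -> ClassifiedObservation:
    return ClassifiedObservation(
        country=d.country,
        period=d.period,
        indicator="abortion_count",
        value=float(d.reported_count),
        datum_id=d.datum_id,
        region=d.region,
    )


def spontaneous_adjust(m: float, b: float) -> tuple[float, float]:
    """Interval for induced abortions when the count includes spontaneous.

    With pregnancies = 1.2 b + 1.1 a and m = a + miscarriages, the induced
    count solves to a = (m - 0.2 b) / 1.1, clipped at zero; the unadjusted
    m is an upper bound.
    """
    if m < 0 or b < 0:
        raise ValueError("counts must be nonnegative")
    low = max(0.0, (m - 0.2 * b) / 1.1)
    return low, float(m)


def subgroup_error(obs: ClassifiedObservation) -> ClassifiedObservation:
    """Attach the subgroup under-reporting variance component."""
    obs.add_component("subgroup")
    obs.note("subgroup breakdown: added subgroup error term")
    return obs


def classify_official(d: AbortionDatum) -> ClassifiedObservation:
    """Apply the six ordered screens for official abortion statistics."""
    if d.source != "official_statistic":
        raise ClassificationError("classify_official requires an official statistic")
    obs = _base_observation(d)
    reason = None
    if not d.legal_broadly_available:
        reason = "legal abortion not broadly available"
    elif (
        d.acknowledged_completeness is not None
        and d.acknowledged_completeness < COMPLETENESS_CUTOFF
    ):
        reason = (
            f"acknowledged completeness {d.acknowledged_completeness:.2f} < "
            f"{COMPLETENESS_CUTOFF:.2f}"
        )
    elif bool(d.below_survey_estimate) and not d.period_quality_established:
        reason = "official count below survey-of-women estimate (country-level)"
    elif d.informal_sector_substantial:
        reason = "substantial informal-sector provision"
    elif d.implausible_per_review:
        reason = "implausible level or trend per expert review"

    if reason is not None:
        obs.bound = "minimum"
        obs.note(f"minimum: {reason}")
    else:
        obs.bound = "point"
        obs.add_component("nonsampling_default")
        obs.note("point estimate with nonsampling error term")

    if d.includes_spontaneous:
        low, high = spontaneous_adjust(d.reported_count, d.live_births)
        if obs.bound == "point":
            obs.bound = "interval"
            obs.value, obs.value_high = low, high
            obs.note(
                "includes spontaneous abortions: revised down via pregnancy "
                "identity; unadjusted count is a maximum"
            )
        else:  # already a minimum: the minimum itself is revised down
            obs.value = low
            obs.note("includes spontaneous abortions: minimum revised down")
    return obs


def aicm_observation(d: AbortionDatum) -> ClassifiedObservation:
    """Classify an AICM (indirect) study.

    value = complications treated x multiplier (+ legal abortions for the
    modified AICM).  Distinct error terms attach to the multiplier and to
    the complications count; the complications term is asymmetric,
    truncated on the right at total complications x multiplier.
    """
    if d.method != "aicm":
        raise ClassificationError("aicm_observation requires method='aicm'")
    if d.aicm_multiplier is None or d.aicm_complications_treated is None:
        raise ClassificationError("AICM datum lacks complications or multiplier")
    obs = _base_observation(d)
    value = d.aicm_complications_treated * d.aicm_multiplier
    truncation = None
    if d.aicm_total_complications is not None:
        truncation = d.aicm_total_complications * d.aicm_multiplier
    obs.add_component("multiplier")
    obs.add_component("complications")
    obs.note("AICM: complications x multiplier with distinct error terms")
    if d.aicm_legal_abortions is not None:
        # modified AICM: legal count folded in, datum is a minimum
        value += d.aicm_legal_abortions
        if truncation is not None:
            truncation += d.aicm_legal_abortions
        obs.add_component("legal_count")
        obs.bound = "minimum"
        obs.note("modified AICM with legal abortions: minimum estimate")
    else:
        obs.bound = "point"
    obs.value = float(value)
    obs.truncation = truncation
    return obs


def classify_abortion_datum(
    d: AbortionDatum, region_has_underreporting_estimate: bool = False
) -> ClassifiedObservation:
    """Route one abortion datum through the full decision tree."""
    if d.special_population:
        obs = _base_observation(d)
        obs.excluded = True
        obs.exclusion_reason = "special population sample"
        obs.note("excluded: special population sample")
        return obs

    if d.source == "official_statistic":
        return classify_official(d)

    if d.source != "published_study":
        raise ClassificationError(f"unknown source {d.source!r}")

    if d.method == "aicm":
        obs = aicm_observation(d)
    elif d.method == "womens_reports":
        obs = _base_observation(d)
        obs.add_component("sampling", d.sampling_variance)
        obs.add_component("nonsampling_default")
        if region_has_underreporting_estimate:
            obs.bound = "point"
            obs.inflation_link = "regional_inflation_factor"
            obs.note(
                "survey of women: point with regional inflation factor "
                "(under-reporting pooled within region)"
            )
        else:
            obs.bound = "minimum"
            obs.note(
                "survey of women, no regional under-reporting estimate: minimum"
            )
        if d.subgroup_breakdown:
            subgroup_error(obs)
    else:
        raise ClassificationError(
            f"published study with unhandled method {d.method!r}"
        )

    if not d.national_probability_sample:
        obs.add_component("non_probability")
        obs.note("not a national probability sample: added error term")
    return obs
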
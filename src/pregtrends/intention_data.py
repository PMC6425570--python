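"""Decision logic classifying pregnancy/birth-intention data.

Surveys report the percent of recent live births (or pregnancies) that
were unintended at conception.  The classifier routes each datum by
sample (special populations excluded, non-probability samples carry an
extra error term), by access to microdata (which determines whether the
survey's own sampling error or the mean sampling error across surveys
is used, and whether long recall windows require response-bias
modeling), by instrument (the London Measure of Unplanned Pregnancy
yields an interval rather than a point), and by scope (all women, ever
married, currently married), which determines whether the datum informs
the all-women percent unintended, the percent of marital births
intended, or only a bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .abortion_data import ClassificationError
from .observations import ClassifiedObservation

__all__ = [
    "IntentionDatum",
    "BirthRecord",
    "classify_intention_datum",
    "lmup_interval",
    "marital_scope",
    "marital_history_bounds",
    "percent_to_logit_variance",
]

SCOPES = ("all_women", "ever_married", "currently_married")


@dataclass
class BirthRecord:
    """Toy microdata record used to bound marital-birth intendedness."""

    birth_date: float
    first_union_date: Optional[float]  # None only if never_in_union
    currently_in_first_union: bool
    intended: bool
    never_in_union: bool = False

    def marital_class(self) -> str:
        """'marital', 'nonmarital' or 'ambiguous'."""
        if self.never_in_union:
            return "nonmarital"
        if self.first_union_date is None:
            raise ValueError("record lacks first-union date and pre-union status")
        if self.birth_date < self.first_union_date:
            return "nonmarital"
        if self.currently_in_first_union:
            return "marital"
        # post-union birth to a woman no longer in her first union
        return "ambiguous"


@dataclass
class IntentionDatum:
    country: str
    period: int
    percent_unintended: float = float("nan")
    scope: str = "all_women"
    denominator: str = "births"  # "births" | "pregnancies"
    special_population: bool = False
    national_probability_sample: bool = True
    microdata_available: bool = True
    sampling_error: Optional[float] = None  # SE in percentage points
    recall_over_one_year: bool = False
    antenatal_clinic_sample: bool = False
    instrument: str = "traditional"  # "traditional" | "lmup"
    lmup_planned: Optional[float] = None
    lmup_ambivalent: Optional[float] = None
    lmup_unwanted: Optional[float] = None
    marital_history_available: bool = True
    recent_birth_restriction: bool = True
    percent_marital_intended: Optional[float] = None
    birth_records: Optional[Sequence[BirthRecord]] = None
    datum_id: Optional[str] = None
    region: Optional[str] = None

    def __post_init__(self) -> None:
        if self.instrument == "lmup":
            parts = (self.lmup_planned, self.lmup_ambivalent, self.lmup_unwanted)
            if any(p is None for p in parts):
                raise ValueError("LMUP datum requires planned/ambivalent/unwanted")


def percent_to_logit_variance(percent: float, se: float) -> float:
    """Delta-method variance of logit(p) given an SE in percentage points."""
    p = min(max(percent / 100.0, 1e-3), 1 - 1e-3)
    return (se / 100.0) ** 2 / (p * (1.0 - p)) ** 2


def lmup_interval(planned: float, ambivalent: float, unwanted: float,
                  tol: float = 0.5) -> tuple[float, float]:
    """Interval for traditional-measure percent unintended from LMUP shares.

    LMUP's ambivalent category mixes conceptions the traditional measure
    would call intended with ones it would call unintended, so the
    traditional percent unintended lies in [unwanted, unwanted + ambivalent]
    (= [unwanted, 100 - planned]).
    """
    if min(planned, ambivalent, unwanted) < 0:
        raise ValueError("LMUP percents must be nonnegative")
    if abs(planned + ambivalent + unwanted - 100.0) > tol:
        raise ValueError("LMUP percents must sum to 100")
    return float(unwanted), float(unwanted + ambivalent)


def marital_history_bounds(records: Sequence[BirthRecord]) -> tuple[float, float]:
    """Bounds on the percent of marital births intended without a marital
    history.

    Births before first union (or to never-married women) are nonmarital;
    post-union births to women still in their first union are marital;
    post-union births to women no longer in their first union are
    ambiguous.  The interval spans the extreme assignments of ambiguous
    births: the lower end counts ambiguous unintended births as marital
    and ambiguous intended ones as nonmarital, the upper end the reverse,
    so any mixed assignment falls inside.
    """
    if not records:
        raise ValueError("no birth records supplied")
    n_marital = i_marital = 0
    a_int = a_unint = 0
    for r in records:
        cls = r.marital_class()
        if cls == "marital":
            n_marital += 1
            i_marital += int(r.intended)
        elif cls == "ambiguous":
            if r.intended:
                a_int += 1
            else:
                a_unint += 1
    lo_den = n_marital + a_unint
    hi_den = n_marital + a_int
    if lo_den == 0 and hi_den == 0:
        raise ValueError("no marital or ambiguous births among the records")
    low = 100.0 * i_marital / lo_den if lo_den else 0.0
    high = 100.0 * (i_marital + a_int) / hi_den if hi_den else 100.0
    return min(low, high), max(low, high)


def _all_women_indicator(d: IntentionDatum) -> str:
    # antenatal samples are treated as information on births: abortion is
    # an improbable outcome in that sample, so the pregnancies denominator
    # would be biased
    if d.antenatal_clinic_sample or d.denominator == "births":
        return "pct_births_unintended"
    if d.denominator == "pregnancies":
        return "pct_pregnancies_unintended"
    raise ClassificationError(f"unknown denominator {d.denominator!r}")


def marital_scope(d: IntentionDatum) -> list[dict]:
    """Observation plans implied by the survey's marital scope.

    Returns dicts with keys indicator / bound / role ("all_women" or
    "marital").  All-women and ever-married surveys inform the percent of
    marital births intended; currently-married surveys do so only when
    recent births are identifiable, and otherwise bound the percent
    intended among all women from above (equivalently, the percent
    unintended from below).
    """
    if d.scope not in SCOPES:
        raise ClassificationError(f"unknown scope {d.scope!r}")
    plans: list[dict] = []
    if d.scope == "all_women":
        plans.append({"indicator": _all_women_indicator(d), "bound": "point",
                      "role": "all_women"})
        plans.append({"indicator": "pct_marital_births_intended",
                      "bound": "point", "role": "marital"})
    elif d.scope == "ever_married":
        plans.append({"indicator": "pct_marital_births_intended",
                      "bound": "point", "role": "marital"})
    else:  # currently_married
        if d.recent_birth_restriction:
            plans.append({"indicator": "pct_marital_births_intended",
                          "bound": "point", "role": "marital"})
        else:
            # maximum percent intended among all women == minimum percent
            # unintended among all women
            plans.append({"indicator": "pct_births_unintended",
                          "bound": "minimum", "role": "all_women"})
    return plans


def classify_intention_datum(
    d: IntentionDatum, mean_sampling_error: float = 2.0
) -> list[ClassifiedObservation]:
    """Route one intention datum through the decision logic.

    Returns one or two observations (all-women surveys also inform the
    marital-births indicator when a marital percent or records exist).
    """
    if d.special_population:
        obs = ClassifiedObservation(
            country=d.country, period=d.period, indicator="pct_births_unintended",
            excluded=True, exclusion_reason="special population sample",
            datum_id=d.datum_id, region=d.region,
        )
        obs.note("excluded: special population sample")
        return [obs]

    # the survey's own sampling error is usable when we processed the
    # microdata or the study published it; otherwise fall back to the mean
    se_known = d.sampling_error is not None
    se = d.sampling_error if se_known else mean_sampling_error
    recall_flag = d.recall_over_one_year and not d.microdata_available

    out: list[ClassifiedObservation] = []
    for plan in marital_scope(d):
        obs = ClassifiedObservation(
            country=d.country, period=d.period, indicator=plan["indicator"],
            bound=plan["bound"], datum_id=d.datum_id, region=d.region,
        )
        if plan["role"] == "all_women":
            value = d.percent_unintended
            if d.instrument == "lmup":
                lo, hi = lmup_interval(
                    d.lmup_planned, d.lmup_ambivalent, d.lmup_unwanted
                )
                if plan["bound"] == "point":
                    obs.bound = "interval"
                    obs.value, obs.value_high = lo, hi
                    obs.note("LMUP instrument: interval on percent unintended")
                else:
                    obs.value = lo
                    obs.note("LMUP instrument: bound at percent unwanted")
            else:
                obs.value = float(value)
            if plan["bound"] == "minimum":
                obs.note(
                    "currently-married sample without recent-birth restriction: "
                    "minimum on all-women percent unintended"
                )
            ref = obs.value
        else:  # marital
            if d.percent_marital_intended is not None:
                marital_pct = float(d.percent_marital_intended)
            elif d.scope != "all_women":
                marital_pct = 100.0 - float(d.percent_unintended)
            elif d.birth_records:
                marital_pct = None
            else:
                continue  # all-women survey without marital detail
            if not d.marital_history_available and not d.birth_records:
                # published percent only: no way to bound the ambiguous
                # births, so the study's own figure is used directly
                obs.value = marital_pct
                obs.note("no marital history or records: published percent used")
            elif not d.marital_history_available:
                lo, hi = marital_history_bounds(d.birth_records)
                if lo == hi:
                    obs.value = lo
                    obs.note("no marital history: degenerate interval (point)")
                else:
                    obs.bound = "interval"
                    obs.value, obs.value_high = lo, hi
                    obs.note(
                        "no marital history: interval over ambiguous "
                        "post-union births"
                    )
            else:
                if marital_pct is None and d.birth_records:
                    lo, hi = marital_history_bounds(d.birth_records)
                    marital_pct = (lo + hi) / 2.0
                obs.value = marital_pct
            obs.add_component("subgroup")
            obs.note("marital indicator: subgroup error term")
            ref = obs.value
        # sampling error: survey's own when microdata/published, else mean
        sv = percent_to_logit_variance(ref if ref == ref else 50.0, se)
        obs.add_component("sampling", sv)
        if not se_known:
            obs.note(f"sampling error unknown: mean SE {mean_sampling_error} used")
        obs.add_component("nonsampling_default")
        if not d.national_probability_sample:
            obs.add_component("non_probability")
            obs.note("not a national probability sample: added error term")
        if recall_flag and plan["role"] == "all_women":
            obs.recall_bias_flag = True
            obs.note(
                "recall period over a year without microdata: response-bias "
                "model flag"
            )
        out.append(obs)
    return out
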
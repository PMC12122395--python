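"""Rule-based classification of antibiotic exposure into full / partial / none.

A *full* course is any of:

a. antibiotics administered on at least four distinct calendar days within
   some five-consecutive-calendar-day window during the stay;
b. a discharge prescription of at least a four-day antibiotic course;
c. a discharge prescription continuing the inpatient regimen, with distinct
   inpatient antibiotic calendar days plus days supplied totalling at least
   four.

Any antibiotic exposure failing all three rules is *partial*; no antibiotic
exposure at all is *none*. The binary analysis outcome is full vs not-full.

``classify_course`` is the production implementation (sorted distinct days
with a four-day-span check); ``oracle_classify`` re-implements the same
contract by exhaustively enumerating every five-day window between the first
and last stay date, and exists so tests can cross-check the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CourseDecision",
    "ValidationError",
    "classify_course",
    "oracle_classify",
    "classify_cohort",
]

CATEGORY_ORDER = {"none": 0, "partial": 1, "full": 2}


class ValidationError(ValueError):
    """Medication events fall outside the encounter's stay interval."""


@dataclass(frozen=True)
class CourseDecision:
    """Classifier output for one encounter."""

    encounter_id: object
    category: str  # full | partial | none
    rule_fired: str  # a | b | c | not_full
    outcome_full: bool


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "is_antibiotic": pd.Series(dtype=bool),
            "admin_time": pd.Series(dtype="datetime64[ns]"),
        }
    )


def _empty_rx() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "is_antibiotic": pd.Series(dtype=bool),
            "days_supplied": pd.Series(dtype=int),
            "continues_inpatient_regimen": pd.Series(dtype=bool),
        }
    )


def _normalize_events(admin_events) -> pd.DataFrame:
    if admin_events is None:
        return _empty_events()
    if not isinstance(admin_events, pd.DataFrame):
        admin_events = pd.DataFrame(list(admin_events))
    if admin_events.empty:
        return _empty_events()
    out = admin_events.copy()
    out["admin_time"] = pd.to_datetime(out["admin_time"])
    out["is_antibiotic"] = out["is_antibiotic"].astype(bool)
    return out


def _normalize_rx(prescriptions) -> pd.DataFrame:
    if prescriptions is None:
        return _empty_rx()
    if not isinstance(prescriptions, pd.DataFrame):
        prescriptions = pd.DataFrame(list(prescriptions))
    if prescriptions.empty:
        return _empty_rx()
    out = prescriptions.copy()
    out["is_antibiotic"] = out["is_antibiotic"].astype(bool)
    out["continues_inpatient_regimen"] = out["continues_inpatient_regimen"].astype(bool)
    out["days_supplied"] = out["days_supplied"].astype(int)
    return out


def _validate_interval(events: pd.DataFrame, stay, encounter_id) -> None:
    if events.empty or stay is None:
        return
    admit, discharge = pd.Timestamp(stay[0]), pd.Timestamp(stay[1])
    bad = (events["admin_time"] < admit) | (events["admin_time"] > discharge)
    if bad.any():
        ids = list(events.index[bad])
        raise ValidationError(
            f"encounter {encounter_id}: administration events outside the "
            f"stay interval at rows {ids}"
        )


def _abx_day_ordinals(events: pd.DataFrame) -> np.ndarray:
    """Sorted distinct calendar days (as ordinals) with antibiotic doses.

    A calendar day is the civil date of the administration timestamp, taken
    as-is (no timezone conversion); multiple doses on one day count once.
    """
    abx = events[events["is_antibiotic"]]
    if abx.empty:
        return np.array([], dtype=int)
    days = abx["admin_time"].dt.normalize().map(pd.Timestamp.toordinal)
    return np.unique(days.to_numpy())


def _decide(
    days: np.ndarray, rx: pd.DataFrame, encounter_id, rule_a_full: bool
) -> CourseDecision:
    abx_rx = rx[rx["is_antibiotic"]]
    if rule_a_full:
        rule = "a"
    elif (abx_rx["days_supplied"] >= 4).any():
        rule = "b"
    elif (
        abx_rx["continues_inpatient_regimen"]
        & (abx_rx["days_supplied"] + len(days) >= 4)
    ).any():
        rule = "c"
    else:
        rule = "not_full"
    if rule != "not_full":
        category = "full"
    elif len(days) or len(abx_rx):
        category = "partial"
    else:
        category = "none"
    return CourseDecision(encounter_id, category, rule, category == "full")


def classify_course(
    admin_events,
    prescriptions,
    stay=None,
    encounter_id=None,
) -> CourseDecision:
    """Classify one encounter's antibiotic exposure.

    ``admin_events`` / ``prescriptions`` are DataFrames (or iterables of
    mappings) with the pipeline schemas; ``stay`` is an optional
    ``(admit_time, discharge_time)`` pair used to validate that every event
    lies inside the stay.

    Rule (a) check: with sorted distinct antibiotic day ordinals ``d``, some
    five-day window holds four antibiotic days iff ``d[i+3] - d[i] <= 4``
    for some ``i``.
    """
    events = _normalize_events(admin_events)
    rx = _normalize_rx(prescriptions)
    _validate_interval(events, stay, encounter_id)
    days = _abx_day_ordinals(events)
    rule_a = bool(len(days) >= 4 and (days[3:] - days[:-3] <= 4).any())
    return _decide(days, rx, encounter_id, rule_a)


def oracle_classify(
    admin_events,
    prescriptions,
    stay=None,
    encounter_id=None,
) -> CourseDecision:
    """Same contract as :func:`classify_course`, by exhaustive enumeration.

    Every window of five consecutive calendar days starting between the
    first and last relevant date is examined and the distinct antibiotic
    days inside it counted — no sliding-window shortcut.
    """
    events = _normalize_events(admin_events)
    rx = _normalize_rx(prescriptions)
    _validate_interval(events, stay, encounter_id)
    days = _abx_day_ordinals(events)
    if stay is not None:
        lo = pd.Timestamp(stay[0]).normalize().toordinal()
        hi = pd.Timestamp(stay[1]).normalize().toordinal()
    elif len(days):
        lo, hi = int(days.min()), int(days.max())
    else:
        lo, hi = 0, -1
    day_set = set(int(d) for d in days)
    rule_a = False
    for start in range(lo, hi + 1):
        window = {start, start + 1, start + 2, start + 3, start + 4}
        if len(window & day_set) >= 4:
            rule_a = True
            break
    return _decide(days, rx, encounter_id, rule_a)


def classify_cohort(
    encounters: pd.DataFrame,
    administrations: pd.DataFrame,
    prescriptions: pd.DataFrame,
    *,
    validate: bool = False,
) -> pd.DataFrame:
    """Classify every encounter of a cohort; returns the decisions table
    (``encounter_id``, ``category``, ``rule_fired``, ``outcome_full``).

    Vectorized application of the same rules as :func:`classify_course`
    (tests assert their agreement). Only medication rows belonging to
    encounters present in ``encounters`` are considered. With
    ``validate=True`` every administration is checked against its
    encounter's stay interval.
    """
    ids = encounters["encounter_id"]
    id_set = set(ids)
    adm = _normalize_events(administrations if len(administrations) else None)
    rx = _normalize_rx(prescriptions if len(prescriptions) else None)
    if len(adm):
        adm = adm[administrations["encounter_id"].isin(id_set).to_numpy()]
        adm = adm.assign(
            encounter_id=administrations.loc[adm.index, "encounter_id"]
        )
    else:
        adm = adm.assign(encounter_id=pd.Series(dtype=object))
    if len(rx):
        rx = rx[prescriptions["encounter_id"].isin(id_set).to_numpy()]
        rx = rx.assign(encounter_id=prescriptions.loc[rx.index, "encounter_id"])
    else:
        rx = rx.assign(encounter_id=pd.Series(dtype=object))

    if validate and {"admit_time", "discharge_time"} <= set(encounters.columns):
        stays = encounters.set_index("encounter_id")[
            ["admit_time", "discharge_time"]
        ]
        t = adm["admin_time"]
        a = adm["encounter_id"].map(stays["admit_time"])
        d = adm["encounter_id"].map(stays["discharge_time"])
        bad = (t < a) | (t > d)
        if bad.any():
            raise ValidationError(
                "administration events outside the stay interval at rows "
                f"{list(adm.index[bad])}"
            )

    abx = adm[adm["is_antibiotic"]]
    days = pd.DataFrame(
        {
            "encounter_id": abx["encounter_id"],
            "day": abx["admin_time"].dt.normalize().map(pd.Timestamp.toordinal),
        }
    ).drop_duplicates()
    days = days.sort_values(["encounter_id", "day"], kind="mergesort")
    # rule (a): among sorted distinct days, some d[i+3] - d[i] <= 4
    d3 = days.groupby("encounter_id", sort=False)["day"].shift(-3)
    hit_a = days.loc[(d3 - days["day"]) <= 4, "encounter_id"].unique()
    n_days = days.groupby("encounter_id")["day"].size()

    abx_rx = rx[rx["is_antibiotic"]].copy()
    hit_b = abx_rx.loc[abx_rx["days_supplied"] >= 4, "encounter_id"].unique()
    inpatient_days = abx_rx["encounter_id"].map(n_days).fillna(0)
    hit_c = abx_rx.loc[
        abx_rx["continues_inpatient_regimen"]
        & (abx_rx["days_supplied"] + inpatient_days >= 4),
        "encounter_id",
    ].unique()
    any_exposure = set(days["encounter_id"]) | set(abx_rx["encounter_id"])

    rule = pd.Series("not_full", index=ids.to_numpy(), dtype=object)
    rule[rule.index.isin(hit_c)] = "c"
    rule[rule.index.isin(hit_b)] = "b"
    rule[rule.index.isin(hit_a)] = "a"
    category = np.where(
        rule != "not_full",
        "full",
        np.where(rule.index.isin(list(any_exposure)), "partial", "none"),
    )
    return pd.DataFrame(
        {
            "encounter_id": rule.index,
            "category": category,
            "rule_fired": rule.to_numpy(),
            "outcome_full": category == "full",
        }
    )
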
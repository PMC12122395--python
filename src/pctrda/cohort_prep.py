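"""Eligibility filtering and per-encounter procalcitonin selection.

Applies the study's inclusion/exclusion rules to the raw encounter and
medication tables and produces an audited analysis cohort. Each excluded row
is attributed to exactly one rule, in a fixed deterministic order, so the
audit counts are well defined and conserve the input row count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "EligibleCohort",
    "EXCLUSION_ORDER",
    "select_first_procalcitonin",
    "first_procalcitonin_by_encounter",
    "apply_exclusions",
]

log = logging.getLogger(__name__)

#: Attribution order for exclusions. The order is a reporting convention
#: (each excluded row is counted once, under the first rule that catches it).
EXCLUSION_ORDER = (
    "unparseable_timestamp",
    "age_under_18",
    "obstetrics",
    "repeat_encounter",
    "late_pct",
    "ed_discharge",
)

REQUIRED_ENCOUNTER_COLUMNS = (
    "encounter_id",
    "patient_id",
    "age",
    "loc",
    "admit_time",
    "discharge_time",
    "pct_value",
    "pct_time",
    "ed_discharge",
    "obstetrics",
)

#: PCT collected more than this long after the first antibiotic dose marks
#: de-escalation rather than initiation use; such encounters are excluded.
LATE_PCT_HOURS = 48.0


class SchemaError(ValueError):
    """Input table does not conform to the expected schema."""


@dataclass
class EligibleCohort:
    """Filtered analysis cohort plus its exclusion audit trail.

    ``audit`` lists ``(rule, count)`` in attribution order; counts conserve
    the input: ``n_raw == len(frame) + sum(counts)``.
    """

    frame: pd.DataFrame
    audit: list[tuple[str, int]] = field(default_factory=list)
    n_raw: int = 0

    @property
    def audit_dict(self) -> dict[str, int]:
        return dict(self.audit)

    def audit_json(self) -> str:
        return json.dumps(
            {"n_raw": self.n_raw, "n_eligible": int(len(self.frame)),
             "excluded": dict(self.audit)},
            indent=2,
        )


def select_first_procalcitonin(results) -> tuple[float, pd.Timestamp]:
    """Return the chronologically earliest PCT ``(value, time)`` for one
    encounter; ties on the timestamp are broken by input order.

    ``results`` is a sequence of ``(time, value)`` pairs or a DataFrame with
    ``pct_time`` / ``pct_value`` columns.
    """
    if isinstance(results, pd.DataFrame):
        if results.empty:
            raise ValueError("no procalcitonin results supplied")
        idx = results["pct_time"].reset_index(drop=True)
        pos = int(np.argmin(pd.to_datetime(idx).to_numpy()))
        row = results.iloc[pos]
        return float(row["pct_value"]), pd.Timestamp(row["pct_time"])
    pairs = [(pd.Timestamp(t), float(v)) for t, v in results]
    if not pairs:
        raise ValueError("no procalcitonin results supplied")
    best = min(range(len(pairs)), key=lambda i: (pairs[i][0], i))
    return pairs[best][1], pairs[best][0]


def first_procalcitonin_by_encounter(results: pd.DataFrame) -> pd.DataFrame:
    """Long-format PCT results -> one (value, time) row per encounter.

    Stable sort preserves input order among identical timestamps, matching
    the tie-break of :func:`select_first_procalcitonin`.
    """
    ordered = results.sort_values("pct_time", kind="mergesort")
    first = ordered.groupby("encounter_id", sort=False).head(1)
    return first[["encounter_id", "pct_value", "pct_time"]].reset_index(drop=True)


def _coerce_times(frame: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    frame = frame.copy()
    for c in cols:
        if not pd.api.types.is_datetime64_any_dtype(frame[c]):
            frame[c] = pd.to_datetime(frame[c], errors="coerce")
    return frame

def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    return s.astype(str).str.lower().isin(("true", "1", "t", "yes"))


def apply_exclusions(
    encounters: pd.DataFrame,
    administrations: pd.DataFrame | None = None,
) -> EligibleCohort:
    """Apply the eligibility rules, in fixed order, and audit each one.

    Rules (after dropping rows with unparseable timestamps, each reported
    with its row index):

    1. age < 18;
    2. obstetrics / positive pregnancy test flag;
    3. non-first encounter per patient (the chronologically first surviving
       encounter is kept; ties broken by input order);
    4. PCT collected more than 48 h (strictly) after the first antibiotic
       dose — applies only when an antibiotic dose exists;
    5. discharged directly from the ED.

    The result carries a ``first_abx_time`` annotation (NaT when no
    antibiotic was administered) and is idempotent under re-application.
    """
    missing = [c for c in REQUIRED_ENCOUNTER_COLUMNS if c not in encounters.columns]
    if missing:
        raise SchemaError(f"encounters table missing required columns: {missing}")

    enc = _coerce_times(encounters, ["admit_time", "discharge_time", "pct_time"])
    enc["ed_discharge"] = _coerce_bool(enc["ed_discharge"])
    enc["obstetrics"] = _coerce_bool(enc["obstetrics"])
    n_raw = len(enc)
    audit: dict[str, int] = {r: 0 for r in EXCLUSION_ORDER}

    bad_time = (
        enc["admit_time"].isna() | enc["discharge_time"].isna() | enc["pct_time"].isna()
    )
    if bad_time.any():
        for i in enc.index[bad_time]:
            log.warning("row %s: unparseable timestamp, excluded", i)
    audit["unparseable_timestamp"] = int(bad_time.sum())
    enc = enc[~bad_time]

    m = enc["age"] < 18
    audit["age_under_18"] = int(m.sum())
    enc = enc[~m]

    m = enc["obstetrics"]
    audit["obstetrics"] = int(m.sum())
    enc = enc[~m]

    first = enc.sort_values("admit_time", kind="mergesort").groupby(
        "patient_id", sort=False
    ).head(1)
    m = ~enc["encounter_id"].isin(first["encounter_id"])
    audit["repeat_encounter"] = int(m.sum())
    enc = enc[~m]

    if "first_abx_time" in enc.columns:
        first_abx = enc.set_index("encounter_id")["first_abx_time"]
        first_abx = pd.to_datetime(first_abx, errors="coerce")
    elif administrations is not None and len(administrations):
        adm = _coerce_times(administrations, ["admin_time"])
        adm = adm[_coerce_bool(adm["is_antibiotic"])]
        first_abx = adm.groupby("encounter_id")["admin_time"].min()
    else:
        first_abx = pd.Series(pd.NaT, index=pd.Index([], name="encounter_id"))
    fa = enc["encounter_id"].map(first_abx)
    late = fa.notna() & (
        enc["pct_time"] > fa + pd.Timedelta(hours=LATE_PCT_HOURS)
    )
    audit["late_pct"] = int(late.sum())
    enc = enc[~late]
    fa = fa[~late]

    m = enc["ed_discharge"]
    audit["ed_discharge"] = int(m.sum())
    enc = enc[~m]
    fa = fa[~m]

    out = enc.copy()
    out["first_abx_time"] = fa.to_numpy()
    ordered = [(r, audit[r]) for r in EXCLUSION_ORDER]
    for rule, count in ordered:
        log.info("exclusion %-22s %6d", rule, count)
    assert n_raw == len(out) + sum(audit.values())
    return EligibleCohort(frame=out.reset_index(drop=True), audit=ordered, n_raw=n_raw)
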
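"""Synthetic EHR cohort generator for procalcitonin-guided prescribing analyses.

Real encounter-level data behind this kind of study live in institutional
warehouses and are not shareable, so every downstream stage of the pipeline
is exercised against a generator that emulates the statistical structure the
analysis assumes:

* a right-skewed serum procalcitonin (PCT) distribution, modelled as a
  lognormal mixture whose shipped defaults were calibrated against published
  cohort anchors (conditional medians 0.29 / 0.08 ng/mL, ~69% full-course
  rate, decision AUC ~0.72);
* a provider prescribing policy mapping PCT to the probability of a *full*
  antibiotic course — smooth in log-PCT ("continuous" interpretation), a
  step at a cut-point ("dichotomous" interpretation), or a mixture of the
  two provider types;
* medication administration and discharge-prescription records realized so
  that the rule-based course classifier provably recovers the latent
  decision (round-trip guarantee);
* optional injection of the study's exclusion categories (late PCT relative
  to the first antibiotic dose, ED discharge, obstetrics, repeat encounter)
  so the eligibility filter can be audited against known truth.

All randomness flows through one :class:`numpy.random.Generator` seeded from
``GeneratorConfig.seed``; identical configs yield byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "ConfigError",
    "GenerationError",
    "PolicyModel",
    "GeneratorConfig",
    "decision_probability",
    "sample_procalcitonin",
    "realize_treatment_records",
    "generate_cohort",
    "CohortTables",
    "STRATA",
    "EXCLUSION_CATEGORIES",
    "DEFAULT_PCT_MIXTURE",
    "DEFAULT_POLICY",
]

STRATA = ("floor", "stepdown", "icu")
#: Injection categories, in the order used by ``exclusion_rates``.
EXCLUSION_CATEGORIES = ("late_pct", "ed_discharge", "obstetrics", "repeat_encounter")

EPOCH = pd.Timestamp("2018-01-01 00:00:00")

# Two-component lognormal mixture for PCT (ng/mL), calibrated by numerical
# integration against published cohort anchors (see docs/methods.md):
# conditional medians 0.29 / 0.08, IQRs 0.1-1.24 / 0.04-0.19, fraction
# above 0.5 ng/mL 39.1% / 10.2%, marginal full-course rate 68.9%, AUC 0.725.
DEFAULT_PCT_MIXTURE = (
    (0.4395, -0.0766, 1.4642),
    (0.5605, -2.4883, 0.9498),
)


class ConfigError(ValueError):
    """Invalid generator configuration."""


class GenerationError(RuntimeError):
    """A requested record pattern cannot be realized for an encounter."""


@dataclass(frozen=True)
class PolicyModel:
    """Provider prescribing policy: P(full course | PCT).

    ``continuous`` providers follow a logistic curve in ln(PCT);
    ``step`` providers add ``jump`` log-odds once PCT reaches
    ``step_location``; a ``mixture`` blends the two provider types on the
    probability scale with ``mixture_weight`` of threshold providers.
    """

    kind: str = "continuous"
    intercept: float = 0.0
    slope: float = 0.0
    jump: float = 0.0
    step_location: float = 0.25
    mixture_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "step", "mixture"):
            raise ConfigError(f"unknown policy kind: {self.kind!r}")
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ConfigError("mixture_weight must be in [0, 1]")
        if self.step_location <= 0:
            raise ConfigError("step_location must be positive")


#: Calibrated default: a purely continuous interpretation of PCT.
DEFAULT_POLICY = PolicyModel(kind="continuous", intercept=1.8293, slope=0.5936)


def decision_probability(
    policy: PolicyModel,
    pct: float | np.ndarray,
    *,
    floor: float = 0.02,
) -> float | np.ndarray:
    """Probability of a full antibiotic course at PCT level ``pct`` (ng/mL).

    ``pct`` is clamped below at ``floor`` before taking logs so that
    assay-floor values (0 is reported by some labs) do not produce
    infinite log-odds.
    """
    x = np.log(np.maximum(np.asarray(pct, dtype=float), floor))
    above = np.asarray(pct, dtype=float) >= policy.step_location
    p_cont = expit(policy.intercept + policy.slope * x)
    if policy.kind == "continuous":
        out = p_cont
    else:
        p_step = expit(policy.intercept + policy.slope * x + policy.jump * above)
        if policy.kind == "step":
            out = p_step
        else:
            w = policy.mixture_weight
            out = w * p_step + (1.0 - w) * p_cont
    return float(out) if np.ndim(pct) == 0 else out


def _as_policy_map(policy) -> dict[str, PolicyModel]:
    if isinstance(policy, PolicyModel):
        return {s: policy for s in STRATA}
    pm = dict(policy)
    missing = [s for s in STRATA if s not in pm]
    if missing:
        raise ConfigError(f"policy missing strata: {missing}")
    return pm


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    n_encounters:
        Number of encounters to draw (before any eligibility filtering).
    seed:
        Mandatory RNG seed; the generator is fully deterministic given it.
    pct_mixture:
        Lognormal mixture components ``(weight, log_mean, log_sd)`` for the
        marginal PCT distribution in ng/mL.
    loc_probs:
        Marginal probabilities of the highest level of care, keys
        ``floor`` / ``stepdown`` / ``icu``.
    policy:
        A single :class:`PolicyModel` applied to every stratum, or a mapping
        stratum -> policy.
    reporting_decimals:
        Lab reporting precision; sampled PCT values are rounded to this many
        decimals before the policy sees them (default 2, matching
        0.01-ng/mL-binned lab reports).
    exclusion_rates:
        Probability that an encounter is injected with each exclusion
        category (keys from :data:`EXCLUSION_CATEGORIES`); categories are
        mutually exclusive per encounter and their rates must sum to <= 1.
    partial_ratio:
        Among encounters whose latent decision is not *full*, probability of
        *partial* (vs *none*); the analysis pools the two, so this only
        exercises the classifier.
    los_log_median_days / los_log_sd:
        Lognormal length of stay (default median 5 days).
    pct_floor:
        Clamp applied before ln(PCT) in the policy.
    """

    n_encounters: int
    seed: int
    pct_mixture: Sequence[tuple[float, float, float]] = DEFAULT_PCT_MIXTURE
    loc_probs: Mapping[str, float] = field(
        default_factory=lambda: {"floor": 0.50, "stepdown": 0.17, "icu": 0.33}
    )
    policy: PolicyModel | Mapping[str, PolicyModel] = DEFAULT_POLICY
    reporting_decimals: int = 2
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "late_pct": 0.12,
            "ed_discharge": 0.10,
            "obstetrics": 0.04,
            "repeat_encounter": 0.05,
        }
    )
    partial_ratio: float = 0.5
    los_log_median_days: float = 5.0
    los_log_sd: float = 0.5
    pct_floor: float = 0.02

    def __post_init__(self) -> None:
        if self.n_encounters < 0:
            raise ConfigError("n_encounters must be non-negative")
        w = np.array([c[0] for c in self.pct_mixture], dtype=float)
        if len(w) == 0 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
            raise ConfigError("pct_mixture weights must be non-negative and sum to 1")
        lp = np.array([self.loc_probs.get(s, 0.0) for s in STRATA], dtype=float)
        if (lp < 0).any() or abs(lp.sum() - 1.0) > 1e-8:
            raise ConfigError("loc_probs must cover floor/stepdown/icu and sum to 1")
        er = {k: float(self.exclusion_rates.get(k, 0.0)) for k in EXCLUSION_CATEGORIES}
        if any(not 0.0 <= v <= 1.0 for v in er.values()) or sum(er.values()) > 1.0:
            raise ConfigError("exclusion_rates must be in [0,1] and sum to <= 1")
        if self.reporting_decimals < 0:
            raise ConfigError("reporting_decimals must be non-negative")
        if not 0.0 <= self.partial_ratio <= 1.0:
            raise ConfigError("partial_ratio must be in [0, 1]")
        self.policy_map = _as_policy_map(self.policy)

    def exclusion_rate_vector(self) -> np.ndarray:
        return np.array(
            [float(self.exclusion_rates.get(k, 0.0)) for k in EXCLUSION_CATEGORIES]
        )


class CohortTables(NamedTuple):
    encounters: pd.DataFrame
    administrations: pd.DataFrame
    prescriptions: pd.DataFrame
    truth: pd.DataFrame


def sample_procalcitonin(
    config: GeneratorConfig,
    count: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``count`` PCT values (ng/mL) from the configured lognormal mixture.

    Values are rounded to ``config.reporting_decimals`` (round-half-to-even,
    as numpy rounds), emulating lab reporting precision.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    comps = np.asarray(config.pct_mixture, dtype=float)
    idx = rng.choice(len(comps), size=count, p=comps[:, 0])
    draws = rng.normal(comps[idx, 1], comps[idx, 2])
    return np.round(np.exp(draws), config.reporting_decimals)


# ---------------------------------------------------------------------------
# record realization


def _day_times(
    dates: Iterable[pd.Timestamp],
    admit: pd.Timestamp,
    discharge: pd.Timestamp,
    rng: np.random.Generator,
) -> list[pd.Timestamp]:
    """One timestamp per calendar day, clamped inside [admit, discharge]."""
    out = []
    for d in dates:
        t = d + pd.Timedelta(minutes=int(rng.integers(0, 24 * 60)))
        t = max(min(t, discharge), admit)
        out.append(t)
    return out


def _stay_dates(admit: pd.Timestamp, discharge: pd.Timestamp) -> pd.DatetimeIndex:
    return pd.date_range(admit.normalize(), discharge.normalize(), freq="D")


def realize_treatment_records(
    encounter: Mapping,
    decision: str,
    rng: np.random.Generator,
    *,
    allowed_rules: Sequence[str] = ("a", "b", "c"),
    require_admin: bool = False,
) -> tuple[list[dict], list[dict], str]:
    """Emit administration events and discharge prescriptions realizing
    ``decision`` for one encounter.

    The emitted records are constructed so the rule-based course classifier
    recovers exactly ``decision``:

    * ``full`` — realized through one qualifying pattern chosen uniformly
      among the feasible course rules: (a) >=4 distinct antibiotic calendar
      days inside a 5-day window, (b) a discharge prescription of >=4 days,
      (c) inpatient days plus a continuation prescription totalling >=4;
    * ``partial`` — at least one antibiotic administration but <=3 distinct
      antibiotic days and no qualifying prescription;
    * ``none`` — no antibiotic records at all.

    Non-antibiotic administrations/prescriptions are sprinkled in regardless
    of the decision, so classifiers must actually filter on the antibiotic
    flag. Returns ``(admin_events, prescriptions, realized_rule)`` where
    ``realized_rule`` is ``a``/``b``/``c`` for full courses and ``""``
    otherwise.

    Raises
    ------
    GenerationError
        If no allowed rule is feasible for the stay (e.g. rule (a) requested
        alone for a stay spanning fewer than four calendar days).
    """
    admit = pd.Timestamp(encounter["admit_time"])
    discharge = pd.Timestamp(encounter["discharge_time"])
    enc_id = encounter["encounter_id"]
    if discharge <= admit:
        raise GenerationError(f"{enc_id}: discharge not after admission")
    dates = _stay_dates(admit, discharge)
    span = len(dates)

    admins: list[dict] = []
    rxs: list[dict] = []
    rule = ""

    def add_admin(times: Iterable[pd.Timestamp], is_abx: bool) -> None:
        for t in times:
            admins.append(
                {"encounter_id": enc_id, "is_antibiotic": is_abx, "admin_time": t}
            )

    def add_rx(is_abx: bool, days: int, continues: bool) -> None:
        rxs.append(
            {
                "encounter_id": enc_id,
                "is_antibiotic": is_abx,
                "days_supplied": int(days),
                "continues_inpatient_regimen": bool(continues),
            }
        )

    if decision == "full":
        feasible = [
            r
            for r in allowed_rules
            if r in ("b", "c") or (r == "a" and span >= 4)
        ]
        if require_admin and "b" in feasible and span < 1:
            feasible.remove("b")
        if not feasible:
            raise GenerationError(
                f"{enc_id}: no feasible full-course pattern for a "
                f"{span}-calendar-day stay (allowed {list(allowed_rules)})"
            )
        rule = str(rng.choice(feasible))
        if rule == "a":
            base = int(rng.integers(0, span - 3))
            chosen = list(dates[base : base + 4])
            if span > base + 4 and rng.random() < 0.3:  # optional 5th day
                chosen.append(dates[base + 4])
            add_admin(_day_times(chosen, admit, discharge, rng), True)
        elif rule == "b":
            n_inpatient = int(rng.integers(1 if require_admin else 0, min(3, span) + 1))
            if n_inpatient:
                picked = rng.choice(span, size=n_inpatient, replace=False)
                add_admin(
                    _day_times(dates[np.sort(picked)], admit, discharge, rng), True
                )
            add_rx(True, int(rng.integers(4, 11)), False)
        else:  # rule c: continuation totalling >= 4 days
            k = int(rng.integers(1, min(3, span) + 1))
            picked = rng.choice(span, size=k, replace=False)
            add_admin(_day_times(dates[np.sort(picked)], admit, discharge, rng), True)
            # keep days_supplied < 4 so rule (b) cannot pre-empt rule (c)
            add_rx(True, int(rng.integers(max(4 - k, 1), 4)), True)
    elif decision == "partial":
        j = int(rng.integers(1, min(3, span) + 1))
        picked = rng.choice(span, size=j, replace=False)
        add_admin(_day_times(dates[np.sort(picked)], admit, discharge, rng), True)
        if rng.random() < 0.3:
            # short, non-continuation script: fails rules (b) and (c)
            add_rx(True, int(rng.integers(1, 4)), False)
    elif decision != "none":
        raise GenerationError(f"unknown decision {decision!r}")

    # non-antibiotic noise records
    if rng.random() < 0.3:
        t = admit + (discharge - admit) * rng.random()
        add_admin([t.floor("min")], False)
    if rng.random() < 0.2:
        add_rx(False, int(rng.integers(1, 15)), False)
    return admins, rxs, rule


# ---------------------------------------------------------------------------
# cohort assembly


def sample_latent_cohort(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Vectorized draw of the latent per-encounter state (no records).

    Columns: pct_value, loc, policy_probability, decision. Used by
    :func:`generate_cohort` and directly by simulation studies that do not
    need medication records.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_encounters
    pct = sample_procalcitonin(config, n, rng)
    loc_p = np.array([config.loc_probs.get(s, 0.0) for s in STRATA])
    loc = rng.choice(STRATA, size=n, p=loc_p)
    prob = np.empty(n)
    for s in STRATA:
        m = loc == s
        if m.any():
            prob[m] = decision_probability(
                config.policy_map[s], pct[m], floor=config.pct_floor
            )
    full = rng.random(n) < prob
    partial = rng.random(n) < config.partial_ratio
    decision = np.where(full, "full", np.where(partial, "partial", "none"))
    return pd.DataFrame(
        {
            "pct_value": pct,
            "loc": loc,
            "policy_probability": prob,
            "decision": decision,
        }
    )


def generate_cohort(config: GeneratorConfig) -> CohortTables:
    """Generate the four pipeline input tables.

    Returns encounters / administrations / prescriptions tables conforming to
    the pipeline's CSV schemas, plus a truth table holding the latent
    decision, stratum, policy probability, realized course rule, and the
    injected exclusion category of every encounter (for test assertions; the
    truth table is never an input to the analysis stages).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_encounters
    latent = sample_latent_cohort(config, rng)

    age = np.clip(np.round(rng.normal(61.4, 16.4, n)), 18, 100).astype(int)
    sex = rng.choice(["female", "male"], size=n, p=[0.425, 0.575])
    race = rng.choice(["white", "black", "other"], size=n, p=[0.627, 0.16, 0.213])
    diagnosis = rng.choice(
        ["noninfectious", "sepsis", "lrti", "uti", "ssti", "other_infection"],
        size=n,
        p=[0.63, 0.19, 0.07, 0.05, 0.03, 0.03],
    )
    disposition = rng.choice(
        ["home", "rehab", "died", "other"], size=n, p=[0.66, 0.18, 0.07, 0.09]
    )

    admit_min = rng.integers(0, 730 * 24 * 60, size=n)
    los_days = rng.lognormal(np.log(config.los_log_median_days), config.los_log_sd, n)
    los_min = np.maximum((los_days * 24 * 60).astype(int), 6 * 60)
    pct_frac = rng.random(n)

    rates = config.exclusion_rate_vector()
    probs = np.append(rates, 1.0 - rates.sum())
    cat_idx = rng.choice(len(probs), size=n, p=probs)
    injected = np.array(list(EXCLUSION_CATEGORIES) + ["none"], dtype=object)[cat_idx]

    admit = EPOCH + pd.to_timedelta(admit_min, unit="m")
    discharge = admit + pd.to_timedelta(los_min, unit="m")
    # PCT drawn early in the stay (within the first day, inside the stay)
    pct_offset = np.minimum(pct_frac * 24 * 60, pct_frac * los_min).astype(int)
    pct_time = admit + pd.to_timedelta(pct_offset, unit="m")

    decision = latent["decision"].to_numpy(copy=True)
    # late-PCT injection needs an antibiotic dose on record: promote none->partial
    late = injected == "late_pct"
    decision[late & (decision == "none")] = "partial"

    # repeat encounters re-use the patient of a clean host and start later
    enc_ids = np.array([f"E{i:06d}" for i in range(n)], dtype=object)
    pat_ids = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    host_pool = np.flatnonzero(injected == "none")
    repeat_idx = np.flatnonzero(injected == "repeat_encounter")
    if len(host_pool) == 0 and len(repeat_idx) > 0:
        injected[repeat_idx] = "none"  # degenerate tiny-n case
        repeat_idx = np.array([], dtype=int)
    admit = pd.Series(admit)
    discharge = pd.Series(discharge)
    pct_time = pd.Series(pct_time)
    for i in repeat_idx:
        host = int(host_pool[rng.integers(0, len(host_pool))])
        pat_ids[i] = pat_ids[host]
        gap = pd.Timedelta(minutes=int(rng.integers(24 * 60, 90 * 24 * 60)))
        shift = (discharge[host] + gap) - admit[i]
        admit[i] += shift
        discharge[i] += shift
        pct_time[i] += shift

    sex = sex.astype(object)
    sex[injected == "obstetrics"] = "female"

    all_admins: list[dict] = []
    all_rxs: list[dict] = []
    realized_rule = np.full(n, "", dtype=object)
    for i in range(n):
        enc = {
            "encounter_id": enc_ids[i],
            "admit_time": admit[i],
            "discharge_time": discharge[i],
        }
        force_admin = injected[i] == "late_pct"
        admins, rxs, rule = realize_treatment_records(
            enc, decision[i], rng, require_admin=force_admin
        )
        if force_admin:
            abx_times = [a["admin_time"] for a in admins if a["is_antibiotic"]]
            first_dose = min(abx_times)
            pct_time[i] = (
                first_dose
                + pd.Timedelta(hours=48)
                + pd.Timedelta(minutes=int(rng.integers(30, 24 * 60)))
            )
        all_admins.extend(admins)
        all_rxs.extend(rxs)
        realized_rule[i] = rule

    encounters = pd.DataFrame(
        {
            "encounter_id": enc_ids,
            "patient_id": pat_ids,
            "age": age,
            "sex": sex,
            "race": race,
            "loc": latent["loc"],
            "admit_time": admit,
            "discharge_time": discharge,
            "pct_value": latent["pct_value"],
            "pct_time": pct_time,
            "disposition": disposition,
            "diagnosis_label": diagnosis,
            "ed_discharge": injected == "ed_discharge",
            "obstetrics": injected == "obstetrics",
        }
    )
    administrations = pd.DataFrame(
        all_admins, columns=["encounter_id", "is_antibiotic", "admin_time"]
    )
    prescriptions = pd.DataFrame(
        all_rxs,
        columns=[
            "encounter_id",
            "is_antibiotic",
            "days_supplied",
            "continues_inpatient_regimen",
        ],
    )
    truth = pd.DataFrame(
        {
            "encounter_id": enc_ids,
            "decision": decision,
            "stratum": latent["loc"],
            "policy_probability": latent["policy_probability"],
            "realized_rule": realized_rule,
            "injected_exclusion": injected,
        }
    )
    return CohortTables(encounters, administrations, prescriptions, truth)
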
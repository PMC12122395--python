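"""Generator: policy curves, PCT sampling, record realization, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, logit

from pctrda.cohort_prep import apply_exclusions
from pctrda.synthetic_cohort import (
    ConfigError,
    DEFAULT_POLICY,
    EXCLUSION_CATEGORIES,
    GenerationError,
    GeneratorConfig,
    PolicyModel,
    decision_probability,
    generate_cohort,
    realize_treatment_records,
    sample_procalcitonin,
)

STEP = PolicyModel(
    kind="step", intercept=logit(0.3), slope=0.0,
    jump=logit(0.6) - logit(0.3), step_location=0.25,
)


class TestDecisionProbability:
    @pytest.mark.parametrize(
        "policy, pct, expected",
        [
            (PolicyModel(kind="continuous"), 0.17, 0.5),  # flat policy
            (PolicyModel(kind="continuous"), 42.0, 0.5),
            (STEP, 0.24, 0.30),
            (STEP, 0.25, 0.60),
            # half threshold-providers, half flat-0.5 providers at the step
            (
                PolicyModel(kind="mixture", intercept=0.0, slope=0.0,
                            jump=logit(0.6), step_location=0.25,
                            mixture_weight=0.5),
                0.25,
                0.5 * 0.6 + 0.5 * 0.5,
            ),
        ],
    )
    def test_known_values(self, policy, pct, expected):
        assert decision_probability(policy, pct) == pytest.approx(expected)

    def test_step_with_zero_jump_reduces_to_continuous(self):
        cont = PolicyModel(kind="continuous", intercept=0.4, slope=0.8)
        step = PolicyModel(kind="step", intercept=0.4, slope=0.8, jump=0.0)
        x = np.linspace(0.01, 3.0, 50)
        np.testing.assert_allclose(
            decision_probability(cont, x), decision_probability(step, x)
        )

    def test_floor_clamps_zero_pct(self):
        p = decision_probability(DEFAULT_POLICY, 0.0, floor=0.02)
        assert p == pytest.approx(
            expit(DEFAULT_POLICY.intercept + DEFAULT_POLICY.slope * np.log(0.02))
        )

    @given(
        intercept=st.floats(-4, 4),
        slope=st.floats(0, 3),
        jump=st.floats(0, 3),
        w=st.floats(0, 1),
        pcts=st.tuples(st.floats(0.01, 50), st.floats(0.01, 50)),
    )
    def test_monotone_and_bounded(self, intercept, slope, jump, w, pcts):
        """Non-negative slope and jump imply a non-decreasing policy, and the
        output is always a probability."""
        pol = PolicyModel(kind="mixture", intercept=intercept, slope=slope,
                          jump=jump, step_location=0.25, mixture_weight=w)
        lo, hi = sorted(pcts)
        p_lo, p_hi = decision_probability(pol, lo), decision_probability(pol, hi)
        assert 0.0 <= p_lo <= 1.0 and 0.0 <= p_hi <= 1.0
        assert p_lo <= p_hi + 1e-12


class TestConfigValidation:
    def test_bad_mixture_weights(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_encounters=10, seed=0,
                            pct_mixture=[(0.5, 0.0, 1.0), (0.6, -2.0, 1.0)])

    def test_bad_loc_probs(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_encounters=10, seed=0,
                            loc_probs={"floor": 0.9, "stepdown": 0.3, "icu": 0.1})

    def test_bad_exclusion_rates(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(n_encounters=10, seed=0,
                            exclusion_rates={"late_pct": 1.4})

    def test_unknown_policy_kind(self):
        with pytest.raises(ConfigError):
            PolicyModel(kind="quadratic")


class TestSampleProcalcitonin:
    def test_single_component_median(self):
        cfg = GeneratorConfig(
            n_encounters=1, seed=3, pct_mixture=[(1.0, np.log(0.08), 0.7)]
        )
        draws = sample_procalcitonin(cfg, 200_000)
        assert np.median(draws) == pytest.approx(0.08, rel=0.05)

    def test_reporting_precision(self):
        cfg = GeneratorConfig(n_encounters=1, seed=3, reporting_decimals=2)
        draws = sample_procalcitonin(cfg, 10_000)
        np.testing.assert_allclose(draws, np.round(draws, 2))
        assert (draws >= 0).all()

    def test_default_calibration_subgroup_medians(self):
        """Under the shipped defaults, the latent full-course subgroup has
        median PCT ~0.29 ng/mL and the rest ~0.08 ng/mL (within 10%)."""
        rng = np.random.default_rng(99)
        cfg = GeneratorConfig(n_encounters=1, seed=99)
        pct = sample_procalcitonin(cfg, 1_000_000, rng)
        p = decision_probability(DEFAULT_POLICY, pct, floor=cfg.pct_floor)
        full = rng.random(len(pct)) < p
        assert np.median(pct[full]) == pytest.approx(0.29, rel=0.10)
        assert np.median(pct[~full]) == pytest.approx(0.08, rel=0.10)


class TestRealizeTreatmentRecords:
    def enc(self, days):
        admit = pd.Timestamp("2018-05-02 09:30")
        return {
            "encounter_id": "E1",
            "admit_time": admit,
            "discharge_time": admit + pd.Timedelta(days=days - 1, hours=8),
        }

    def test_none_emits_no_antibiotics(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            adm, rx, rule = realize_treatment_records(self.enc(5), "none", rng)
            assert not any(a["is_antibiotic"] for a in adm)
            assert not any(r["is_antibiotic"] for r in rx)
            assert rule == ""

    def test_full_rule_a_has_four_days_in_window(self):
        rng = np.random.default_rng(1)
        adm, _, rule = realize_treatment_records(
            self.enc(10), "full", rng, allowed_rules=("a",)
        )
        assert rule == "a"
        days = sorted(
            {pd.Timestamp(a["admin_time"]).normalize() for a in adm
             if a["is_antibiotic"]}
        )
        spans = [
            (days[i + 3] - days[i]).days for i in range(len(days) - 3)
        ]
        assert any(s <= 4 for s in spans)

    def test_infeasible_rule_raises(self):
        rng = np.random.default_rng(2)
        with pytest.raises(GenerationError):
            realize_treatment_records(
                self.enc(2), "full", rng, allowed_rules=("a",)
            )

    def test_events_stay_inside_interval(self):
        rng = np.random.default_rng(3)
        e = self.enc(6)
        for decision in ("full", "partial"):
            for _ in range(100):
                adm, _, _ = realize_treatment_records(e, decision, rng)
                for a in adm:
                    assert e["admit_time"] <= a["admin_time"] <= e["discharge_time"]


class TestGenerateCohort:
    def test_empty_cohort_has_headers(self):
        tabs = generate_cohort(GeneratorConfig(n_encounters=0, seed=5))
        for df in tabs:
            assert len(df) == 0 and len(df.columns) > 0

    def test_no_exclusions_all_eligible(self, clean_cohort):
        _, tabs = clean_cohort
        cohort = apply_exclusions(tabs.encounters, tabs.administrations)
        assert len(cohort.frame) == len(tabs.encounters)
        assert all(n == 0 for _, n in cohort.audit)

    def test_injected_exclusion_counts_binomial(self):
        from scipy import stats
        from conftest import SEED

        rates = dict(zip(EXCLUSION_CATEGORIES, (0.1, 0.1, 0.05, 0.05)))
        n = 10_000
        tabs = generate_cohort(
            GeneratorConfig(n_encounters=n, seed=SEED, exclusion_rates=rates)
        )
        counts = tabs.truth["injected_exclusion"].value_counts()
        for cat, rate in rates.items():
            sd = np.sqrt(n * rate * (1 - rate))
            assert abs(counts.get(cat, 0) - n * rate) < 3 * sd
        observed = [counts.get(c, 0) for c in EXCLUSION_CATEGORIES]
        expected = [n * r for r in rates.values()]
        observed.append(n - sum(observed))
        expected.append(n - sum(expected))
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_seed_determinism_byte_identical(self):
        cfg = dict(n_encounters=400, seed=123)
        t1 = generate_cohort(GeneratorConfig(**cfg))
        t2 = generate_cohort(GeneratorConfig(**cfg))
        for a, b in zip(t1, t2):
            assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_type_invariants(self, default_cohort):
        cfg, tabs = default_cohort
        enc = tabs.encounters
        assert (enc["admit_time"] < enc["discharge_time"]).all()
        assert (enc["pct_value"] >= 0).all()
        np.testing.assert_allclose(
            enc["pct_value"], enc["pct_value"].round(cfg.reporting_decimals)
        )
        assert (enc["age"] >= 18).all()
        assert set(enc["loc"]) <= {"floor", "stepdown", "icu"}
        # administration events inside their encounter's stay
        stays = enc.set_index("encounter_id")
        adm = tabs.administrations
        a = adm["encounter_id"].map(stays["admit_time"])
        d = adm["encounter_id"].map(stays["discharge_time"])
        assert ((adm["admin_time"] >= a) & (adm["admin_time"] <= d)).all()
        assert (tabs.prescriptions["days_supplied"] >= 0).all()

    def test_marginal_full_rate_in_plausibility_band(self, default_cohort):
        """Eligible-encounter full-course fraction brackets the published
        cohort composition (not a reproduction)."""
        _, tabs = default_cohort
        cohort = apply_exclusions(tabs.encounters, tabs.administrations)
        truth = tabs.truth.set_index("encounter_id")
        lat = truth.loc[cohort.frame["encounter_id"], "decision"]
        assert 0.60 <= (lat == "full").mean() <= 0.78
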
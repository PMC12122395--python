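import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pctrda.synthetic_cohort import GeneratorConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

SEED = 20180101


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort under the shipped default configuration,
    shared across tests that only read it."""
    cfg = GeneratorConfig(n_encounters=10_000, seed=SEED)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with no injected exclusions: everything is eligible."""
    cfg = GeneratorConfig(
        n_encounters=3_000,
        seed=SEED + 1,
        exclusion_rates={k: 0.0 for k in ("late_pct", "ed_discharge",
                                          "obstetrics", "repeat_encounter")},
    )
    return cfg, generate_cohort(cfg)


def stay_frame(n_days: int, admit_hour: int = 8) -> tuple[pd.Timestamp, pd.Timestamp]:
    admit = pd.Timestamp("2018-03-01") + pd.Timedelta(hours=admit_hour)
    return admit, admit + pd.Timedelta(days=n_days - 1, hours=10)


def events_on_days(day_numbers, is_antibiotic=True, hour=12):
    """Administration events on 1-based calendar day numbers of a stay
    starting 2018-03-01."""
    base = pd.Timestamp("2018-03-01")
    return pd.DataFrame(
        {
            "is_antibiotic": is_antibiotic,
            "admin_time": [
                base + pd.Timedelta(days=d - 1, hours=hour) for d in day_numbers
            ],
        }
    )


def rx_rows(*rows):
    return pd.DataFrame(
        list(rows),
        columns=["is_antibiotic", "days_supplied", "continues_inpatient_regimen"],
    )
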
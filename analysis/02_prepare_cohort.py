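"""Apply the eligibility rules to the raw tables and audit every exclusion.

Rules, in attribution order: unparseable timestamps, age under 18,
obstetrics/pregnancy, repeat encounters (first admission kept), PCT drawn
more than 48 h after the first antibiotic dose, and ED discharges. Writes
eligible_cohort.csv plus a JSON audit sidecar.
"""

import argparse
import json
import logging
from pathlib import Path

from pctrda.pipeline import RunConfig, stage_prep, _Manifest

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

logging.basicConfig(level=logging.INFO, format="%(levelname)-7s %(message)s")
cfg = RunConfig(outdir=args.outdir)
cohort = stage_prep(cfg, _Manifest(cfg.outdir, cfg))

print(f"\n{cohort.n_raw} raw encounters -> {len(cohort.frame)} eligible")
print(json.dumps(dict(cohort.audit), indent=2))
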
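"""Classify each eligible encounter's antibiotic exposure.

Full course = >=4 distinct antibiotic calendar days inside a 5-day window
(rule a), a >=4-day discharge prescription (rule b), or an inpatient +
continuation-prescription total of >=4 days (rule c); otherwise partial
(any exposure) or none. The binary analysis outcome is full vs not-full.
"""

import argparse
import logging
from pathlib import Path

from pctrda.pipeline import RunConfig, stage_classify, _Manifest

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

logging.basicConfig(level=logging.INFO, format="%(levelname)-7s %(message)s")
cfg = RunConfig(outdir=args.outdir)
decisions = stage_classify(cfg, _Manifest(cfg.outdir, cfg))

n = len(decisions)
full = decisions["outcome_full"].sum()
print(f"\n{n} encounters classified; {full} ({100 * full / n:.1f}%) full course")
print("categories:", decisions["category"].value_counts().to_dict())
print("qualifying rule:", decisions["rule_fired"].value_counts().to_dict())
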
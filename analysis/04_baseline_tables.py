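"""Baseline comparison tables.

Two shapes: full-course vs partial/none over the whole eligible cohort, and
below vs above each pre-specified cut-point within its primary bandwidth
(the exchangeability check of the discontinuity design: near-threshold
groups should look alike at baseline).
"""

import argparse
import logging
from pathlib import Path

from pctrda.pipeline import RunConfig, stage_tables, _Manifest

parser = argparse.ArgumentParser()
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

logging.basicConfig(level=logging.INFO, format="%(levelname)-7s %(message)s")
cfg = RunConfig(outdir=args.outdir)
outputs = stage_tables(cfg, _Manifest(cfg.outdir, cfg))

for name, table in outputs:
    print(f"\n=== {name} (groups: {table.group_labels}) ===")
    print(table.render())
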
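#!/usr/bin/env python
"""Simulate the toy genome and call spread boundaries at every anchor.

Runs the full demo pipeline (simulate -> aggregate -> smooth -> infer) on
the 60 kb toy genome: two silencer-flanked silent loci, two telomere-like
ends with boundary elements, and a control region. Bulky intermediates
(per-read text, bedGraphs) go to scratch/; the boundary-call table and a
run summary go to results/.

Finding: every silencer and X-element anchor yields a boundary call;
methylation spreads several kb from each recruitment site and returns to
the control-region background, except where a neighboring locus's spread
overlaps the walk (reported as unbounded within the window).
"""

import json
import shutil
import sys
from pathlib import Path

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from sirspread.pipeline import RunConfig, run_pipeline  # noqa: E402

outdir = REPO / "scratch" / "analysis01"
results = REPO / "results"
results.mkdir(exist_ok=True)

cfg = RunConfig.from_yaml(REPO / "configs" / "demo.yaml", outdir=str(outdir))
manifest = run_pipeline(cfg)

shutil.copy(outdir / "boundaries.tsv", results / "01_boundaries.tsv")
with open(results / "01_run_summary.json", "w") as fh:
    json.dump(
        {"record_counts": manifest["record_counts"], "config": manifest["config"]},
        fh,
        indent=2,
    )
    fh.write("\n")

print((outdir / "boundaries.tsv").read_text())
print(f"tables: {results}/01_boundaries.tsv, {results}/01_run_summary.json")
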
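#!/usr/bin/env python
"""Boundary fixity under overexpression.

Doubles the recruitment-peak occupancy against a fixed, fully attenuating
boundary element and classifies the response of the methylation domain
(extended / increased_only / unchanged) per replicate pair.

Finding: more occupancy raises the methylation level across the existing
domain (level ratio ~2) but the boundary does not move (shifts of tens of
bp, far below the 500 bp extension threshold) — classified increased_only.
"""

import sys
from pathlib import Path

import pandas as pd

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from sirspread import evaluation as ev  # noqa: E402

results = REPO / "results"
results.mkdir(exist_ok=True)

res = ev.overexpression_fixity(n_reps=20, seed=2024)
pd.DataFrame([res]).to_csv(results / "04_overexpression_summary.tsv", sep="\t", index=False)
print(
    f"increased_only with |shift| <= 500 bp in {res['n_success']}/{res['n_reps']} "
    f"replicates; max |boundary shift| {res['max_abs_shift_bp']:.0f} bp; "
    f"categories {res['categories']}"
)
print(f"table: {results}/04_overexpression_summary.tsv")
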
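#!/usr/bin/env python
"""Recruitment without spread: the computational nucleosome-binding-mutant contrast.

Simulates matched replicate pairs of a wild-type-like configuration
(recruitment peaks plus kb-scale spread) and a spread-deficient one (same
peaks, spread decay collapsed to 1 bp), then compares spread extents and
anchor-interval methylation.

Finding: the spread-deficient configuration shows the same methylation over
the recruitment intervals (within a few percent) but a far smaller spread
extent at every anchor — recruitment and spread are separable readouts.
"""

import sys
from pathlib import Path

import pandas as pd

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from sirspread import evaluation as ev  # noqa: E402

results = REPO / "results"
results.mkdir(exist_ok=True)

res = ev.contrast_recovery(n_reps=20, seed=2024)
pd.DataFrame([res]).to_csv(results / "03_contrast_summary.tsv", sep="\t", index=False)
print(
    f"spread-deficient < wild-type extent at every anchor in "
    f"{res['n_success']}/{res['n_reps']} replicate pairs; "
    f"mean anchor-methylation relative difference "
    f"{100 * res['mean_anchor_rel_diff']:.1f}%"
)
print(f"table: {results}/03_contrast_summary.tsv")
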